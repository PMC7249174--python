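"""Five co-solvency correlation models and RMSD%/R^2 model comparison.

Implemented models for the mole-fraction solubility x of a solute in a
binary (co-solvent + anti-solvent) mixture at mass fraction m1 of
co-solvent (m2 = 1 - m1) and temperature T:

  van't Hoff           ln x = a + b/T                      (per series)
  Apelblat             ln x = A + B/T + C ln T             (per series)
  Yalkowsky-Roseman    log10 x = m1 log10 x1 + m2 log10 x2
  Jouyban-Acree        ln x = m1 ln x1 + m2 ln x2
                              + (m1 m2 / T) sum_i J_i (m1 - m2)^i
  Jouyban-Acree-van't Hoff: as above with the pure-solvent terms
                       replaced by fitted van't Hoff lines
                       m1 (A1 + B1/T) + m2 (A2 + B2/T)

x1, x2 are the solubilities in pure co-solvent and pure anti-solvent.
The comparison metric is the percentage root-mean-square of relative
deviations per composition series; a model's overall RMSD% is the
unweighted mean of its per-series values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset_io import SolubilityGrid
from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    MissingEndpointError,
)


def rmsd_percent(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """100 * sqrt(mean(((obs - pred) / obs)^2)).

    The relative-deviation convention makes series spanning four orders
    of magnitude of solubility comparable on one scale.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise InvalidInputError(
            "observed and predicted must be equal-length, non-empty"
        )
    if np.any(obs == 0):
        raise InvalidInputError("observed solubilities must be nonzero")
    return float(100.0 * np.sqrt(np.mean(((obs - pred) / obs) ** 2)))


# ---------------------------------------------------------------------------
# single-series temperature models


@dataclass(frozen=True)
class VantHoffFit:
    """ln x = a + b/T for one composition series."""

    a: float
    b: float
    r_squared: float
    rmsd_percent: float

    def predict(self, temperature) -> np.ndarray | float:
        t = np.asarray(temperature, dtype=float)
        out = np.exp(self.a + self.b / t)
        return float(out) if np.isscalar(temperature) else out


def fit_vant_hoff(
    temperatures: Sequence[float], x_exp: Sequence[float]
) -> VantHoffFit:
    """OLS of ln x on 1/T; RMSD% on the back-transformed predictions."""
    t = np.asarray(temperatures, dtype=float)
    x = np.asarray(x_exp, dtype=float)
    _check_series(t, x, min_temps=2)
    reg = stats.linregress(1.0 / t, np.log(x))
    fit = VantHoffFit(
        a=reg.intercept, b=reg.slope, r_squared=reg.rvalue**2,
        rmsd_percent=0.0,
    )
    pred = np.exp(reg.intercept + reg.slope / t)
    object.__setattr__(fit, "rmsd_percent", rmsd_percent(x, pred))
    return fit


@dataclass(frozen=True)
class ApelblatFit:
    """ln x = A + B/T + C ln T for one composition series.

    The model is linear in (A, B, C) and is fitted by least squares in
    the basis (1, 1/T, ln T).  Over a narrow temperature window 1/T and
    ln T are nearly collinear, so individual coefficients are poorly
    determined even when predictions are excellent;
    ``conditioning_warning`` records when the basis is ill-conditioned.
    """

    A: float
    B: float
    C: float
    r_squared: float
    rmsd_percent: float
    conditioning_warning: str | None = None

    def predict(self, temperature) -> np.ndarray | float:
        t = np.asarray(temperature, dtype=float)
        out = np.exp(self.A + self.B / t + self.C * np.log(t))
        return float(out) if np.isscalar(temperature) else out


def fit_apelblat(
    temperatures: Sequence[float], x_exp: Sequence[float]
) -> ApelblatFit:
    t = np.asarray(temperatures, dtype=float)
    x = np.asarray(x_exp, dtype=float)
    _check_series(t, x, min_temps=3)
    basis = np.column_stack([np.ones_like(t), 1.0 / t, np.log(t)])
    # column scaling tames the severe 1/T vs ln T collinearity over
    # narrow temperature windows without changing the fitted subspace
    norms = np.linalg.norm(basis, axis=0)
    scaled, _, rank, _ = np.linalg.lstsq(basis / norms, np.log(x), rcond=None)
    coeffs = scaled / norms
    warning = None
    cond = np.linalg.cond(basis)
    if rank < 3 or cond > 1e12:
        warning = (
            f"near-collinear basis (condition number {cond:.3g}); "
            "coefficients are not individually meaningful, predictions are"
        )
    ln_pred = basis @ coeffs
    ln_x = np.log(x)
    ss_res = float(np.sum((ln_x - ln_pred) ** 2))
    ss_tot = float(np.sum((ln_x - ln_x.mean()) ** 2))
    return ApelblatFit(
        A=float(coeffs[0]), B=float(coeffs[1]), C=float(coeffs[2]),
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        rmsd_percent=rmsd_percent(x, np.exp(ln_pred)),
        conditioning_warning=warning,
    )


# ---------------------------------------------------------------------------
# mixture models


def predict_yalkowsky(x1: float, x2: float, m1) -> float | np.ndarray:
    """Log-linear mixing rule: log10 x = m1 log10 x1 + (1-m1) log10 x2.

    ``x1`` and ``x2`` are the measured solubilities in pure co-solvent
    and pure anti-solvent at the same temperature.  Returns the base-10
    logarithm of the predicted mixed-solvent solubility.
    """
    if x1 <= 0 or x2 <= 0:
        raise InvalidInputError("pure-solvent solubilities must be positive")
    m = np.asarray(m1, dtype=float)
    if np.any((m < 0) | (m > 1)):
        raise InvalidInputError("mass fraction must lie in [0, 1]")
    out = m * np.log10(x1) + (1.0 - m) * np.log10(x2)
    return float(out) if np.isscalar(m1) else out


@dataclass(frozen=True)
class JouybanAcreeFit:
    """Fitted interaction coefficients of the Jouyban-Acree model.

    ``j_coeffs[i]`` multiplies m1*m2*(m1-m2)^i / T (units of K).  In the
    pure variant the mono-solvent terms use the measured endpoint
    solubilities at each grid temperature (``endpoint_ln_x``); in the
    combined variant they come from van't Hoff lines with coefficients
    (A1, B1) and (A2, B2) and the model extrapolates in temperature.
    """

    j_coeffs: tuple[float, ...]
    with_vant_hoff_terms: bool
    rmsd_percent: float
    per_series_rmsd: dict[float, float] = field(default_factory=dict)
    A1: float | None = None
    B1: float | None = None
    A2: float | None = None
    B2: float | None = None
    endpoint_ln_x: dict[float, tuple[float, float]] = field(
        default_factory=dict, repr=False
    )

    def interaction(self, m1, temperature) -> np.ndarray | float:
        """The excess term (m1 m2 / T) sum_i J_i (m1-m2)^i; 0 at m1 in {0,1}."""
        m = np.asarray(m1, dtype=float)
        t = np.asarray(temperature, dtype=float)
        m2 = 1.0 - m
        acc = np.zeros(np.broadcast(m, t).shape)
        for i, j in enumerate(self.j_coeffs):
            acc = acc + j * (m - m2) ** i
        out = m * m2 / t * acc
        return float(out) if np.isscalar(m1) and np.isscalar(temperature) else out

    def predict_ln(self, m1: float, temperature: float) -> float:
        if self.with_vant_hoff_terms:
            ln1 = self.A1 + self.B1 / temperature
            ln2 = self.A2 + self.B2 / temperature
        else:
            try:
                ln1, ln2 = self.endpoint_ln_x[temperature]
            except KeyError:
                raise InvalidInputError(
                    f"pure-endpoint variant has no measured endpoints at "
                    f"T={temperature}; refit with van't Hoff terms to "
                    f"extrapolate in temperature"
                ) from None
        return (
            m1 * ln1 + (1.0 - m1) * ln2
            + self.interaction(m1, temperature)
        )

    def predict(self, m1: float, temperature: float) -> float:
        return float(np.exp(self.predict_ln(m1, temperature)))


def fit_jouyban_acree(
    grid: SolubilityGrid,
    order: int = 2,
    combined_with_vant_hoff: bool = False,
) -> JouybanAcreeFit:
    """Fit the Jouyban-Acree interaction polynomial to a solubility grid.

    The excess log-solubility y = ln x_m - m1 ln x1 - m2 ln x2 of every
    mixed-composition sample is regressed without intercept on the
    basis functions m1*m2*(m1-m2)^i / T for i = 0..order.  The pure
    variant takes ln x1, ln x2 from the measured pure-solvent samples
    at the same temperature; the combined variant first fits van't Hoff
    lines to both pure series and uses those modelled endpoints both in
    the excess and in prediction.

    Per-series RMSD% covers the mixed compositions; the combined
    variant also scores the two pure series (whose predictions are the
    fitted van't Hoff lines, not identities).
    """
    if order not in (0, 1, 2):
        raise InvalidInputError(f"order must be 0, 1 or 2, got {order}")
    comps = grid.compositions()
    if 0.0 not in comps or 1.0 not in comps:
        raise MissingEndpointError(
            "grid must contain both pure-solvent series (m=0 and m=1)"
        )
    mixed = [m for m in comps if 0.0 < m < 1.0]
    if not mixed:
        raise InsufficientDataError(
            "grid has no mixed composition to estimate interaction terms"
        )

    t1, x1 = grid.series(1.0)
    t2, x2 = grid.series(0.0)

    if combined_with_vant_hoff:
        vh1 = fit_vant_hoff(t1, x1)
        vh2 = fit_vant_hoff(t2, x2)
        ln_endpoint = {
            t: (vh1.a + vh1.b / t, vh2.a + vh2.b / t)
            for t in grid.temperatures()
        }
    else:
        lookup1 = dict(zip(t1, np.log(x1)))
        lookup2 = dict(zip(t2, np.log(x2)))
        missing = [
            t for t in grid.temperatures()
            if t not in lookup1 or t not in lookup2
        ]
        if missing:
            raise MissingEndpointError(
                f"pure-solvent measurements missing at T={missing}"
            )
        ln_endpoint = {t: (lookup1[t], lookup2[t]) for t in grid.temperatures()}

    rows, ys = [], []
    for s in grid.samples:
        m1 = s.mass_fraction_cosolvent
        if m1 in (0.0, 1.0):
            continue
        m2 = 1.0 - m1
        ln1, ln2 = ln_endpoint[s.temperature]
        ys.append(np.log(s.x_exp) - m1 * ln1 - m2 * ln2)
        rows.append(
            [m1 * m2 * (m1 - m2) ** i / s.temperature
             for i in range(order + 1)]
        )
    design = np.array(rows)
    j, *_ = np.linalg.lstsq(design, np.array(ys), rcond=None)

    fit = JouybanAcreeFit(
        j_coeffs=tuple(float(v) for v in j),
        with_vant_hoff_terms=combined_with_vant_hoff,
        rmsd_percent=0.0,
        A1=vh1.a if combined_with_vant_hoff else None,
        B1=vh1.b if combined_with_vant_hoff else None,
        A2=vh2.a if combined_with_vant_hoff else None,
        B2=vh2.b if combined_with_vant_hoff else None,
        endpoint_ln_x=ln_endpoint,
    )
    scored = comps if combined_with_vant_hoff else mixed
    per_series = {}
    for m in scored:
        t, x = grid.series(m)
        pred = np.array([fit.predict(m, ti) for ti in t])
        per_series[m] = rmsd_percent(x, pred)
    object.__setattr__(fit, "per_series_rmsd", per_series)
    object.__setattr__(
        fit, "rmsd_percent", float(np.mean(list(per_series.values())))
    )
    return fit


# ---------------------------------------------------------------------------
# model comparison


@dataclass(frozen=True)
class ModelComparison:
    """Per-series and overall RMSD% for one model on one grid."""

    model: str
    per_series_rmsd: dict[float, float]
    overall_rmsd: float | None
    status: str = "ok"
    coefficients: dict = field(default_factory=dict)


MODEL_NAMES = (
    "vanthoff",
    "apelblat",
    "yalkowsky",
    "jouyban_acree",
    "jouyban_acree_vanthoff",
)


def _per_series_comparison(grid, name, fitter, coeff_fields):
    per, coeffs = {}, {}
    for m in grid.compositions():
        t, x = grid.series(m)
        f = fitter(t, x)
        per[m] = f.rmsd_percent
        coeffs[m] = {k: getattr(f, k) for k in coeff_fields}
    return ModelComparison(
        model=name,
        per_series_rmsd=per,
        overall_rmsd=float(np.mean(list(per.values()))),
        coefficients=coeffs,
    )


def yalkowsky_comparison(grid: SolubilityGrid) -> ModelComparison:
    """Score the log-linear mixing rule on every mixed composition.

    Predictions at each (m, T) blend the measured pure-solvent
    solubilities at that temperature; pure series are identities and
    are not scored.
    """
    comps = grid.compositions()
    if 0.0 not in comps or 1.0 not in comps:
        raise MissingEndpointError(
            "grid must contain both pure-solvent series (m=0 and m=1)"
        )
    mixed = [m for m in comps if 0.0 < m < 1.0]
    if not mixed:
        return ModelComparison(
            model="yalkowsky", per_series_rmsd={}, overall_rmsd=None,
            status="no mixed compositions: the mixing rule has nothing to "
                   "predict beyond its fixed endpoints",
        )
    t1, x1 = grid.series(1.0)
    t2, x2 = grid.series(0.0)
    lookup1, lookup2 = dict(zip(t1, x1)), dict(zip(t2, x2))
    per, logs = {}, {}
    for m in mixed:
        t, x = grid.series(m)
        try:
            log_pred = np.array(
                [predict_yalkowsky(lookup1[ti], lookup2[ti], m) for ti in t]
            )
        except KeyError as err:
            raise MissingEndpointError(
                f"pure-solvent measurement missing at T={err.args[0]}"
            ) from None
        per[m] = rmsd_percent(x, 10.0 ** log_pred)
        logs[m] = dict(zip(t, log_pred))
    return ModelComparison(
        model="yalkowsky",
        per_series_rmsd=per,
        overall_rmsd=float(np.mean(list(per.values()))),
        coefficients={"log10_prediction": logs},
    )


def compare_models(
    grid: SolubilityGrid,
    jouyban_order: int = 2,
    models: Sequence[str] = MODEL_NAMES,
) -> list[ModelComparison]:
    """Run the requested co-solvency models on one grid.

    Mixture models that cannot run on a degenerate grid (e.g. no mixed
    composition) are reported with an empty comparison and an
    explanatory status rather than raising.
    """
    unknown = set(models) - set(MODEL_NAMES)
    if unknown:
        raise InvalidInputError(f"unknown model(s): {sorted(unknown)}")
    out: list[ModelComparison] = []
    for name in models:
        if name == "vanthoff":
            out.append(_per_series_comparison(
                grid, name, fit_vant_hoff, ("a", "b", "r_squared")))
        elif name == "apelblat":
            out.append(_per_series_comparison(
                grid, name, fit_apelblat, ("A", "B", "C", "r_squared")))
        elif name == "yalkowsky":
            out.append(yalkowsky_comparison(grid))
        else:
            combined = name == "jouyban_acree_vanthoff"
            try:
                f = fit_jouyban_acree(
                    grid, order=jouyban_order,
                    combined_with_vant_hoff=combined,
                )
            except (MissingEndpointError, InsufficientDataError) as err:
                out.append(ModelComparison(
                    model=name, per_series_rmsd={}, overall_rmsd=None,
                    status=str(err),
                ))
                continue
            coeffs = {"j_coeffs": f.j_coeffs}
            if combined:
                coeffs.update(A1=f.A1, B1=f.B1, A2=f.A2, B2=f.B2)
            out.append(ModelComparison(
                model=name,
                per_series_rmsd=f.per_series_rmsd,
                overall_rmsd=f.rmsd_percent,
                coefficients=coeffs,
            ))
    return out


def _check_series(t: np.ndarray, x: np.ndarray, min_temps: int) -> None:
    if t.shape != x.shape:
        raise InvalidInputError("temperatures and x_exp differ in length")
    if np.unique(t).size < min_temps:
        raise InsufficientDataError(
            f"need >= {min_temps} distinct temperatures"
        )
    if np.any((x <= 0) | (x >= 1)):
        raise InvalidInputError("x values must lie in (0, 1)")
    if np.any(t <= 0):
        raise InvalidInputError("temperatures must be positive")
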