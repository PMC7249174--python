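# Methods

## Scope and data model

`cosolve` analyses saturation mole-fraction solubility surfaces
x(m, T) of one solute in a binary solvent blend: m is the solute-free
mass fraction of the co-solvent, T the absolute temperature in kelvin.
The central container (`SolubilityGrid`) enforces the physical
invariants up front — x strictly inside (0, 1), T > 0, unique (m, T)
keys — because every downstream model works on ln x or log₁₀ x and a
silently clamped or duplicated value would corrupt the fits.
Validation therefore rejects rather than repairs.

## The bundled reference dataset

The reference grid is the published solubility of baricitinib in
DMSO + water: 11 compositions × 5 temperatures (298.2, 303.2, 308.2,
313.2, 323.2 K) at 0.1 MPa, with reported standard deviations.  One
printed cell, (m = 0.2, T = 323.2 K) = 7.05 × 10⁻⁵, breaks the
otherwise universal monotone increase of solubility with temperature
and contradicts the van't Hoff correlation published for that same
series (a = 16.31, b = −7610.3 K predicts ≈ 7.2 × 10⁻⁴ at 323.2 K).
We read it as a power-of-ten typo and store 7.05 × 10⁻⁴, recording the
correction in the grid's machine-readable provenance notes;
`load_reference_dataset(corrected=False)` returns the verbatim table.
The published molar masses are kept as defaults — including water at
18.07 g/mol rather than the standard 18.015 — because reproduction of
the published mole fractions, not metrological accuracy, is the
purpose of the bundled constants; callers may supply their own
`SoluteConstants`.

## Ideal solubility and activity coefficients

Ideal solubility uses the full fusion expression including the ΔCp
term, with R = 8.314 J/mol/K fixed (the value consistent with the
reference study's derived quantities).  For baricitinib
(T_fus = 487.42 K, ΔH_fus = 41.11 kJ/mol, ΔCp = 84.34 J/mol/K) this
gives 6.842 × 10⁻³ at 298.2 K up to 1.548 × 10⁻² at 323.2 K.  The
published table prints 1.54 × 10⁻² and a handful of last digits of
γ = x_idl/x_e differ from full-precision recomputation by one rounding
step (e.g. printed 0.21 vs recomputed 0.217 in pure DMSO at 298.2 K);
the authors' intermediate precision is unknowable, so tests compare
those cells at 1% relative tolerance while computation always keeps
full precision and rounding happens only in the report layer.

## Apparent dissolution thermodynamics

Per composition, ln x_e is regressed by ordinary least squares on
(1/T − 1/T_hm), where T_hm = n/Σ(1/Tᵢ) is the harmonic-mean
temperature of the study window (308.96 K for the reference
temperatures).  Centring the regressor at 1/T_hm decorrelates slope
and intercept, so ΔG = −R·T_hm·intercept is read directly off the
intercept while the slope (hence ΔH = −R·slope) is identical to the
uncentred regression.  ΔS = (ΔH − ΔG)/T_hm holds as an identity by
construction.  The same T_hm is shared across compositions so the ΔG
values are comparable.

A known reproduction limit: the reference study's ΔH for pure water
(64.85 kJ/mol) is not recoverable from the rounded published
solubility table by plain OLS (recomputation gives ≈ 63.7 kJ/mol,
≈ 2% low), while the pure-DMSO row reproduces within 0.4%; the authors
most plausibly fitted unrounded replicate-level data.  ΔG, dominated
by the intercept, is robust (reproduces within 0.1%), so tests pin ΔG
tightly and ΔH loosely.

Enthalpy–entropy compensation is an unweighted OLS of ΔH on ΔG across
compositions.  No weighting scheme is specified anywhere for the
"weighted" compensation plot, and unweighted OLS on the published
per-composition thermodynamic table reproduces the published slope
0.64 exactly; on the refitted chain the slope is 0.61, the difference
being the ~2% ΔH reproduction limit above.  The published
thermodynamic table is bundled (`reference.PUBLISHED_THERMO`) so that
the compensation analysis can be run on either input; the CLI reports
both.

## Co-solvency models

All temperature-dependent models are fitted in ln space, matching the
convention of the field; the Yalkowsky–Roseman rule is base-10 as it
is conventionally typeset.  Numerical choices:

- **van't Hoff** — `scipy.stats.linregress` of ln x on 1/T.
- **Apelblat** — the model is linear in (A, B, C), so it is solved by
  least squares in the basis (1, 1/T, ln T) rather than iterative
  nonlinear search.  Over a 25 K window, 1/T and ln T are nearly
  collinear (condition number ~5 × 10⁶ raw); the basis columns are
  norm-scaled before the SVD solve, which restores prediction-space
  accuracy to ~10⁻¹³ relative.  Coefficient values are consequently
  not individually meaningful — prediction space is the correct test
  surface, and a conditioning warning is attached to the fit when the
  basis is effectively rank-deficient.
- **Jouyban–Acree** — the excess y = ln x_m − m₁ln x₁ − m₂ln x₂ is
  regressed without intercept on m₁m₂(m₁ − m₂)ⁱ/T, i = 0..order
  (default order 2, configurable 0–2).  In the pure variant the
  endpoint terms are the measured pure-solvent solubilities at each
  grid temperature (both endpoint series are required), so only mixed
  compositions are scored; in the combined (van't Hoff) variant the
  endpoints are fitted lines, every series including the pure ones is
  a genuine prediction and all are scored.
- **RMSD%** — 100·√(mean of squared relative deviations) per series;
  overall = unweighted mean over the scored series.  This convention
  is validated by the reference study's own log-linear-rule table,
  whose printed overall 1.26% is exactly the mean of its nine printed
  per-series values.  The reference study's printed per-series values
  for the water-rich mixtures are noticeably lower than full-precision
  recomputation (1.47 vs 2.38 at m = 0.1); they are consistent with
  RMSD computed from predictions rounded to the printed two-decimal
  logarithms, and the printed overall RMSDs of the Jouyban-type models
  (0.98% / 0.76%) are consistent with deviations measured on
  logarithmic rather than linear solubility.  We keep one metric — the
  relative deviation on x — for all five models; under it every model
  stays below 5% overall on the reference grid, which is the
  scientifically meaningful claim.
- The reference study's single printed interaction coefficient
  Ji = 82,431 K is dimensionally irreconcilable with its own data: at
  m = 0.5 it would contribute ≈ 69 ln-units where the measured excess
  is ≈ 0.006.  The fitted coefficients (≈ 16, −8, 29 K at order 2) are
  reported as-is.

## Synthetic surfaces

The generator draws from the combined Jouyban–Acree–van't Hoff form —
the most general model in the package, which nests the van't Hoff
endpoints and the log-linear blend as special cases.  Noise is
multiplicative lognormal with coefficient of variation `noise_cv`,
mean-zero on the ln scale (σ² = ln(1 + cv²)): since every model here
is fitted by least squares in log space, this makes coefficient
recovery unbiased in expectation and lets the Monte-Carlo recovery
tests use plain two-standard-error bounds.  Defaults mimic the
reference system: endpoint coefficients equal to its fitted
pure-solvent van't Hoff lines (18.21, −6445.3; 15.53, −7808.8),
11 × 5 grid at the study temperatures, and noise_cv = 0.012, the
study's stated mean relative uncertainty of x_e; interaction
coefficients default to (600, 200, 100) K, which produce a sub-unit
ln-excess of realistic magnitude.  What the generator does not
emulate: replicate-level shake-flask structure, heteroscedastic or
temperature-dependent error, and any lack of fit of the generating
form itself — so passing recovery tests demonstrate estimator
correctness, not that real surfaces follow the model.

## Problem sizes and determinism

Every analysis in the test suite and acceptance script is desk-scale:
55-cell grids, five-point regressions, and a 200-replicate Monte-Carlo
recovery study (seconds in total).  The analysis chain itself contains
no randomness; only the synthetic generator consumes a seed (numpy
PCG64, recorded in grid provenance), so repeated runs of `cosolve fit`
on the same input produce byte-identical JSON.

## Limitations

Binary solvent systems only; no group-contribution HSP estimation
(component δd/δp/δh are user inputs); no replicate-level uncertainty
propagation — the reported standard deviations are carried through I/O
but not used as regression weights; Apelblat coefficients should not
be interpreted individually (see conditioning note above).
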