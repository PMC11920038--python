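# Methods

## One-ligand competitive-exchange model

The titration model assumes a single ligand class L with conditional
stability constant `K = [FeL]/([Fe'][L'])` (L/mol, referenced to inorganic
iron Fe', the sum of hydrolysis species) and an added competing ligand
(salicylaldoxime, SA) summarised by its side-reaction coefficient
`α_SA = K₁[SA] + β₂[SA]²` (the bis complex Fe(SA)₂ is off by default).
Mass balance

```
Fe_T = [Fe'](1 + α_SA) + K [Fe'] L_T / (1 + K [Fe'])
```

is a quadratic `a f² + b f + c = 0` in `f = [Fe']` with
`a = K(1+α_SA)`, `b = (1+α_SA) + K(L_T − Fe_T)`, `c = −Fe_T`. Because
`c ≤ 0` the discriminant satisfies `b² − 4ac ≥ b²`, the equation has exactly
one non-negative root, and the cancellation-free form
`q = −(b + sign(b)√(b²−4ac))/2`, roots `q/a` and `c/q`, avoids the
catastrophic subtraction that the textbook formula suffers when
`b² ≫ |4ac|` (weak binding or trace iron). Concentrations are mol/L
internally; titration interfaces are nmol/L. `Fe_T = 0` returns the all-zero
state. The test suite checks the closed form against an independent
bisection root-finder on the mass-balance residual over 1000 random
parameter draws (1e-10 relative) and asserts mass closure in a property
test.

### Side-reaction coefficient

The Fe'–SA constants are a configuration input, not a measured quantity of
this package. The shipped defaults, `log K₁' = 6.45` and `log β₂' = 10.72`
for seawater at pH ≈ 8.2, are drawn from the CLE-AdCSV literature for
salicylaldoxime; at the standard 5 µM SA they give α_SA ≈ 14.1 (mono
complex only). All internal consistency checks are simulate→fit loops with
the same α_SA on both sides, so none of the package's verified results
depend on this choice; users analysing real titrations should set the
constants appropriate to their method.

### Fitters

*Sensitivity* (peak current per mol/L FeSA) defaults to internal
calibration: the OLS slope of peak current on total Fe over the last 3
titration points, multiplied by `(1+α_SA)/α_SA` — once the ligand is
saturated, each Fe increment partitions between Fe' and FeSA in the fixed
ratio `α_SA/(1+α_SA)`. With additions to only 9 nmol/L and 2 nmol/L of
strong ligand the tail is not fully saturated and the calibration is biased
low by ≲1%; a known sensitivity can be passed explicitly.

*Linearisation.* `y = [Fe']/[FeL]` on `x = [Fe']` gives `L_T = 1/slope`,
`K = slope/intercept`. Points whose back-calculated [FeL] is non-positive
are dropped with a warning (fewer than 3 survivors is an error). Standard
errors come from the OLS covariance by the delta method, using
`Cov(b₀,b₁) = −x̄·Var(b₁)`. The transform is fragile for strong ligands
under noise — the intercept `1/(K·L_T)` is tiny and readily fits negative —
in which case the fit fails loudly rather than returning a negative K.

*Nonlinear fit* minimises squared residuals of observed vs modelled peaks
over `(L_T, log K, log₁₀ sensitivity)` with `scipy.optimize.least_squares`
(bounds 6 ≤ log K ≤ 16, L_T ≥ 0; residuals scaled by the peak maximum so
fits are invariant to common rescaling of currents and sensitivity).
Initialisation is the linearised fit when it succeeds, otherwise a
heuristic start: L_T from the x-intercept of the saturated tail line (the
classic graphical estimate) and log K from a coarse grid (9.0–13.5, step
0.25) at that L_T. Since the optimiser starts at the initialisation, the
residual sum never increases relative to it. Standard errors are asymptotic
(Jacobian-based). Under the reference conditions (L_T = 2 nmol/L,
log K = 11.3, 10 points over 0–9 nmol/L additions, 2% multiplicative
noise), 100 Monte-Carlo replicates fit with median |L_T error| ≈ 3–4% and
mean log K bias < 0.02.

## Humic equivalence and the capacity criterion

The substance table carries, per candidate (bacterial / phytoplankton /
in-situ EPS, poly- and monosaccharides, Suwannee River FA and HA):
carbohydrate content (mg C-Carb/mg), eHS content (mg eHS/mg, SRFA-mass
equivalents), Fe-binding capacity (nmol Fe/mg) and log K_Fe'L. Reported
spreads and observation counts are carried as metadata only; no error
propagation is performed.

The chain is linear: `L_X = eHS(mg/L)/c_eHS × q_Fe`, contribution
`= 100·L_X/Fe-L`. Contributions far above 100% are meaningful — they say
the substance pool would only need a small Fe saturation
(`100·Fe-L/L_X` %) to supply the whole in-situ ligand pool.

**HA convention.** HA has no measured eHS content; the pipeline treats it
as unit eHS mass (1.0 mg eHS/mg), consistent with the SRFA-equivalent
scale on which eHS is calibrated (FA itself measures 1.02 ≈ 1). The default
is exposed (`ha_ehs_default`) because the alternative — leaving HA out of
the equivalence — is also defensible.

**Complexing capacity** is reported as `log₁₀(eL × K)` with the excess
ligand eL = Fe-L − DFe in mol/L. The product's units are conventional;
because all comparisons are differences of the same form, the unit choice
shifts every value by a constant and never changes an ordering. Capacities
for eL ≤ 0 (ligands saturated with Fe) are undefined: they are flagged,
excluded from aggregates, and counted, not imputed. For the substance-side
capacity the substance's own log K is paired with the *record's* eL,
mirroring how the criterion is used in the field.

Box summaries report mean, sample SD and 5th/95th percentiles
(linear-interpolation percentile method).

## Synthetic data

The generator emulates the joint structure the analysis assumes, at the
study's scales:

| parameter | default | origin |
|---|---|---|
| eHS surface / deep mean | 75.7 / 39.9 µg/L | observed surface (0–100 m) and deep means |
| eHS lognormal CV | 0.8 | matches the reported surface SD/mean ≈ 1 |
| Fe-L ~ eHS intercept, slope | 1.3 nmol/L, 0.045 nmol/µg | observed circumpolar regression |
| Fe-L noise SD | 0.5 nmol/L | package convention |
| log K mean, SD | 11.28, 0.46 | observed distribution |
| DFe fraction of Fe-L | Beta(1.5, 3.5), mean 0.3 | package convention; keeps ligands in excess |
| depth grid | 0–1000 m, 7 levels | study's sampling span |
| Carb surface/deep mean | 200 / 50 µg/L glucose-eq | plausible labile-DOM scales |
| bacteria surface/deep | 5×10⁵ / 4×10⁴ cells/mL | typical marine abundances |

Depth profiles of the means relax exponentially from the surface to the
deep value with a 100 m e-folding scale (the surface/deep split of the
summary statistics is at 100 m). Lognormal draws are parameterised by
arithmetic mean and CV; Gaussian Fe-L noise is resampled (not clipped) when
a draw lands non-positive. DFe is a Beta fraction of Fe-L, so ligand excess
holds by construction. All draws derive from one `numpy` Generator seeded
explicitly; titration collections spawn per-curve seeds from a
`SeedSequence`, so outputs are byte-reproducible from (config, seed).

What the generator does **not** emulate: spatial/circumpolar structure and
water masses, any DFe–eHS decoupling (synthetic DFe inherits the eHS signal
through Fe-L, whereas the two are uncorrelated in the southernmost ocean),
colloids, multiple ligand classes, and non-Gaussian titration noise.
Passing tests therefore demonstrate correctness of the estimators under the
stated model, not field performance.

## Statistics conventions

Pearson correlations use pairwise deletion (per-pair n), two-sided p from
the exact t-transform with n−2 df, significance flagged at 0.05, no
multiple-testing correction. PCA uses complete cases, z-scored variables
(correlation-matrix eigendecomposition), loadings = eigenvectors ×
√eigenvalue, communalities over PC1–2, and a fixed sign convention (the
largest-magnitude loading of each component is positive) for
reproducibility; near-zero eigenvalues reduce the component count with a
warning.

## Problem sizes and numerical choices

Verification runs use: 1000 random draws for the solver-vs-bisection check
(1e-10 relative), 100 curves for Monte-Carlo recovery, ~500 rows (72
stations × 7 depths) for regression self-consistency, and ~10⁴ draws for
the law-of-large-numbers check on generator marginals (3% tolerance). The
displayed EPS capacity bounds (415, 602 nmol Fe per mg eHS) are
round-half-even integers at display time only; internal values stay full
precision. Degenerate inputs fail loudly and specifically: flat titration
tails raise a degenerate-fit error, curves shorter than 5 points are
rejected at construction, zero total iron yields the zero state, and eL ≤ 0
capacities propagate as flagged NaN rather than exceptions inside the
pipeline.

## Known limitations

* One ligand class only; multi-class titration resolution is out of scope.
* No voltammogram signal processing — the input is the already-reduced
  (Fe added, peak current) series.
* The Fe'–SA constants are literature defaults, not calibrated here; the
  detection window they imply (centred near `K ≈ α_SA/L`) bounds which
  log K values a titration can actually resolve.
* The equivalence arithmetic assumes 1:1 Fe:L binding, a single behaviour
  per substance, and no competition from other metals; substance-side
  numbers are upper estimates by construction.
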