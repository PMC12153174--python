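# Methods

## Scope and model structure

`allomprop` implements a compatible individual-tree prediction system for
one species group and the Monte Carlo machinery to propagate its model
error into post-stratified population estimates. "Compatible" means the
components are constrained to add up: outside-bark volume is the sum of
inside-bark and bark volume by construction; stem-wood, bark, and branch
biomass are proportionally rescaled (harmonized) to sum to the directly
predicted aboveground total; carbon is harmonized biomass times a common
carbon fraction, so carbon additivity follows automatically. Merchantable
components are tied to whole-stem components through the volume-ratio
curve, and merchantable biomass uses *realized* specific gravities
(harmonized stem biomass over predicted stem volume), which keeps the
merchantable chain consistent with the harmonized whole-stem chain.

The four regression forms and the residual-SD functions are listed in the
README. Assumptions worth making explicit:

- Model errors are treated as independent across component models. The
  component models are fitted to different, partially overlapping
  datasets, and cross-model residual correlations are not modelled; this
  makes the model variances of sum components approximately additive.
- Residual deviates are independent across trees within a replicate,
  while coefficient draws and the WDSG/CF perturbations are shared by all
  trees in a replicate. Shared draws are what create model variance in
  population totals: tree-level residual noise largely averages out over
  ~900 trees, whereas a coefficient draw shifts every tree the same way.
  The alternative reading (a single residual deviate shared by all trees)
  would make residual error behave like parameter error; independence per
  tree is the standard hybrid-inference interpretation and is the
  default. Both sit behind the same configuration surface.
- WDSG and CF enter as population means with standard errors of the mean,
  not per-tree random effects.

## Fitting

Each component model is fitted by unweighted nonlinear least squares
(Levenberg–Marquardt, convergence 1e-8 on parameter/function change,
generous evaluation budget). Starting values come from OLS on the
log-linearised model; the damping coefficient of the exponential form
starts at 0, and the upper-segment exponent of the segmented form starts
at the common exponent b (so the start is the plain power law — starting
that coefficient at 0 puts the segmented form in a pathological corner).
Fit quality is reported as pseudo-R² (1 − SSE/SST) with a residual
summary.

Coefficient uncertainty is approximated by a nonparametric bootstrap:
B refits on with-replacement resamples, resampled at the TREE level so
that the many correlated stem-profile rows of one tree enter or leave
together. Refits start from the full-data estimate; a failed refit redraws
its resample (up to 10 times) so the ensemble size stays exact, and a
refit returning a non-positive scale coefficient counts as failed.

Residual heteroscedasticity is summarised by ordering observations,
cutting them into floor(n/25) equal-sized sequential groups (remainder
into the last group), and fitting the power or bell SD function to the
group (mean prediction, residual SD) pairs by least squares, with
positivity of φ1 (and of φ2 in the bell form) enforced through a log
reparameterisation. The default ordering is by observed value, following
the published procedure. Note a subtlety we document because it matters
for validation: ordering by observed value selects on the noise itself
(within a narrow observed-value window the "residual SD" partly measures
the spread of predictions at a given observation), which biases the
recovered SD function when the truth is known. The package therefore also
supports ordering by predicted value; the calibration study in the test
suite uses that mode, and compares the fitted scale against the exact
expectation of a group-SD estimator (the normal-sample c4 factor at group
size 25).

## Monte Carlo propagation

Per replicate r: draw one coefficient vector per model uniformly from its
ensemble; draw WDSG_r and CF_r as mean + z·se with truncated-normal z
(|z| ≤ 3, rejection sampling); then per tree, follow the prediction chain
(volumes → stem biomass via WDSG → direct bark/branch/aboveground biomass
→ harmonization → carbon → realized specific gravities → merchantable
components), adding z·σ(ŷ) residual noise at every regression prediction,
including the ratio curve at both window bounds. Perturbed ratios are
clamped to [0,1] and the window to ≥0; merchantable bark volume is
obtained by subtraction (outside-bark minus inside-bark merchantable) so
additivity is preserved by construction, with the inside-bark part capped
at the outside-bark total when noise would invert them (counted). Negative
perturbed predictions are clamped to zero and counted; a tree whose
perturbed aboveground total is clamped to zero is treated as a zero-biomass
tree for that replicate (all harmonized components zero, still additive,
counted separately). With the white-pine noise levels these clamps touch
mainly the smallest stems' branch predictions.

Merchantable height is solved per replicate from the implied taper with
the replicate's own outside-bark volume and ratio coefficients: a coarse
scan locates the uppermost sign change of d(h) − top_dob on
(stump, H·(1−1e-9)) and bisection/Brent polishes it. The uppermost
crossing is chosen because butt swell (β < 1 makes d² singular at
groundline) can produce a second, lower crossing; the merchantable top is
the upper one. Trees whose taper never reaches the top diameter are
marked non-merchantable and contribute zeros to merchantable components
(domain zeros, required for unbiased stratum means).

Randomness flows from one seed through `SeedSequence.spawn` replicate
substreams, so results are independent of evaluation order and replicate
prefixes are stable when R changes. A failed replicate aborts with its
index; nothing is silently skipped.

Estimation uses the standard post-stratified estimators (within-stratum
SRS mean and variance of the mean with the n_h(n_h−1) divisor, combined
with known weights W_h and total area A_T). The decomposition uses the
replicate mean for y, the replicate mean of v(y_r) for v_y, and the
R−1-divisor variance among y_r for v_m.

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| segmentation diameter k | 22.86 | cm | white-pine join point of the segmented form |
| stump height | 0.30 | m | lower merchantable bound |
| merchantable top diameter | 10.16 | cm | outside bark |
| merchantable min dbh | 12.7 | cm | domain threshold for merchantable components |
| overall min dbh | 2.5 | cm | prediction domain |
| bootstrap draws B | 2500 | — | ensemble size; scaled runs use 300–400 |
| replicates R | 1500 | — | Monte Carlo size; scaled runs use 300 |
| z cap | 3.0 | — | truncation of all standard-normal deviates |
| taper constant | 0.000078540 | m³/(cm²·m) | cross-section conversion |

## The synthetic-data generator

The generator defines the study conditions the package is exercised
under. It emulates: the per-component sample sizes (2783/2597/3409 for
volumes, 392/338/239 for biomass, 39509/54757 stem-profile observations),
a truncated-lognormal dbh distribution matched to the reported size range
(2.54–111.76 cm, mean ≈ 31.8, SD ≈ 15.8) with height following
H = 3.0·D^0.55 with lognormal residual SD 0.23 (chosen to reproduce the
reported height SD of 7.18 m) truncated to 2.68–48.16 m; heteroscedastic
noise generated from the fitted residual-SD functions themselves (power
forms for volume/biomass, bell for ratios); WDSG and CF samples with the
reported means, standard errors, and sample sizes (0.338 ± 0.004, n=96;
0.507 ± 0.003, n=6); overlapping-but-unequal tree subsets per component,
mimicking data pooled from partially disjoint source studies; and an
inventory of 1124 plots in three post-strata (weights 0.45/0.35/0.20)
with negative-binomial tree counts per plot (dispersion 0.13, stratum
density ratios 1.5/0.8/0.2, expected 864 trees) and two-size-class
expansion factors (74.97 per ha below 12.7 cm, 14.87 per ha above). The
dispersion value was calibrated so the design's relative sampling errors
(se_y/y ≈ 10–11%) match the level reported for the real inventory; the
true allometric coefficients are frozen constants chosen once to land
near the reported component means at the mean tree.

What it does **not** emulate: the mapped-plot/condition structure of a
real FIA sample, measurement error in dbh and height, spatial
autocorrelation, species mixtures, or the exact joint size distribution
of the real inventory trees. Passing tests therefore demonstrate that the
method behaves correctly under realistic statistical structure — additive
identities, unbiased recovery, the qualitative error-propagation pattern —
not that absolute population totals match any real landscape. Absolute
y and v_y depend on the (synthetic) population and are not comparable to
published values; the percent quantities m% and s% are, and their
realized values vary across regenerations of the synthetic fitting data
because the small-sample biomass ensembles (n = 239/392) differ
realization to realization — branch m% typically lands between ~2.5 and
~7 with the published ≈4 in the middle of that range.

## Numerical choices

- Taper tip guard 1e-9·H avoids the (1−h/H)^(α−1) singularity; volume
  conservation (∫0.000078540·d² = whole-stem volume) holds to better than
  1e-6 relative by adaptive quadrature even with the integrable butt-swell
  singularity at β < 1.
- Root solves: 512-point scan + Brent (scalar), 256-point scan + 60
  bisection steps (vectorised batch); both meet 1e-6 cm on the recovered
  top diameter and agree with each other to 1e-6 m.
- The optimiser explores raw parameter space through unchecked model
  kernels (a transient negative scale is evaluable); validity (a > 0,
  α, β > 0) is enforced on converged estimates only.
- Degenerate inputs: power-form residual SD requires ŷ > 0; ratio inputs
  outside [0, H] raise rather than clamp; zero harmonization totals are
  handled only inside the Monte Carlo engine (zero-biomass tree), the
  plain `harmonize()` call keeps its strict positive-input contract.
- Group SDs use the ddof=1 sample SD around the group-mean residual.

## Scaled problem sizes

Default ensemble and replicate counts (B = 2500, R = 1500) reproduce the
full-size analysis in a few minutes. The test suite and the acceptance
script run the same pipeline at B = 300–400 and R = 300 with fitting data
at the full study sample sizes; at those sizes the Monte Carlo noise on
m% is a few percent of its value, which is ample for the qualitative
pattern checks they perform. The parameter-recovery study uses 100
regenerations of the full-size fitting data without bootstrap.

## Known limitations

- Cross-model residual correlation is not modelled; for components built
  from correlated inputs the independence assumption can under- or
  over-state v_m.
- The bell-form variance fit is sensitive to its centre when groups cover
  the [0,1] range unevenly; starting values are data-driven (peak group).
- The observed-value grouping convention biases variance-function
  recovery in simulation studies (see Fitting); it is kept as the default
  for fidelity to the published procedure.
- Single species group; no foliage component; no finite-population
  corrections; no SUR-style joint fitting (harmonization is proportional
  rescaling only).
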