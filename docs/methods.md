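# Methods

## Signal model

One MPRAGE cycle is modelled as: perfect adiabatic inversion, free
recovery, a train of `n_lines` excitations of angle α spaced ES apart
(readout duration τ = n_lines·ES), then free recovery for TD until the
next inversion, with cycle length TR. During the train the longitudinal
magnetisation relaxes with the apparent rate `1/T1* = R1 − ln(cos α)/ES`
towards `M0·T1*·R1`; solving the cycle's periodic steady state and reading
the signal at the centre of the train gives the closed form implemented in
`morphosynth.mprage` (the `f_R1` factor), multiplied by `PD` and
`exp(−TE·R2*)`. We re-derived this closed form from the cycle recursion
rather than transcribing it, and guard it with an independent oracle
(`morphosynth.bloch`) that applies every RF pulse discretely and iterates
cycles to convergence. The two agree to <1 % at the default protocol over
R1 ∈ [0.2, 2] s⁻¹. The residual discrepancy is real, not numerical: the
closed form replaces the discrete train's fixed point
`M0(1−E_ES)/(1−cos α·E_ES)` with the continuum limit `M0·T1*·R1`, an error
that grows toward small α and small R1 (≈2 % at α = 6°, R1 = 0.2 s⁻¹); the
wider-grid test documents this envelope.

**Timing convention.** The printed default timing (TI = 960 ms,
τ = 1742.4 ms, TR = 2420 ms) admits no non-negative recovery delay if TI
is measured to the start of the readout. We therefore interpret TI as
running to the *centre* of the (centric-ordered) readout train, so
`TD = TR − TI − τ/2 = 588.8 ms`; the inversion-to-first-pulse time used in
E1 is `TI − τ/2`. The start convention is selectable
(`MprageProtocol(ti_convention="start")`) and validates its own timing.

**Synthetic TE.** The echo time of the synthetic images is a free
parameter of the simulation; the default is 3 ms, a typical MPRAGE echo
time, short enough that the R2\* factor is a weak (percent-level)
modulation — which is precisely why the deep-nucleus effects are subtle.

## Map estimation

R2\* comes from ordinary least squares on the log-signal of the eight
PD-weighted echoes (the T1-weighted echoes are not used). Negative fitted
rates are clipped to zero and counted; voxels with non-positive signal at
any echo become NaN and are counted. R1 and PD come from the exact
two-point inversion of the spoiled gradient-echo steady state through the
linearisation `y = E1·x + PD(1−E1)` with `y = S/sin α_eff`,
`x = S/tan α_eff`; a supplied B1 map rescales the nominal angles
voxelwise. We use the exact inversion rather than the small-angle rational
approximation common in the multi-parameter-mapping literature because
exactness makes the round trip testable to numerical precision; ignoring a
true B1 factor b biases R1 by ≈1/b² (verified against a numeric
root-finder in the tests).

The composite `estimate_maps` feeds the two-point inversion with TE = 0
signals: the PDw side uses the S0 extrapolated by the R2\* fit, and the
T1w first echo is corrected by `exp(+TE₁·R̂2*)` with the PDw-fitted rate.
This keeps the noise-free round trip exact; with a first-echo-only
convention PD would absorb a tissue-dependent `exp(−TE₁·R2*)` factor.
All relaxation arithmetic is internal in 1/ms (the natural unit of the
protocol timings); public maps are in 1/s, conversion factor exactly 1000.

Monte-Carlo calibration at 1 % signal noise (fixed seeds, 48³–64³
phantoms) put the median relative errors at ≈1.9 % (R1), ≈1.0 % (PD) and
≈5.5 % (R2\*; the CSF class with R2\* = 1 s⁻¹ dominates the upper tail);
the test bounds 3 % / 2 % / 8 % were frozen from those runs.

## Phantom

The phantom is deliberately non-anatomical but topologically faithful: a
WM box wrapped on every face by a gray-matter shell (as cortex wraps white
matter — there is no WM–CSF interface anywhere), a flat top face whose
GM–WM border is a plane with known normal, a sensorimotor-like subregion
(higher R1, PD ratio closer to WM) on one third of that face, two
spherical iron-rich nuclei inside the WM, a thin CSF rim, and a deep CSF
pool above the slab so the outer cortical boundary is measurable. Default
tissue values are order-of-magnitude 3 T literature constants (see
`DEFAULT_TISSUES`): they place cortex at R_PD = PD_GM/PD_WM ≈ 1.20 and
give the nuclei R2\* = 55 s⁻¹, pallidum-like, enough to drop their
short-TE intensity below the GM/WM midpoint once the R2\* factor is
included. Within-tissue heterogeneity is multiplicative Gaussian
(default 0 for exact tests, 1 % for morphometry experiments). Acquisition
noise is additive Gaussian on magnitude signals — a simplification of
Rician noise acceptable at the simulated SNR, and a stated limitation.

The ageing cohort draws uniform ages (18–78 y by default) and applies
per-tissue linear/quadratic trends around the sample mean age plus 0.5 %
between-subject parameter jitter. The default cortical PD trend is
+1·10⁻³ per year (~0.12 %/y): age-related density reduction of myelinated
fibres raises free-water content, so R_PD grows with age and the
PD-including image loses apparent GM faster. What the generator does *not*
emulate: real cortical folding, partial-volume geometry of curved
surfaces, B0/motion artefacts, Rician noise floors, or registration error.
Tests passing on this phantom show that the contrast mechanism is
implemented correctly — not that effect sizes transfer quantitatively to
real cohorts.

## Morphometry proxy

Tissue classification fits a K = 3 one-dimensional Gaussian mixture to the
masked intensities by EM (deterministic quantile initialisation, collapse
re-seeding, per-iteration log-likelihood trace). Two numerical choices are
load-bearing:

- **Variance floor.** Component sds are floored at 1 % of the intensity
  range. Without it the near-delta CSF peak attracts two components
  through variance collapse (the likelihood of a spike grows without bound
  as σ→0) and no component is left for the GM/WM modes.
- **Labelling rule.** Voxels are assigned to the *nearest component mean*
  — maximum posterior under shared variance and uniform class priors —
  rather than the full fitted-weight MAP. Without spatial priors, full MAP
  moves each pairwise decision threshold by `σ²·ln(w_i/w_j)/Δμ` toward the
  minority class, so the majority class (GM) systematically annexes
  low-contrast boundary zones; at the PD-reduced GM–WM gap this weight
  term dominates and *inverts* the between-modality volume direction that
  prior-constrained tools produce. The midpoint rule removes that
  instability and leaves exactly the contrast-driven mechanism under
  study: for a product image T1w(R1)·PD, the blurred boundary ramp is
  convex relative to its plateau midpoint, so the apparent border shifts
  into GM by a fraction of the blur width proportional to the contrast
  change — the same sign rule as the closed-form ΔC prediction. Full MAP
  remains available (`labeling="map"`).

Intensity is pre-smoothed with an isotropic Gaussian before fitting,
default FWHM 2 mm. The phantom cortex is ~8 voxels thick, roughly three
times real cortical thickness at 1 mm; 2 mm is therefore the standard
6–8 mm VBM kernel scaled to the phantom's structure scale. At 6 mm on this
grid, partial-volume mass outweighs pure-tissue mass and no three-class
intensity fit tracks tissue at all.

Slab thickness is the contiguous run of GM labels along the border normal,
walking downward first to catch borders displaced into WM; columns without
a GM run give NaN and are counted. Apparent volumes are label counts times
voxel volume, so GM+WM+CSF always equals the masked volume exactly.

## Contrast analysis

Boundary sampling follows the fixed-depth convention: WM 1 mm below the
GM–WM border along the normal, GM at `round(0.35·thickness)` voxels (at
least one) above it, nearest-voxel, no interpolation — a voxelized
analogue of surface-based sampling. Two closed forms for the PD-induced
contrast change ship side by side: the `derived` form
`4·R_T1(R_PD−1)/((1+R_T1)(1+R_PD·R_T1))` is the exact algebraic
consequence of the contrast definition applied to the factorised images
and matches the pipeline difference to ≤1e−12; the `printed` variant
`4·(R_PD−1)·R_T1/((1+R_PD)(1+R_T1))` agrees in sign and at the R_PD = 1
zero but differs in magnitude (0.1478 vs 0.1803 at the phantom's cortical
ratios). Both are retained deliberately; `derived` is the default. The
thickness-change regression is no-intercept OLS (`β = Σxy/Σx²`,
`t = β/SE`, n−1 dof), with optional 1-D Gaussian smoothing along the site
ordering as the flat-phantom analogue of surface smoothing (off by
default in tests).

## Statistics

The GLM is plain OLS per site with one-tailed t-tests; designs hold
modality indicators (cell-means coding), age centred over observations,
the square of centred age itself re-centred, sex, modality×age
interactions, and optional sum-to-zero subject deviations for paired
contrasts (a simplification of a full flexible-factorial covariance
structure, stated as such). Rank deficiency is reported with the names of
the collinear columns. Familywise control is Bonferroni — conservative
and exactly testable, standing in for random-field-theory correction,
which is out of scope on non-stationary phantom fields. Null calibration
(fixed seeds): the uncorrected type-I rate over 1000 independent sites
falls within binomial 99 % bounds of 0.05, and the familywise error over
400 null families stays at its nominal level.

## Problem sizes and determinism

Default experiments use a 64³ phantom at 1 mm and 40-subject cohorts; the
test suite runs the same checks at 32³–48³ and 30 subjects. All randomness
flows through explicit `numpy.random.default_rng` seeds; identical seeds
give bit-identical volumes, tables and manifest checksums (NIfTI written
uncompressed so file hashes are stable).

## Known limitations

- The Bloch oracle shares the package's idealisations (perfect inversion
  and spoiling, instantaneous pulses); it guards the algebra of the closed
  form, not scanner physics.
- Additive Gaussian noise, piecewise-constant tissues and a planar cortex
  understate real-data variability; effect magnitudes here are not
  calibrated to any empirical cohort.
- The segmentation proxy has no spatial priors, registration or Jacobian
  modulation; it isolates the intensity mechanism and cannot reproduce
  tool-specific behaviour of SPM/FreeSurfer pipelines.
- Imperfect-RF-spoiling correction is accepted only as a pre-computed
  multiplicative map; no correction coefficients are computed.
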