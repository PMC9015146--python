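# Methods

## The HV index and its derived quantities

A cohort table carries one row per animal × timepoint with the smallest
internal graft diameter `d_min` (mm) seen on angiography, the IVC–HV
junction angle (degrees), and peak right-atrial / distal-IVC pressures
(mmHg).  Derived per record:

* least estimated area `A = π (d_min/2)²` (mm²) — the circular cross-section
  at the narrowest point;
* HV index `= angle / A` (degrees/mm²);
* pressure gradient `= p_distal − p_ra` (mmHg).

The angle is treated as a given measurement (its landmark construction on
the angiogram is outside this package's scope) and must lie strictly inside
(0°, 180°); diameters must be positive.  Negative gradients are retained —
near-zero gradients measured with catheter noise can legitimately come out
slightly negative — but records missing either pressure are excluded from
gradient-based analyses and listed in the report's skip log.  The `native`
timepoint always denotes the separate untreated control cohort, never month
0 of an implanted animal.

Units: because the angle enters in degrees, a native vessel (angle ≈ 19°,
area ≈ 69 mm²) scores ≈ 0.27 degrees/mm²; radians would shrink every index
by ~57× without changing any rank-based statistic.

## Statistical battery

**Spearman correlation.**  ρ is the Pearson correlation of midranks
(average ranks on ties).  The two-sided p-value is computed by full
enumeration of the n! rank permutations for n ≤ 10 — the per-timepoint
group sizes of the emulated design — and by the t approximation
`t = ρ√((n−2)/(1−ρ²))` on n−2 df above that.  Confidence intervals use the
Fisher transform `tanh(atanh ρ ± z·(n−3)^{−1/2})`; at |ρ| = 1 the interval
degenerates to a point with a warning.

**Equality of k independent correlations.**  Each coefficient is mapped to
`z_i = atanh ρ_i` with weight `w_i = n_i − 3`; the statistic
`χ² = Σ w_i (z_i − z̄)²` with `z̄ = Σ w_i z_i / Σ w_i` is referred to the
χ² distribution on k−1 df.  A non-significant result supports using one
pooled correlation across timepoints.  Pooling repeated measures on the
same animal as if independent is a deliberate reproduction of common field
practice; see Limitations.

**Group comparisons.**  Kruskal–Wallis uses the tie-corrected H (delegated
to `scipy.stats.kruskal`; an explicit rank-formula oracle lives in the test
suite); all-identical pooled data raise an error because the tie-correction
denominator vanishes.  Steel–Dwass ranks each pair of groups jointly,
standardizes the rank sum by its exact permutation mean and tie-corrected
variance (computed as the finite-population sampling variance of the
midranks), and refers √2·|t| to the studentized range q_{k,∞}, whose tail
is evaluated by numerical integration of
`k ∫ φ(z) [Φ(z) − Φ(z−q)]^{k−1} dz`.  For k = 2 this reduces exactly to the
two-sided normal tail.  The optional permutation mode implements a max-T
null: pooled group labels are permuted (10⁵ resamples by default, explicit
seed), every pairwise statistic is recomputed, and each observed pair is
calibrated against the null distribution of the maximum √2|t*| — the
resampling analogue of the familywise q_{k,∞} reference.  The two modes
agree to ~0.01 at group sizes ≥ 15 but diverge by up to ~0.1 at n_i = 4,
where the asymptotic reference is simply inaccurate; the permutation mode
is the more trustworthy one for very small groups.  No additional
multiplicity adjustment is applied on top of Steel–Dwass.

**Wilcoxon rank-sum** enumerates all C(N, n_x) midrank assignments exactly
for N ≤ 12 (ties handled naturally) and otherwise uses the normal
approximation with tie-corrected variance and a 0.5 continuity correction;
the approximation sits within 0.02 of enumeration at the handover sizes
(both groups ≥ 4).

**Normality screen** reports biased moment coefficients of skewness and
excess kurtosis plus Shapiro–Wilk (scipy's AS R94 implementation) for
n ≥ 8.

## MINE statistics

The characteristic matrix scores every grid shape (k, l) with
`k·l ≤ B(n) = max(n^0.6, 4)` (the floor keeps the 2×2 grid admissible for
small samples): `M[k,l] = I*(k,l) / log2 min(k,l)` where I* is the maximal
mutual information over k×l grids.  Two search modes:

* **exhaustive** (default for n ≤ 12): every combination of cut points
  between distinct values on both axes — exact by construction;
* **heuristic**: the standard equipartition search.  One axis is
  equipartitioned into l bins (tied values kept together); the other axis
  is pre-partitioned into at most c·k superclumps (c = 15) and its cuts are
  optimized by dynamic programming on the prefix decomposition of the
  conditional entropy; both orientations are run and the elementwise
  maximum taken.  The heuristic can miss the global two-axis optimum on
  small irregular samples, which is why small n defaults to exhaustive; on
  noiseless monotone data the two modes agree exactly.

Summaries: MIC = max M; MAS = max |M[k,l] − M[l,k]|; MCN = log2 of the
smallest k·l attaining MIC (tolerance `eps_mcn`, default 0); MIC-R² = MIC
minus the squared Pearson correlation; TIC = Σ M over all admissible
shapes.  All are invariant under strictly increasing transforms of either
variable.  No p-value calibration for MIC is provided.

## Synthetic cohort generator

The generator emulates the study design: `n_native = 10` untreated controls
with a single visit, `n_implanted = 10` implanted animals at 0.5, 1, 3, 6
and 12 months, with `n_implanted − n_at_12m = 2` animals missing the
12-month visit (missing completely at random — no dropout mechanism is
modeled).

One latent severity per animal drives all channels, reflecting the premise
that a single remodeling process underlies narrowing, angle change and
pressure gradient:

```
s_i(t) = A_i · exp(−(ln t − ln τ)² / (2σ²)),   A_i ~ min(LogNormal(μ_A, σ_A), 1)
```

with τ = 1.5 months and σ = 2.9 in log-time.  Truncating the amplitude at 1
(rather than clipping s itself) keeps severity in [0, 1] while preserving a
strict peak: for every animal the 12-month severity is below its peak, and
the peak falls between 1 and 3 months.  Channels:

```
d_it     = d_i0 (1 − f_max s_i(t)) + σ_d z_d        f_max = 0.54, σ_d = 0.3 mm
angle_it = angle_i0 + κ s_i(t) + σ_a z_hv           κ = 40°, σ_a = 5°
grad_it  = g_i0 + β s_i(t) exp(σ_m z_g)             β = 3.6 mmHg, σ_m = 0.3
```

Baselines are drawn from the native distributions (d: 9.4 ± 0.6 mm, angle:
18.7 ± 8.0°, gradient: 1.3 ± 0.7 mmHg).  The noise triple (z_hv, z_g, z_d)
is a Gaussian copula: the angle and gradient components have Pearson
correlation `2 sin(π ρ_s / 6)` so their rank correlation is the configured
`copula_rank_corr` (default 0.75), and the diameter component loads
negatively (−0.7) on the shared factor — narrowing accompanies congestion.
The multiplicative lognormal on the gradient's severity term reproduces the
strong heteroscedasticity of the measured gradients (native sd ≈ 0.7 mmHg
vs ≈ 2.8 mmHg at the 1-month peak).

Calibration: the trajectory and gain defaults were fixed by matching the
seed-averaged per-timepoint medians of area, angle, HV index and gradient
to the reference group summaries the acceptance checks encode (all ratios
within ±21% over 20–30 seeds; the checked tolerance is ±30%), with the
pooled HV-index↔gradient rank correlation at 0.765 and the n = 200
copula-recovery value at 0.744.  The maximal diameter-loss fraction 0.54
follows from the reference medians themselves: the 1-month median area
(≈ 16.5 mm²) implies a ~51% median diameter loss from the 9.4 mm baseline.

Randomness: every animal owns a counter-based stream seeded as
`[seed, cohort-role, animal-index]`, so enlarging a cohort never perturbs
existing animals (the 12-month dropout *set* does depend on `n_implanted`).

What the generator does **not** emulate: per-animal trajectory shapes other
than the common bump (real animals differ in peak time, not just
amplitude); serial correlation of measurement errors within an animal;
informative dropout; any fluid-dynamics relation between lumen and
gradient.  Passing calibration therefore shows the battery behaves
correctly on data *with the study's marginal structure*, not that the
biological trajectory model is right.

The densitometry generator produces marker/α-SMA ratios per animal and
timepoint: MYH11 (a late smooth-muscle maturity marker) rises from 1 to 12
months along log-time toward the mature native level, desmin and vimentin
stay flat, all with multiplicative lognormal noise (σ = 0.35, n = 6 per
group).

## Pipeline

`run_study` computes: pooled and per-timepoint Spearman correlations of
angle, area and HV index against the gradient; one equality-of-correlations
test per predictor; Kruskal–Wallis plus Steel–Dwass for each of the four
quantities across timepoints; MINE statistics for the three pooled pairs;
and per-group summaries (mean, SEM = sd/√n with the n−1 sd, median, range).
Undersized groups (n < 4 for correlations, n < 2 for group tests) and
records without a pressure pair are skipped with an entry in
`StudyReport.skipped`, never silently.  Reports are written as CSV with a
fixed float format, so identical inputs give byte-identical files.
Significance stars follow the 0.05 / 0.01 / 0.001 convention.

## Numerical choices and limitations

* Exact Spearman p-values cache the permutation matrix per n (36 MB at
  n = 10); `method="approx"` avoids this entirely.
* The studentized-range tail is integrated over z ∈ [−9, 9]; absolute error
  is far below the Monte-Carlo noise of any permutation comparison.
* MCN uses exact attainment of the maximum (eps 0 with a 1e-12 float
  guard); with an all-zero matrix it reports log2(4) by convention.
* Repeated measures are pooled as independent in correlations and posthoc
  tests (field practice for this design); a repeated-measures correction is
  deliberately out of scope.
* Steel–Dwass asymptotic p-values are anti-conservative for group sizes
  around 4; use the permutation mode there.
* The acceptance-grade reproduction targets are the three equality-of-
  correlations χ² statistics, which depend only on printed per-timepoint
  coefficients; per-animal raw data are not public, so pooled CIs, MINE
  values and posthoc p-values of the original cohort are not reproduction
  targets.
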