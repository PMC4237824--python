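# Methods

This note documents the models implemented in `plaquedce`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not demonstrate.

## Acquisition and forward model

The simulated acquisition is an axial multi-slice 2D spoiled gradient
recalled echo (SPGR) dynamic protocol: 18 frames at 18 s intervals, a
0.05 mmol/kg gadolinium bolus injected coincident with frame 3 (so frames
1–2 are pre-contrast baseline), 160 mm field of view on a 256 matrix
(0.625 mm pixels), flip angle 50°, TE 5 ms. Two vendor variants differ in
slice prescription and TR (GE: 8 × 2 mm slices, TR 117 ms; Philips:
4 × 3 mm, TR 126 ms).

**Phantom.** A 2D cross-section on a 64 × 64 lattice: a circular lumen
(default radius 3 mm), an annular wall (default 1.5 mm), and an eccentric
plaque bulge (smooth angular bump, default 2 mm high) so the default
geometry passes the distinct-plaque inclusion rule (maximum wall thickness
> 1 mm). Ground truth is `K^trans = 0.062 min⁻¹`, `v_p = 0.067` in the wall
(carotid-plaque magnitudes), `v_p = 1`, `K^trans = 0` in the lumen (pure
plasma), zeros in the background.

**AIF.** The in-vivo pipeline extracts the AIF from the lumen; simulation
needs a population bolus model. We use a gamma-variate first pass peaking
one frame after injection plus a slowly rising tail decaying at the
`washout_rate` (default 0.2 min⁻¹), scaled so the sampled peak equals
`peak` (default 2 mmol/L, typical plasma concentration for this dose).

**Signal.** Tissue concentration follows the Patlak forward model (exactly
linear in `(K^trans, v_p)`; trapezoidal AIF integral on the frame times in
minutes). Concentration maps to signal via the steady-state SPGR equation
`S = M0 sin α (1−E)/(1−E cos α)`, `E = exp(−TR·R1)`,
`R1 = 1/T10 + r1·C`. Baseline relaxation defaults (not measurable from the
analysis itself, configurable in `TissueProperties`): wall T10 1000 ms,
blood 1650 ms, relaxivity r1 = 4.5 L·mmol⁻¹·s⁻¹ — literature-typical 3T
values. Noise is additive zero-mean Gaussian on magnitude signal, a
high-SNR approximation of Rician noise that keeps the inversion simple;
optional per-frame rigid translations emulate patient motion.

## Kinetic analysis chain

1. **Registration** — translation-only, per slice, maximizing normalized
   cross-correlation over integer shifts (optional parabolic subpixel
   refinement) against a running reference updated with a scalar Kalman
   gain, so the reference tracks contrast enhancement while averaging down
   frame noise. The proprietary registration/smoothing stage used by
   clinical vessel-wall software is not publicly specified; this is a
   functionally equivalent surrogate. All-zero frames are skipped and
   flagged.
2. **Temporal smoothing** — fixed-interval Kalman (RTS) smoothing under a
   random-walk state model. `kalman_smooth` takes explicit scalar process
   and observation variances. The pipeline's automatic mode estimates the
   observation variance from consecutive baseline frames and the process
   variance *per pixel* (mean squared frame-to-frame increment minus the
   noise contribution): flat wall curves are smoothed hard while the sharp
   lumen bolus is left intact. A noise-free series is returned unchanged —
   with zero observation variance the optimal smoother is the identity.
3. **SPGR inversion** — the equilibrium amplitude `M0 sin α` is estimated
   per pixel from the baseline-frame mean and the assumed T10 (blood value
   inside the lumen contour, wall value elsewhere); `T1(t)` then follows in
   closed form and `C = (1/T1 − 1/T10)/r1`. Signals outside the invertible
   branch of the SPGR curve flag the pixel invalid rather than being
   extrapolated.
4. **AIF extraction** — per frame, the mean concentration of the top
   quartile of lumen pixels ranked by total post-injection enhancement,
   divided by `1 − hematocrit` (default 0.42 for in-vivo-style blood
   curves; 0 when the simulation's AIF is already plasma concentration).
   The ranking sum excludes the frame being averaged (leave-one-frame-out)
   so a pixel's own noise never influences its selection at that frame.
5. **Patlak fit** — per-pixel ordinary least squares of
   `C_t(t_k) = K^trans·∫C_p + v_p·C_p(t_k)` over all frames. Baseline
   frames (where `C_p = 0`) are included: the model has no intercept, so
   they are harmless and stabilize the fit. Raw, unclamped estimates are
   kept for averaging and statistics — clamping before averaging would bias
   plaque means; display ranges (`K^trans`: 0–0.2 min⁻¹ in green, `v_p`:
   0–1 in red) apply only when rendering V-V images.
6. **Measurement** — pixel centers at `(i + 0.5)·pixel_size`,
   point-in-polygon by the even-odd rule, wall mask = inside outer contour,
   outside lumen contour, and at Euclidean distance > 1 mm from the lumen
   polygon (polygon distance, not rasterized-mask distance). Plaque means
   are arithmetic means of valid masked pixels; when several slices are
   analyzed the per-subject value is the area-weighted mean, equivalent to
   pooling all analyzed pixels.

## Scan-rescan statistics

The measurement model for subject *i*, scan *j* ∈ {1, 2} is the balanced
random-intercept model `y_ij = μ + b_i + e_ij`, `b_i ~ N(0, σ_b²)`,
`e_ij ~ N(0, σ_w²)`. Estimation uses the one-way random-effects ANOVA
moment solution — `σ̂_w² = MSW` (mean of `d_i²/2`), `σ̂_b² = max(0,
(MSB − MSW)/2)` — which coincides with REML in this balanced two-scan
design (verified against a brute-force REML optimization in the tests);
negative between-subject variance estimates are truncated at zero and
recorded. Derived metrics: between-scan CV `= σ_w/μ` on the raw scale, ICC
`= σ_b²/(σ_b² + σ_w²)` (defined as 0 for all-constant data). Confidence
intervals use the subject-level nonparametric percentile bootstrap
(B = 2000 default, scan pairs resampled intact — the only
structure-respecting resampling for paired data). Vendor means are compared
with the balanced mixed model (equivalently a two-sample t-test on subject
means); vendor between-scan SDs with a permutation test on
`|σ̂_w(GE) − σ̂_w(Philips)|` (default 10 000 permutations, add-one
correction, so p ∈ [1/(n+1), 1]). Per-subject variability is
`|y_i1 − y_i2|/√2` (the two-point sample SD), related to subject means and
plaque areas by Spearman rank correlation. Bland–Altman limits of agreement
use mean ± 2·SD of the differences (factor 2, the convention of the
agreement plots this mirrors). The large-lesion subgroup keeps subjects
whose *smaller* of the two scans' analyzed areas is ≥ 25 mm².

## Sample-size planning

The planning target is a between-arm difference in percent change
(follow-up minus baseline over the baseline mean) tested with a two-sided
unpaired t-test at α = 0.05 and 80% power, assuming measurement error
dominates within-arm variability and equal allocation; the per-arm SD of
percent change is therefore the single-measurement CV times √2. The solver
finds the continuous n at which the noncentral-t power equals the target
(degrees of freedom 2n − 2, noncentrality `δ/(σ√(2/n))`, no normal
shortcut) and rounds to the nearest integer — the behaviour of R's
`power.t.test` followed by rounding. For CV = 25% the continuous solutions
are 197.19, 50.03 and 22.80 per arm for 10/20/30% differences, reported as
197, 50 and 23; note the achieved power at the rounded n may sit
marginally below the target (49.05 and 21.8 are the normal-approximation
values). Dropout is deliberately not modelled.

## Synthetic cohorts and the study roster

`generate_measurement_cohort` draws directly from the random-intercept
model; the default spec is 35 subjects (20 GE / 15 Philips),
μ = 0.062 min⁻¹, between-scan CV 25%, ICC 0.65 — `CohortSpec.from_cv_icc`
maps (CV, ICC) to (σ_w, σ_b). Plaque areas are lognormal
(log-mean ln 28 mm², log-SD 0.55, small per-scan jitter), chosen so
roughly half the cohort passes the 25 mm² subgroup cutoff.

`generate_roster_fixture` builds 51 subjects across 15 sites (1–6 subjects
each, sites single-vendor, chosen so the analyzable set splits 20 GE / 15
Philips): exactly 10 subjects carry one disjoint protocol violation each —
3 wrong frame interval (|Δt − 18 s| > 1 s), 2 too few frames, 2 missed
injections, 3 misaligned slabs — spread over 9 sites including one
two-subject site that loses both; 6 further subjects have an
uninterpretable scan (quality score 1), spread over 6 sites. Exclusion
order is protocol compliance first, then image quality among the
compliant, so the cascade 51 = 10 + 6 + 35 is conserved by construction
(the categories are disjoint because the counts only add up that way). The
seed randomizes which scan carries each flag and the benign quality scores;
the counts themselves are structural.

The image-level pipeline mode forward-simulates both scans of every
analyzed subject: subject-level true parameters are lognormal around the
grand mean with the between-subject CV implied by the configured ICC, and
scan-rescan differences combine multiplicative kinetic jitter at the
between-scan CV, sub-pixel repositioning (≤ 0.3 mm) and fresh image noise.

## What the synthetic data do not show

* Generated cohorts match the *assumed* variance structure; recovering
  CV 25%/ICC 0.65 on them validates the estimators, not the physiology of
  any real cohort.
* The phantom is a single 2D slice with piecewise-constant kinetics: no
  through-plane partial volume, coil shading, inflow enhancement, B1
  variation or multi-site scanner drift.
* AIF extraction is noise-sensitive: the per-pixel SPGR baseline rests on
  only two pre-contrast frames, and at peak blood enhancement the inversion
  amplifies baseline error asymmetrically, which biases extracted-AIF
  kinetic estimates downward at realistic SNR (the 18-s frame interval is
  a genuine limitation of such protocols). Kinetic-recovery accuracy is
  therefore assessed with the known simulation input function; closed-loop
  AIF recovery is exact only in the noise-free limit. Ratio statistics
  (CV, ICC) are first-order invariant to the resulting multiplicative
  bias.
* Temporal smoothing attenuates the early `v_p`-driven transient in wall
  curves more than the slow `K^trans` accumulation — consistent with
  `v_p` being the less reliable parameter at this temporal resolution.

## Numerical choices

* Registration search: integer shifts within ±3 pixels, NCC scores,
  optional parabolic subpixel refinement; integer shifts are applied by
  array roll (no interpolation), subpixel by first-order spline.
* Patlak fit: one pseudoinverse of the shared 18 × 2 design applied to all
  pixels; singular designs (AIF ≡ 0) flag pixels invalid.
* Bootstrap/permutation: vectorized index resampling from
  `numpy.random.default_rng`; every stochastic routine is a pure function
  of its arguments including the seed, and the study report embeds
  (config hash, seed, version) so any run can be regenerated bit-identically.
* Problem sizes in the test suite (64 × 64 phantoms, 500 kinetic
  replicates, 1000 cohort replicates, 999-permutation nulls, 200 × 2000
  bootstrap coverage) were chosen to give comfortable Monte-Carlo margins
  for the tolerances tested.
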