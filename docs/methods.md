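# Methods

This note documents the models, calibrations and numerical choices behind
`epicardio`: what the synthetic study conditions are, how the signal chain
extracts activation/repolarization markers, how the whole-heart metrics
and the risk model are defined, and where the synthetic setting is known
to differ from real electrocardiographic-imaging data.

## 1. Study design being emulated

The package reproduces a two-part analysis on an HCM exercise-testing
cohort: (a) whole-heart activation/repolarization metrics compared between
study groups (pooled HCM vs structurally normal controls; VF/VT survivors
vs HCM patients without an arrhythmic history) at two phases — immediately
after peak exercise and in late recovery; (b) a logistic model on the
recovery-phase measures that discriminates VF survivors within the HCM
cohort, evaluated by repeated stratified cross-validation.

Because the underlying patient data are unavailable, all inputs are
synthetic.  The generator is calibrated so that the *published* group
statistics — group means and SDs of each whole-heart measure, group heart
rates, rank-test separations and qualitative map patterns — are the
distributions the cohorts are drawn from.  The generator's defaults are
the study conditions; they are not tuning knobs.

## 2. The epicardial mesh

`prolate_spheroid_mesh` builds the default shell: 200 nodes placed
area-uniformly (jittered golden-angle spiral) on a prolate spheroid with
equatorial radius 6.5 mm and polar semi-axis 105 mm, triangulated by their
convex hull.  The apex is the −z pole; the base centroid the +z pole; an
area-equalized apico-basal coordinate (0 at apex, 1 at base) parameterizes
field construction and the apical/basal pattern rules.

The shape is deliberately stylized.  Two printed facts constrain it
jointly: whole-heart activation dispersions of ~50–60 ms coexist with mean
5-mm gradients of only 0.36–0.45 ms/mm, which by the coarea inequality
requires an effective conduction path of roughly 130–160 mm; and 5-mm
Euclidean neighborhoods must contain enough of the 200 nodes (≈2.3
neighbors per node on average here) for the plane-fit gradient to be
defined.  A compact ~90 mm ventricle satisfying the density requirement
forces a smooth-field gradient floor near 0.55 ms/mm — above every printed
gradient — so the default shell is elongated (~210 mm apico-basal arc),
trading anatomical proportions for the printed dispersion-to-gradient
ratios.  On a real epicardium the same ratios arise from the much larger
biventricular surface; the elongated tube is the 200-node stand-in for
that path length.  Node counts, radii and jitter are arguments; PLY and
VTK legacy ASCII I/O are provided (gradient maps export as per-node VTK
scalars).

## 3. Cohort presets and the metric-level sampler

`presets/default.yaml` stores, per group (HCM_VF, HCM, pooled HCM,
control) and phase, the marginal distribution of each whole-heart measure
(mean AT, AT dispersion, AT gradient, mean ARI, ARI dispersion, ARI
gradient), heart rates, and the prevalences of four qualitative map
patterns.  Where a group/phase value was not reported (the groups did not
differ significantly there), a fixed documented value is used and marked
"chosen" in the file.

Subjects are drawn from a latent multivariate normal with a correlation
structure built from three rules: different measures within a phase 0.30
(except mean AT vs mean ARI: 0.21 — the model pair is poorly correlated);
the same measure across phases 0.72 (0.93 for mean AT, which is why the
peak-phase mean AT is the collinearity casualty in model building);
different measures across phases 0.25.  The matrix is checked for positive
definiteness at load time.

Two refinements matter for fidelity:

* **Non-Gaussian model-pair marginals.**  The recovery-phase mean AT and
  mean ARI of the two HCM groups are sampled through shared monotone
  broken-stick (two-slope piecewise-linear) transforms of the latent
  normal.  The latent group shifts are set from the reported rank-sum
  separations (rank AUC ≈ 0.80 for mean AT, ≈ 0.74 for mean ARI), and the
  transform parameters are solved so the group means and SDs match the
  reported values: a heavy *low* tail for AT (giving the non-VF group the
  larger SD) and a heavy *high* tail for ARI (giving VF survivors the
  larger SD), both as reported.  A bivariate normal with the reported
  moments cannot reproduce the reported rank separation or the
  cross-validated model discrimination; the reported tests themselves say
  the measures were not Gaussian.  The frozen transform constants live in
  the preset file.
* **Matched sample moments.**  By default the latent draws of each cohort
  are affinely standardized so the sample mean/covariance equal the preset
  values exactly ("matched" mode; population sampling is available).  The
  published values are the observed cohort's sample statistics, and
  matching removes the large cohort-lottery variance that would otherwise
  dominate any single-seed model evaluation.
* **Pattern flags.**  Three patterns are Bernoulli draws at the group
  prevalence.  The late-activation-patch flag is instead assigned to the
  subjects with the highest sampled activation-gradient targets (marginal
  prevalence preserved): late patches ring themselves with steep
  gradients, so their presence co-varies with the whole-heart gradient.

## 4. Ground-truth fields

`build_truth_fields` turns one subject's target metrics into node-level
true AT and RT.  The AT field is an apico-basal ramp plus
squared-exponential correlated noise (length scale 15 mm) plus, when the
late-patch flag is set, one plateau patch (8 mm flat core, 6 mm
raised-cosine taper, fixed 9 ms height) centred mid-ramp at a node whose
8-mm ball holds at least 5 nodes, so the sampling can resolve it.  The ARI
field is built analogously (gentler apico-basal trend, 7 mm noise, an
optional apical prolongation bump); RT = AT + ARI, and ARI is positive
everywhere by construction.  T-wave polarity is set by the apical-inversion
and isolated-patch flags.

Calibration is exact for the mean (shift) and the central-95% dispersion
(scale), and iterative for the gradient: the correlated-noise weight is
bisected until the markers module's own 5-mm plane-fit gradient on the
true field matches the target within 2% or 0.01 ms/mm.  When a sampled
gradient target lies below the smooth-field floor, or an extreme tail draw
exceeds what the noise can produce, the nearest achievable value is
recorded and flagged rather than aborting the cohort.  The residual
upward pull on the VF group's mean activation gradient is a few percent;
it is the irreducible cost of injecting *detectable* patches at a 200-node
sampling density.

## 5. Waveform synthesis

Each node's beat is built from three analytic pieces on the 1 kHz grid:

* a **far-field QRS envelope** shared by all nodes: its derivative is a
  positive bump starting exactly at the beat onset (the map's global QRS
  start) with sharp onset/offset edges and duration ≥ 105 ms;
* an **intrinsic deflection**: a 12 ms negative cosine derivative lobe
  centred at the node's AT, scaled so the discrete QRS derivative
  integrates to zero (the complex returns to baseline) — this makes the
  steepest negative slope fall exactly at AT;
* a **T wave**: a raised cosine of width 160 ms (110 ms at peak exercise,
  where the shorter cycle length leaves no room for a broad T) whose
  steepest *positive* slope falls exactly at RT — at RT − w/4 into an
  upright T, at RT − 3w/4 into an inverted one, which is what makes the
  Wyatt convention polarity-independent.

Every generated beat is verified by numerical differentiation (argmin and
argmax of dV/dt at AT and RT within 1.5 samples) before use.  Beats repeat
at RR intervals drawn per subject from the group heart rate with 3%
jitter, floored at max(RT) + 0.8·T-width + 30 ms so the latest T wave ends
before the next QRS; baseline wander (0.25 Hz sinusoid at 30% of the QRS
amplitude) and white noise (SD 2% of the QRS amplitude) are added on top.
Ten beats per strip.  QRS amplitude is normalized per node; all
delineation thresholds are relative, so absolute amplitude is arbitrary.

## 6. The processing chain

1. **Baseline removal** — zero-phase 2nd-order Butterworth high-pass at
   0.5 Hz (zero-phase preserves the dV/dt timing the markers depend on);
   ≥ 24 dB attenuation at the 0.25 Hz wander frequency.
2. **Common beat windows** — all nodes are channels of one recording, so
   the regions of interest averaged per node must be the *same* time
   windows; per-node anchoring would destroy the inter-node activation
   timing that the map metrics measure.  Beats are detected and
   template-matched on the map-mean smoothed |dV/dt| envelope; each window
   spans one estimated beat period plus margin.  Up to 10 non-overlapping
   windows above a 0.8 correlation floor are used; a shortfall is recorded,
   not fatal.
3. **Signal averaging** — pointwise mean over the shared windows.  The
   generic `signal_average` aligns windows to the template by maximal
   cross-correlation; the map pipeline passes zero alignment shift because
   the shared windows are already at their matched lags and per-node
   re-alignment would re-introduce timing jitter.
4. **Delineation** — deterministic slope thresholds replacing the original
   pretrained network with the same output contract.  QRS: the first
   strong suprathreshold run of smoothed |dV/dt| (θ_qrs = 0.2 of the
   window maximum; "first" because at peak heart rates the next beat is
   inside the window), expanded outward while |dV/dt| stays above a
   hysteresis floor (max of 1.5% of peak and 2.5× the baseline noise,
   estimated from the quietest 25 ms block), bridging sub-floor stretches
   shorter than 15 ms — the zero crossings between the R and S limbs of
   one complex.  T: the longest merged suprathreshold region (θ_t = 0.15
   of the post-QRS maximum, floored at 4× baseline noise) after the QRS
   and before the next beat.  Per-node QRS onsets snap to the map-level
   onset when within one smoothing width: the global onset is estimated
   from the envelope's rising edge by tangent extrapolation (the ~200-
   channel average makes it accurate to about a sample), and no single
   node resolves the QRS foot better than that.
5. **Quality rejection** — T-wave peak-to-peak below 5% of the QRS
   peak-to-peak, or three or more prominent T deflections (prominence
   ≥ 10% of the segment's peak-to-peak), or no T region at all; reasons
   are recorded per node.
6. **Markers** — global time zero is the minimum QRS onset over accepted
   nodes.  LAT/LRT are located as the argmin/argmax of the 10 ms-smoothed
   derivative inside the QRS/T windows (earliest sample on ties), then
   polished by a least-squares parabola on the *raw* derivative (±6 ms for
   LAT, ±22 ms for the gentler T upstroke).  The two-stage estimator
   matters: the smoothed trough is flat, and interpolating it directly
   scallops the sub-sample timing with each node's phase on the sample
   grid — a spatially rough error that inflates the 5-mm gradient metric.
7. **Whole-heart metrics** — mean, central-95% dispersion (linear-
   interpolation percentiles) and the mean 5-mm gradient over accepted
   nodes (≥ 10 required).  The per-node gradient is the norm of the
   least-squares plane slope over the node and its ≤ 5 mm neighbors
   (≥ 3 points); spatial directions the neighborhood barely spans
   (singular value < 5% of the largest) are excluded from the fit, which
   keeps near-collinear point sets from blowing it up while remaining
   exact on well-sampled linear fields.  A max-range/max-distance variant
   is available behind `gradient_method` for sensitivity analysis.
   Rate correction uses Bazett (interval/√RR), a declared stand-in.

## 7. Pattern detectors

The published pattern calls were visual; the detectors are declared
numeric stand-ins.  A **late patch** is a connected set of ≥ 4 nodes each
activating ≥ 4 ms later than the median of its 10–24 mm surrounding
annulus — local contrast, which is what visual "isolated patch" reading
responds to (a global mean + k·SD rule cannot work: on any monotone
apico-basal field the late ramp end is always a connected suprathreshold
set).  **Apical ARI prolongation**: apical-third mean ARI exceeds the
basal third by ≥ 10 ms.  **Apical T inversion**: > 50% of apical-third
nodes negative.  **Isolated T patch**: a connected negative-T set of ≥ 4
nodes ringed by positive-T nodes.  Rough high-gradient maps genuinely
contain small noise-built late regions, so the late-patch detector fires
on a sizable fraction of maps without injected patches; prevalences are
cohort-specific and are not treated as quantitative reproduction targets.

## 8. Statistics and the risk model

Two-group comparisons use the Wilcoxon rank-sum test — exact enumeration
over rank assignments (tie-aware) when both groups have n ≤ 8, otherwise
the tie-corrected normal approximation; multi-group comparisons use
Kruskal–Wallis with a chi-square p-value.  Proportions are compared on the
variance-stabilizing arcsine scale with Cohen's *h* as the effect size
(the study's "T test" phrasing for proportions is interpreted this way,
as documented).  No multiple-testing correction is applied, matching the
original analysis plan.

The risk model follows the study's recipe exactly: qualifying measures
(univariate rank-sum p < 0.05) are z-scaled; of any pair with Pearson
|r| ≥ 0.9 the peak-phase member is dropped; Newton–Raphson maximizes the
binomial likelihood (gradient norm < 1e-8 or 50 iterations; Wald SEs from
the observed information; odds ratios back-transformed to per-millisecond
units; likelihood-ratio p against the intercept-only model); backward
stepwise removal of the largest Wald p > 0.15.  Quasi-complete separation
(|scaled coefficient| > 15) raises an error naming the covariate in direct
fits and returns a capped, flagged fit inside cross-validation.

Cross-validation is stratified 5-fold, repeated (default 20×), with the
scaling parameters learned inside each training fold — a deliberate
strengthening against leakage.  Pooled (concatenated) held-out predictions
give the reference AUC (rank statistic, ties counted half) and the
balanced accuracy at the fixed 0.5 threshold; the Youden operating point
is read off the ROC of each subject's out-of-fold probability *averaged
across repeats* (the "aggregated models" reading — an empirical Youden
point on a single pooled run is strongly optimistic at n = 37, which is
visible in the reported sensitivity/specificity), with the per-repeat
average also reported.  Confidence intervals are percentile intervals over
repeats.

## 9. Emulations and problem sizes

`epicardio.emulation` packages the study-level runs used by the acceptance
script and tests: the model emulation averages 20 replicate cohorts
(17 + 20 subjects; each with 20×5-fold CV) because a single synthetic
cohort's pooled AUC carries sampling noise of several points even with
matched moments; the full-waveform emulation generates complete cohorts
(37 pooled-HCM, 32 controls, 17 VF survivors; 200-node shell, 10 beats,
default noise, peak phase) through the entire chain — about 0.3 s per
subject — with the control and VF cohorts run as two and three seeded
replicates respectively to stabilize the tightest targets.  All randomness
descends from one root seed through spawned seed sequences, so per-subject
results are stable when cohort sizes change.

## 10. What the synthetic conditions do and do not show

The generator reproduces cohort-level distributions, rank separations,
pattern prevalences and waveform structure sufficient to exercise every
processing stage against known truth.  It does **not** emulate: real
inter-node waveform morphology variation (all beats of a node are
identical up to noise; QRS/T shapes are analytic pieces), reconstruction
artifacts of inverse ECGi (spatially correlated timing errors of up to
~10 ms reported for such systems), fractionated or low-voltage
electrograms, ectopy or other rhythm disturbance, anatomically realistic
geometry (Section 2), or any within-subject coupling between the AT and
ARI fields beyond their whole-heart summary correlation.  Passing tests
therefore demonstrate the *pipeline's* correctness and the
reproducibility of the published statistics under these stated
conditions — not the accuracy of electrocardiographic imaging itself.

Known numerical limitations: marker timing is quantized by the 1 kHz grid
before sub-sample refinement; the whole-heart gradient is mildly inflated
(≈ +0.01–0.02 ms/mm) by residual marker jitter interacting with sparse
plane-fit neighborhoods; heart rates drawn above the RR floor are clipped,
so peak-phase heart-rate distributions are truncated at the fast end; and
the VF-group activation gradient runs a few percent above its target
because detectable late patches steepen 200-node maps (Section 4).
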