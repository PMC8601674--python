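# Methods

## Signal model

The sequence model is an RF-spoiled steady-state gradient echo with a
constant low flip angle and a multiecho ultrashort-TE readout. The
closed-form signal at echo time TE is

    S = PD · sin α · (1 − E1) / (1 − E1 cos α) · exp(−TE/T2*),  E1 = exp(−TR/T1).

Defaults: α = 5°, TR = 5 ms, echoes at 0.1/1.2/2.3 ms. The flip angle is
the one printed for the clinical sequence; TR and the echo train are
representative UTE timings and are configurable — nothing downstream
assumes their exact values. Fat is a second pool (T1 = 380 ms,
T2* = 30 ms) removed entirely when fat saturation is enabled; saturation
is modelled as perfect because no further detail is available.

The Bloch simulator iterates tip → echo readout → T1 relaxation over TR
with ideal spoiling (transverse magnetization zeroed every TR; RF phase
cycling is out of scope). It exists as an independent derivation of the
same physics: steady state must match the closed form to 1e−3 relative,
and the simulator flags non-convergence (relative Mz change > 1e−6
between the last two repetitions) instead of failing silently.

Lung tissue maps water fraction w to parameters as PD = w with relaxation
*rates* interpolating linearly between a dry-parenchyma anchor
(T1 = 1100 ms, T2* = 0.5 ms at w = 0) and free water (T1 = 3000 ms,
T2* = 50 ms at w = 1). The anchors are order-of-magnitude literature
values; only the *linearity conclusion* — that the 5° sequence stays
linear in w although T1 and T2* co-vary with it — is asserted anywhere,
never the anchor numbers themselves. The anchors sit at w = 0 and w = 1 so
that the interpolation rule has the simple property 1/T1(0.5) = mean of
the anchor rates.

## Phantoms

The sponge phantom thresholds a Gaussian-smoothed white-noise field
(correlation length = pore scale, default 3–4 px) at the quantile that
makes the pore area fraction equal the requested fill fraction; pores are
water (w = 1), matrix is empty. Filling one fixed texture (fixed seed) to
different fractions is the digital analog of progressively doping a
physical sponge.

The thorax slice is built from five analytic ellipses (body, two lungs,
heart, optional posterior-basal effusion inside the right lung) painted in
that order, with small seed-driven jitter (±2 mm centers, ±3% axes) for
inter-subject variation. Ellipses give the slice an exact closed-form
Fourier transform, so acquisition can be simulated without an inverse
crime. Geometry never depends on the lung water fraction: rest/stress
pairs share identical label maps.

## Motion model

Exercise motion is rigid: a sinusoidal superior-inferior breathing
excursion (projected in-plane) plus, per sampling event with a configured
probability, a random jitter burst of bounded magnitude. Because
superior-inferior motion is largely through-plane for an axial slice, a
displacement of s mm also multiplies the slice signal by
(1 + 0.02·s) and imparts a spoke-wide phase of 0.3·s radians (motion
through the slice-select gradient). These couplings are what make
corrupted spokes observable at the k-space center; pure in-plane
translation would leave the center sample invariant. `displace()` itself
is a pure translation (periodic pixel roll, conserving total proton
density exactly); the through-plane modulation applies at acquisition
time.

## Acquisition

Spokes are center-out half-lines rotated by the full-circle golden angle
π(3 − √5) rad = 137.5078°, giving near-uniform angular coverage for any
spoke count (the 111.25° variant applies to full-diameter spokes covering
π). Readouts are 2× oversampled along the spoke (sample spacing
1/(2·FOV)), standard for center-out radial; without it the
density-compensated quadrature of the steep low-k spectrum biases
reconstructed amplitudes by several percent. Samples are the continuous
Fourier transform of the signal-weighted phantom: exact for ellipses,
direct NDFT on the phantom's fine grid for sponges (the reconstruction
grid is half the sponge grid, so simulation and reconstruction never share
a discretisation). Translation enters as its exact phase ramp; complex
white noise is added last; everything is deterministic given the seeds.

## Reconstruction

Gridding approximates the conjugate-phase sum Σ wᵢ Sᵢ e^{+2πi kᵢ·x} with a
width-4 Kaiser-Bessel kernel (Beatty β) on a grid oversampled by the
configured factor (default 2, i.e. reconstruction at twice the field of
view with central cropping). Deapodization divides by the image of a
single unit sample gridded at k = 0, which cancels all kernel and FFT
constants exactly — reconstructed pixel values are on the forward model's
tissue-signal scale with no empirical calibration. Density compensation
is the analytic radial area element with per-spoke angular extents taken
from the actual gaps between (kept) spokes; Pipe-Menon iterative weights
are available and are stopped after 8 passes, where the iteration has
converged but k-space-edge effects have not yet leaked inward.

The motion filter scores each spoke by the deviation of its complex DC
sample from the componentwise running median over 15 spokes — slow
breathing drift is tracked by the median, sudden bursts are not — and
zeroes spokes beyond 3 median-absolute-deviations. Survivors' angular
extents widen to cover the gaps, keeping amplitudes unbiased. With 2×
FOV reconstruction and cropping, residual streak energy preferentially
lands outside the cropped lung region. The filter targets burst-like
corruption; smooth respiratory translation blur affects all spokes
equally and is not correctable by rejection — acquisitions dominated by
large breathing excursions see little benefit.

TE→0 extrapolation fits a per-pixel log-linear decay across the echo
images and evaluates it at TE = 0, falling back to the first-echo value
wherever any echo magnitude is non-positive (fallback fraction reported).

Correctness is anchored to two explicit-DFT references: a conjugate-phase
direct sum with identical weights (isolates the kernel/FFT machinery,
agreement ~1e−3 NRMSD) and a least-squares solve of the encoding matrix
with singular values truncated at 1e−2 of the maximum (the raw system is
ill-conditioned at fine radial spacing), which is accuracy-limited only by
the pixel basis and agrees with gridding to NRMSD ≤ 0.05 on 32² problems.

## Quantitation

The default ROI statistic is the *sum* over the lung mask: the cohort's
lung-water values are integrated ROI signal on a ~10⁴ AU scale against
which changes of a few hundred AU are reported; mean and median are
offered for per-pixel interpretation. Rest and stress ROIs are contoured
independently with no coregistration, mirroring the manual workflow. ROI
masks derived from thorax phantoms are eroded by 1 px so Gibbs ringing at
the pleural boundary stays outside. The look-up table maps the window
linearly to 0–255 with clipping; the midpoint rounds half-to-even to 128.
Bland-Altman limits are bias ± 1.96·SD of paired differences (n − 1
denominator).

## Cardiac metrics

Peak filling rate: the volume-time curve is smoothed by a
Savitzky-Golay filter (window 9 phases, order 2) and differentiated by
central differences on the true timestamps; the diastolic limb runs from
the global volume minimum (searched over the first 90% of the cycle, so
boundary noise cannot masquerade as end-systole) to the end of the cycle.
The window was widened from the conventional 5 because, at 30 phases and
1 mL noise, a 5-phase window lets noise bias the derivative peak by up to
~19%, versus ≤ 7% at window 9 with only ~1% attenuation of a clean cosine
peak. Chamber volumetry takes EDV/ESV as the curve extrema with the exact
identities SV = EDV − ESV, EF = 100·SV/EDV, and the RV coupling surrogate
SV/ESV.

PCr/ATP is (PCr·f_PCr)/((ATP − c_blood·DPG)·f_ATP). The saturation
factors and blood-contamination coefficient default to identity (1.0 /
0.0) and are configuration, not constants: the published correction values
live in external references and sites should set their own.

## Cohort statistics

Jonckheere-Terpstra: J sums between-group Mann-Whitney counts (ties ½)
over the severity ordering control < T2D < HFpEF < amyloid. The exact
method computes the tie-free null as the convolution of independent
Mann-Whitney null distributions U(N_{h−1}, n_h) — a dynamic program, not
an enumeration — and refuses tied data; the permutation method (seeded,
vectorised, default 10⁴ resamples) handles ties; the normal approximation
uses the tie-corrected variance without continuity correction. One-sided
p is against the increasing alternative; two-sided doubles the smaller
tail.

Wilcoxon signed-rank drops zero differences, requires ≥ 5 non-zero pairs,
and uses the exact null for n ≤ 20 tie-free differences (normal
approximation with continuity correction otherwise). Kruskal-Wallis uses
the tie-corrected H; Dunn z statistics come from pooled mean ranks with
tie-corrected variance, Holm-adjusted by default (the adjustment method is
configurable; the choice of Holm is ours, as none is prescribed).

Mediation follows the Preacher-Hayes single-mediator scheme on raw
(unstandardised) complete cases: path a from m ~ x, path b and the direct
effect from y ~ x + m, indirect = a·b, with a bias-corrected (BC, no
acceleration) percentile interval from seeded case-resampling bootstrap
(default 5000 resamples; ≥ 1000 enforced). Three separate single-mediator
models — not one multi-mediator model — mirror how the three moderator
analyses are reported. The batched bootstrap solves the normal equations
for all resamples at once.

The synthetic cohort generator draws each metric per group from a normal
matched to a target median and IQR through stratified (quantile-spaced,
jittered, permuted) uniforms, so sample medians converge tightly to the
targets; group sizes default to 11/9/14/9. PCr/ATP and the lung-water
changes use the cohort's printed medians/IQRs; the echocardiographic and
exercise-reserve metrics are plausible graded values chosen once. Metrics
are drawn *independently* within subjects: the generator reproduces
marginal group gradients, not between-metric correlation structure, so
passing trend tests on it says nothing about real-data mediation effects —
mediation is validated instead by parameter recovery on explicitly
constructed x→m→y chains.

## What the synthetic data does not emulate

Phantoms are 2D, single-coil, noise-white, with rigid motion only — no
deformation, perfusion, B0 inhomogeneity, coil shading or gradient
delays. Sponge pores are binary water/matrix. Consequently, passing tests
demonstrate the internal consistency and contracts of the measurement
chain (linearity, motion rejection, quantitation identities), not
performance on clinical data.

## Problem sizes

Default desk-scale sizes: 128² phantoms reconstructed at 64², 200 spokes,
8 water fractions for the linearity experiment, 200 repetitions for
bootstrap-coverage studies, 10 seeds for the motion contract. These sizes
put every experiment at seconds-to-a-minute on one CPU while keeping all
acceptance margins comfortable.
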