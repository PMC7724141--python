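# Methods

This note documents the models implemented in `scwm`, the choices made
where the design was genuinely open, and what the synthetic-data tests
do and do not establish.

## Coordinate and timing conventions

Polar angle is measured counterclockwise from the right horizontal
meridian, in degrees on [0, 360); Cartesian y > 0 is the upper visual
field. All times are in seconds; the sampling interval (TR) is 1.5 s.
The modeled field of view is a square of half-width 16 degrees.

## Forward model and HRF

A voxel's population receptive field (pRF) is a 2D isotropic Gaussian
with center (x, y) and size sigma (degrees of visual angle). Neural
drive at each TR is the Gaussian-weighted fraction of the visual field
covered by the stimulus aperture, normalized so a full-field aperture
gives drive 1. The BOLD prediction is

    BOLD(t) = amplitude * (drive * HRF)(t) + baseline

The HRF is a difference of two gamma densities parameterized directly
by their modes — delay to peak (default 6 s) and delay to undershoot
(default 16 s) — each scaled to unit peak before the undershoot is
subtracted with a fixed amplitude ratio of 1/6. This gives exactly the
two free temporal parameters the fitting stage estimates. The simulator
and the pRF model share this code path, so a noiselessly simulated
voxel is reproduced exactly by the model's prediction.

The retinotopy stimulus is an 8-degree-wide bar sweeping the display in
four 30 s passes (L→R, R→L, T→B, B→T) with 12 s blanks at both ends of
the run: 96 frames at TR 1.5 s. The bar's center traverses the full
extent linearly, one position per TR (the step size is a modeling
choice; only the 8-degree width, sweep and blank durations are fixed by
the task description).

## pRF fitting

Three stages, each seeding the next:

1. **Coarse grid search** over x, y on a 2-degree lattice spanning the
   extent and sigma in {0.5, 1, 2, 4, 8} degrees, against the movie
   spatially downsampled by bilinear interpolation to 5% of its
   original resolution (floored at 16 pixels per axis so that already
   low-resolution synthetic movies retain usable spatial structure).
   Amplitude and baseline are profiled out in closed form at every grid
   point, so the best point maximizes a centered correlation computed
   in a single matrix product.
2. **HRF delay search** over peak in [4, 9] s (0.5 s steps) and
   undershoot in [10, 20] s (1 s steps), holding the spatial seed
   fixed. Series that cannot constrain the delays (flat or unfittable,
   r² below 1e-3) keep the defaults and are flagged.
3. **Refinement** by bounded L-BFGS-B over (x, y, log sigma, peak,
   undershoot) on the full-resolution movie, amplitude/baseline again
   profiled; at most 500 iterations. The refined fit is discarded (and
   flagged unconverged) if it would lower r² relative to its seed, so
   refinement is monotone by construction.

Goodness of fit is r² = 1 − SSR/SST. ROI selection keeps voxels with
r² ≥ 0.1 (boundary inclusive). If no voxel passes, the pipeline raises
rather than silently proceeding; callers can substitute an anatomical
index set. The field-coverage map is the pointwise maximum over voxels
of unit-height pRF Gaussians; size–eccentricity scaling is summarized
by OLS of sigma on eccentricity plus a Pearson correlation.

## Memory-guided saccade task and its simulation

Each run holds 16 trials of 22.5 s: a 300 ms peripheral sample at one
of eight polar-angle bins (22.5°–337.5° in 45° steps, jittered ±10°,
eccentricity uniform in 9–11°), a 10.5 s memory delay, a 400 ms
visually guided saccade (VGS) target at a uniformly random angle inside
a 1.4 s saccade window, 500 ms feedback, and a 9.8 s intertrial
interval. The event chain sums to 22.5 s exactly when the VGS dot is
counted inside the saccade window, which is the reading adopted. Each
run samples every bin twice; the four transformation conditions (same,
mirror across the horizontal meridian, across the vertical, across
both) are counterbalanced so that every (condition, bin) cell occurs
exactly once per pair of successive runs. The memory target (MGS goal)
is the condition's reflection of the sample location.

The WM simulator anchors each voxel's polar-angle tuning to its pRF
polar angle — the retinotopic-architecture assumption made explicit —
with tuning curve T(Δ) = ((1 + cos Δ)/2)^p (default p = 1, the same
functional family as the encoding-model basis, making the encoding
model's generative assumption exactly true in the noiseless limit).
Responses encode one reference location per dataset (visual sample,
VGS target, or MGS goal); trial noise is white Gaussian with SD =
amplitude/SNR. A time-series mode places the tuned response as a boxcar
over the delay and convolves with the HRF; runs are 240 TRs.

## Inverted encoding model

Nine channels tile polar angle, f_k(θ) = cos²((θ − c_k)/2) =
(1 + cos(θ − c_k))/2, centers 40° apart. The basis partitions: the
channels sum to 9/2 everywhere. Because this basis contains only a DC
term and the first circular harmonic, any channel design matrix built
from it has rank exactly 3; weight estimation is therefore the
minimum-norm least-squares solution, the design is required to reach
rank 3 (at least three distinct training angles), and "exact weight
recovery" holds precisely for weights inside the recoverable subspace —
e.g. weights that are basis functions evaluated at voxel preferred
angles, which is how the round-trip tests generate ground truth.

Trial responses are the mean of the last four TRs of the delay (a TR
belongs to the delay if its acquisition midpoint falls inside it; with
a 10.5 s delay at TR 1.5 s that is TRs 4–7 of seven). Trials are then
combined in seeded random pairs within (condition × bin) cells —
halving trial count while preserving counterbalancing — with combined
angle labels the circular means of the pair. Odd cell counts raise by
default; `on_odd="drop"` discards one random trial per odd cell (needed
for, e.g., 10-run sessions where cells hold five trials).

Training uses only untransformed ("same") trials; weights are inverted
by Moore–Penrose pseudoinverse (ridge regularization is available but
off by default) to estimate channel coefficients for the transformed
trials, and reconstructions are evaluated analytically from the basis,
so circular alignment to a reference location introduces no
interpolation error and rotational equivariance holds to machine
precision. The bootstrap repeats the twofold pairing (retraining each
iteration by default) to confirm results are not artifacts of one
particular trial recombination.

## Fidelity and inference

Two statistics summarize how strongly an aligned reconstruction points
at the true location:

* **basic fidelity** F = mean_θ recon(θ)·cos(θ): the projection of the
  reconstruction, read as weighted unit vectors, onto the true
  direction. It is zero for flat profiles and sign-symmetric, so its
  permutation null is centered on zero; all null-calibration checks use
  this form.
* **modified fidelity** F = ⟨f_std, f_recon⟩ · g(err): the inner
  product with a raised-cosine standard tuning at the true location
  (grid-mean normalized, so resolution-independent), multiplied by a
  cost g(err) = exp(−err²/(2κ²)) of the circular distance between the
  reconstruction peak and the true location, κ = 90° (the standard
  tuning's half-width at half-maximum), g(0) = 1. Both factors decrease
  as a fixed profile is rotated off-target, so the statistic is
  strictly decreasing in the rotation. It is not sign-symmetric: its
  null is positively offset by the reconstruction's mean level, which
  is why calibration checks use the basic form. A mean-centered variant
  was considered and rejected because centering destroys the
  monotonicity (the cosine factor changes sign and the decaying cost
  then raises values near 180°).

The permutation null retrains the model after shuffling the
training-trial angle labels (shuffling voxel order is available as an
alternative) and recomputes the aligned fidelity; the bootstrap
distribution of the real data is compared against it with a two-sample
KS test per subject and a paired t test over bootstrap-stabilized
subject means at the group level.

Two properties of this null are worth knowing. First, a shuffled-label
model fit to n training trials retains a residual angular coupling of
order 1/√n whose inversion is further amplified when the shuffled
weight map is weakly conditioned, so single-dataset null draws can
exceed the statistic's noiseless ceiling; group-level nulls (means over
subjects at each permutation index) are correspondingly tighter, and
the selectivity analysis is therefore run at the group level, as in
the group-mean figures it emulates. Second, when delay activity encodes
the MGS goal, reconstructions aligned to the *visual* sample are
systematically anti-tuned at exactly −1/3 of the MGS tuning: the
mirror-both condition places every reconstruction peak 180° from the
visual reference while the single-mirror conditions cancel. This is a
real geometric prediction of the task design, visible at high SNR. The
selectivity check consequently compares all three reference fidelities
against one common null — the shuffled-training null of the MGS-aligned
analysis, the widest of the three and hence conservative — rather than
against per-reference nulls, whose widths scale with the same geometric
factors as the real values and would make the joint check insensitive
to any implementation.

The pRF↔IEM tuning comparison filters voxels to pRF eccentricity ≥ 5°
(the task only stimulates the periphery), takes each voxel's tuning
peak from its weight row summed over channels, and computes the
Fisher–Lee circular correlation with the pRF polar angle; p values come
from label permutation (default 10,000). The Fisher–Lee pair sums are
evaluated with an O(n) identity, verified in tests against the literal
O(n²) definition. The univariate delay summary reports the change of
the last-four-delay-TR mean versus a 3 s pretrial baseline, split by
whether the MGS goal is contralateral or ipsilateral to a voxel's
hemisphere, with a one-tailed t test against zero.

## Pipeline, determinism, problem sizes

`run_full_pipeline` chains simulate → detrend/z-score (per voxel per
run; zero-variance voxels are zeroed and flagged) → pRF fit → ROI →
WM simulation → delay averaging → IEM per reference → fidelity with
permutation null → pRF/IEM tuning comparison → summary. Every stage
consumes a named seed derived from the config seed; all floats are
serialized at 17 significant digits (exact float64 round trip), so
reruns with one config are byte-identical and cached stage outputs can
be reloaded without changing downstream numbers.

Default analysis sizes were chosen so a full desk-scale run completes
in minutes on one core: 200 voxels for pRF recovery, 6 synthetic
subjects × 100 voxels × 10 runs (160 trials) at SNR 2 for the
selectivity analysis, 1000-draw permutation nulls, 100-seed replication
for the size–eccentricity interval coverage. Generator defaults
(eccentricity ≤ 12°, size = 1.0 + 0.2·ecc + truncated N(0, 0.3²)
floored at 0.1°, amplitude 1, HRF 6/16 s) are stated once in
`scwm.synth` and reflect typical collicular/early-visual pRF scales.

## What the synthetic tests do not show

The generator emulates the task structure, retinotopic tuning
architecture, HRF dynamics and white measurement noise. It does not
emulate physiological noise spectra (temporal autocorrelation is off by
default), partial-volume or draining-vein effects, eye movements,
attention or arousal fluctuations, nonlinear hemodynamics, or any
spatial correlation between voxels. Passing recovery tests therefore
demonstrates correctness of the estimators under their own generative
assumptions — not performance on real collicular data, where effect
sizes are orders of magnitude smaller and noise is structured.
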