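# scwm

Population receptive field (pRF) mapping and spatial inverted encoding
models (IEM) for testing whether delay-period activity in a retinotopic
brain region encodes locations held in spatial working memory —
implemented end-to-end on synthetic voxel data with known ground truth.

The package is aimed at computational-neuroimaging researchers who want
a tested, reusable version of this analysis chain: a bar-sweep
retinotopy simulator and Gaussian pRF fitter, a memory-guided-saccade
(MGS) task generator whose mirror transformations dissociate the
remembered location from the visual stimulus and from the saccade
metrics, a polar-angle encoding model, and a representational-fidelity
statistic with permutation inference.

## Models

**pRF.** Each voxel's BOLD series is modeled as
`amplitude * (drive ⊛ HRF) + baseline`, where the drive is the overlap
between the stimulus aperture and a 2D Gaussian N((x, y), σ²) in
visual-field coordinates, and the HRF is a difference of gamma
densities parameterized by its delay to peak and delay to undershoot.
Fitting is a coarse grid search (amplitude/baseline solved in closed
form), an HRF-delay search, and a bounded quasi-Newton refinement;
voxels with r² ≥ 0.1 form the ROI.

**IEM.** Voxel responses are weighted sums of nine channels
f_k(θ) = cos²((θ − c_k)/2) tiling polar angle (Σ_k f_k ≡ 4.5). Weights
W solve min ‖B_train − C_train Wᵀ‖² on trials where no spatial
transformation was required; channel coefficients for held-out
transformed trials are recovered as C_test = B_test (Wᵀ)⁺, and the
reconstruction is the coefficient-weighted sum of basis functions,
aligned to a reference location and averaged.

**Fidelity.** The basic statistic projects the reconstruction onto the
true direction, F = mean_θ recon(θ)·cos(θ − θ_true); the modified
statistic multiplies the inner product with a raised-cosine standard
tuning by a cost g(err) = exp(−err²/(2·90°²)) of the reconstruction's
peak error. Significance comes from retraining the model after
shuffling training labels (10,000 permutations at study scale), with a
KS test per subject and a paired t test across subjects.

See `docs/methods.md` for conventions, defaults, and known limitations.

## Worked example

```python
import numpy as np
from scwm import iem, prf, stats, stimulus, synth

# 1. simulate a retinotopy run for 50 voxels and fit their pRFs
movie = stimulus.make_bar_aperture_sequence()
voxels = synth.sample_ground_truth_voxels(50, noise_sd=0.5, seed=1)
bold = synth.simulate_retinotopy_run(movie, voxels, seed=2)
fits = prf.fit_prf(bold, movie)
roi = prf.select_roi(fits, r2_threshold=0.1)
line = prf.size_eccentricity_stats([fits[i] for i in roi])
print(f"{roi.size}/50 voxels pass r2 >= 0.1; "
      f"size-ecc slope {line.slope:.3f} (r = {line.pearson_r:.2f})")

# 2. simulate the memory-guided saccade task, encode the MGS goal
trials = synth.make_wm_trial_schedule(n_runs=8, seed=3)
resp = synth.simulate_wm_dataset(trials, [voxels[i] for i in roi],
                                 encoded_reference="mgs", snr=2.0, seed=4)
trm = iem.TrialResponseMatrix(responses=resp, trials=trials)

# 3. train the encoding model on "same" trials, reconstruct the rest
basis = iem.make_channel_basis(9)
combined = iem.twofold_combine(trm, seed=5)
for reference in ("visual", "vgs", "mgs"):
    out = iem.train_and_reconstruct(combined, basis, reference)
    f = stats.fidelity_basic(out["profile"], out["grid_deg"])
    print(f"{reference:6s} aligned fidelity {f:+.3f} "
          f"(peak error {out['peak_error_deg']:.0f} deg)")

# 4. permutation inference for the MGS alignment
null = stats.permutation_null(trm, basis, "mgs", n_perm=500, seed=6)
real = stats.bootstrap_fidelity(trm, basis, "mgs", n_iter=200, seed=7)
ks, p = stats.subject_level_test(real["basic"], null["basic"])
print(f"real vs shuffled-training null: KS = {ks:.2f}, p = {p:.2g}")
```

Output:

```
50/50 voxels pass r2 >= 0.1; size-ecc slope 0.187 (r = 0.67)
visual aligned fidelity -0.166 (peak error 180 deg)
vgs    aligned fidelity +0.067 (peak error 43 deg)
mgs    aligned fidelity +0.499 (peak error 5 deg)
real vs shuffled-training null: KS = 0.93, p = 5.6e-138
```

Reading this: the generated delay activity encodes the *transformed*
memory location, and reconstructions aligned to it are strongly tuned
(fidelity +0.50, peak at the target), while alignment to the visually
guided saccade target yields none. Alignment to the visual sample shows
the expected *anti*-tuning of −1/3 of the MGS fidelity: in the
mirror-both condition the remembered goal is exactly opposite the
sample, so a model that encodes the goal necessarily peaks 180° from
the sample (see `docs/methods.md`).

A command-line interface wraps the same functions:

```bash
scwm simulate retinotopy --n-voxels 200 --seed 1 --out out/ret
scwm fit-prf --bold out/ret/bold.nii.gz --out out/fit
scwm run-all --seed 1 --out out/full
```

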