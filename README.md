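# octmotion

4D spatio-temporal deep learning for motion estimation from OCT volume
sequences — with a fully ground-truthed synthetic data generator, so the
whole study runs on a desk machine with no external data.

## The problem

Optical coherence tomography (OCT) images a millimetre-scale field of view
(FOV) at high spatial and temporal resolution.  During intraoperative
imaging the tissue region of interest (ROI) drifts out of the FOV, and
motion compensation needs an accurate estimate of the relative translation
Δs between the ROI's initial and current position.  Classical approaches
register a template volume against the current volume; when the motion is
large, the overlap shrinks and pairwise estimation degrades.  Fast OCT
systems can instead deliver a whole *sequence* of volumes x_{t0..t4}
following the drift — and a network that consumes the full 4D
(3 space × 1 time) tensor can exploit it.

This package implements that study end to end:

- **`octmotion.phantom`** — speckle tissue phantoms (surface + depth
  attenuation + log-normal speckle + coarse macrostructure) and sub-voxel
  acquisition of 32×32×32 volumes with a 5×5×3.5 mm FOV; shifts carry
  exact ground-truth labels in mm.
- **`octmotion.trajectories`** — smooth five-step drift trajectories from
  natural cubic splines through a random endpoint and connection point;
  Δs_t0 = 0, |Δs_t4| uniform over a configurable magnitude range;
  dataset assembly of R ROIs × P patterns.
- **`octmotion.augmentations`** — ramped axial-axis rotations
  (α_i = α_max/4·i; labels untouched in noise mode, rotated by R(α_i) in
  motion mode) and B-scan motion distortion (each B-scan shifted 1–2 px
  with probability p_dist).
- **`octmotion.nets`** — the five architectures: `two_path_3d`,
  `s_two_path_3d`, `five_path_3d`, `dense4d`, `five_path_4d`, built from
  weight-shared stems and a dense trunk (3 blocks × 2 layers, growth
  rate 10, average pooling, GAP, linear 3-vector head), including a
  from-scratch differentiable 4D convolution.
- **`octmotion.training`** — the MSE objective
  L = 1/N Σ‖Δs_tn − y_tn‖², its temporally regularized extension
  L + w_{n−1}‖Δs_{tn−1} − y_{tn−1}‖² + w_{n−2}‖Δs_{tn−2} − y_{tn−2}‖²,
  ROI-wise train/val/test splits, and a deterministic Adam training loop.
- **`octmotion.evaluation`** — MAE, rMAE (MAE normalized by target std),
  aCC (mean per-axis Pearson correlation, %), magnitude-binned errors,
  Wilcoxon signed-rank model comparisons and rotation/distortion
  robustness sweeps.
- **`octmotion.nn`** — the numpy reverse-mode autodiff toolkit the models
  run on (N-dimensional convolution with verified gradients, pooling,
  dense layers, Adam); no GPU or deep-learning framework required.

## Worked example

```python
from octmotion import benchmark as bm
from octmotion.evaluation import wilcoxon_compare

data = bm.desk_data(seed=7)                      # 20 ROIs x 50 patterns
two_path, _ = bm.train_desk_model("two_path_3d", data, seed=7)
five_4d, _ = bm.train_desk_model("five_path_4d", data, seed=7)

rep2, rmae2 = bm.evaluate_on(two_path, data.test)
rep5, rmae5 = bm.evaluate_on(five_4d, data.test)
print(f"two_path_3d : rMAE {rep2.rmae_mean:.3f}  aCC {rep2.acc_percent:.1f}%")
print(f"five_path_4d: rMAE {rep5.rmae_mean:.3f}  aCC {rep5.acc_percent:.1f}%")
print("wilcoxon p = %.2e" % wilcoxon_compare(rmae5, rmae2)[1])
```

prints (one CPU core, roughly one and five minutes of training
respectively):

```
two_path_3d : rMAE 0.592  aCC 75.0%
five_path_4d: rMAE 0.469  aCC 85.6%
wilcoxon p = 1.28e-05
```

The two-volume baseline sees only the first and last volume and loses
accuracy as the drift grows; the 4D sequence model uses the whole
trajectory — its rMAE is about 1.26× lower here and the paired
signed-rank test on per-sequence rMAE is significant at α = 0.05.  The
gap is concentrated at large motion: the per-magnitude-bin error grows
by 0.68 mm from the smallest to the largest quantile bin for the
baseline but only by 0.38 mm for the 4D model.  (rMAE is the mean
absolute error divided by the target standard deviation — 0 is perfect,
≈1 is a trivial predictor; desk-scale numbers move by a few hundredths
with the seed.)

A command-line pipeline wraps the same steps:

```sh
octmotion run --profile desk --seed 7 --out runs/desk
octmotion simulate --profile desk --out data/            # dataset only
octmotion train --data data/ --arch five_path_4d --w-n1 0.75 --w-n2 0.75 \
    --out models/
octmotion evaluate --model models/five_path_4d.npz --data data/ \
    --report reports/five_path_4d.json --p-dist 0.5 --dist-px 2
octmotion compare --a reports/five_path_4d.json --b reports/two_path_3d.json
```

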