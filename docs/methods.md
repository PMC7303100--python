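# Methods

This note documents the models, the synthetic data generator, the numerical
choices and the limits of what the desk-scale experiments can show.  It is
the design record of the package; empirical numbers quoted anywhere in the
documentation are produced by the test suite or by `scripts/acceptance.py`,
never asserted from memory.

## Problem setting

During intraoperative OCT imaging a tissue region of interest (ROI) drifts
out of the field of view (FOV).  The estimation task: given a time sequence
of five OCT volumes `x_t0 .. x_t4` (32×32×32 voxels covering ≈5×5×3.5 mm),
regress the relative translation Δs_t4 (mm) of the ROI with respect to its
initial position.  All shifts in a sequence are relative to the initial
position, not incremental, and Δs_t0 = 0 by construction.

A shared axis convention holds everywhere: index order (x, y, z) with z the
axial/depth axis, 0-based indices, FOV positions referring to the crop's
minimum corner, positive shifts moving the FOV in positive world
coordinates, and rotations measured counterclockwise about +z viewed from
+z.  One voxel is (5/32, 5/32, 3.5/32) mm — exact binary fractions, so
integer-voxel shifts incur no interpolation error at all.

## Synthetic acquisition model

The simulator replaces a galvo/stepper acquisition rig by sampling shifted
crops from a large *phantom* grid of scatter amplitudes (≥3× the FOV per
axis).  Acquisition at a sub-voxel shift uses trilinear interpolation; a
shifted FOV that would leave the phantom raises an error rather than being
zero-padded.  Shifts convert to stepper-motor steps through a linear
`Calibration` (default 1000 steps/mm) purely so labels can round-trip
through motor space the way a hand-eye-calibrated rig produces them.

The phantom texture is a product of:

- a smooth random top surface (Gaussian-filtered height field; correlation
  length 1.0 mm, amplitude 0.35 mm, mean depth 0.8 mm), giving the strong
  axial structure characteristic of OCT tissue scans;
- exponential depth attenuation below the surface (0.45 /mm);
- band-limited multiplicative log-normal speckle (σ = 0.7, grain 0.16 mm),
  the fine texture that makes sub-voxel correspondence possible;
- a coarser multiplicative heterogeneity field (σ = 0.6, correlation
  1.0 mm) emulating tissue macrostructure such as fiber bundles and fascia.

The macrostructure term matters: without it the phantom is laterally
statistically stationary at every scale above the speckle grain, which is
unrealistic for muscle tissue and leaves almost no lateral localization
signal once feature maps are spatially decimated.  All texture parameters
are exposed in the `phantom:` config block; setting the speckle and
macrostructure amplitudes and the attenuation to zero yields the degenerate
constant-below-surface phantom used in tests.

Values are normalized to [0, 1] per phantom; trilinear resampling cannot
leave that range.

## Trajectories

A motion pattern is five shifts sampled from a per-coordinate natural cubic
spline through Δs_0 = 0, a connection point Δs_c, and an endpoint Δs_4,
with knots at curve parameter u ∈ {0, 0.5, 1} and samples at
u ∈ {0, 0.25, 0.5, 0.75, 1} (so Δs_2 = Δs_c exactly).  Equal-parameter
rather than equal-arc-length sampling is used; for the gentle curvatures
involved the difference is small.

The endpoint direction is isotropic with its axial component compressed by
3.5/5 and renormalized — the compression respects the shallower axial FOV,
the renormalization keeps |Δs_4| exactly uniform over the configured
magnitude range (default 0.2–2.4 mm, i.e. up to roughly half the lateral
FOV, spanning near-total to small overlap).  The connection point is the
midpoint plus an isotropic Gaussian perturbation (σ = 0.15·|Δs_4|,
truncated at 2σ) so drifts are curved but stay inside the phantom.

## Augmentations

*Rotations.*  Volume i of a sequence is rotated about the depth axis by
α_i = α_max/4 · i (bilinear, about the volume centre at index 15.5,
out-of-support voxels filled by edge replication to avoid a dark-corner cue
correlated with the label).  In `noise` mode labels are untouched.  In
`motion` mode the lateral components of the step-i label are mapped by the
in-plane rotation R(α_i); the final-step label therefore transforms by
R(α_max).  The choice between R(α) and its inverse is a pure handedness
convention; the counterclockwise one is fixed here and documented.

*B-scan distortion.*  Each B-scan (plane at fixed slow-axis y index) is
independently selected with probability `p_dist` and shifted by 1 or 2
voxels along one uniformly chosen in-plane axis (x or z) with uniform sign,
vacated voxels edge-replicated.  This reproduces the standard model of
intra-volume motion artifacts as inter-B-scan shifts.

## Architectures

All five models share a backbone: dense blocks (2 layers, growth rate 10,
3 blocks joined by factor-2 average pooling), global average pooling and a
linear 3-vector regression head.  The initial stage differs: two or five
weight-shared 3D convolutional paths fused by channel concatenation
(`two_path_3d`, `five_path_3d`), pairwise estimation summed over the four
consecutive pairs (`s_two_path_3d`, trained end-to-end through the sum),
full 4D convolutions from the first layer (`dense4d`), or shared 3D paths
reassembled into a temporal axis feeding a 4D dense trunk
(`five_path_4d`).  Auxiliary heads predicting the two preceding shifts are
enabled by `aux_outputs` for temporal output regularization; they share the
GAP features and are ignored at inference.

The 4D convolution is implemented as a windowed tensor contraction
(implicit im2col + GEMM) identical to the nested-sum definition; the test
suite checks it against a six-nested-loop oracle and verifies analytic
gradients against central differences.  4D trunk pooling pools the temporal
axis together with space (ceil semantics: 5 → 3 → 2 frames) while more
than one frame remains.

Hyperparameters the backbone recipe leaves open default to: spatial kernel
3, temporal kernel 2, He initialization, bias in every layer, no
normalization (an instance-norm option exists), stride-1 stems, initial
channels (8, 16, 32).  The regression targets stay in mm (no target
normalization); with shifts of order 1 mm the loss is already well scaled.

Two deliberate departures from the minimal recipe, both externalized in
`ModelConfig`:

- `stem_strides` allows the three stem convolutions to use spatial stride
  2.  The desk-scale profile uses (2, 2, 2) so the dense trunk operates on
  4³ (3D) or 5×4³ (4D) feature maps; this is what makes CPU-only training
  runs take minutes instead of hours.
- `activation` defaults to ReLU; the desk profile uses `leaky_relu`
  (slope 0.1).  At desk-scale widths, plain ReLU nets frequently suffered
  complete dead-unit collapse (constant predictions) within a few epochs;
  the leaky variant removes that failure mode without otherwise changing
  behaviour.

## Training

Mean squared error over the batch of the final-step shift (the w = 0 case),
optionally plus `w_n1`/`w_n2`-weighted squared errors of the two preceding
steps (temporal output regularization; weights in [0, 1]).  With both
weights zero the regularized loss is bit-identical to the plain one.

Adam (lr 1e-3 by default, float64 moment accumulators), global
gradient-norm clipping at 5 scaled by (1 + w_n1 + w_n2) so the larger
regularized objective keeps a comparable effective step (0 disables),
optional cosine annealing, shuffled mini-batches, per-epoch train/val
records.  The returned weights are either the best-validation checkpoint
or, with `average_tail = k`, the mean of the last k epochs' parameters;
final-epoch weights are always kept as well.  Splits are ROI-wise —
every sequence of a tissue region lands in the same partition, so held-out
evaluation is on unseen tissue.  The full-scale protocol is 150 epochs at
batch 50 with a 30/5/5 ROI split; it is configured by the `full` profile
and is not run by the test suite.

## Desk-scale study conditions

The package's desk benchmark (used by the acceptance script and the
trained-model tests) is sized for a single CPU core:

- dataset: 20 ROIs × 50 patterns (16/2/2 ROI split at 800/100/100
  sequences), endpoint magnitudes 0.2–2.4 mm;
- models: initial channels (8, 16, 24), stem strides (2, 2, 2),
  temporal kernel 3, leaky-ReLU activations; growth rate 10 and block
  structure unchanged;
- optimization: Adam (float64 moment accumulators over float32
  parameters), lr 3e-3 with cosine decay, batch 5, gradient-norm clip 5
  scaled by (1 + w_n1 + w_n2) so regularized runs keep a comparable
  effective step size; 12 epochs for the 3D architectures and 18 for the
  4D ones (the spatio-temporal trunks converge later);
- final weights are the average of the last 4 epochs' parameters
  (SWA-style tail averaging under the annealed learning rate), which
  stabilizes the noisy late trajectory far better than best-validation
  checkpointing does for the 4D models;
- the small batch is sized to the 800-sequence training set: the 4D
  trunks are update-limited, and 160 updates per epoch at batch 5 buy
  twice the optimization of batch 10 at identical epoch cost;
- distortion-robustness arms evaluate and augment the 4D sequence model,
  whose finer spatio-temporal features are the ones B-scan shifts can
  plausibly disturb.

Run-to-run variability at this scale is substantial (held-out rMAE moves
by about ±0.05 per trained model across dataset seeds), so single-seed
comparisons of overall rMAE between architectures carry limited power;
the error-growth-with-magnitude ordering is the robust signature and
reproduces in every configuration tested.

Findings from sizing pilots, in case the conditions are revisited:

- Optimization at desk widths is limited by dead units and steps, not
  data cost — simulating data is two orders of magnitude cheaper than one
  epoch over it.
- Generalization to held-out ROIs is limited by ROI diversity: training
  on 4 ROIs memorizes them (training loss near zero, validation loss
  growing) while 16 ROIs generalize.  The desk profile therefore favors
  many ROIs with few patterns each.
- The 4D trunk needs a 3-tap temporal kernel at this scale: a 2-tap
  kernel (whose size-preserving padding is necessarily asymmetric) cannot
  form centred temporal differences, and the sequence models then fail to
  exploit the intermediate frames at all.  The default config keeps the
  minimal 2-tap kernel; the desk profile overrides it.
- The width of the final stem channel (the per-frame descriptor the
  temporal trunk correlates) is the binding capacity constraint of the
  spatio-temporal models once stems are strided; widening it from 16 to
  24 channels moves the 4D model from parity with the baseline to a
  clear, significant advantage while barely changing the baseline.

## Evaluation

- MAE: per-axis mean ± std of |error| in mm, on the final-step shift.
- rMAE: per-axis absolute errors divided by the per-axis sample std (n−1)
  of the targets, pooled across axes (concatenated, then averaged).  The
  per-sample variant (mean over axes per sequence) feeds the paired tests.
- aCC: per-axis Pearson correlation × 100 averaged over the three axes.
  Averaging axes (rather than concatenating before correlating) is one of
  two near-equivalent readings; the choice is fixed and documented.
- Magnitude-binned MAE: quantile bins of ‖Δs_t4‖ (default 4), per-bin mean
  of ‖error‖.
- Model comparison: two-sided Wilcoxon signed-rank test on paired
  per-sample rMAE values, α = 0.05, zero differences dropped.
- Robustness sweeps apply evaluation-time-only rotation
  (α_max ∈ {2°, 5°, 10°, 20°} × {noise, motion}) or distortion
  (p_dist ∈ {10%, 25%, 50%} × {1, 2} px) to the test sequences.

## What the synthetic benchmark does and does not show

The generator reproduces the *geometry* of the emulated acquisition
protocol exactly (volume/FOV sizes, five-step spline drifts, relative
labels, rotation ramps, B-scan distortion statistics) and a plausible OCT
tissue appearance (speckle, attenuation, surface, macrostructure).  It does
not model the OCT physics (no interferometric point-spread function, no
shadowing, no refraction), sensor noise, nor deformable or rotational
tissue motion during acquisition.  Passing desk-scale tests therefore
demonstrates that the implementations are correct and that the
architectural ordering (the sequence model outperforming the two-volume
baseline overall and degrading most gracefully with motion magnitude)
reproduces directionally; it does not certify absolute accuracies on
real tissue, which the generator only emulates.

One full-resolution phenomenon does *not* transfer to desk scale: B-scan
motion-distortion sensitivity.  With stride-(2, 2, 2) stems the feature
grid is 8× coarser than the volume, so a 1–2 voxel B-scan shift perturbs
the features negligibly and averages out across the 32 B-scans — the
desk models evaluate essentially unchanged under 50% distortion, and the
distortion-augmented training arm only adds noise.  The
degradation-and-recovery experiment is still computed and reported, but
its premise (a measurable degradation) belongs to the full-resolution
regime.

## Numerical choices and degenerate inputs

- Trilinear interpolation for acquisition (no anti-aliasing; shifts only).
- Natural cubic splines (`scipy.interpolate.CubicSpline`, natural BC).
- Sample std uses n−1 everywhere; a single sample reports std 0.
- rMAE and aCC raise on degenerate target variance rather than returning
  NaN; the Wilcoxon comparison reports p = 1 / not significant when every
  paired difference is zero and raises below 6 pairs.
- Quantile bin edges are half-open with the last edge nudged up so the
  maximum-magnitude sample lands in the top bin.
- All randomness flows from `numpy.random.SeedSequence` spawns of a single
  seed; training is bit-deterministic on a fixed BLAS/numpy stack.
- Training arithmetic is strictly float32 — scalar factors (gradient-clip
  scale, scheduled learning rate) are kept as python floats because a
  stray numpy float64 scalar would silently promote every parameter to
  float64 and double the compute.
- The convolution lowers to explicit im2col + GEMM; the large transient
  buffers (padded input, columns, gradient columns) are recycled through
  a small pool, and evaluation passes run in a no-tape inference mode, so
  sustained training speed does not degrade through allocator churn.
  The per-offset gather/scatter loops use numba JIT kernels with a pure
  numpy fallback.

## Known limitations

- The architecture family fixes layer counts, block structure and growth
  rate but not kernel sizes, widths or normalization, so absolute
  parameter counts are a free design choice; the configuration space is
  fully externalized instead of hard-coded.
- The numpy training backend is single-threaded and ~2 orders of magnitude
  slower than a GPU framework; the full-scale protocol is configured but
  impractical on one core.
- `s_two_path_3d` re-runs its two-path network four times per sequence,
  so it trains ~4× slower than `two_path_3d` despite equal parameters.
- Rotation resampling and distortion fills are label-neutral by design,
  but rotation does attenuate corner information at large α_max; the
  noise-mode degradation measured by the robustness sweep includes that
  resampling loss.
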