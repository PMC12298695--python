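# Methods

## Scope and data model

`herbfp` classifies powdered plant-food supplements as containing / not
containing one target plant from full-run LC-MS fingerprints. A sample's raw
record is a time series of `(retention time, base-peak m/z, summed intensity)`
triples. All modeling operates on the *unfolded* representation: samples ×
(2 × timepoints), intensity features first (time-ordered) then mass features.
This column convention is a package choice — partial least squares is
order-invariant, but VIP reporting and refolding need one fixed layout.

The base-peak m/z is kept as a plain numeric channel, interpolated linearly
onto the shared time grid exactly like intensity, even though it is
categorical per scan. That mirrors how such exports carry mass as an ordinary
data column; the classifier sees component changes as sharp numeric steps.
The consequences are discussed under *Limitations*.

## Alignment

Retention-time drift between runs is corrected in two stages, fitted on the
intensity channel only; the mass channel always follows the same mapping so
the per-scan (intensity, mass) pairing is never torn apart.

1. **Global lag.** The overlap-normalized cross-correlation between the
   sample and the reference trace is maximized over integer lags within a
   band (default 5 % of the grid length), then refined to sub-sample
   precision by parabolic interpolation of the correlation peak. Run-level
   shifts are by far the dominant drift mode, and a lag handles them without
   giving a warping algorithm enough freedom to distort the signal.
2. **Correlation optimized warping.** The reference is cut into segments of a
   nominal length (default 50 points; the last segment absorbs any
   remainder). Segment boundaries in the sample may each displace by at most
   `slack` points (default 1) relative to the previous boundary's
   displacement; first and last points are pinned. Dynamic programming finds
   the boundary placement maximizing the summed per-segment Pearson
   correlation between the linearly resampled sample segments and the
   reference segments — an exact optimum over the admissible warp set, which
   unit tests confirm against exhaustive enumeration on small instances.
   Zero-variance segments contribute correlation 0 rather than NaN, so flat
   baseline stretches cannot poison the optimisation. A grid search over
   (segment, slack) combinations is available (`cow_grid_search`), scored by
   mean post-alignment correlation with the reference; ties prefer the
   smaller slack, then the smaller segment, so an already-aligned set returns
   the least aggressive warp.

**Warp target.** By default every run is warped onto the *most
representative* sample — the one with the highest mean correlation to all
others, typically a mid-ratio trituration. Warping a blank onto the pure
reference plant is ill-posed (the two share little structure, so the
optimiser drags blank peaks onto reference peaks and measurably distorts the
blank); warping onto a representative blend, which shares excipient and
system peaks with everything, is well-posed. Warping onto the designated
reference-plant run remains available (`reference_policy="designated"`).

Small slack after a good global lag is deliberate: residual drift is below a
few points, and surplus slack only buys the DP freedom to chase spurious
correlation. We measured warp fidelity as the feature-space correlation
between aligned runs and their zero-shift twins; slack 1–2 after the lag
stage dominates slack 5 on every generator setting examined.

## Pretreatment

Row-wise steps are stateless and applied per channel block (never across the
intensity/mass boundary):

* **Savitzky–Golay derivative** — window 15 points, polynomial order 2,
  first derivative by default; interior-scheme convolution with reflected
  padding. Exact for polynomials up to the fitted order at interior points.
  The derivative can be restricted to the intensity block
  (`sg1-intensity`): derivatizing the stepwise mass channel turns plateaus
  into spikes and discards the plateau values, which carry the information.
* **SNV** — per row and per channel block, (x − mean)/sd; removes overall
  loading/dilution scale. Constant rows raise an error naming the sample.

Column statistics (autoscaling or mean centering, always the last step) are
fitted on the training partition only and replayed on every other partition;
zero-variance training columns are centered and left unscaled. The default
training configuration cross-validates three candidate recipes — intensity
derivative + mean centering, both-channel derivative + mean centering, mean
centering alone — and keeps the best CV ccr% (ties: first listed), mirroring
how pretreatment is normally chosen per target plant.

## Splitting, compression, classification

* **Duplex split** (deterministic): the mutually most distant pair of rows
  (Euclidean distance, after the stateless row-wise pretreatment) seeds the
  training set, the most distant remaining pair seeds the test set, and the
  sets alternately claim the remaining point farthest (max–min distance) from
  their members; the surplus is directed so the test set receives
  round(fraction × n) points (17 of 67 at the default 25 %). Ties break
  toward the lowest row index, so the split is reproducible to the byte.
  Distances use only statistics-free pretreatment, because autoscaling would
  need a training set that does not exist before the split.
* **PLS compression**: univariate-response NIPALS PLS fitted on training rows
  (default up to 30 factors), with the score matrix passed downstream — the
  "double PLS-DA" treatment. Inside cross-validation the compressor is refit
  on each fold's training rows.
* **PLS-DA**: NIPALS PLS1 on class codes 1 (present) / 2 (absent); per factor
  the weight vector is proportional to Xᵀy on deflated data, scores are
  orthogonal (asserted to 1e-8 relative), and cumulative prediction per
  factor count yields the whole ccr%-versus-complexity curve from one fit.
  Training predictions at full rank coincide with ordinary least squares
  (oracle-checked), and factor-wise predictions match an independent PLS
  implementation to 1e-8.
* **Decision rule**: ŷ < 1.5 → class 1, else class 2. 1.5 is the midpoint of
  the codes; exact ties resolve to "absent", the conservative call for an
  adulteration claim.
* **Model selection**: stratified 10-fold CV (a balanced dealer that keeps
  fold sizes within one sample even when a class is rarer than the fold
  count; it errors only if a fold's *training* side would lose a class),
  complexity 1..30, smallest factor count attaining the maximum CV ccr%.
* **Reporting**: ccr% = 100·(TP+TN)/n per stage (calibration, CV, external
  test), rounded to integer percent for tables with the raw value retained;
  misclassified sample ids are listed per stage.
* **VIP**: VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) with SSY_a
  the response variance explained by factor a; mean squared VIP is 1 by
  construction, which doubles as a self-test.

## Fusion

Two detector blocks over identical samples are combined after per-block
compression: PCA scores (mid-level; components covering 95 % of training
variance by default, deterministic sign convention) or supervised PLS scores
(high-level; 10 per block by default), each block scaled so its columns
contribute total variance 1 regardless of how many components it kept. Raw
block-scaled concatenation (low-level) is included as a baseline. Block
compressors are fitted on training rows only, also inside CV folds.
`compare_models` renders per-model rows (preprocessing, factors, CV /
calibration / test ccr%) and refuses to tabulate reports built on different
splits.

## The synthetic study generator

The generator is the package's stand-in for the physical calibration study:
one target plant, 10 botanical blank matrices plus a lactose filler, 55
triturations at ratios {1/20, 1/15, 1/10, 1/5, 1/2}, one pure reference — 67
runs. Design choices, with their physical rationale:

* **Grid**: 0–13 min at 214 points/min (≈1500 points across the 3–10 min
  fingerprint region; the order of magnitude real exports show).
* **Peaks**: Gaussian in time. Signature: 24 marker peaks, σ 0.025–0.06 min,
  heights 250–400 units, apexes kept inside 3.6–9.4 min (markers away from
  region edges survive warping). Blanks: 15–40 peaks each (σ 0.015–0.05 min,
  heights 20–150) — narrow UHPLC peaks leave clean inter-peak windows, which
  is precisely why marker-based detection works on real fingerprints.
* **Shared structure**: botanical blends share formulation excipients, so all
  botanical blanks carry a common excipient peak set (per-matrix height
  jitter ±8 %) plus a handful of matrix-specific peaks (heights damped ×0.6);
  every run carries the same system peaks (a solvent front and column
  artifacts, 300–800 units) and a broad gradient background. The shared
  content is what makes run-level lags identifiable for every sample type.
* **Mass channel**: per time point, the m/z of the dominant peak of the
  mixture — recorded only where that contribution exceeds a peak-picker
  detection limit of 5 units (≈10× the noise floor), else 0. In a
  trituration the reference's markers claim the base peak wherever
  r·(marker) beats (1−r)·(matrix), the nonlinearity that makes presence
  detectable independently of dilution.
* **Noise**: intensity noise sd = 0.02·√I + 0.5 (shot-like plus detector
  floor); whole-trace injection/weighing variability of 3 % RSD; per-sample
  retention shifts uniform in ±2 % of the run length (±15.6 s). The mass
  channel itself is noiseless given the peak geometry.
* **Separability dial**: `signal_scale` multiplies the signature heights
  only. At 1.0 the study is cleanly separable (CV, calibration and external
  test all reach 100 % across generator seeds); as it shrinks, the mass
  flips of the lowest ratios are the first evidence to cross the detection
  limit.

What the generator does **not** emulate: mass-spectral physics (isotopes,
adducts, fragmentation), chromatographic band shape beyond fixed-width
Gaussians, real matrix chemistry, inter-batch drift structure, carry-over, or
scan-to-scan base-peak jitter. Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it assumes — not that it would
reach the same figures on any particular instrument's data.

Paired detector blocks for fusion experiments re-render one study plan (same
chemistry and shifts) under two instrument configurations (default: a dense
MS-like grid and a coarser, noisier DAD-like grid), so class structure and
sample order are identical while feature dimensions differ.

## Behavior at the detection edge

With the signature attenuated, resubstitution stays perfect long after
generalization degrades — compression to 30 supervised factors can always
interpolate 50 training rows — so degradation appears first in CV and
external-test predictions. Two failure modes then compete:

* low-ratio triturations lose their last above-threshold mass flips and drift
  toward the blank side (false negatives at 1/20, then 1/15) — the behavior
  expected of a detection-limited screening method;
* held-out blanks drift toward the positive side (false positives). This mode
  is structural: the class codes average 1.16, so weak-evidence predictions
  shrink toward "present"; and a trituration equals (1−r)·blank +
  r·reference, so wherever the blank dominates, a held-out blank presents
  exactly the features its own positively-labelled triturations had — a
  linear discriminant is dragged toward calling it positive.

In our experiments the two modes interleave near the edge: scans over
decreasing signal find the first errors to be low-ratio false negatives in
roughly half the replicate seeds and a lone blank false positive in the rest.
Real studies of this design report the same mixture (low-ratio test false
negatives alongside an occasional training-CV false positive). Screening
decisions at the edge should therefore never rest on the binary call alone;
the continuous decision value and the per-stage misclassification lists are
exposed for exactly that reason.

## Numerical and degenerate-case conventions

* Pearson correlation of any zero-variance vector is defined as 0.
* PLS stops early when the residual is numerically exhausted, recording a
  truncation note on the model rather than failing.
* Zero-variance columns autoscale to centered zeros.
* Duplex and DP tie-breaks are lexicographic (lowest index / smallest
  displacement), making every run byte-reproducible.
* All randomness (generator, fold assignment) flows from explicit integer
  seeds; models persist their seeds, parameters and fitted statistics, so a
  stored model file is sufficient for prediction with no training data.

## Problem sizes used in the test suite

Unit and integration tests run the generator at 40 points/min with 2–4
matrices and 2 ratios (7–13 samples); study-scale checks (design arithmetic,
split sizes, parameter recovery, fusion) use the full default study (67
samples, 214 points/min). The attenuation scan runs ten replicate studies
over an 11-point geometric grid of signal scales (0.45 down to 0.16). These
sizes were chosen so the whole suite completes in a few minutes on one CPU
while still exercising the full-size study.
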