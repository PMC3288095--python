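# Methods

## Feature hierarchy

**S1 (simple cells).** Each Gabor kernel is built on rotated coordinates
x₀ = x cosθ + y sinθ, y₀ = −x sinθ + y cosθ as
`exp(−(x₀² + γ²y₀²)/(2σ²)) · cos(2π x₀/λ)`, restricted to a circular
aperture of radius size/2, then mean-subtracted (over the aperture) and
scaled to unit Euclidean norm. The pyramid uses 16 sizes (7…37 px, step 2)
× 4 orientations (0°, 45°, 90°, 135°) = 64 filters. Per-size envelope
widths and wavelengths follow the standard published HMAX parameterization
(σ: 2.8 → 18.2, λ: 3.5 → 22.8, γ = 0.3); all values can be overridden from
a YAML config, and the test-suite relies only on structure and closed-form
oracles, never on these defaults.

The S1 response at a pixel is |k·v| / ‖v‖, where v is the image
neighborhood over the kernel's aperture; by Cauchy–Schwarz it lies in
[0, 1], it is invariant to positive rescaling of the image, and zero-mean
kernels give exactly zero on constant regions. Borders use **symmetric
(edge-reflecting) padding**, with the norm divisor computed over the padded
window. Reflective padding is this package's dialect: it keeps border
windows of a constant image constant, so uniform images produce identically
zero S1 (and hence C1) maps — with zero padding the partial border windows
would see a spurious step edge. Where the neighborhood norm vanishes the
response is defined as 0. Correlations are evaluated by FFT
(`scipy.signal.fftconvolve`); responses are clipped to [0, 1] to absorb
floating-point residue near the bound.

**C1 (complex cells).** Two max-pooling stages: (1) element-wise max over
the two adjacent filter sizes of each band at the same orientation (bands
1…8 pair sizes (7, 9), (11, 13), …, (35, 37)), giving 32 maps; (2) a local
max over N^Σ×N^Σ windows anchored at stride N^Σ − Δs. N^Σ grows
arithmetically 8, 10, …, 22 across bands (the published endpoints,
interpolated linearly), and Δs defaults to N^Σ/2 — the standard
half-overlap, since only the symbol, not the value, is published. Border
windows are **clipped** (partial windows kept) so stimuli near the edge are
never dropped; output dims are ⌈(dim − N)/(N − Δs)⌉ + 1 per axis. Max is a
selection, not arithmetic: every C1 value equals some S1 value in its
pooling region, and C1 is monotone in S1.

**Patch codebook.** Prototypes are n×n×4 blocks (all four orientation
channels) of **band-2** C1 activations of training images, n ∈
{4, 8, 12, 16}, drawn at uniformly random images and positions, with
replacement, size-major order, reproducibly from a seed. Patches are stored
raw (no normalization) — distances are computed on C1 activations as-is.
By default the pool is drawn from target-class training images only
(selected features are expected to be object parts; a flag admits
negatives).

**S2/C2.** For every patch and every band large enough to contain it, the
Euclidean distance d between the patch and each co-located block is tuned
as `exp(−d²/(2σ²))` with σ = 1.0 by default, so similarity is in (0, 1]
and the C2 feature is a literal global **max** over all positions and
bands. A `min_distance` mode reports the raw global minimum distance
instead (the natural pool for untuned distances). Because the global max
per patch is independent of the other patches, selection commutes with
computation: masking rows of a precomputed full C2 matrix is exactly
equivalent to recomputing C2 with the sub-dictionary. This property (unit
tested) is what makes wrapper fitness evaluation cheap — the full matrix is
computed once per split and the GA only masks rows.

## Genetic algorithm

Chromosomes are binary vectors of length N (pool size); bit i = patch i
participates in learning. Fitness F = 1 − ρ, where ρ is the
equilibrium-point performance (1 − equal-error rate) on the evaluation
split of a linear SVM trained on the training split with the selected rows
(accuracy mode available). Defaults, all configurable: population 20,
crossover probability 0.9 (uniform crossover, per-locus swap 0.5), per-bit
mutation rate 1/N, elitism 1, generation cap 100, stagnation patience 15.
The published description names rank selection, uniform crossover, mutation
and elitist replacement but no rates; these are canonical textbook
settings, chosen once.

Selection is linear-rank: the best of s individuals gets weight s, the
worst weight 1, and **tied fitnesses share the average of their rank
weights**, so equal fitnesses yield uniform selection probabilities.
Initialization is i.i.d. Bernoulli (density 0.5 by default; all-zero
individuals are re-drawn). The mutation validity guard re-draws a child
that came out all-zero; at mutation rate exactly 1.0 the flip mask is
deterministic, so the guard instead sets one random bit. All randomness
comes from one seeded generator per run; the stream order (init, then per
offspring pair: two selection draws, crossover coin, crossover mask, two
mutation masks) is fixed, making runs bit-reproducible. Identical
chromosomes are fitness-evaluated once (cached) — observationally identical
to re-evaluation because the fitness is deterministic.

Termination is generation cap OR stagnation patience without improvement of
the best F, whichever comes first. Elitism makes the best-so-far history
non-increasing (asserted in tests).

## Evaluation protocol

Data are split per class into shuffled **equal thirds** (train /
evaluation / test); remainders are dropped, not reassigned. Fixed-count
protocols (100+100 train, 50+50 test; 150+150 train, 75+75 test) are
provided for datasets organized that way. The classifier is a linear SVM
(C = 1.0, recorded in the report); scores are its decision function.

The **equilibrium error** is the point on the ROC where the false-positive
rate equals the false-negative rate, found by sweeping all thresholds and
linearly interpolating between adjacent operating points when no exact
crossing exists; it is invariant under strictly increasing transforms of
the scores. AUC is the rank statistic (ties counted half). Run-level
comparisons use the two-sided Wilcoxon rank-sum and two-sample
Kolmogorov–Smirnov tests.

The headline experiment, per seeded run r (seed = base + r, with the
random-baseline stream at base + 500000 + r for auditability): split,
extract a pool (50 patches per size × 4 sizes = 200 by default), compute
the full C2 matrices, run the GA (for this protocol: initialization density
0.2 so the evolved subset lands near P ≈ 40 of 200, generation cap 60,
patience 15 — a runtime-conscious cap of the GA defaults, chosen once), and
measure test EER/AUC for (i) the selected P patches, (ii) a size-matched
random subset, (iii) the full pool. Means and standard deviations are
aggregated over 10 runs, along with per-size selection percentages, the
population matrix (rows = chromosomes, columns = patches, plus per-column
selection frequencies), and — when motif boxes are available — the rate of
selected patches lying on the motif versus the pool's base rate.

## Synthetic fixture

Positives contain exactly one "stick face" motif — two vertical bars
(eyes), one 45° bar (nose), one horizontal bar (mouth) at fixed relative
offsets — at a jittered scale (±15%) and uniform position, over 14–22
random clutter bars (uniform orientation 0–180°, length 10–30 px);
negatives contain clutter only. Additive Gaussian noise (sd 0.10) and
clipping to [0, 1] finish each 112×150 image. Defaults (50 images per
class) put full-pool test EER around 0.05–0.15 — well above chance but not
saturated, so selection has signal to find. The motif is built from
oriented bars because S1 is an oriented-edge bank; discriminability at the
C1 level is by construction.

The C1-to-image coordinate mapping used for provenance scoring is: cell
(i, j) of band b covers pixels [i·stride_b, i·stride_b + N^Σ_b) per axis;
a patch's footprint spans its n×n cells, and it counts as "on-motif" when
the footprint overlaps the motif box by ≥ 50% of the footprint area. Note
that band-2 footprints grow quickly with n (an n = 16 patch covers
85×85 px), so under the 50% rule only the smaller patch sizes can ever
qualify at these image sizes; enrichment statistics are dominated by them.

What the fixture does **not** emulate: photometric variation (lighting,
texture), within-class shape variability beyond scale jitter, occlusion,
correlated natural-image statistics. Passing the synthetic tests shows the
pipeline and the selection mechanism work as specified; it does not certify
performance on natural-image benchmarks.

## Numerical notes and edge cases

- Image loading: Rec. 601 luminance via Pillow, 8-bit scaling to [0, 1].
- Resizing: bilinear with anti-aliasing when downscaling; width =
  round-half-away-from-zero(w·h′/h), floored at 1 px; images already at the
  target height are returned untouched (bit-exact idempotence).
- Feature matrices: CSV with 17 significant digits (≥ 12 survive a round
  trip); empty or non-finite matrices are rejected at write time; parse
  errors name the offending line.
- S2 distances are computed as ‖x‖² − 2x·p + ‖p‖² (clipped at 0) via BLAS;
  exact-match responses equal 1.0 up to ~1e−12 cancellation noise.
- C2 translation tolerance is exact for shifts that are multiples of a
  band's pooling stride when the stimulus and its matching block stay
  inside the borders; the tests shift by 10 px = 2 band-2 strides.
- Equilibrium error endpoints: the ROC always starts at (FPR, FNR) = (0, 1)
  and ends at (1, 0), so a crossing always exists.
- GA fitness on small evaluation splits is coarsely quantized (steps of
  1/#eval-negatives); stagnation patience, not the cap, usually terminates
  runs.

## Limitations

- Per-size (σ, λ) values and the C1 overlap are standard defaults, not
  values printed in the source description; results depend on them only
  through structure-level tests.
- Only binary (two-class) recognition; no multi-class machinery.
- The GA is a wrapper method: cost scales with generations × population ×
  classifier fits. The row-masking trick removes the C2 recomputation cost
  but not the classifier fits.
- Diversity-preserving replacement and alternative selection schemes
  (roulette, Boltzmann) are out of scope; elitist replacement only.
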