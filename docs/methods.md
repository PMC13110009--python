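# Methods

## The problem

Mass spectrometry imaging (MSI) produces a datacube: a full mass spectrum at
every pixel of a tissue section, i.e. an `n_pixels × n_channels` intensity
matrix with tens of thousands of rows and thousands of m/z channels.
Non-linear dimensionality reduction (t-SNE, UMAP) is the standard way to
visualize such data and to precede clustering, but the embedding quality
depends strongly on hyperparameters, and most evaluation metrics measure
either purely local (neighbourhood) or purely global (triplet-order)
preservation. Dimensional Cophenetic Integrity (DCI) instead scores the
preservation of *hierarchical cluster relationships* — the structure an MSI
analyst actually interprets.

## The DCI score

Given a cube `X ∈ R^{n×c}` and an embedding `Y ∈ R^{n×3}`:

1. **Sampling.** k-means (k-means++ init, 10 restarts, fixed seed) with
   `k = round(n · f)` is run on the *embedding*; for each centroid the
   Euclidean-nearest pixel is taken (ties by lowest index; duplicates
   removed, so the sample can shrink). Default `f = 0.01`; fractions
   between 0.5% and 25% give very similar scores, so 1% is used for
   efficiency. Sampling in the low-dimensional space follows the method's
   definition; it does mean different embeddings of the same cube are scored
   on different sample sets, which is faithful to the procedure but worth
   knowing when comparing embeddings — pass `sample_indices` to hold the
   subset fixed.
2. **Dual hierarchical clustering.** Condensed pairwise distances over the
   sample: cosine in the cube (scale-free, the metric used by the embedders),
   Euclidean in the embedding. Average linkage (UPGMA) in each space;
   average linkage is monotone, and the implementation asserts
   non-decreasing merge heights on every tree.
3. **Cophenetic distances.** For each sampled pair, the height of the lowest
   merge uniting them, per space.
4. **Normalized mutual information.** Each condensed cophenetic vector is
   converted to categorical labels by exact value equality — merge heights
   are replicated bit-exactly within one dendrogram, so no binning is needed
   or introduced — and compared with arithmetic-mean NMI:
   `NMI = I(A;B) / ((H(A)+H(B))/2) ∈ [0, 1]`.

Conventions for degenerate inputs: if both cophenetic vectors are constant
the score is 1.0 (two trivial, identical partitions); if exactly one is
constant (e.g. a collapsed/constant embedding) the score is 0.0. When
k-means collapses every centroid onto one representative (constant
embedding), the sample is topped back up to `min_samples` with the lowest
unused pixel indices so the degenerate low-space structure is still
computable.

Properties guaranteed by construction and asserted in tests: DCI ∈ [0, 1];
symmetry of NMI; invariance under isometries of the embedding (with the
sample held fixed) and under strictly increasing transforms of either
cophenetic vector; exact agreement of the cophenetic computation with a
brute-force dendrogram-traversal oracle.

Tie-breaking in the linkage (equal inter-cluster means) follows the linkage
routine's internal order; cophenetic vectors, and hence DCI, can differ
between tie-break conventions, which matters only for exactly symmetric
synthetic inputs.

## Comparator metrics

* **co-KNN accuracy** (local): mean over pixels of
  `|kNN_high ∩ kNN_low| / k`, self excluded, default `k = 10`.
* **Random-triplet accuracy** (global): for seeded triplets `(i, j, l)` —
  5 per anchor by default — score 1 when
  `sign(d_high(i,j) − d_high(i,l)) = sign(d_low(i,j) − d_low(i,l))`,
  0.5 on a tie, else 0.
* **Spearman of pairwise distances** (global): average-rank Spearman between
  condensed distance vectors.
* **Centroid-distance correlation** (labelled): Spearman between
  inter-centroid distance vectors of the two spaces; needs ≥ 3 classes.
* **Mean-based Dunn index** (labelled): mean inter-class over mean
  intra-class pairwise distance in the embedding; > 1 indicates separation.

The neighbour count and triplet budget are this package's documented
defaults (the metrics' definitions leave them open); both are configurable
and logged. All metrics accept a shared subsample to bound O(n²) cost.

## Synthetic data generator

The generator emulates a multi-region MALDI experiment:

* **Mask:** an elliptical "tissue" foreground on a rectangular grid,
  partitioned into k contiguous regions by a seeded Voronoi tessellation of
  sites drawn from the foreground. A procedural mask replaces any external
  anatomy atlas: what the metrics exercise is k contiguous regions with
  distinct templates, not anatomical realism.
* **Spectra:** each species gets a random monoisotopic mass (100–1000 Th),
  three adduct offsets (+1.00728, +22.98922, +38.96316 Th for [M+H]+,
  [M+Na]+, [M+K]+ at relative yields 1 : 0.6 : 0.3) and a 3-peak isotope
  envelope with geometric decay 0.5. Peak intensity ratios are elevated for
  a species in its "home" region (uniform 1–8) and low elsewhere (0.02–0.2),
  giving region-distinct templates; a set of matrix-background peaks
  (100–400 Th) shares one intensity row across all regions.
* **Noise:** multiplicative Gaussian fluctuation,
  `intensity = template · (1 + ε)`, `ε ~ N(0, cv)`, truncated at 0;
  default `cv = 0.10`, a typical relative intensity spread for MALDI peak
  intensities.

Three transforms create standard stress tests:

* **Homogenization** `p_new = p_i − s·μ_r + s·μ_w` pulls every pixel toward
  the whole-dataset mean while keeping its deviation from its region mean;
  post-transform region means are exactly `(1−s)μ_r + sμ_w`. The formula
  can produce negative intensities; they are kept by default (an optional
  flag clips at zero) because the transform is defined by the equation, not
  by a physical detector.
* **Disparate bootstrap** duplicates spectra (sampling with replacement)
  from one region, appending them on new mask rows, to create one dominant
  cluster.
* **Concatenation** stacks two cubes sharing an m/z axis, offsetting the
  second cube's labels and recording the region pairing.

What the generator does **not** model: isotope fine structure, mass
resolution and calibration error, chemical noise beyond the Gaussian term,
pixel-to-pixel spatial correlation, and detector saturation. Passing tests
on this generator therefore demonstrate the metric's behaviour on data with
clean region structure; conclusions about subtle real-tissue chemistry
require real data.

## Embedders

Thin wrappers: t-SNE (3 components, cosine metric, random init,
learning-rate "auto"; perplexity and exaggeration swept) and UMAP
(3 components, cosine, spectral init; neighbour count swept). "Exaggeration"
maps to t-SNE's early-exaggeration factor — the only exaggeration control
standard t-SNE exposes — and sweeping it to values in the hundreds is
intentional. Embeddings are cached to disk keyed by (cube content hash,
parameters) so grid searches are resumable.

## Optimization

`grid_search` evaluates DCI over a perplexity × exaggeration grid, recording
failed cells (reason string, NaN score) without aborting. `bayes_optimize`
maximizes DCI (as minimizing −DCI) over an integer box with a Gaussian-
process surrogate: Matérn 5/2 kernel with a small white-noise term on the
unit-scaled box, Sobol quasi-random initial design, expected-improvement
acquisition maximized over a random candidate set with no repeated
evaluations. Failed evaluations enter the surrogate at the worst observed
value and are excluded from the incumbent. Default space: perplexity
[5, 10000] (clipped below the pixel count), exaggeration [1, 1000],
120 calls, 60 initial points, seed 42.

## Desk-scale study conditions

All bundled tests and the acceptance script run on a generated cube of
~1,900 pixels (64 × 42 elliptical mask), 8 regions, 150 channels
(16 species × 3 adducts × 3 isotopes + 6 matrix peaks), `noise_cv = 0.10`.
Desk-scale t-SNE runs use `max_iter = 500` — 250 exaggerated exploration
iterations plus 250 relaxation iterations — which is ample for a cube this
size; grids use a {5, 30, 200, 600} × {1, 12, 100} hyperparameter lattice
and medians over 3 embedding seeds. These sizes are the package's chosen
benchmark conditions; the library itself has no scale assumptions beyond
memory for the pairwise matrices over the sampled subset.

## Numerical choices

* Intensities are float64 throughout regardless of file precision.
* Cosine distances are clamped at 0 from below (rounding can produce −1e-17).
* Rebinning uses piecewise-linear interpolation with zero extrapolation, on
  a grid of `floor(span/width) + 1` channels (with a 1e-9 relative tolerance
  when the span is an exact multiple of the width).
* Representative ties (two pixels equidistant from a centroid) resolve to
  the lowest index; duplicate representatives shrink the sample.
* The GP surrogate's kernel hyperparameters are refit each iteration; fits
  that hit their bounds are accepted (they do not change the acquisition
  argmax materially on these small designs).

## Known limitations

* DCI re-samples representatives per embedding (by definition), so scores of
  two embeddings are estimates over different subsets; use `sample_indices`
  for paired comparisons.
* Exact-equality labelling of cophenetic values assumes merge heights are
  not accidentally duplicated across unrelated merges; with continuous
  distances ties have probability ~0, but exactly symmetric constructions
  can inflate category collisions.
* The Bayesian optimizer's acquisition argmax is approximate (random
  candidate set), which is adequate for 2-D integer boxes but would need a
  proper inner optimizer in higher dimensions.
* imzML support is limited to continuous mode; processed-mode files must be
  re-binned upstream.
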