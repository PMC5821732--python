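# Methods

This note records the modelling choices in `hicenhance`, what the
synthetic generator does and does not emulate, and the numerical
conventions that a maintainer would otherwise have to reverse-engineer.

## Data model

An intra-chromosomal contact map is a square symmetric grid of
non-negative values, one row per fixed-width genomic bin (default 10 kb),
0-based half-open bin intervals. Raw maps hold integer read-pair counts;
balanced (normalised) maps hold reals and are flagged `is_normalized`, in
which case read thinning is refused (thinning is defined on reads) but
every other operation applies unchanged. Only the band within 2 Mb of the
diagonal is modelled: TADs are sub-megabase, and interactions beyond that
distance are sparse and rarely interpretable at 10 kb.

## Network and training

The enhancer is a three-layer convolutional network operating on 40×40-bin
windows: 16 filters of 5×5 (ReLU), 16 pointwise 1×1 filters (ReLU), one
9×9 filter (linear). No padding is used anywhere, so the output is the
28×28 centre of the input window and one output cell depends on a 13×13
input neighbourhood. The 9×9 size of the last filter is forced by the
geometry: the three layers together must consume 12 bins of border, and
5 + 1 + 9 − 2 also reproduces the 13×13 neighbourhood that maximises
prediction accuracy among tested neighbourhood sizes.

Weights are initialised Glorot-uniform
(±√(6/(fan_in + fan_out)), biases 0) and fitted by mini-batch stochastic
gradient descent with classical momentum on the mean squared error. All
convolution passes (forward, weight gradient, input gradient) are computed
exactly — zero-padded FFT correlation for spatial kernels, BLAS matrix
products for 1×1 layers and small-kernel patch matrices — so training is
deterministic given the seed, to the last bit, on a fixed software stack.

### Window standardisation

Raw Hi-C counts are a hostile optimisation surface: near-diagonal cells
reach hundreds of counts while the input windows of a 1/16-depth library
are mostly zeros and ones. With Glorot initialisation and a single global
learning rate, SGD on raw windows either diverges (the near-diagonal
windows dominate the gradient) or crawls: after the full 300-epoch budget
the fit was still worse than the un-enhanced input. The model layer
(`ContactEnhancer`) therefore standardises once, from training data only:
inputs are multiplied by the empirical target/input count ratio (bringing
a thinned library back to the deep scale) and both sides are divided by
the standard deviation of the target counts. Predictions are multiplied
back at enhancement time, so the user-visible mapping is still
counts → counts. `standardize=False` restores the raw behaviour.

### Optimiser defaults

Learning rate 1e-2, momentum 0.9, batch 256, at most 300 epochs, early
stopping when validation MSE has not improved for 20 epochs, returning the
best-validation parameters. The rate was selected by a small sweep on the
standardised default simulation (3e-3, 1e-2 and 3e-2 all converge to the
same validation MSE; 1e-2 is fastest); on raw counts ~1e-4 is the largest
stable rate. Validation is by held-out chromosome where supplied
(recommended), else a random 10% of windows. Divergence (non-finite loss)
raises immediately with a suggestion to lower the rate.

## Patch tiling and merging

Input windows step by `stride = 40 − 12 = 28` so the predicted centres
tile the matrix exactly while inputs overlap by the 12 bins the network
consumes; a clamped final window covers chromosomes whose length is not a
multiple of the stride, and cells predicted by several windows are
averaged. Only upper-triangle windows are processed; symmetry supplies the
lower triangle. Negative predictions are clipped to zero (counts cannot be
negative). Cells never covered by any window — a 6-bin frame at the
chromosome ends and everything beyond the 2 Mb band — are filled from the
low-depth input so a complete matrix is always returned. The model-level
`enhance()` scales those fallback cells by the training depth ratio so the
whole returned matrix is on the deep-count scale; leaving them at raw
1/16-scale counts plants gross outliers in any per-distance statistic that
mixes covered and uncovered cells (at 30 kb separation they alone drag the
Pearson correlation from ≈0.51 to ≈0.26).

## Synthetic chromosomes

`default_spec()` describes a 4 Mb chromosome (400 bins at 10 kb) with the
three statistical features the enhancer relies on:

* **distance decay** — expected intensity ∝ (1 + d)⁻¹;
* **TADs** — 8 domains with a ×3 within-domain enrichment. Widths are
  deliberately heterogeneous (0.2–1.15 Mb): real domains vary severalfold
  in size, and a uniform width would be degenerate — beyond that single
  width every same-distance bin pair is cross-domain and the structural
  signal vanishes, which no real chromosome exhibits;
* **loops** — 12 isotropic Gaussian bumps (width 1 bin) with anchor
  separations covering 0.15–1.5 Mb, amplitude four times the decayed
  background at the anchor distance.

Counts are independent Poisson draws of the intensity scaled so the
expected in-band total equals the requested depth (default 5 × 10⁵ read
pairs), mirrored to keep symmetry; shallow libraries are made by binomial
thinning of a deep draw, exactly as for real data. The layout is fixed;
the seed only moves the sampling randomness, so different seeds are
technical replicates of one chromosome.

Not emulated: A/B compartments, inter-chromosomal contacts, coverage /
mappability biases, fragment-level artefacts, replicate-to-replicate
biological variability, and overdispersion beyond Poisson. Passing tests
on this generator therefore demonstrate that the pipeline recovers
planted local structure from thinned counts — not that it handles the
bias structure of real libraries, for which balanced input matrices are
the expected entry point.

## Evaluation

Agreement between two maps is computed per genomic distance: the k-th
diagonals are paired and Pearson and Spearman correlations taken across
bins; constant diagonals yield undefined (NaN) entries that are excluded
from summaries rather than imputed. Correlations are per chromosome and
never pooled across chromosomes.

One caveat drives the choice of reference in the end-to-end tests: a
thinned matrix is a binomial sub-sample *of the deep realisation itself*,
so the two share Poisson noise, and at distances where structural variance
is weak this shared noise alone produces r ≈ 0.3 between the input and the
sampled deep matrix — an advantage unrelated to recovery that no denoiser
can match cell-for-cell. On synthetic data the noiseless expected
intensity is available, so recovery is measured against it; against that
ground truth the trained network exceeds the thinned input at every
distance in the 30 kb–1 Mb band and exceeds Gaussian smoothing on the band
average (evaluation replicate seed 5; replicate seeds 7 and 8 give the
same verdict). Comparisons against the sampled deep matrix remain
available through the same functions and are reported by
`summarize_methods`.

Virtual-4C extraction returns one row of the matrix as a BED-like track;
the enhancement-tier helper classifies a candidate library by its in-band
(25 kb–1 Mb) read total relative to a reference, assigning sub-1/16
libraries to the deepest (×16) tier.

## Problem sizes

The shipped defaults — 400-bin chromosomes, ~90 windows each, three
training chromosomes plus one validation chromosome, ≤300 epochs — fit a
model in a few minutes on one CPU core and are the sizes used throughout
the test suite. The same code paths scale to whole human chromosomes
(21 000 bins at 10 kb ⇒ ~5 000 band-restricted windows per chromosome);
training cost grows linearly in the number of windows.

## Known limitations

* The network is translation-invariant and sees a 13×13 neighbourhood: it
  cannot use absolute genomic distance except through count magnitude, and
  focal features whose evidence at low depth is below ~1 read per window
  (e.g. width-1 loops at megabase separation in a 3 × 10⁴-pair library)
  are unrecoverable by any local method.
* Thinning models exchangeable reads; duplicate-read structure and
  coverage biases are not represented.
* The random-forest baseline subsamples training cells (default cap
  2 × 10⁴) for tractability; its exact predictions depend on that cap.
* Model files store exact float64 weights but no architecture versioning
  beyond a format tag.
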