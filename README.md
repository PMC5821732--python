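# hicenhance

Super-resolution of Hi-C chromatin contact matrices with a three-layer
convolutional network, together with the classical baselines it is judged
against, read-thinning simulation, a synthetic chromosome generator, and
distance-stratified evaluation.

## The problem

A Hi-C experiment summarises the 3D folding of a chromosome as an *n* × *n*
symmetric **contact matrix**: the genome is cut into fixed-width bins
(10 kb here) and entry *(i, j)* counts the read pairs linking bins *i* and
*j*. Fine structure — topologically associating domains (TADs), chromatin
loops between regulatory elements — only becomes visible at small bin
sizes, but halving the bin size requires roughly four times the reads, so
most public datasets are too shallow for 10 kb analysis.

Contact maps are, however, highly redundant: the value at one position is
strongly constrained by its neighbourhood (distance decay, domain blocks,
focal peaks are all *local* patterns). `hicenhance` exploits this by
learning a mapping from a shallow (e.g. 1/16-depth) matrix to its deeply
sequenced counterpart, one 40 × 40-bin window at a time, and applying it to
new shallow matrices.

## The model

Each input window `X` (40 × 40 bins = 0.4 × 0.4 Mb) is pushed through three
valid (un-padded) convolutions,

```
F1(X) = max(0, w1 * X + b1)      16 filters, 5 × 5    pattern extraction
F2(X) = max(0, w2 * F1(X) + b2)  16 filters, 1 × 1    non-linear mapping
F3(X) = w3 * F2(X) + b3           1 filter,  9 × 9    recombination
```

so the output window is 28 × 28, registered at the centre of the input, and
each output cell sees a 13 × 13 input footprint (5 + 1 + 9 − 2). Weights
start Glorot-uniform; Θ = {w₁, w₂, w₃, b₁, b₂, b₃} (1985 parameters) is
fitted by mini-batch SGD on the mean squared error between predicted and
true deep-count windows. Only bin pairs within 2 Mb of the diagonal are
modelled. A whole chromosome is enhanced by tiling it with overlapping
windows and merging the predicted centres back into a full symmetric
matrix.

Baselines: 2-D Gaussian smoothing, 2-D average smoothing, Perona–Malik
anisotropic diffusion, neighbourhood averaging (centre excluded), and a
random-forest regressor on the flattened 13 × 13 neighbourhood.

Everything runs on plain NumPy/SciPy — the network, its gradients and the
SGD loop are implemented in `hicenhance.nn` with FFT-based convolutions;
no deep-learning framework is required.

## Worked example

Train on three simulated replicate chromosomes (4 Mb, 400 bins at 10 kb,
heterogeneous TADs, 12 loops, 5 × 10⁵ in-band read pairs, thinned to 1/16),
early-stop on a fourth, evaluate on a fifth:

```python
import numpy as np
from hicenhance import (
    ContactEnhancer, correlation_by_distance, default_spec,
    ground_truth_intensity, make_pair,
)
from hicenhance.baselines import gaussian_smooth

train = [make_pair(default_spec(seed=s), fraction=1 / 16) for s in (1, 2, 3)]
val_high, val_low = make_pair(default_spec(seed=4), fraction=1 / 16)

model = ContactEnhancer(
    [(low, high) for high, low in train],
    validation_pairs=[(val_low, val_high)],
)
results = model.fit(seed=0)
print(results.summary())

spec = default_spec(seed=5)
truth = ground_truth_intensity(spec)          # noiseless expected intensity
_, low = make_pair(spec, fraction=1 / 16)
enhanced = results.enhance(low)

band = slice(3, 101)                          # 30 kb .. 1 Mb
for name, m in [("downsampled", low),
                ("gaussian", gaussian_smooth(low)),
                ("enhanced", enhanced)]:
    r = correlation_by_distance(truth, m).pearson[band]
    print(f"mean Pearson vs truth, {name:12s}: {np.nanmean(r):.3f}")
```

Output (about four minutes on one CPU core):

```
Contact-matrix enhancement ConvNet
==================================
architecture        : 16x5x5 -> ReLU -> 16x1x1 -> ReLU -> 1x9x9
window geometry     : 40 -> 28 bins (padding 12, stride 28)
receptive field     : 13 x 13 bins
parameters          : 1985
epochs run          : 300 (best validation at epoch 290)
training MSE        : first 0.8725  last 0.0213
validation MSE      : best 0.0199  last 0.0201
optimiser           : SGD lr=0.01 momentum=0.9 batch=256 seed=0
standardisation     : depth ratio 8.409, count scale 29.63
mean Pearson vs truth, downsampled : 0.245
mean Pearson vs truth, gaussian    : 0.631
mean Pearson vs truth, enhanced    : 0.723
```

Reading this: the raw 1/16-depth matrix correlates 0.245 with the true
contact intensity per genomic distance (averaged over 30 kb–1 Mb); plain
Gaussian smoothing recovers 0.631; the trained network recovers 0.723 and
is higher at *every* individual distance in that band. The MSE values are
in standardised count units (see `docs/methods.md`).

The same loop is available from the shell:

```sh
hicenhance simulate --seed 1 --out-high high.txt --out-low low.txt
hicenhance train --low low.txt --high high.txt --out model.npz
hicenhance enhance --model model.npz --in low.txt --out enhanced.txt
hicenhance evaluate --truth high.txt --pred enhanced.txt --pred low.txt
hicenhance v4c --in enhanced.txt --anchor-bin 125   # virtual-4C track
```

Real matrices are accepted as dense whitespace-delimited text or sparse
`bin_i bin_j count` triplets (`--format triplets --n-bins N`).

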