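"""Synthetic chromatin-contact maps with the structure the enhancer assumes.

A simulated chromosome is described by a :class:`SyntheticSpec` and built in
two stages.  First a smooth, strictly positive *intensity* surface

    lambda[i, j] = baseline * (1 + |i - j|)^(-alpha)
                   * (tad_enrichment if i, j share a TAD else 1)
                   + sum over loops of amp * exp(-((i-a)^2 + (j-b)^2) / (2 w^2))

combines the three hallmarks of real intra-chromosomal Hi-C: a power-law
distance decay, block-enriched topologically associating domains (TADs)
along the diagonal, and focal loop peaks between anchor pairs (each loop
bump is mirrored across the diagonal).  Second, integer read counts are
drawn: the intensity is scaled so its in-band upper-triangle sum equals the
requested sequencing depth and each cell receives an independent Poisson
draw — counts therefore scale linearly with depth, and reducing depth is
equivalent in distribution to binomial read thinning.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .contacts import ContactMatrix
from .downsample import downsample

__all__ = ["SyntheticSpec", "default_spec", "ground_truth_intensity", "sample_counts", "make_pair"]


@dataclasses.dataclass
class SyntheticSpec:
    """Parametric description of one simulated chromosome.

    Attributes
    ----------
    n_bins, resolution : size of the map (bins) and bin width (bp).
    decay_exponent : power-law exponent alpha of the contact decay
        ``(1 + d)^(-alpha)``; ~1 for mammalian intra-chromosomal maps.
    baseline_intensity : multiplicative level of the decay curve (the
        absolute scale is set later by the sequencing depth).
    tad_boundaries : strictly increasing interior bin indices partitioning
        ``[0, n_bins)`` into TADs.
    tad_enrichment : within-TAD contact multiplier (> 1).
    loops : ``(anchor_i, anchor_j, amplitude, width_bins)`` tuples; each adds
        a mirrored 2-D Gaussian bump.
    depth : expected total in-band read pairs of a full-depth library.
    max_dist_bins : diagonal band half-width for count sampling (2 Mb
        default at 10 kb).
    seed : seed for count sampling (and thinning in :func:`make_pair`).
    """

    n_bins: int = 400
    resolution: int = 10_000
    decay_exponent: float = 1.0
    baseline_intensity: float = 1.0
    tad_boundaries: tuple[int, ...] = ()
    tad_enrichment: float = 3.0
    loops: tuple[tuple[int, int, float, float], ...] = ()
    depth: float = 5e5
    max_dist_bins: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2 or self.resolution <= 0:
            raise ValueError("n_bins must be >= 2 and resolution positive")
        if self.decay_exponent <= 0 or self.baseline_intensity <= 0:
            raise ValueError("decay_exponent and baseline_intensity must be positive")
        b = list(self.tad_boundaries)
        if b != sorted(set(b)) or any(not 0 < x < self.n_bins for x in b):
            raise ValueError("tad_boundaries must be strictly increasing interior bin indices")
        if self.tad_enrichment <= 1:
            raise ValueError("tad_enrichment must be > 1")
        for i, j, amp, w in self.loops:
            if not 0 <= i < j < self.n_bins:
                raise ValueError(f"loop anchors must satisfy 0 <= i < j < n_bins, got ({i}, {j})")
            if amp <= 0 or w <= 0:
                raise ValueError("loop amplitude and width must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    def to_json(self, path: str | Path) -> None:
        """Write the spec (planted TADs/loops included) as a JSON sidecar."""
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        d = json.loads(Path(path).read_text())
        d["tad_boundaries"] = tuple(d["tad_boundaries"])
        d["loops"] = tuple(tuple(l) for l in d["loops"])
        return cls(**d)


def default_spec(seed: int = 0, depth: float = 5e5) -> SyntheticSpec:
    """The standard 4 Mb test chromosome: 400 bins at 10 kb, 8 TADs of
    heterogeneous width, 12 loops, 5e5 expected in-band read pairs.

    The layout (TADs and loop positions) is fixed; only the Poisson/thinning
    randomness varies with ``seed``, so matrices from different seeds are
    replicates of the same chromosome.  TAD widths span 0.2-1.15 Mb — real
    domains vary several-fold in size, and the mixture keeps structural
    signal (same-TAD vs cross-TAD contrast) present at every genomic
    distance inside the 2 Mb band rather than vanishing beyond one uniform
    domain width.  Loop anchor spans likewise cover the 0.15-1.5 Mb range,
    and loop amplitudes are four times the decayed background at the anchor
    distance, a strong but realistic focal enrichment.
    """
    n_bins = 400
    tad_sizes = (115, 100, 45, 40, 35, 25, 20, 20)  # bins; 1.15 Mb .. 0.2 Mb
    boundaries = tuple(int(b) for b in np.cumsum(tad_sizes)[:-1])
    anchor_pairs = [
        (5, 20), (130, 155), (230, 265), (30, 65),  # spans 0.15-0.35 Mb
        (120, 165), (10, 65), (225, 290), (320, 395),  # spans 0.45-0.75 Mb
        (20, 105), (125, 220), (5, 105), (270, 390),  # spans 0.85-1.5 Mb
    ]
    alpha, baseline = 1.0, 1.0
    loops = tuple(
        (i, j, 4.0 * baseline * (1 + (j - i)) ** (-alpha), 1.0) for i, j in anchor_pairs
    )
    return SyntheticSpec(
        n_bins=n_bins,
        resolution=10_000,
        decay_exponent=alpha,
        baseline_intensity=baseline,
        tad_boundaries=boundaries,
        tad_enrichment=3.0,
        loops=loops,
        depth=depth,
        max_dist_bins=200,
        seed=seed,
    )


def _tad_labels(spec: SyntheticSpec) -> np.ndarray:
    labels = np.zeros(spec.n_bins, dtype=int)
    for k, b in enumerate(spec.tad_boundaries, start=1):
        labels[b:] = k
    return labels


def ground_truth_intensity(spec: SyntheticSpec) -> ContactMatrix:
    """The noiseless expected-contact surface lambda (real-valued, symmetric,
    strictly positive)."""
    idx = np.arange(spec.n_bins)
    d = np.abs(idx[:, None] - idx[None, :])
    lam = spec.baseline_intensity * (1.0 + d) ** (-spec.decay_exponent)
    if spec.tad_boundaries:  # no boundaries declared = no domain structure
        labels = _tad_labels(spec)
        same_tad = labels[:, None] == labels[None, :]
        lam = np.where(same_tad, lam * spec.tad_enrichment, lam)
    ii = idx[:, None]
    jj = idx[None, :]
    for a, b, amp, w in spec.loops:
        for ci, cj in ((a, b), (b, a)):  # mirror the bump across the diagonal
            lam = lam + amp * np.exp(-((ii - ci) ** 2 + (jj - cj) ** 2) / (2.0 * w**2))
    return ContactMatrix(f"sim{spec.seed}", spec.resolution, lam, is_normalized=True)


def sample_counts(
    intensity: ContactMatrix,
    depth: float,
    max_dist: int,
    seed: int | None = None,
) -> ContactMatrix:
    """Draw an integer count matrix from an intensity surface.

    The surface is scaled so the expected in-band upper-triangle total equals
    ``depth`` (band: ``|i - j| * res <= max_dist``); each in-band
    upper-triangle cell gets an independent ``Poisson`` draw, mirrored to the
    lower triangle; out-of-band cells are 0.  Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    lam = intensity.values
    n = intensity.n_bins
    iu, ju = np.triu_indices(n)
    band = (ju - iu) * intensity.resolution <= max_dist
    band_lam = lam[iu[band], ju[band]]
    if np.any(band_lam <= 0):
        raise ValueError("intensity must be strictly positive within the band")
    scale = depth / band_lam.sum()
    rng = np.random.default_rng(seed)
    draws = rng.poisson(scale * band_lam)
    out = np.zeros((n, n))
    out[iu[band], ju[band]] = draws
    out[ju[band], iu[band]] = draws
    return ContactMatrix(intensity.chrom, intensity.resolution, out, is_normalized=False)


def make_pair(spec: SyntheticSpec, fraction: float = 1 / 16) -> tuple[ContactMatrix, ContactMatrix]:
    """Simulate a (deep, shallow) matrix pair for one chromosome.

    The deep matrix is sampled at ``spec.depth``; the shallow one is the
    deep matrix binomially thinned to ``fraction`` of its reads — exactly
    the down-sampling protocol used on real libraries.  Both randomness
    sources derive from ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    seed_counts, seed_thin = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    lam = ground_truth_intensity(spec)
    high = sample_counts(lam, spec.depth, spec.max_dist_bins * spec.resolution, seed_counts)
    low = downsample(high, fraction, seed_thin)
    return high, low
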