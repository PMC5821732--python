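"""Read thinning and sequencing-depth bookkeeping.

A shallow Hi-C library is simulated from a deep one by binomially thinning
every contact count: keeping each of the ``c`` read pairs behind an entry
independently with probability ``p`` gives a ``Binomial(c, p)`` draw, which
is distributionally identical to subsampling the read list when reads are
exchangeable.  The matrix is thinned on the upper triangle and mirrored, so
symmetry and integrality are preserved; diagonal entries are thinned like
any other entry.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .contacts import ContactMatrix

__all__ = ["downsample", "effective_depth_ratio", "select_model_tier", "DEFAULT_TIERS"]

#: Enhancement-scale tiers: the first tier whose depth-ratio threshold is
#: <= the observed ratio is chosen; anything shallower than 1/16 of the
#: training library still uses the deepest (x16) model.
DEFAULT_TIERS: tuple[tuple[float, str], ...] = (
    (1 / 4, "x4"),
    (1 / 8, "x8"),
    (1 / 16, "x16"),
)


def downsample(m: ContactMatrix, fraction: float, seed: int | None = None) -> ContactMatrix:
    """Binomially thin a raw count matrix to ``fraction`` of its depth.

    Every upper-triangle entry ``c`` is replaced by a ``Binomial(c, fraction)``
    draw and mirrored to the lower triangle, so
    ``E[out[i, j]] = fraction * m[i, j]``.  The same seed gives the same
    output.  Normalized matrices are rejected: thinning is defined on reads.
    """
    if m.is_normalized:
        raise ValueError("downsample operates on raw read counts, not normalized matrices")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    counts = np.round(m.values).astype(np.int64)
    if not np.allclose(m.values, counts):
        raise ValueError("downsample requires integer counts")
    rng = np.random.default_rng(seed)
    n = m.n_bins
    iu, ju = np.triu_indices(n)
    thinned = rng.binomial(counts[iu, ju], fraction)
    out = np.zeros((n, n), dtype=float)
    out[iu, ju] = thinned
    out[ju, iu] = thinned
    return ContactMatrix(m.chrom, m.resolution, out, is_normalized=False)


def effective_depth_ratio(
    candidate: ContactMatrix,
    reference: ContactMatrix,
    d_min: int = 25_000,
    d_max: int = 1_000_000,
) -> float:
    """Ratio of in-band read totals between a candidate and a reference map.

    Sums upper-triangle entries whose genomic distance ``|i - j| * res`` lies
    in ``[d_min, d_max]`` (inclusive after rounding ``d_min`` up and ``d_max``
    down to whole bins — at 10 kb resolution the default band is 3..100 bins)
    and divides candidate by reference.  Used to pick which enhancement model
    tier a shallow library needs.
    """
    if candidate.resolution != reference.resolution:
        raise ValueError("matrices must share a resolution")
    if not d_min < d_max:
        raise ValueError("d_min must be < d_max")

    def _band_sum(m: ContactMatrix) -> float:
        res = m.resolution
        k_min = math.ceil(d_min / res)
        k_max = math.floor(d_max / res)
        n = m.n_bins
        i, j = np.triu_indices(n)
        d = j - i
        sel = (d >= k_min) & (d <= k_max)
        return float(m.values[i[sel], j[sel]].sum())

    ref_sum = _band_sum(reference)
    if ref_sum == 0:
        raise ZeroDivisionError("reference matrix has zero total in the distance band")
    return _band_sum(candidate) / ref_sum


def select_model_tier(ratio: float, tiers: Sequence[tuple[float, str]] = DEFAULT_TIERS) -> str:
    """Map a depth ratio to an enhancement-model tag.

    ``tiers`` is ordered by descending threshold; the first tier whose
    threshold is ``<=`` the ratio wins (so a ratio exactly on a boundary is
    assigned to that tier), and ratios below every threshold fall through to
    the deepest-enhancement tier.
    """
    if not tiers:
        raise ValueError("tier list must not be empty")
    thresholds = [t for t, _ in tiers]
    if any(a <= b for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("tiers must be ordered by strictly descending threshold")
    for threshold, tag in tiers:
        if ratio >= threshold:
            return tag
    return tiers[-1][1]
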