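"""Distance-stratified agreement metrics and virtual-4C track extraction.

Hi-C signal drops steeply with genomic distance, so a single genome-wide
correlation between two matrices is dominated by the distance decay itself.
Agreement is therefore computed one diagonal at a time: for each genomic
distance ``d = k * resolution`` the k-th upper diagonals of the two matrices
are paired and Pearson and Spearman correlations computed across bins.
Diagonals that are constant in either matrix have no defined correlation and
are recorded as NaN and excluded from summaries.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactMatrix

__all__ = ["DistanceCorrelation", "correlation_by_distance", "summarize_methods", "virtual_4c"]


@dataclasses.dataclass
class DistanceCorrelation:
    """Per-distance Pearson/Spearman profiles between two matrices."""

    distances: np.ndarray  # genomic distances in bp
    pearson: np.ndarray  # NaN where undefined
    spearman: np.ndarray
    n_pairs: np.ndarray

    def mean_pearson(self, d_min: int | None = None, d_max: int | None = None) -> float:
        """Mean Pearson over defined distances, optionally restricted to
        ``[d_min, d_max]`` bp."""
        return self._mean(self.pearson, d_min, d_max)

    def mean_spearman(self, d_min: int | None = None, d_max: int | None = None) -> float:
        return self._mean(self.spearman, d_min, d_max)

    def _mean(self, vals: np.ndarray, d_min, d_max) -> float:
        sel = np.isfinite(vals)
        if d_min is not None:
            sel &= self.distances >= d_min
        if d_max is not None:
            sel &= self.distances <= d_max
        if not sel.any():
            return float("nan")
        return float(vals[sel].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance": self.distances,
                "pearson": self.pearson,
                "spearman": self.spearman,
                "n_pairs": self.n_pairs,
            }
        )


def correlation_by_distance(
    a: ContactMatrix, b: ContactMatrix, max_dist: int = 2_000_000
) -> DistanceCorrelation:
    """Pearson/Spearman between two matrices at each genomic distance.

    For ``k = 0 .. max_dist / resolution`` the k-th upper diagonals of both
    matrices are correlated across bins.  Symmetric in its arguments.
    """
    if a.n_bins != b.n_bins or a.resolution != b.resolution:
        raise ValueError("matrices must share shape and resolution")
    res = a.resolution
    k_max = min(max_dist // res, a.n_bins - 1)
    ks = np.arange(k_max + 1)
    pearson = np.full(len(ks), np.nan)
    spearman = np.full(len(ks), np.nan)
    n_pairs = np.zeros(len(ks), dtype=int)
    for idx, k in enumerate(ks):
        da = np.diagonal(a.values, offset=k)
        db = np.diagonal(b.values, offset=k)
        n_pairs[idx] = len(da)
        if len(da) < 2 or np.ptp(da) == 0 or np.ptp(db) == 0:
            continue  # correlation undefined on constant diagonals
        with warnings.catch_warnings():
            # near-constant diagonals (e.g. far-band intensity surfaces) are
            # legitimate inputs; precision loss there is acceptable
            warnings.simplefilter("ignore", stats.NearConstantInputWarning)
            pearson[idx] = stats.pearsonr(da, db).statistic
            spearman[idx] = stats.spearmanr(da, db).statistic
    return DistanceCorrelation(ks * res, pearson, spearman, n_pairs)


def summarize_methods(
    truth: ContactMatrix,
    candidates: Mapping[str, ContactMatrix],
    max_dist: int = 2_000_000,
) -> pd.DataFrame:
    """Per-distance correlations of several candidate matrices against a truth.

    Returns a long-format table (method, distance, pearson, spearman,
    n_pairs); per-method means over defined distances are available via
    ``df.groupby("method")[["pearson", "spearman"]].mean()``.
    """
    frames = []
    for name, cand in candidates.items():
        dc = correlation_by_distance(truth, cand, max_dist)
        frame = dc.to_frame()
        frame.insert(0, "method", name)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def virtual_4c(m: ContactMatrix, anchor: int) -> pd.DataFrame:
    """Extract one row of the matrix as a per-bin interaction track.

    Anchoring a symmetric contact map at one bin yields the Hi-C analogue of
    a 4C experiment viewed from that locus.  Returns a BED-like frame with
    columns chrom, start, end, value.
    """
    if not 0 <= anchor < m.n_bins:
        raise ValueError(f"anchor bin {anchor} out of range [0, {m.n_bins})")
    starts = np.arange(m.n_bins) * m.resolution
    return pd.DataFrame(
        {
            "chrom": m.chrom,
            "start": starts,
            "end": starts + m.resolution,
            "value": m.values[anchor],
        }
    )
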