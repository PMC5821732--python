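"""Dividing a chromosome matrix into network samples and merging them back.

The network consumes fixed-size square windows (default 40x40 bins) and,
because every convolution is valid (no zero padding), returns a smaller
window (default 28x28) registered at the same centre: a border of
``padding / 2`` bins (6 by default) is consumed on each side.  Extraction
therefore steps the input window by ``stride = N - padding`` so the output
windows tile the matrix seamlessly while the inputs overlap by ``padding``
bins; a clamped final window makes the tiling cover chromosomes whose
length is not a multiple of the stride.  Only upper-triangle windows are
processed (the matrix is symmetric) and only windows whose output touches
the 2 Mb diagonal band are kept — contacts beyond TAD scale are not
modelled.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .contacts import ContactMatrix

__all__ = ["PatchGeometry", "Patch", "extract_patches", "merge_patches"]


@dataclasses.dataclass(frozen=True)
class PatchGeometry:
    """Window geometry shared by patch extraction and the network.

    Attributes
    ----------
    N : int
        Input window side in bins (default 40, i.e. 0.4 Mb at 10 kb).
    padding : int
        Total border loss in bins across the three valid convolutions
        (default 12, so the output side is ``N - padding = 28``).
    stride : int
        Step between window origins; defaults to ``N - padding`` so output
        windows abut exactly.
    max_dist_bins : int
        Half-width of the diagonal band in bins (default 200 = 2 Mb at
        10 kb); windows whose output window lies entirely outside the band
        are dropped.
    """

    N: int = 40
    padding: int = 12
    stride: int | None = None
    max_dist_bins: int = 200

    def __post_init__(self) -> None:
        if self.padding % 2 != 0 or not 0 < self.padding < self.N:
            raise ValueError(f"padding must be even and in (0, N), got {self.padding}")
        if self.stride is None:
            object.__setattr__(self, "stride", self.N - self.padding)
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.max_dist_bins < 0:
            raise ValueError("max_dist_bins must be non-negative")

    @property
    def target_size(self) -> int:
        return self.N - self.padding

    @property
    def border(self) -> int:
        """Bins lost on each side of the input window (``padding / 2``)."""
        return self.padding // 2


@dataclasses.dataclass
class Patch:
    """One training/prediction sample: an input window and (optionally) its target.

    ``row_off``/``col_off`` locate the top-left corner of the *input* window
    in bin coordinates; the target window is centred on the input, offset by
    ``padding / 2`` on both axes.
    """

    row_off: int
    col_off: int
    input: np.ndarray
    target: np.ndarray | None = None

    def target_offsets(self, geom: PatchGeometry) -> tuple[int, int]:
        return self.row_off + geom.border, self.col_off + geom.border


def _origins(n_bins: int, N: int, stride: int) -> list[int]:
    """Window origins: the stride lattice plus a clamped final origin."""
    xs = list(range(0, n_bins - N + 1, stride))
    if xs[-1] != n_bins - N:
        xs.append(n_bins - N)
    return xs


def extract_patches(
    low: ContactMatrix,
    high: ContactMatrix | None,
    geom: PatchGeometry = PatchGeometry(),
) -> list[Patch]:
    """Cut paired (input, target) windows from a low/high matrix pair.

    With ``high=None`` (prediction mode) targets are left absent.  A window
    is kept iff its origin pair is in the upper triangle
    (``col_off >= row_off``) and its *target* window contains at least one
    cell within ``max_dist_bins`` of the diagonal.
    """
    n = low.n_bins
    if n < geom.N:
        raise ValueError(f"matrix too small: n_bins={n} < window size N={geom.N}")
    if high is not None:
        if high.n_bins != n:
            raise ValueError("low and high matrices must have the same n_bins")
    t = geom.target_size
    patches: list[Patch] = []
    for row_off in _origins(n, geom.N, geom.stride):
        for col_off in _origins(n, geom.N, geom.stride):
            if col_off < row_off:
                continue
            # Closest approach of the target window to the diagonal.
            min_dist = max(0, col_off - row_off - t + 1)
            if min_dist > geom.max_dist_bins:
                continue
            inp = low.values[row_off : row_off + geom.N, col_off : col_off + geom.N].copy()
            tgt = None
            if high is not None:
                r0, c0 = row_off + geom.border, col_off + geom.border
                tgt = high.values[r0 : r0 + t, c0 : c0 + t].copy()
            patches.append(Patch(row_off, col_off, inp, tgt))
    return patches


def merge_patches(
    patches: list[Patch],
    n_bins: int,
    geom: PatchGeometry,
    fallback: ContactMatrix,
) -> ContactMatrix:
    """Assemble predicted target windows into a chromosome-wide matrix.

    Each target cell is written at its absolute coordinates; cells covered
    by several windows (overlaps come from the clamped final window) are
    averaged; upper-triangle values are mirrored to the lower triangle;
    cells no window covers — the ``padding/2`` border frame and the
    out-of-band region — are filled from ``fallback`` (normally the
    low-depth input), so a complete matrix is always returned.  Negative
    predictions are clipped to 0: contact counts cannot be negative.
    """
    if fallback.n_bins != n_bins:
        raise ValueError("fallback matrix size does not match n_bins")
    t = geom.target_size
    sums = np.zeros((n_bins, n_bins))
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    for p in patches:
        if p.target is None:
            raise ValueError("merge_patches requires predicted targets on every patch")
        if p.target.shape != (t, t):
            raise ValueError(f"target shape {p.target.shape} != ({t}, {t})")
        r0, c0 = p.target_offsets(geom)
        sums[r0 : r0 + t, c0 : c0 + t] += p.target
        counts[r0 : r0 + t, c0 : c0 + t] += 1
    if not counts.any():
        raise ValueError("no patches to merge")
    covered = counts > 0
    avg = np.zeros_like(sums)
    avg[covered] = np.clip(sums[covered] / counts[covered], 0.0, None)

    out = fallback.values.copy()
    upper = np.triu(np.ones((n_bins, n_bins), dtype=bool))
    write = covered & upper
    out[write] = avg[write]
    out = np.triu(out) + np.triu(out, k=1).T  # mirror upper triangle
    return ContactMatrix(fallback.chrom, fallback.resolution, out, fallback.is_normalized)
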