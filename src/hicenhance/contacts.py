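"""Intra-chromosomal Hi-C contact matrices and their plain-text formats.

A contact matrix is the universal currency of this package: an ``n × n``
symmetric grid of non-negative values, one row/column per fixed-width
genomic bin of a single chromosome.  Raw matrices hold read-pair counts
(integers); matrices that went through an upstream balancing step hold
real values and carry ``is_normalized=True``.

Two text formats are supported:

* **dense** — whitespace-delimited square matrix, one row per line;
* **triplets** — three whitespace-delimited columns ``bin_i bin_j value``,
  ``#`` comment lines ignored.  Only listed pairs are stored; each pair
  fills both triangles, duplicates are summed.  Export writes the upper
  triangle (``i <= j``) only.

Bins are 0-based, half-open genomic intervals ``[k*res, (k+1)*res)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "ContactMatrix",
    "FormatError",
    "read_dense",
    "write_dense",
    "read_triplets",
    "write_triplets",
    "band_mask",
]


class FormatError(ValueError):
    """A file does not conform to the dense/triplet text conventions."""


@dataclasses.dataclass
class ContactMatrix:
    """Square symmetric contact map for one chromosome at a fixed bin size.

    Parameters
    ----------
    chrom : str
        Chromosome label, e.g. ``"chr18"`` or ``"sim0"``.
    resolution : int
        Bin size in base pairs (default convention in this package: 10 kb).
    values : numpy.ndarray
        ``(n_bins, n_bins)`` array, symmetric and non-negative.
    is_normalized : bool
        ``False`` for raw read counts, ``True`` for balanced real-valued
        matrices (accepted everywhere except read thinning).
    """

    chrom: str
    resolution: int
    values: np.ndarray
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise FormatError(f"contact matrix must be square, got shape {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("contact matrix entries must be non-negative")
        if not np.allclose(self.values, self.values.T, rtol=1e-8, atol=1e-8):
            raise ValueError("contact matrix must be symmetric (use symmetrize=True on read)")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.chrom, self.resolution, self.values.copy(), self.is_normalized)

    def total(self) -> float:
        """Total count over the upper triangle including the diagonal.

        Diagonal entries counted once, off-diagonal pairs once — i.e. the
        number of read pairs the matrix represents.
        """
        return float(np.triu(self.values).sum())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "normalized" if self.is_normalized else "counts"
        return (
            f"ContactMatrix({self.chrom!r}, res={self.resolution}, "
            f"n_bins={self.n_bins}, {kind})"
        )


def read_dense(
    path: str | Path,
    resolution: int = 10_000,
    chrom: str = "chr?",
    *,
    symmetrize: bool = False,
    is_normalized: bool = False,
) -> ContactMatrix:
    """Read a whitespace-delimited square matrix file.

    Asymmetric input is rejected unless ``symmetrize=True``, in which case
    the matrix is replaced by ``(M + M.T) / 2``.
    """
    values = np.loadtxt(path, dtype=float, ndmin=2)
    if values.shape[0] != values.shape[1]:
        raise FormatError(
            f"{path}: dense matrix must be square, got {values.shape[0]} rows x "
            f"{values.shape[1]} columns"
        )
    if symmetrize:
        values = (values + values.T) / 2.0
    return ContactMatrix(chrom, resolution, values, is_normalized)


def write_dense(m: ContactMatrix, path: str | Path) -> None:
    """Write a dense whitespace-delimited matrix, one row per line.

    Integer-valued matrices are written without a decimal point so that a
    dense round trip of raw counts is exact.
    """
    vals = m.values
    if not m.is_normalized and np.allclose(vals, np.round(vals)):
        np.savetxt(path, vals, fmt="%d")
    else:
        np.savetxt(path, vals, fmt="%.10g")


def read_triplets(
    path: str | Path,
    n_bins: int,
    resolution: int = 10_000,
    chrom: str = "chr?",
    *,
    index_base: int = 0,
    is_normalized: bool = False,
) -> ContactMatrix:
    """Read sparse ``bin_i bin_j value`` triplets into a dense symmetric matrix.

    Each listed pair fills both ``(i, j)`` and ``(j, i)``; unlisted pairs are
    zero; duplicate pairs are summed.  ``index_base`` selects the 0-based
    (default) or 1-based dialect.
    """
    if index_base not in (0, 1):
        raise ValueError("index_base must be 0 or 1")
    values = np.zeros((n_bins, n_bins), dtype=float)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                i = int(parts[0]) - index_base
                j = int(parts[1]) - index_base
                v = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable triplet {line!r}") from exc
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise ValueError(
                    f"{path}:{lineno}: bin index out of range for n_bins={n_bins}: {line!r}"
                )
            values[i, j] += v
            if i != j:
                values[j, i] += v
    return ContactMatrix(chrom, resolution, values, is_normalized)


def write_triplets(m: ContactMatrix, path: str | Path) -> None:
    """Write non-zero upper-triangle entries (``i <= j``) as triplets."""
    vals = m.values
    integral = not m.is_normalized and np.allclose(vals, np.round(vals))
    with open(path, "w") as fh:
        fh.write(f"# chrom={m.chrom} resolution={m.resolution} n_bins={m.n_bins}\n")
        iu, ju = np.triu_indices(m.n_bins)
        for i, j in zip(iu, ju):
            v = vals[i, j]
            if v != 0:
                fh.write(f"{i} {j} {int(v) if integral else repr(float(v))}\n")


def band_mask(m: ContactMatrix, max_dist: int) -> ContactMatrix:
    """Zero all entries farther than ``max_dist`` bp from the diagonal.

    ``max_dist`` is a genomic distance; entries with
    ``|i - j| * resolution > max_dist`` are set to 0, the rest untouched.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be non-negative")
    n = m.n_bins
    offsets = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    keep = offsets * m.resolution <= max_dist
    return ContactMatrix(m.chrom, m.resolution, np.where(keep, m.values, 0.0), m.is_normalized)
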