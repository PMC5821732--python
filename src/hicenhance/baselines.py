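"""Reference enhancement methods the network is compared against.

Three image denoisers — 2-D Gaussian smoothing, 2-D average smoothing and
Perona-Malik anisotropic diffusion — plus two neighbourhood *predictors*:
a naive average of the surrounding cells (centre excluded) and a random
forest regressed on the flattened surrounding window.  The distinction
matters: a denoiser re-estimates a cell using its own value, whereas a
predictor must infer it from the neighbours alone.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestRegressor

from .contacts import ContactMatrix

__all__ = [
    "SmoothingConfig",
    "neighborhood_average_predict",
    "gaussian_smooth",
    "mean_smooth",
    "anisotropic_diffusion",
    "RandomForestEnhancer",
    "rf_fit",
    "rf_predict",
]


@dataclasses.dataclass
class SmoothingConfig:
    """Parameters of the smoothing baselines.

    method: one of ``gaussian``, ``mean``, ``diffusion``.
    kernel_size / sigma apply to the kernel smoothers; n_iter / kappa /
    gamma to diffusion (gamma <= 0.25 for 2-D explicit-step stability).
    """

    method: str = "gaussian"
    kernel_size: int = 5
    sigma: float = 1.0
    n_iter: int = 10
    kappa: float = 30.0
    gamma: float = 0.2

    def __post_init__(self) -> None:
        if self.method not in ("gaussian", "mean", "diffusion"):
            raise ValueError(f"unknown smoothing method {self.method!r}")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and >= 1")
        if self.sigma <= 0 or self.kappa <= 0:
            raise ValueError("sigma and kappa must be positive")
        if not 0 < self.gamma <= 0.25:
            raise ValueError("gamma must be in (0, 0.25] for stability")

    def apply(self, m: ContactMatrix) -> ContactMatrix:
        if self.method == "gaussian":
            return gaussian_smooth(m, self.sigma, self.kernel_size)
        if self.method == "mean":
            return mean_smooth(m, self.kernel_size)
        return anisotropic_diffusion(m, self.n_iter, self.kappa, self.gamma)


def _renormalized_correlate(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Correlate with a kernel, renormalising by the in-bounds kernel mass at
    the borders so that a constant matrix stays constant."""
    num = ndimage.correlate(values, kernel, mode="constant", cval=0.0)
    den = ndimage.correlate(np.ones_like(values), kernel, mode="constant", cval=0.0)
    return num / den


def neighborhood_average_predict(m: ContactMatrix, k: int = 3) -> ContactMatrix:
    """Predict each cell as the mean of its k x k neighbourhood, centre excluded.

    Border cells use the truncated neighbourhood.  The result is symmetrised
    by averaging with its transpose (a no-op on exactly symmetric input).
    """
    if k % 2 == 0 or k < 3:
        raise ValueError("k must be odd and >= 3")
    ones = np.ones((k, k))
    sums = ndimage.correlate(m.values, ones, mode="constant", cval=0.0)
    counts = ndimage.correlate(np.ones_like(m.values), ones, mode="constant", cval=0.0)
    pred = (sums - m.values) / (counts - 1)
    pred = (pred + pred.T) / 2
    return ContactMatrix(m.chrom, m.resolution, pred, m.is_normalized)


def gaussian_smooth(m: ContactMatrix, sigma: float = 1.0, kernel_size: int = 5) -> ContactMatrix:
    """2-D Gaussian smoothing with a truncated kernel normalised to sum 1."""
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ValueError("kernel_size must be odd")
    half = kernel_size // 2
    ax = np.arange(-half, half + 1)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    kernel = np.outer(g1, g1)
    kernel /= kernel.sum()
    out = _renormalized_correlate(m.values, kernel)
    return ContactMatrix(m.chrom, m.resolution, out, m.is_normalized)


def mean_smooth(m: ContactMatrix, kernel_size: int = 3) -> ContactMatrix:
    """2-D average smoothing: uniform k x k kernel, centre included,
    truncated-and-renormalised at the borders."""
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ValueError("kernel_size must be odd")
    kernel = np.ones((kernel_size, kernel_size)) / kernel_size**2
    out = _renormalized_correlate(m.values, kernel)
    return ContactMatrix(m.chrom, m.resolution, out, m.is_normalized)


def anisotropic_diffusion(
    m: ContactMatrix, n_iter: int = 10, kappa: float = 30.0, gamma: float = 0.2
) -> ContactMatrix:
    """Perona-Malik edge-preserving diffusion.

    Each step updates ``u += gamma * sum over 4-neighbours of g(grad) * grad``
    with conductance ``g(x) = exp(-(x / kappa)^2)``.  Reflective borders make
    the update a discrete divergence, so the total sum is conserved.
    """
    if not 0 < gamma <= 0.25:
        raise ValueError("gamma must be in (0, 0.25] for 2-D stability")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    u = m.values.copy()
    for _ in range(n_iter):
        p = np.pad(u, 1, mode="edge")  # reflective: zero flux across borders
        flux = np.zeros_like(u)
        for dn in (p[:-2, 1:-1], p[2:, 1:-1], p[1:-1, :-2], p[1:-1, 2:]):
            d = dn - u
            flux += np.exp(-((d / kappa) ** 2)) * d
        u = u + gamma * flux
    u = (u + u.T) / 2  # guard against float asymmetry
    return ContactMatrix(m.chrom, m.resolution, u, m.is_normalized)


class RandomForestEnhancer:
    """Random-forest regressor from a surrounding low-depth window to the
    high-depth centre value.

    Features are the flattened ``window x window`` neighbourhood of a cell in
    the low-depth matrix (zero-padded at the borders) plus the bin distance
    ``|i - j|``; the target is the corresponding high-depth value.  The
    default 13-bin window matches the network's receptive field; the forest
    itself uses scikit-learn's RandomForestRegressor with its default
    parameters apart from an explicit 100 trees and the seed.
    """

    def __init__(self, window: int = 13, max_dist_bins: int = 200, seed: int = 0,
                 n_estimators: int = 100, max_training_cells: int | None = 20_000):
        if window % 2 == 0 or window < 1:
            raise ValueError("window must be odd")
        self.window = window
        self.max_dist_bins = max_dist_bins
        self.seed = seed
        self.n_estimators = n_estimators
        self.max_training_cells = max_training_cells
        self._forest: RandomForestRegressor | None = None

    def _band_cells(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        iu, ju = np.triu_indices(n)
        sel = (ju - iu) <= self.max_dist_bins
        return iu[sel], ju[sel]

    def _features(self, low: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        half = self.window // 2
        padded = np.pad(low, half, mode="constant")
        win = np.lib.stride_tricks.sliding_window_view(padded, (self.window, self.window))
        feats = win[rows, cols].reshape(len(rows), -1)
        return np.column_stack([feats, np.abs(cols - rows)])

    def fit(self, low: ContactMatrix, high: ContactMatrix) -> "RandomForestEnhancer":
        if low.n_bins != high.n_bins:
            raise ValueError("low and high matrices must have the same size")
        rows, cols = self._band_cells(low.n_bins)
        if self.max_training_cells is not None and len(rows) > self.max_training_cells:
            rng = np.random.default_rng(self.seed)
            keep = rng.choice(len(rows), self.max_training_cells, replace=False)
            rows, cols = rows[keep], cols[keep]
        X = self._features(low.values, rows, cols)
        y = high.values[rows, cols]
        if np.all(y == y[0]):
            import warnings

            warnings.warn("all training targets identical; forest degenerates to a constant")
        self._forest = RandomForestRegressor(
            n_estimators=self.n_estimators, random_state=self.seed, n_jobs=1
        )
        self._forest.fit(X, y)
        return self

    def predict(self, low: ContactMatrix) -> ContactMatrix:
        if self._forest is None:
            raise RuntimeError("fit() must be called before predict()")
        if self._forest.n_features_in_ != self.window**2 + 1:
            raise ValueError("fitted window size does not match this predictor")
        rows, cols = self._band_cells(low.n_bins)
        pred = self._forest.predict(self._features(low.values, rows, cols))
        out = low.values.copy()
        out[rows, cols] = pred
        out[cols, rows] = pred
        return ContactMatrix(low.chrom, low.resolution, out, low.is_normalized)


def rf_fit(
    low: ContactMatrix,
    high: ContactMatrix,
    window: int = 13,
    seed: int = 0,
    **kwargs,
) -> RandomForestEnhancer:
    """Fit a :class:`RandomForestEnhancer` (functional convenience wrapper)."""
    return RandomForestEnhancer(window=window, seed=seed, **kwargs).fit(low, high)


def rf_predict(handle: RandomForestEnhancer, low: ContactMatrix) -> ContactMatrix:
    """Predict the band of ``low`` with a fitted forest; out-of-band cells
    keep their input values."""
    return handle.predict(low)
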