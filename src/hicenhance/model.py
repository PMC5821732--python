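"""Model/results interface for fitting and applying the contact enhancer.

:class:`ContactEnhancer` is built from one or more (low-depth, high-depth)
chromosome matrix pairs; :meth:`ContactEnhancer.fit` runs the SGD training
loop and returns an :class:`EnhancerResults` carrying the learned filters,
the loss history, a ``summary()`` table, whole-matrix ``enhance()``, and
model persistence.  The functional layer lives in :mod:`hicenhance.nn`;
this module only organises it around data.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .contacts import ContactMatrix
from .patches import Patch, PatchGeometry, extract_patches

__all__ = ["ContactEnhancer", "EnhancerResults"]


class ContactEnhancer:
    """Learns the low-depth -> high-depth window mapping from matrix pairs.

    Parameters
    ----------
    pairs : list of (low, high) ContactMatrix tuples
        Training chromosomes.  Each pair is cut into overlapping 40x40 /
        28x28 windows within the 2 Mb diagonal band.
    validation_pairs : optional list of pairs
        Held-out chromosomes used for early stopping; when omitted, a
        random fraction of the training windows is held out instead
        (splitting by chromosome is the recommended protocol).
    geometry : PatchGeometry
        Window geometry; must be consistent with the filter sizes.
    standardize : bool
        When True (default) the windows are put on a common O(1) scale
        before training: inputs are multiplied by the empirical depth ratio
        between the high and low training matrices (so a 1/16 library is
        brought back to the deep-count scale) and both sides are divided by
        the standard deviation of the target counts.  Predictions are
        mapped back to raw counts at enhancement time, so the scaling is
        invisible to the caller; it only conditions the optimisation, which
        Glorot-initialised SGD needs on raw Hi-C counts.

    Attributes
    ----------
    depth_ratio : float
        Sum of target counts over sum of input counts across the training
        windows.  Of the order of the library depth ratio (1/fraction) but
        window-weighted — inputs are the full 40x40 windows, targets the
        central 28x28 — so it need not equal it exactly; any residual scale
        is absorbed by the learned weights.
    count_scale : float
        Standard deviation of the target counts; the unit of the
        standardised problem.
    """

    def __init__(
        self,
        pairs: list[tuple[ContactMatrix, ContactMatrix]],
        validation_pairs: list[tuple[ContactMatrix, ContactMatrix]] | None = None,
        geometry: PatchGeometry = PatchGeometry(),
        standardize: bool = True,
    ):
        if not pairs:
            raise ValueError("at least one (low, high) training pair is required")
        self.geometry = geometry
        self.train_patches: list[Patch] = []
        for low, high in pairs:
            self.train_patches.extend(extract_patches(low, high, geometry))

        self.depth_ratio = 1.0
        self.count_scale = 1.0
        if standardize:
            tgt_sum = sum(p.target.sum() for p in self.train_patches)
            in_sum = sum(p.input.sum() for p in self.train_patches)
            scale = float(np.std(np.concatenate([p.target.ravel() for p in self.train_patches])))
            if in_sum > 0 and tgt_sum > 0 and scale > 0:
                self.depth_ratio = float(tgt_sum / in_sum)
                self.count_scale = scale

        def rescale(patches: list[Patch]) -> list[Patch]:
            return [
                Patch(
                    p.row_off,
                    p.col_off,
                    p.input * (self.depth_ratio / self.count_scale),
                    None if p.target is None else p.target / self.count_scale,
                )
                for p in patches
            ]

        self.train_patches = rescale(self.train_patches)
        self.validation_patches: list[Patch] | None = None
        if validation_pairs is not None:
            self.validation_patches = []
            for low, high in validation_pairs:
                self.validation_patches.extend(extract_patches(low, high, geometry))
            self.validation_patches = rescale(self.validation_patches)

    @classmethod
    def from_matrices(
        cls,
        low: ContactMatrix | list[ContactMatrix],
        high: ContactMatrix | list[ContactMatrix],
        validation_low: ContactMatrix | list[ContactMatrix] | None = None,
        validation_high: ContactMatrix | list[ContactMatrix] | None = None,
        geometry: PatchGeometry = PatchGeometry(),
    ) -> "ContactEnhancer":
        """Build the model from parallel lists of low/high matrices."""

        def aslist(x):
            if x is None:
                return None
            return x if isinstance(x, list) else [x]

        pairs = list(zip(aslist(low), aslist(high)))
        vlow, vhigh = aslist(validation_low), aslist(validation_high)
        vpairs = list(zip(vlow, vhigh)) if vlow is not None else None
        return cls(pairs, vpairs, geometry)

    def fit(
        self,
        config: nn.TrainConfig | None = None,
        start_params: nn.ConvNetParams | None = None,
        **config_overrides,
    ) -> "EnhancerResults":
        """Train by mini-batch SGD on MSE; returns the best-validation model.

        Keyword overrides (``learning_rate=...``, ``max_epochs=...``, ...)
        are applied on top of ``config`` or the defaults.
        """
        if config is None:
            config = nn.TrainConfig(**config_overrides)
        elif config_overrides:
            import dataclasses

            config = dataclasses.replace(config, **config_overrides)
        params, history = nn.train(
            self.train_patches,
            config,
            self.geometry,
            validation_patches=self.validation_patches,
            params=start_params,
        )
        return EnhancerResults(
            params, history, config, self.geometry, self,
            depth_ratio=self.depth_ratio, count_scale=self.count_scale,
        )


class EnhancerResults:
    """Fitted enhancer: learned filters plus training diagnostics."""

    def __init__(
        self,
        params: nn.ConvNetParams,
        loss_history: nn.LossHistory,
        config: nn.TrainConfig,
        geometry: PatchGeometry,
        model: ContactEnhancer | None = None,
        depth_ratio: float = 1.0,
        count_scale: float = 1.0,
    ):
        self.params = params
        self.loss_history = loss_history
        self.config = config
        self.geometry = geometry
        self.model = model
        self.depth_ratio = depth_ratio
        self.count_scale = count_scale

    # -- application ------------------------------------------------------
    def enhance(self, low: ContactMatrix) -> ContactMatrix:
        """Enhance a whole low-depth chromosome matrix with the fitted net.

        The input windows are standardised exactly as during training and
        the predictions are mapped back to raw counts before merging.  The
        returned matrix is on the deep-count scale everywhere: cells no
        window covers (the border frame and the out-of-band region) are
        filled from the low-depth input multiplied by the training depth
        ratio, so covered and uncovered cells share one scale instead of
        mixing deep predictions with 1/16-depth raw counts.
        """
        from .patches import extract_patches, merge_patches

        patches = extract_patches(low, None, self.geometry)
        x = np.stack([p.input for p in patches])[:, None].astype(float)
        x *= self.depth_ratio / self.count_scale
        preds = nn._forward_batch(self.params, x) * self.count_scale
        for p, pred in zip(patches, preds):
            p.target = pred[0]
        fallback = ContactMatrix(
            low.chrom, low.resolution, low.values * self.depth_ratio, low.is_normalized
        )
        return merge_patches(patches, low.n_bins, self.geometry, fallback=fallback)

    predict = enhance

    def predict_patch(self, window: np.ndarray) -> np.ndarray:
        """Run the network on a single raw-count input window."""
        pred = nn.forward(self.params, window * (self.depth_ratio / self.count_scale))
        return pred * self.count_scale

    # -- diagnostics ------------------------------------------------------
    @property
    def receptive_field(self) -> int:
        return nn.receptive_field(self.params)

    def summary(self) -> str:
        h = self.loss_history
        f1, f2, f3 = self.params.filter_sizes
        n1 = self.params.w1.shape[0]
        n2 = self.params.w2.shape[0]
        lines = [
            "Contact-matrix enhancement ConvNet",
            "==================================",
            f"architecture        : {n1}x{f1}x{f1} -> ReLU -> {n2}x{f2}x{f2} -> ReLU -> 1x{f3}x{f3}",
            f"window geometry     : {self.geometry.N} -> {self.geometry.target_size} bins "
            f"(padding {self.geometry.padding}, stride {self.geometry.stride})",
            f"receptive field     : {self.receptive_field} x {self.receptive_field} bins",
            f"parameters          : {self.params.n_parameters()}",
            f"epochs run          : {h.n_epochs} (best validation at epoch {h.best_epoch})",
            f"training MSE        : first {h.train[0]:.4f}  last {h.train[-1]:.4f}",
            f"validation MSE      : best {min(h.validation):.4f}  last {h.validation[-1]:.4f}",
            f"optimiser           : SGD lr={self.config.learning_rate} "
            f"momentum={self.config.momentum} batch={self.config.batch_size} "
            f"seed={self.config.seed}",
            f"standardisation     : depth ratio {self.depth_ratio:.4g}, "
            f"count scale {self.count_scale:.4g}",
        ]
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Training/validation MSE per epoch (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(self.loss_history.n_epochs)
        ax.plot(epochs, self.loss_history.train, label="training MSE")
        ax.plot(epochs, self.loss_history.validation, label="validation MSE")
        ax.axvline(self.loss_history.best_epoch, ls="--", c="grey", lw=0.8)
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE")
        ax.legend()
        return ax

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        nn.save_params(
            self.params,
            path,
            self.geometry,
            meta={
                "train_config": {
                    "learning_rate": self.config.learning_rate,
                    "batch_size": self.config.batch_size,
                    "max_epochs": self.config.max_epochs,
                    "seed": self.config.seed,
                    "momentum": self.config.momentum,
                    "patience": self.config.patience,
                },
                "best_epoch": self.loss_history.best_epoch,
                "epochs_run": self.loss_history.n_epochs,
                "depth_ratio": self.depth_ratio,
                "count_scale": self.count_scale,
            },
        )

    @classmethod
    def load(cls, path) -> "EnhancerResults":
        params, geom, meta = nn.load_params(path)
        tc = meta.get("train_config", {})
        config = nn.TrainConfig(
            learning_rate=tc.get("learning_rate", 1e-2),
            batch_size=tc.get("batch_size", 256),
            max_epochs=tc.get("max_epochs", 300),
            seed=tc.get("seed", 0),
            momentum=tc.get("momentum", 0.9),
            patience=tc.get("patience", 20),
        )
        n_epochs = meta.get("epochs_run", 0)
        history = nn.LossHistory(
            train=[float("nan")] * n_epochs,
            validation=[float("nan")] * n_epochs,
            best_epoch=meta.get("best_epoch", 0),
        )
        return cls(
            params, history, config, geom,
            depth_ratio=meta.get("depth_ratio", 1.0),
            count_scale=meta.get("count_scale", 1.0),
        )
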