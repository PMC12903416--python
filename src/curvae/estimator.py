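"""Scikit-learn-style estimator wrapping the decomposed-latent VAE.

``MixedCurvatureVAE`` is fit on a cells x genes UMI count matrix and
transforms cells into the concatenated per-component latent
coordinates.  It composes with sklearn pipelines and model selection;
the lower-level :mod:`curvae.model` / :mod:`curvae.training` machinery
stays accessible through the fitted attributes.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import autodiff as ad
from .manifolds import CurvatureSpace
from .model import (CellBatchDesign, DecomposedVAE, GenePartition, LatentSpec,
                    dense_counts)
from .training import TrainConfig, train


def _component_defaults(comp: dict) -> dict:
    out = {"geometry": "euclidean", "curvature": 0.0, "dim": 10,
           "distribution": None, "genes": None, "decode_inputs": None,
           "stop_grad_epochs": 0, "batch_keys": None}
    out.update(comp)
    if out["distribution"] is None:
        out["distribution"] = ("normal" if out["geometry"] == "euclidean"
                               else "wrapped-normal")
    if out["geometry"] != "euclidean" and out["curvature"] == 0.0:
        out["curvature"] = -2.0 if out["geometry"] == "hyperbolic" else 1.0
    return out


DEFAULT_COMPONENTS = (
    {"name": "signal", "geometry": "hyperbolic", "curvature": -2.0, "dim": 2,
     "distribution": "rown", "genes": "markers"},
    {"name": "rest", "geometry": "euclidean", "dim": 10},
)


class MixedCurvatureVAE(BaseEstimator, TransformerMixin):
    """VAE over a product of constant-curvature latent subspaces.

    Parameters
    ----------
    components
        Ordered component descriptions.  Each is a dict with keys
        ``name``, ``genes`` (marker gene indices or names; the string
        ``"markers"`` refers to the ``markers`` fit parameter; omit or
        ``None`` for the remainder component), ``geometry``
        (``euclidean`` / ``hyperspherical`` / ``hyperbolic``),
        ``curvature``, ``dim``, ``distribution`` (``normal`` /
        ``wrapped-normal`` / ``rown``), ``decode_inputs``,
        ``stop_grad_epochs`` and ``batch_keys`` (covariates appended to
        this component's decoder; default all).
    epochs, batch_size, learning_rate, weight_decay
        Training recipe (defaults: 500, 128, 1e-3, 0.01).
    random_state
        Seed for initialisation, minibatch order and the ELBO's
        Monte-Carlo draws.
    """

    def __init__(self, components=DEFAULT_COMPONENTS, epochs: int = 500,
                 batch_size: int = 128, learning_rate: float = 1e-3,
                 weight_decay: float = 0.01, random_state: int = 0,
                 log_every: int = 0):
        self.components = components
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.random_state = random_state
        self.log_every = log_every

    # -- helpers -------------------------------------------------------
    def _resolve_genes(self, spec_genes, markers, gene_names, n_genes):
        if spec_genes is None:
            return None
        if isinstance(spec_genes, str):
            if markers is None or spec_genes not in markers:
                raise ValueError(f"marker set {spec_genes!r} not provided")
            spec_genes = markers[spec_genes]
        spec_genes = list(spec_genes)
        if spec_genes and not isinstance(spec_genes[0], numbers.Integral):
            if gene_names is None:
                raise ValueError("gene names required to resolve symbols")
            lookup = {g: i for i, g in enumerate(gene_names)}
            resolved = [lookup[g] for g in spec_genes if g in lookup]
            if not resolved:
                raise ValueError("no marker symbols found in the matrix")
            return np.asarray(resolved, dtype=np.int64)
        return np.asarray(spec_genes, dtype=np.int64)

    def _build(self, n_genes, markers, gene_names, batches: pd.DataFrame | None):
        comps = [_component_defaults(dict(c)) for c in self.components]
        if len(comps) < 1:
            raise ValueError("need at least one component")
        if markers is not None and all(c["genes"] is None for c in comps):
            # convenience: a single markers set feeds the first component
            if len(markers) == 1 and len(comps) > 1:
                comps[0]["genes"] = next(iter(markers.values()))
        part = GenePartition(
            [(c["name"], self._resolve_genes(c["genes"], markers, gene_names,
                                             n_genes)) for c in comps],
            n_genes)
        specs = []
        applicability = {}
        for c in comps:
            specs.append(LatentSpec(
                name=c["name"],
                space=CurvatureSpace(c["geometry"], float(c["curvature"]),
                                     int(c["dim"])),
                distribution=c["distribution"],
                decode_inputs=(tuple(c["decode_inputs"])
                               if c["decode_inputs"] else None),
                stop_grad_epochs=int(c["stop_grad_epochs"])))
            if c["batch_keys"] is not None:
                applicability[c["name"]] = tuple(c["batch_keys"])
        bd = CellBatchDesign(batches, applicability or None)
        return DecomposedVAE(part, specs, bd)

    @staticmethod
    def _as_frame(batches, n) -> pd.DataFrame | None:
        if batches is None:
            return None
        if isinstance(batches, pd.DataFrame):
            df = batches.reset_index(drop=True)
        elif isinstance(batches, (pd.Series, np.ndarray, list)):
            df = pd.DataFrame({"batch": np.asarray(batches)})
        else:
            raise TypeError("batches must be a DataFrame, Series or array")
        if len(df) != n:
            raise ValueError("one batch row per cell required")
        return df.astype(str)

    # -- sklearn API ---------------------------------------------------
    def fit(self, X, y=None, *, markers=None, gene_names=None, batches=None):
        """Train on a cells x genes count matrix.

        ``markers`` maps set names to gene symbols/indices; ``batches``
        is a per-cell categorical table.  AnnData input contributes its
        ``var_names`` as gene names.
        """
        try:
            import anndata
            if isinstance(X, anndata.AnnData) and gene_names is None:
                gene_names = list(X.var_names)
        except ImportError:  # pragma: no cover
            pass
        Xd = dense_counts(X)
        bframe = self._as_frame(batches, Xd.shape[0])
        model = self._build(Xd.shape[1], markers, gene_names, bframe)
        cfg = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                          learning_rate=self.learning_rate,
                          weight_decay=self.weight_decay,
                          seed=self.random_state, log_every=self.log_every)
        rng = np.random.default_rng(self.random_state)
        model, history = train(model, Xd, bframe, cfg, rng)
        self.model_ = model
        self.history_ = history
        self.partition_ = model.partition
        self.n_features_in_ = Xd.shape[1]
        return self

    def encode_components(self, X) -> dict[str, np.ndarray]:
        """Posterior locations per component (ambient coordinates)."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "model_")
        posts = self.model_.encode(dense_counts(X))
        return {p["spec"].name: np.asarray(ad.value(p["mu"])) for p in posts}

    def transform(self, X) -> np.ndarray:
        """Concatenated per-component posterior locations."""
        comps = self.encode_components(X)
        return np.concatenate([comps[n] for n in self.partition_.names], axis=1)

    def score(self, X, y=None, batches=None) -> float:
        """Mean ELBO (higher is better) under a fixed evaluation seed."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "model_")
        Xd = dense_counts(X)
        rows = self._as_frame(batches, Xd.shape[0])
        loss, _ = self.model_.elbo_loss(Xd, rows, np.random.default_rng(0))
        return -float(ad.value(loss))
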