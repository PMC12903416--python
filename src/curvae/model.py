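"""The decomposed-latent VAE.

A cell's UMI count vector ``x`` is split by a :class:`GenePartition`
into blocks (marker genes for each modelled signal; the final component
owns every unclaimed gene).  Each component has its own encoder (the
other blocks are masked out of its input), its own latent geometry, and
the gene blocks are decoded with negative-binomial likelihoods whose
means are a softmax over the block scaled by the cell's total UMI
count.  The objective is the standard ELBO: reconstruction minus the
KL between the per-component variational posterior and a wrapped
standard normal prior at each component's origin.

A per-component stop-gradient switch can block, for an initial number
of epochs, the gradients that a block's reconstruction would otherwise
send into *other* components' latents — keeping an already-learned
signal latent fixed while the remaining components absorb what is left.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse as sps

from . import autodiff as ad
from . import distributions as dist
from . import manifolds as mf
from .config import TOLERANCES
from .manifolds import CurvatureSpace

ENCODER_WIDTHS = (128, 64, 32)
DECODER_WIDTHS = (64, 128)


# ---------------------------------------------------------------------------
# gene partition
# ---------------------------------------------------------------------------

class GenePartition:
    """Ordered, named gene index sets over G genes.

    Any two components' sets must be identical or disjoint; a component
    given ``None`` (conventionally the final one) owns every gene not
    claimed by the others.  Components sharing a gene set are modelled
    once (a single decoded block).
    """

    def __init__(self, components, n_genes: int):
        if n_genes < 1 or not components:
            raise ValueError("need at least one gene and one component")
        self.n_genes = int(n_genes)
        names, sets = [], []
        remainder_slots = []
        claimed = np.zeros(n_genes, dtype=bool)
        for i, (name, idx) in enumerate(components):
            names.append(str(name))
            if idx is None:
                remainder_slots.append(i)
                sets.append(None)
                continue
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size == 0:
                raise ValueError(f"component {name!r} has an empty gene set")
            if idx.min() < 0 or idx.max() >= n_genes or len(np.unique(idx)) != idx.size:
                raise ValueError(f"invalid gene indices for component {name!r}")
            sets.append(np.sort(idx))
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        if len(remainder_slots) > 1:
            raise ValueError("at most one remainder component")
        for i, s in enumerate(sets):
            if s is None:
                continue
            for j in range(i):
                if sets[j] is None:
                    continue
                shared = np.intersect1d(s, sets[j])
                if shared.size and not np.array_equal(s, sets[j]):
                    raise ValueError(
                        f"gene sets of {names[i]!r} and {names[j]!r} must be "
                        "either the same or disjoint")
            claimed[s] = True
        if remainder_slots:
            rest = np.flatnonzero(~claimed)
            if rest.size == 0:
                raise ValueError("remainder component would be empty")
            sets[remainder_slots[0]] = rest
        elif not claimed.all():
            raise ValueError("union of gene sets must cover all genes")
        self.names: list[str] = names
        self.index_sets: list[np.ndarray] = sets
        # distinct blocks: (gene indices, list of owning component positions)
        blocks: list[tuple[np.ndarray, list[int]]] = []
        for i, s in enumerate(sets):
            for genes, owners in blocks:
                if np.array_equal(genes, s):
                    owners.append(i)
                    break
            else:
                blocks.append((s, [i]))
        self.blocks = blocks

    @property
    def k(self) -> int:
        return len(self.names)

    def partition_counts(self, x):
        """Split a length-G count vector (or cells x G matrix) per component."""
        x = np.asarray(x)
        if x.shape[-1] != self.n_genes:
            raise ValueError("length mismatch with the partition")
        return [x[..., s] for s in self.index_sets]


# ---------------------------------------------------------------------------
# component / batch specifications
# ---------------------------------------------------------------------------

@dataclass
class LatentSpec:
    """Geometry, distribution family and decoding wiring of one component."""

    name: str
    space: CurvatureSpace
    distribution: str = "wrapped-normal"  # normal | wrapped-normal | rown
    decode_inputs: tuple[str, ...] | None = None  # resolved by the model
    stop_grad_epochs: int = 0

    def __post_init__(self):
        if self.distribution not in ("normal", "wrapped-normal", "rown"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "normal" and self.space.curved:
            raise ValueError("plain normal posterior requires a Euclidean space")
        if self.stop_grad_epochs < 0:
            raise ValueError("stop_grad_epochs must be >= 0")


class CellBatchDesign:
    """Per-cell categorical covariates and their per-component applicability.

    ``applicability`` maps a component name to the covariates whose
    one-hot encodings are appended to that component's decoder input
    (e.g. append a time covariate only to the signal component).  By
    default every covariate applies to every component.
    """

    def __init__(self, covariates: pd.DataFrame | None = None,
                 applicability: dict[str, tuple[str, ...]] | None = None):
        if covariates is None:
            covariates = pd.DataFrame(index=pd.RangeIndex(0))
        self.covariates = covariates
        self._names = [str(c) for c in covariates.columns]
        self.levels = {c: sorted(map(str, covariates[c].astype(str).unique()))
                       for c in covariates.columns}
        self.applicability = applicability or {}
        for comp, covs in self.applicability.items():
            for c in covs:
                if c not in self.levels:
                    raise ValueError(f"unknown covariate {c!r} for component {comp!r}")

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def covs_for(self, component: str) -> list[str]:
        if component in self.applicability:
            return list(self.applicability[component])
        return self.names

    def width_for(self, component: str) -> int:
        return sum(len(self.levels[c]) for c in self.covs_for(component))

    def onehot(self, rows: pd.DataFrame, component: str) -> np.ndarray:
        """One-hot encode the applicable covariates for the given cells."""
        parts = []
        for c in self.covs_for(component):
            lv = self.levels[c]
            vals = rows[c].astype(str).to_numpy()
            codes = np.array([lv.index(v) if v in lv else -1 for v in vals])
            if np.any(codes < 0):
                bad = vals[codes < 0][0]
                raise ValueError(f"unseen level {bad!r} for covariate {c!r}")
            oh = np.zeros((len(vals), len(lv)))
            oh[np.arange(len(vals)), codes] = 1.0
            parts.append(oh)
        if not parts:
            return np.zeros((len(rows), 0))
        return np.concatenate(parts, axis=1)

    def n_dispersion_levels(self) -> int:
        if not self.names:
            return 1
        return len(self.levels[self.names[0]])

    def dispersion_index(self, rows: pd.DataFrame) -> np.ndarray:
        if not self.names:
            return np.zeros(len(rows), dtype=np.int64)
        c = self.names[0]
        lv = self.levels[c]
        return np.array([lv.index(str(v)) for v in rows[c]], dtype=np.int64)


# ---------------------------------------------------------------------------
# negative binomial
# ---------------------------------------------------------------------------

def nb_log_likelihood(x, mean, dispersion):
    """Sum over the last axis of the NB log-pmf (mean/dispersion form).

    ``log NB(x; mu, th) = lgam(x+th) - lgam(th) - lgam(x+1)
                          + th*log(th/(th+mu)) + x*log(mu/(th+mu))``
    """
    xv = np.asarray(ad.value(x))
    if np.any(xv < 0) or not np.allclose(xv, np.round(xv)):
        raise ValueError("counts must be nonnegative integers")
    th, mu = dispersion, mean
    log_th_mu = ad.log(ad.add(th, mu))
    t1 = ad.add(ad.gammaln(ad.add(th, xv)), ad.mul(ad.gammaln(th), -1.0))
    t1 = ad.add(t1, -_gammaln_const(xv + 1.0))
    t2 = ad.mul(th, ad.add(ad.log(th), ad.mul(log_th_mu, -1.0)))
    t3 = ad.mul(xv, ad.add(ad.log(mu), ad.mul(log_th_mu, -1.0)))
    return ad.sum(ad.add(ad.add(t1, t2), t3), axis=-1)


def _gammaln_const(x):
    from scipy.special import gammaln
    return gammaln(x)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

def _linear(params, name, x):
    return ad.add(ad.matmul(x, params[name + "/W"]), params[name + "/b"])


class DecomposedVAE:
    """Encoders, decoders, dispersions and the ELBO for one dataset layout."""

    def __init__(self, partition: GenePartition, specs: list[LatentSpec],
                 batch_design: CellBatchDesign | None = None):
        if len(specs) != partition.k:
            raise ValueError("one LatentSpec per partition component")
        for name, spec in zip(partition.names, specs):
            if spec.name != name:
                raise ValueError("spec order must match partition order")
        self.partition = partition
        self.specs = specs
        self.batches = batch_design or CellBatchDesign()
        self._resolve_wiring()
        self.params: dict[str, ad.Tensor] = {}

    # -- wiring --------------------------------------------------------
    def _resolve_wiring(self):
        names = self.partition.names
        k = self.partition.k
        for j, spec in enumerate(self.specs):
            if spec.decode_inputs is None:
                if j == k - 1:
                    spec.decode_inputs = tuple(names)  # final: all latents
                else:
                    spec.decode_inputs = (spec.name,)
            if spec.name not in spec.decode_inputs:
                raise ValueError(
                    f"component {spec.name!r} must decode from its own latent")
        # per block: owner component (earliest sharer) and input components
        self.block_owner: list[int] = []
        self.block_inputs: list[tuple[int, ...]] = []
        for genes, owners in self.partition.blocks:
            owner = owners[0]
            inputs: list[int] = []
            for o in owners:
                for nm in self.specs[o].decode_inputs:
                    i = names.index(nm)
                    if i not in inputs:
                        inputs.append(i)
            self.block_owner.append(owner)
            self.block_inputs.append(tuple(sorted(inputs)))

    # -- parameters ----------------------------------------------------
    def layer_shapes(self) -> dict[str, tuple]:
        """Name -> shape for every learnable array."""
        shapes: dict[str, tuple] = {}
        for j, spec in enumerate(self.specs):
            n_in = len(self.partition.index_sets[j])
            for li, w in enumerate(ENCODER_WIDTHS):
                shapes[f"enc/{spec.name}/l{li}/W"] = (n_in, w)
                shapes[f"enc/{spec.name}/l{li}/b"] = (w,)
                n_in = w
            shapes[f"enc/{spec.name}/loc/W"] = (n_in, spec.space.d)
            shapes[f"enc/{spec.name}/loc/b"] = (spec.space.d,)
            shapes[f"enc/{spec.name}/sig/W"] = (n_in, spec.space.d)
            shapes[f"enc/{spec.name}/sig/b"] = (spec.space.d,)
        n_disp_levels = self.batches.n_dispersion_levels()
        for bi, (genes, owners) in enumerate(self.partition.blocks):
            owner = self.specs[self.block_owner[bi]]
            n_in = sum(self.specs[i].space.ambient_dim for i in self.block_inputs[bi])
            n_in += self.batches.width_for(owner.name)
            for li, w in enumerate(DECODER_WIDTHS):
                shapes[f"dec/block{bi}/l{li}/W"] = (n_in, w)
                shapes[f"dec/block{bi}/l{li}/b"] = (w,)
                n_in = w
            shapes[f"dec/block{bi}/out/W"] = (n_in, len(genes))
            shapes[f"dec/block{bi}/out/b"] = (len(genes),)
            shapes[f"disp/block{bi}"] = (n_disp_levels, len(genes))
        return shapes

    def signal_head_names(self) -> list[str]:
        """The posterior-parameter output layers of the signal component."""
        nm = self.specs[0].name
        return [f"enc/{nm}/loc/W", f"enc/{nm}/sig/W"]

    # -- forward -------------------------------------------------------
    def encode(self, x_counts) -> list[dict]:
        """Per-component posterior parameters from raw counts.

        Component ``j`` sees only its own gene block (all other genes
        masked), log1p-transformed.  Curved locations are lifted onto
        the manifold through the exponential map at the origin.
        """
        xv = np.asarray(ad.value(x_counts), dtype=np.float64)
        if np.any(~np.isfinite(xv)):
            raise ValueError("NaN/Inf in input counts")
        single = xv.ndim == 1
        if single:
            xv = xv[None]
        posts = []
        for j, spec in enumerate(self.specs):
            h = np.log1p(xv[:, self.partition.index_sets[j]])
            for li in range(len(ENCODER_WIDTHS)):
                h = ad.gelu(_linear(self.params, f"enc/{spec.name}/l{li}", h))
            loc = _linear(self.params, f"enc/{spec.name}/loc", h)
            sig_raw = _linear(self.params, f"enc/{spec.name}/sig", h)
            sigma = ad.add(ad.softplus(sig_raw), TOLERANCES.sigma_floor)
            mu = mf.tangent_lift(loc, spec.space)
            posts.append({"mu": mu, "sigma": sigma, "loc": loc, "spec": spec})
        return posts

    def posterior_params(self, post) -> dist.WrappedNormalParams:
        spec = post["spec"]
        return dist.WrappedNormalParams(
            mu=post["mu"], sigma=post["sigma"], rown=spec.distribution == "rown")

    def sample_latents(self, posts, rng: np.random.Generator):
        """Reparameterised samples and per-component KL terms.

        Curved components use a 1-sample Monte-Carlo KL against the
        wrapped standard normal at the origin; Euclidean components use
        the closed-form Gaussian KL.
        """
        zs, kls = [], []
        for post in posts:
            spec = post["spec"]
            n = ad.value(post["sigma"]).shape[0]
            eps = rng.standard_normal((n, spec.space.d))
            q = self.posterior_params(post)
            z = dist.sample_wrapped_normal(q, spec.space, eps=eps)
            if spec.space.curved:
                p = dist.standard_prior(spec.space)
                lq = dist.log_prob_wrapped_normal(z, q, spec.space)
                lp = dist.log_prob_wrapped_normal(z, p, spec.space)
                kl = ad.add(lq, ad.mul(lp, -1.0))
            else:
                kl = dist.gaussian_kl_closed_form(post["mu"], post["sigma"])
            zs.append(z)
            kls.append(kl)
        return zs, kls

    def decode(self, zs, batch_rows: pd.DataFrame | None, lib_size,
               stop_grad: set[int] | None = None):
        """Per-block NB means from the designated latents.

        ``lib_size`` is the cell's total UMI count; the softmax over a
        block makes each block's means sum to it.  ``stop_grad`` names
        block indices whose decoder must not backpropagate into other
        components' latents.
        """
        lib = ad.value(lib_size)
        lib = np.asarray(lib, dtype=np.float64).reshape(-1, 1)
        if np.any(lib < 0):
            raise ValueError("library sizes must be nonnegative")
        lib = np.maximum(lib, 1e-8)  # all-zero cells keep the loss finite
        n = lib.shape[0]
        if batch_rows is None:
            batch_rows = pd.DataFrame(index=pd.RangeIndex(n))
        means = []
        for bi, (genes, owners) in enumerate(self.partition.blocks):
            owner_spec = self.specs[self.block_owner[bi]]
            parts = []
            for ci in self.block_inputs[bi]:
                z = zs[ci]
                if stop_grad and bi in stop_grad and ci != self.block_owner[bi]:
                    z = ad.detach(z)
                parts.append(z)
            oh = self.batches.onehot(batch_rows, owner_spec.name)
            if oh.shape[1]:
                parts.append(oh)
            h = ad.concat(parts, axis=-1)
            for li in range(len(DECODER_WIDTHS)):
                h = ad.gelu(_linear(self.params, f"dec/block{bi}/l{li}", h))
            logits = _linear(self.params, f"dec/block{bi}/out", h)
            probs = ad.softmax(logits, axis=-1)
            means.append(ad.mul(probs, lib))
        return means

    def block_dispersion(self, bi: int, batch_rows: pd.DataFrame | None, n: int):
        """Per-cell, per-gene dispersion for one block (softplus + floor)."""
        raw = self.params[f"disp/block{bi}"]
        if batch_rows is None or not self.batches.names:
            idx = np.zeros(n, dtype=np.int64)
        else:
            idx = self.batches.dispersion_index(batch_rows)
        return ad.add(ad.softplus(ad.take(raw, (idx,))), 1e-4)

    # -- objective -----------------------------------------------------
    def elbo_loss(self, x_counts: np.ndarray, batch_rows: pd.DataFrame | None,
                  rng: np.random.Generator, epoch: int = 0):
        """Mean negative ELBO over a minibatch, with per-term statistics."""
        x = np.asarray(x_counts, dtype=np.float64)
        if x.ndim == 1:
            x = x[None]
        lib = x.sum(axis=1)
        posts = self.encode(x)
        zs, kls = self.sample_latents(posts, rng)
        stop = {bi for bi, (g, o) in enumerate(self.partition.blocks)
                if epoch < self.specs[self.block_owner[bi]].stop_grad_epochs}
        means = self.decode(zs, batch_rows, lib, stop_grad=stop)
        recon = None
        for bi, (genes, owners) in enumerate(self.partition.blocks):
            disp = self.block_dispersion(bi, batch_rows, x.shape[0])
            ll = nb_log_likelihood(x[:, genes], means[bi], disp)
            recon = ll if recon is None else ad.add(recon, ll)
        kl_total = kls[0]
        for kl in kls[1:]:
            kl_total = ad.add(kl_total, kl)
        loss = ad.mean(ad.add(kl_total, ad.mul(recon, -1.0)))
        stats = {"loss": float(ad.value(loss)),
                 "kl": float(np.mean(ad.value(kl_total))),
                 "recon": float(np.mean(ad.value(recon)))}
        return loss, stats

    # -- persistence ---------------------------------------------------
    def spec_dict(self) -> dict:
        return {
            "partition": {
                "n_genes": self.partition.n_genes,
                "components": [(n, s.tolist()) for n, s in
                               zip(self.partition.names, self.partition.index_sets)],
            },
            "specs": [{
                "name": s.name, "kind": s.space.kind, "K": s.space.K,
                "d": s.space.d, "distribution": s.distribution,
                "decode_inputs": list(s.decode_inputs),
                "stop_grad_epochs": s.stop_grad_epochs,
            } for s in self.specs],
            "batches": {
                "levels": self.batches.levels,
                "names": self.batches.names,
                "applicability": {k: list(v) for k, v in
                                  self.batches.applicability.items()},
            },
        }

    def save(self, path):
        """Single-archive checkpoint: config JSON + weight arrays."""
        cfg = json.dumps(self.spec_dict())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", cfg)
            for name, p in self.params.items():
                buf = io.BytesIO()
                np.save(buf, p.data)
                zf.writestr("weights/" + name.replace("/", "|") + ".npy",
                            buf.getvalue())

    @classmethod
    def load(cls, path) -> "DecomposedVAE":
        with zipfile.ZipFile(path) as zf:
            cfg = json.loads(zf.read("config.json"))
            model = cls._from_spec_dict(cfg)
            for name in model.layer_shapes():
                raw = zf.read("weights/" + name.replace("/", "|") + ".npy")
                arr = np.load(io.BytesIO(raw))
                model.params[name] = ad.Tensor(arr, requires_grad=True)
        return model

    @classmethod
    def _from_spec_dict(cls, cfg) -> "DecomposedVAE":
        part = GenePartition(
            [(n, np.asarray(s)) for n, s in cfg["partition"]["components"]],
            cfg["partition"]["n_genes"])
        specs = []
        for s in cfg["specs"]:
            specs.append(LatentSpec(
                name=s["name"],
                space=CurvatureSpace(s["kind"], s["K"], s["d"]),
                distribution=s["distribution"],
                decode_inputs=tuple(s["decode_inputs"]),
                stop_grad_epochs=s["stop_grad_epochs"]))
        bd = CellBatchDesign(None, None)
        bd._names = list(cfg["batches"]["names"])
        bd.levels = cfg["batches"]["levels"]
        bd.applicability = {k: tuple(v) for k, v in
                            cfg["batches"]["applicability"].items()}
        return cls(part, specs, bd)


def dense_counts(X) -> np.ndarray:
    """Cells x genes counts as a dense float array (accepts sparse/AnnData)."""
    try:
        import anndata
        if isinstance(X, anndata.AnnData):
            X = X.X
    except ImportError:      # pragma: no cover
        pass
    if sps.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=np.float64)
    if np.any(X < 0) or not np.allclose(X, np.round(X)):
        raise ValueError("counts must be nonnegative integers")
    return X
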