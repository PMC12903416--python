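"""Post-hoc procedures on a trained model.

Pseudotime (the Poincaré angle of a 2-D hyperbolic component),
alignment of circular pseudotimes against a reference, selective and
counterfactual decoding, portal/central classification of genes from
counterfactual expression, k-NN identity transfer with an unanimity
rule, and the paired decode-and-rank discovery of upregulated genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import KNeighborsClassifier

from . import autodiff as ad
from . import manifolds as mf
from .manifolds import CurvatureSpace
from .model import DecomposedVAE, dense_counts

DEFAULT_KNN_KS = (5, 11, 17, 23, 29, 35, 41, 47, 53, 59, 65, 71, 73)


# ---------------------------------------------------------------------------
# pseudotime
# ---------------------------------------------------------------------------

def pseudotime(z1: np.ndarray, space: CurvatureSpace,
               recenter_origin: np.ndarray | None = None) -> np.ndarray:
    """Angle in [0, 2pi) of each cell's Poincaré projection.

    ``z1`` holds Lorentz coordinates of a 2-D hyperbolic component; the
    angle is measured against the (0,0)->(1,0) edge of the disk.  An
    optional ``recenter_origin`` (disk coordinates) is applied by Möbius
    addition before measuring angles.
    """
    if space.kind != "hyperbolic" or space.d != 2:
        raise ValueError("pseudotime requires a 2-D hyperbolic component")
    p = mf.lorentz_to_poincare(np.asarray(z1, dtype=np.float64), space)
    if recenter_origin is not None:
        p = mf.recenter(p, np.asarray(recenter_origin, dtype=np.float64), space.K)
    at_origin = np.linalg.norm(p, axis=-1) < 1e-12
    if np.any(at_origin):
        warnings.warn("cells exactly at the origin get pseudotime 0")
    ang = np.arctan2(p[..., 1], p[..., 0])
    ang = np.where(at_origin, 0.0, ang)
    return np.mod(ang, 2 * np.pi)


def auto_recenter_origin(poincare_pts: np.ndarray, K: float,
                         coverage_bins: int = 36,
                         coverage_needed: float = 0.95) -> np.ndarray | None:
    """Decide whether a cloud of (cycling) cells needs recentering.

    If their angles already cover (nearly) the full circle around the
    current origin, returns None; otherwise returns the advisory origin
    diagonally across from the cells' bounding-box center, near the
    edge of the disk.
    """
    ang = np.mod(np.arctan2(poincare_pts[:, 1], poincare_pts[:, 0]), 2 * np.pi)
    occ = np.bincount((ang / (2 * np.pi) * coverage_bins).astype(int) % coverage_bins,
                      minlength=coverage_bins) > 0
    if occ.mean() >= coverage_needed:
        return None
    p_c = mf.estimate_cycling_center(poincare_pts)
    return mf.suggest_new_origin(p_c, K)


def align_pseudotime(est: np.ndarray, truth: np.ndarray, n_grid: int = 720):
    """Best rotation/flip of `est` against `truth` by Pearson correlation.

    Searches ``n_grid`` rotations x {flip, no flip}; returns
    ``(rotation, flip, pearson_r, sin_r)`` where ``sin_r`` is the
    correlation of the sines of the aligned angles (a wraparound-robust
    companion statistic).
    """
    est = np.asarray(est, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if est.shape != truth.shape or est.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(truth) == 0 or np.std(est) == 0:
        raise ValueError("constant pseudotime: correlation undefined")
    best = (-np.inf, 0.0, False)
    for flip in (False, True):
        base = np.mod(-est, 2 * np.pi) if flip else est
        for rot in np.linspace(0, 2 * np.pi, n_grid, endpoint=False):
            cand = np.mod(base + rot, 2 * np.pi)
            if np.std(cand) == 0:
                continue
            r = np.corrcoef(cand, truth)[0, 1]
            if r > best[0]:
                best = (r, rot, flip)
    r, rot, flip = best
    aligned = np.mod((np.mod(-est, 2 * np.pi) if flip else est) + rot, 2 * np.pi)
    sin_r = np.corrcoef(np.sin(aligned), np.sin(truth))[0, 1]
    return rot, flip, r, sin_r


def phase_correlation(expr: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Circular-linear correlation of each gene's profile with a phase.

    sqrt(R^2) of the least-squares fit of expression on (sin, cos) of
    the phase; in [0, 1], zero for phase-independent profiles.
    """
    expr = np.atleast_2d(np.asarray(expr, dtype=np.float64).T).T
    design = np.column_stack([np.ones_like(phase), np.sin(phase), np.cos(phase)])
    coef, *_ = np.linalg.lstsq(design, expr, rcond=None)
    fitted = design @ coef
    ssr = ((fitted - expr.mean(0)) ** 2).sum(0)
    sst = ((expr - expr.mean(0)) ** 2).sum(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, ssr / sst, 0.0)
    return np.sqrt(np.clip(r2, 0.0, 1.0))


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _posterior_latents(model: DecomposedVAE, X) -> list[np.ndarray]:
    X = dense_counts(X)
    posts = model.encode(X)
    return [np.asarray(ad.value(p["mu"])) for p in posts]


def _component_index(model: DecomposedVAE, name: str) -> int:
    try:
        return model.partition.names.index(name)
    except ValueError:
        raise KeyError(f"unknown component {name!r}") from None


def _origin_fill(spec, n: int) -> np.ndarray:
    return np.broadcast_to(spec.space.origin, (n, spec.space.ambient_dim)).copy()


def _fill_point(spec, point: np.ndarray, n: int) -> np.ndarray:
    """A user override in latent coordinates: spatial/tangent coordinates
    are lifted onto curved manifolds; ambient-length vectors pass through."""
    point = np.asarray(point, dtype=np.float64)
    if point.shape[-1] == spec.space.d and spec.space.curved:
        point = np.asarray(ad.value(mf.tangent_lift(point, spec.space)))
    return np.broadcast_to(point, (n, spec.space.ambient_dim)).copy()


def _decode_full(model: DecomposedVAE, zs: list[np.ndarray],
                 batch_rows: pd.DataFrame | None, lib: np.ndarray) -> np.ndarray:
    means = model.decode(zs, batch_rows, lib)
    out = np.zeros((lib.shape[0], model.partition.n_genes))
    for bi, (genes, owners) in enumerate(model.partition.blocks):
        out[:, genes] = np.asarray(ad.value(means[bi]))
    return out


def selective_decode(model: DecomposedVAE, X, keep: set[str] | list[str],
                     fill: dict[str, np.ndarray] | None = None,
                     batch_rows: pd.DataFrame | None = None) -> np.ndarray:
    """Reconstruct expression from a subset of components.

    Kept components contribute each cell's posterior location; dropped
    components are replaced by their origin (or a per-component ``fill``
    override in latent coordinates).  Returns the NB mean matrix.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep must be nonempty")
    for name in keep:
        _component_index(model, name)
    X = dense_counts(X)
    lib = X.sum(axis=1)
    zs = _posterior_latents(model, X)
    n = X.shape[0]
    for j, spec in enumerate(model.specs):
        if spec.name in keep:
            continue
        if fill and spec.name in fill:
            zs[j] = _fill_point(spec, fill[spec.name], n)
        else:
            zs[j] = _origin_fill(spec, n)
    return _decode_full(model, zs, batch_rows, lib)


def counterfactual_decode(model: DecomposedVAE, X, component: str,
                          coordinate_index: int, value: float,
                          batch_rows: pd.DataFrame | None = None) -> np.ndarray:
    """Overwrite one latent coordinate for every cell, then decode.

    The coordinate is indexed in intrinsic (tangent/spatial) terms; for
    curved components the edited tangent location is lifted back onto
    the manifold.
    """
    j = _component_index(model, component)
    spec = model.specs[j]
    if not 0 <= coordinate_index < spec.space.d:
        raise IndexError("coordinate index out of range")
    X = dense_counts(X)
    lib = X.sum(axis=1)
    posts = model.encode(X)
    zs = [np.asarray(ad.value(p["mu"])) for p in posts]
    loc = np.asarray(ad.value(posts[j]["loc"])).copy()
    loc[:, coordinate_index] = value
    zs[j] = np.asarray(ad.value(mf.tangent_lift(loc, spec.space)))
    return _decode_full(model, zs, batch_rows, lib)


# ---------------------------------------------------------------------------
# portal / central gene classification
# ---------------------------------------------------------------------------

@dataclass
class RatioClassification:
    """Per-gene central/(central+portal) expression ratio and label."""

    table: pd.DataFrame

    def __getitem__(self, col):
        return self.table[col].to_numpy()


def central_portal_classify(expr_central: np.ndarray, expr_portal: np.ndarray,
                            gene_names=None) -> RatioClassification:
    """ratio = central / (central + portal); label "central" iff
    ratio < 0.2, "portal" iff ratio > 0.8, else "unclassified"."""
    c = np.asarray(expr_central, dtype=np.float64)
    p = np.asarray(expr_portal, dtype=np.float64)
    if np.any(c < 0) or np.any(p < 0):
        raise ValueError("expression means must be nonnegative")
    tot = c + p
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(tot > 0, c / np.where(tot > 0, tot, 1.0), 0.5)
    label = np.full(c.shape, "unclassified", dtype=object)
    label[ratio < 0.2] = "central"
    label[ratio > 0.8] = "portal"
    if gene_names is None:
        gene_names = np.arange(c.size)
    return RatioClassification(pd.DataFrame(
        {"gene": gene_names, "ratio": ratio, "label": label}))


# ---------------------------------------------------------------------------
# k-NN identity
# ---------------------------------------------------------------------------

def knn_identity(ref_embeddings: np.ndarray, ref_labels, query_embeddings: np.ndarray,
                 k_list=DEFAULT_KNN_KS) -> np.ndarray:
    """Label transfer with an unanimity rule over several k.

    One k-NN vote (Euclidean metric) per k; a query keeps a label only
    if every classifier agrees, otherwise it is "uncertain".
    """
    ref = np.asarray(ref_embeddings, dtype=np.float64)
    qry = np.asarray(query_embeddings, dtype=np.float64)
    labels = np.asarray(ref_labels)
    if ref.shape[0] == 0:
        raise ValueError("empty reference")
    if max(k_list) > ref.shape[0]:
        raise ValueError("k exceeds the reference size")
    votes = []
    for k in k_list:
        clf = KNeighborsClassifier(n_neighbors=int(k)).fit(ref, labels)
        votes.append(clf.predict(qry))
    votes = np.stack(votes)
    out = votes[0].astype(object)
    disagree = (votes != votes[0]).any(axis=0)
    out[disagree] = "uncertain"
    return out


def knn_accuracy(embeddings: np.ndarray, labels, k: int = 15,
                 rng: np.random.Generator | None = None) -> float:
    """Leave-one-out k-NN accuracy of a labelling in an embedding."""
    emb = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    codes, _ = pd.factorize(labels)
    clf = KNeighborsClassifier(n_neighbors=k + 1).fit(emb, codes)
    # drop the self-neighbour
    _, idx = clf.kneighbors(emb)
    neigh = codes[idx[:, 1:]]
    pred = np.array([np.bincount(row).argmax() for row in neigh])
    return float((pred == codes).mean())


# ---------------------------------------------------------------------------
# upregulated-gene discovery
# ---------------------------------------------------------------------------

def discover_upregulated(model: DecomposedVAE, X, component: str,
                         group_labels, group_a, group_b,
                         n_cells_per_group: int = 100, n_pcs: int = 4,
                         pc_axes: tuple[int, ...] | None = None,
                         top_n: int = 50, exclude=None,
                         fill: dict[str, np.ndarray] | None = None,
                         batch_rows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Paired decode-and-rank discovery of group-A-upregulated genes.

    PCA is run on the named component's posterior locations; per group,
    the ``n_cells_per_group`` most extreme cells along the
    group-separating direction (restricted to ``pc_axes``) are taken,
    their latents are reconstructed from ``n_pcs`` components with the
    non-designated axes zeroed, the other components are filled (origin
    by default), both groups are decoded, cells are paired by rank, and
    each pair's ``top_n`` genes by positive (A - B) difference are
    tallied.  Returns a gene -> frequency table (descending).
    """
    j = _component_index(model, component)
    labels = np.asarray(group_labels)
    X = dense_counts(X)
    ia = np.flatnonzero(labels == group_a)
    ib = np.flatnonzero(labels == group_b)
    if min(ia.size, ib.size) < n_cells_per_group:
        raise ValueError("group smaller than n_cells_per_group")
    zs_all = _posterior_latents(model, X)
    z = zs_all[j]
    spec = model.specs[j]
    pca = PCA(n_components=min(n_pcs, z.shape[1]))
    scores = pca.fit_transform(z)  # centered, unscaled
    if pc_axes is None:
        pc_axes = tuple(range(scores.shape[1]))
    designated = np.zeros(scores.shape[1], dtype=bool)
    designated[list(pc_axes)] = True
    # group-separating direction restricted to the designated axes
    sep = scores[ia].mean(0) - scores[ib].mean(0)
    sep = np.where(designated, sep, 0.0)
    nrm = np.linalg.norm(sep)
    degenerate = nrm < 1e-12
    if degenerate:
        warnings.warn("groups are not separated in the designated axes; "
                      "ranking is degenerate")
        sep = np.where(designated, 1.0, 0.0)
        nrm = np.linalg.norm(sep)
    sep = sep / nrm
    proj = scores @ sep
    sel_a = ia[np.argsort(proj[ia])[::-1][:n_cells_per_group]]
    sel_b = ib[np.argsort(proj[ib])[:n_cells_per_group]]
    # pair by rank along the separating direction
    sel_a = sel_a[np.argsort(proj[sel_a])]
    sel_b = sel_b[np.argsort(proj[sel_b])]

    def _reconstruct(idx):
        s = np.where(designated, scores[idx], 0.0)
        rec = pca.inverse_transform(s)
        if spec.space.curved:
            rec = np.asarray(ad.value(mf.project_to_manifold(rec, spec.space)))
        return rec

    sel = np.concatenate([sel_a, sel_b])
    lib = np.full(sel.size, X.sum(axis=1)[sel].mean())  # common depth for the pairings
    zs = []
    n = sel.size
    for i, sp in enumerate(model.specs):
        if i == j:
            zs.append(_reconstruct(sel))
        elif fill and sp.name in fill:
            zs.append(_fill_point(sp, fill[sp.name], n))
        else:
            zs.append(_origin_fill(sp, n))
    rows = batch_rows.iloc[sel].reset_index(drop=True) if batch_rows is not None else None
    decoded = _decode_full(model, zs, rows, lib)
    dec_a, dec_b = decoded[:n_cells_per_group], decoded[n_cells_per_group:]
    gene_idx = np.arange(model.partition.n_genes)
    mask = np.ones(gene_idx.size, dtype=bool)
    if exclude is not None:
        mask[np.asarray(list(exclude), dtype=np.int64)] = False
    counts = np.zeros(gene_idx.size, dtype=np.int64)
    for pa, pb in zip(dec_a, dec_b):
        diff = np.where(mask, pa - pb, -np.inf)
        top = np.argsort(diff)[::-1][:top_n]
        counts[top] += 1
    order = np.argsort(counts)[::-1]
    return pd.DataFrame({"gene": gene_idx[order], "frequency": counts[order],
                         "degenerate": degenerate})
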