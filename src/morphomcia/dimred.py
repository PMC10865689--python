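"""Low-dimensional projection: PCA and t-SNE per organ, MCIA jointly.

Multiple co-inertia analysis (MCIA) finds, per axis, block loading
vectors u_s (one per feature matrix X_s, ||u_s|| = 1) and a shared
synthetic axis h (h'Wh = 1, W = diag(w_i) sample weights) maximizing

    sum_s  Cov_W^2( X_s' u_s , h ),

i.e. the sum over blocks of squared covariances between each block's
sample projection and the common axis.  With X features x samples this
is solved by the top eigenvector of K = sum_s W^{1/2} X_s' X_s W^{1/2};
subsequent axes are obtained after deflating every block by its
component along h under the W inner product, which makes the h axes
mutually W-orthogonal.

The per-block squared covariance ("pseudo-eigenvalue") measures how much
a given organ contributes to an axis; all block sample scores live in
the same 2-D space, with a per-individual "synthetic center" tying the
organs of one individual together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .shape_features import FeatureMatrix

__all__ = [
    "MCIAConfig",
    "MCIAResult",
    "Embedding2D",
    "inertia",
    "coinertia",
    "mcia_fit",
    "summed_center_distances",
    "pca_embed",
    "tsne_embed",
]


@dataclass
class MCIAConfig:
    n_axes: int = 2
    block_scaling: str = "unit_inertia"  # or "none"
    weights: np.ndarray | None = None    # w_i; default uniform 1/n

    def __post_init__(self) -> None:
        if self.block_scaling not in ("unit_inertia", "none"):
            raise ValueError("block_scaling must be 'unit_inertia' or 'none'")


@dataclass
class MCIAResult:
    block_names: list[str]
    block_scores: list[np.ndarray]        # per block: n x n_axes
    synthetic_axes: np.ndarray            # h: n x n_axes, unit W-norm columns
    centers: np.ndarray                   # n x n_axes
    loadings: list[np.ndarray]            # per block: d_s x n_axes, unit norm
    pseudo_eigenvalues: np.ndarray        # S x n_axes
    eigenvalues: np.ndarray               # n_axes (axis objectives)
    variance_explained: np.ndarray        # n_axes
    weights: np.ndarray                   # w_i
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return self.synthetic_axes.shape[1]


@dataclass
class Embedding2D:
    coords: np.ndarray          # n x 2
    method: str                 # pca | tsne | mcia-block
    organ: str = ""
    variance_explained: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)


def _as_matrix(X) -> np.ndarray:
    return X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def inertia(X, w: np.ndarray | None = None, Q: np.ndarray | None = None) -> float:
    """Total weighted variability sum_i w_i ||x_i||_Q^2 of a centered cloud.

    X is features x samples with zero row means; with w_i = 1/n, Q = I
    and standardized rows this equals the feature count exactly.
    """
    X = _as_matrix(X)
    d, n = X.shape
    w = np.full(n, 1.0 / n) if w is None else np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError("weight vector length must equal the sample count")
    if Q is None:
        return float(np.sum(w * np.einsum("ij,ij->j", X, X)))
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (d, d):
        raise ValueError("Q must be d x d")
    return float(np.sum(w * np.einsum("ij,ik,kj->j", X, Q, X)))


def coinertia(
    X, Y, w: np.ndarray | None = None,
    Q: np.ndarray | None = None, R: np.ndarray | None = None,
) -> float:
    """Co-inertia: squared W-cross-covariance mass between two clouds.

    With identity metrics this is || X W Y' ||_F^2, the sum over all
    feature pairs of squared weighted covariances; symmetric and >= 0.
    """
    X = _as_matrix(X)
    Y = _as_matrix(Y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share the sample count")
    n = X.shape[1]
    w = np.full(n, 1.0 / n) if w is None else np.asarray(w, dtype=float)
    M = (X * w) @ Y.T
    if Q is None and R is None:
        return float(np.sum(M * M))
    Qm = np.eye(X.shape[0]) if Q is None else np.asarray(Q, dtype=float)
    Rm = np.eye(Y.shape[0]) if R is None else np.asarray(R, dtype=float)
    return float(np.trace(Qm @ M @ Rm @ M.T))


def _prepare_blocks(blocks: list[FeatureMatrix], config: MCIAConfig):
    if len(blocks) < 2:
        raise ValueError("MCIA needs at least 2 blocks; use pca_embed for one")
    n = blocks[0].n
    ids = list(blocks[0].sample_ids)
    mats = []
    names = []
    for b in blocks:
        if not b.standardized:
            raise ValueError(f"block '{b.organ}' is not standardized")
        if b.n != n:
            raise ValueError("all blocks must share the same individuals")
        Xs = b.X.copy()
        if config.block_scaling == "unit_inertia":
            w = config.weights if config.weights is not None else None
            Xs = Xs / np.sqrt(inertia(Xs, w))
        mats.append(Xs)
        names.append(b.organ or f"block_{len(names)}")
    return mats, names, n, ids


def mcia_fit(blocks: list[FeatureMatrix], config: MCIAConfig | None = None) -> MCIAResult:
    """Fit MCIA axes by successive eigen-decompositions with deflation."""
    config = config or MCIAConfig()
    mats, names, n, ids = _prepare_blocks(blocks, config)
    S = len(mats)
    w = (np.full(n, 1.0 / n) if config.weights is None
         else np.asarray(config.weights, dtype=float))
    if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be positive and sum to 1")
    sw = np.sqrt(w)

    K0 = np.zeros((n, n))
    for Xs in mats:
        B = Xs * sw  # X W^{1/2}
        K0 += B.T @ B
    total_inertia = float(np.trace(K0))

    work = [Xs.copy() for Xs in mats]
    n_axes = config.n_axes
    hs, eigs, us_all, pe_all = [], [], [], []
    for axis in range(n_axes):
        K = np.zeros((n, n))
        for Xs in work:
            B = Xs * sw
            K += B.T @ B
        evals, evecs = np.linalg.eigh(K)
        lam = float(evals[-1])
        if lam <= 1e-12 * max(1.0, total_inertia):
            warnings.warn(
                f"rank deficiency: only {axis} informative axes", stacklevel=2
            )
            n_axes = axis
            break
        z = evecs[:, -1]
        h = z / sw                      # h'Wh = z'z = 1
        u_axis, pe_axis = [], []
        for Xs in work:
            g = Xs @ (w * h)            # X_s W h
            norm = np.linalg.norm(g)
            u = g / norm if norm > 0 else g
            u_axis.append(u)
            pe_axis.append(norm**2)     # Cov_W^2(X_s'u_s, h)
        # deterministic sign: largest |loading| entry positive
        cat = np.concatenate(u_axis)
        if cat[np.argmax(np.abs(cat))] < 0:
            h = -h
            u_axis = [-u for u in u_axis]
        hs.append(h)
        eigs.append(lam)
        us_all.append(u_axis)
        pe_all.append(pe_axis)
        # deflate: remove each block's component along h under W
        for k, Xs in enumerate(work):
            work[k] = Xs - np.outer(Xs @ (w * h), h)

    if n_axes == 0:
        raise ValueError("no informative axes (all blocks are zero)")
    H = np.column_stack(hs)
    eigenvalues = np.array(eigs)
    pseudo = np.array(pe_all).T          # S x n_axes
    loadings = [
        np.column_stack([us_all[a][s] for a in range(n_axes)]) for s in range(S)
    ]
    # block sample scores per axis, computed on the deflated blocks of
    # that axis so that consecutive axes carry non-redundant structure;
    # each block/axis score is rescaled to unit W-variance so all organs
    # are comparable in the common space (line lengths to the synthetic
    # center then reflect between-organ correlation, not block amplitude)
    def _unit_wvar(v: np.ndarray) -> np.ndarray:
        mu = np.sum(w * v)
        var = np.sum(w * (v - mu) ** 2)
        return v / np.sqrt(var) if var > 0 else v

    scores = [np.zeros((n, n_axes)) for _ in range(S)]
    work = [Xs.copy() for Xs in mats]
    for a in range(n_axes):
        for s, Xs in enumerate(work):
            scores[s][:, a] = _unit_wvar(Xs.T @ us_all[a][s])
        for k, Xs in enumerate(work):
            work[k] = Xs - np.outer(Xs @ (w * H[:, a]), H[:, a])

    centers = np.mean([sc for sc in scores], axis=0)
    centers = np.column_stack([_unit_wvar(centers[:, a]) for a in range(n_axes)])

    return MCIAResult(
        block_names=names,
        block_scores=scores,
        synthetic_axes=H,
        centers=centers,
        loadings=loadings,
        pseudo_eigenvalues=pseudo,
        eigenvalues=eigenvalues,
        variance_explained=eigenvalues / total_inertia,
        weights=w,
        sample_ids=ids,
    )


def mcia_objective(mats: list[np.ndarray], us: list[np.ndarray], h: np.ndarray,
                   w: np.ndarray) -> float:
    """Axis objective sum_s Cov_W^2(X_s'u_s, h) for given directions."""
    return float(sum((u @ (Xs @ (w * h))) ** 2 for Xs, u in zip(mats, us)))


def summed_center_distances(res: MCIAResult) -> np.ndarray:
    """Per individual: sum over organs of the 2-D distance from that
    organ's score to the individual's synthetic center."""
    if res.n_axes < 2:
        raise ValueError("needs at least 2 fitted axes")
    c = res.centers[:, :2]
    d = np.zeros(len(c))
    for sc in res.block_scores:
        d += np.linalg.norm(sc[:, :2] - c, axis=1)
    return d


def pca_embed(fm: FeatureMatrix, n_axes: int = 2) -> Embedding2D:
    """Principal-component scores of the individuals (columns of X)."""
    X = fm.X
    n = X.shape[1]
    if n < 3:
        raise ValueError("PCA embedding needs at least 3 individuals")
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_axes = min(n_axes, len(s))
    coords = (Vt[:n_axes].T * s[:n_axes])
    for k in range(n_axes):
        if U[np.argmax(np.abs(U[:, k])), k] < 0:
            coords[:, k] = -coords[:, k]
    var = s**2
    return Embedding2D(
        coords=coords,
        method="pca",
        organ=fm.organ,
        variance_explained=var[:n_axes] / var.sum(),
        sample_ids=list(fm.sample_ids),
    )


def tsne_embed(
    fm: FeatureMatrix,
    perplexity: float | None = None,
    seed: int = 0,
    iters: int = 1000,
) -> Embedding2D:
    """t-SNE embedding of the individuals; deterministic for a given seed."""
    from sklearn.manifold import TSNE

    X = fm.X.T  # samples x features
    n = X.shape[0]
    max_perp = (n - 1) / 3
    if perplexity is None:
        perplexity = min(30.0, np.floor(max_perp - 1e-9))
    if perplexity >= max_perp or perplexity < 1:
        raise ValueError(
            f"perplexity {perplexity} infeasible for n={n}; "
            f"must be in [1, {max_perp:.2f})"
        )
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        max_iter=iters,
        init="pca",
        method="exact",
        early_exaggeration=12.0,
    )
    coords = ts.fit_transform(X)
    return Embedding2D(
        coords=np.asarray(coords, dtype=float),
        method="tsne",
        organ=fm.organ,
        sample_ids=list(fm.sample_ids),
    )
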