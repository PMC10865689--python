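"""Point-set registration: template selection, two-step coherent point
drift (affine, then non-rigid) and Hungarian vertex correspondence.

CPD treats the source point set as centroids of an isotropic Gaussian
mixture fitted to the target by EM; the affine step removes pose and
gross size differences, the non-rigid step deforms the source along a
smooth (Gaussian-kernel) displacement field.  Correspondence between the
moved source and the template is then the minimum-cost bijection under
Euclidean distance, solved exactly with the Hungarian algorithm.

The EM solver is deterministic (initialized from the identity) and
works on point sets pre-scaled internally to unit RMS radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "select_template",
    "cpd_affine",
    "cpd_nonrigid",
    "hungarian_correspondence",
    "register_organ_set",
    "AffineCPDResult",
    "NonRigidCPDResult",
    "RegisteredOrganSet",
]


@dataclass
class AffineCPDResult:
    B: np.ndarray            # 3x3 (or DxD) affine matrix
    t: np.ndarray            # translation
    moved: np.ndarray        # transformed source points
    n_iter: int
    converged: bool
    nll_history: list[float] = field(default_factory=list)


@dataclass
class NonRigidCPDResult:
    moved: np.ndarray
    displacement: np.ndarray  # moved - source
    n_iter: int
    converged: bool
    nll_history: list[float] = field(default_factory=list)


@dataclass
class RegisteredOrganSet:
    """Meshes of one organ family, vertex k aligned to template vertex k."""

    template_index: int
    meshes: list[trimesh.Trimesh]
    transform_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = {len(m.vertices) for m in self.meshes}
        if len(counts) > 1:
            raise ValueError(f"meshes have differing vertex counts: {sorted(counts)}")

    @property
    def n_vertices(self) -> int:
        return len(self.meshes[0].vertices)


def select_template(meshes: list[trimesh.Trimesh]) -> int:
    """Index of the mesh whose volume is closest to the median volume.

    Ties are broken by the lowest index.  Volumes come from the
    divergence theorem (signed mesh volume, absolute value).
    """
    if len(meshes) == 0:
        raise ValueError("no meshes given")
    vols = np.array([abs(m.volume) for m in meshes])
    dist = np.abs(vols - np.median(vols))
    # tolerance-based tie so float noise cannot override the
    # lowest-index rule for geometrically tied volumes
    tol = 1e-9 * max(1.0, vols.max())
    return int(np.flatnonzero(dist <= dist.min() + tol)[0])


def _normalize(X: np.ndarray, Y: np.ndarray):
    """Center each set at its centroid; scale both by the target RMS radius."""
    mu_x = X.mean(axis=0)
    mu_y = Y.mean(axis=0)
    Xc = X - mu_x
    Yc = Y - mu_y
    s = np.sqrt((Xc**2).sum() / len(Xc))
    if s <= 0:
        raise ValueError("degenerate target point set")
    return Xc / s, Yc / s, mu_x, mu_y, s


def _estep(X: np.ndarray, TY: np.ndarray, sigma2: float, w: float):
    """CPD posteriors P (M x N) plus the mixture negative log-likelihood."""
    M, D = TY.shape
    N = X.shape[0]
    d2 = cdist(TY, X, "sqeuclidean")
    g = np.exp(-d2 / (2 * sigma2))
    norm = (2 * np.pi * sigma2) ** (D / 2)
    c = norm * (w / (1 - w)) * (M / N) if w > 0 else 0.0
    den = g.sum(axis=0) + c
    den = np.where(den <= np.finfo(float).tiny, np.finfo(float).tiny, den)
    P = g / den
    # mixture NLL of the data (uniform outlier component folded into den)
    nll = -np.sum(np.log((1 - w) * den / (M * norm) + np.finfo(float).tiny))
    return P, nll


def cpd_affine(
    source: np.ndarray,
    target: np.ndarray,
    max_iters: int = 100,
    tol: float = 1e-5,
    w: float = 0.0,
) -> AffineCPDResult:
    """Affine coherent point drift: fit ``B, t`` moving source onto target."""
    X = np.asarray(target, dtype=float)
    Y = np.asarray(source, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("point sets must be (n, D) with matching D")
    Xn, Yn, mu_x, mu_y, s = _normalize(X, Y)
    M, D = Yn.shape
    N = Xn.shape[0]
    B = np.eye(D)
    t = np.zeros(D)
    sigma2 = ((cdist(Yn, Xn, "sqeuclidean")).sum()) / (D * M * N)
    nll_hist: list[float] = []
    converged = False
    prev = np.inf
    it = 0
    for it in range(1, max_iters + 1):
        TY = Yn @ B.T + t
        P, nll = _estep(Xn, TY, sigma2, w)
        nll_hist.append(nll)
        Np = P.sum()
        mu_xh = (P.sum(axis=0) @ Xn) / Np
        mu_yh = (P.sum(axis=1) @ Yn) / Np
        Xh = Xn - mu_xh
        Yh = Yn - mu_yh
        A = Xh.T @ P.T @ Yh
        G = (Yh * P.sum(axis=1)[:, None]).T @ Yh
        try:
            B = A @ np.linalg.inv(G)
        except np.linalg.LinAlgError:
            B = A @ np.linalg.pinv(G)
        t = mu_xh - B @ mu_yh
        TY = Yn @ B.T + t
        trXPX = np.sum(P.sum(axis=0) * (Xn**2).sum(axis=1)) - Np * (mu_xh @ mu_xh)
        sigma2 = max(
            (trXPX - np.trace(A @ B.T)) / (Np * D), np.finfo(float).eps * 100
        )
        if abs(prev - nll) < tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = nll
    if not converged:
        warnings.warn("cpd_affine did not converge; returning best iterate", stacklevel=2)
    # undo normalization: x ~ s*(B yn) + s*t + mu_x with yn=(y-mu_y)/s
    t_full = s * t + mu_x - B @ mu_y
    moved = np.asarray(source, dtype=float) @ B.T + t_full
    return AffineCPDResult(B=B, t=t_full, moved=moved, n_iter=it, converged=converged, nll_history=nll_hist)


def cpd_nonrigid(
    source: np.ndarray,
    target: np.ndarray,
    beta: float = 2.0,
    lam: float = 2.0,
    max_iters: int = 100,
    tol: float = 1e-5,
    w: float = 0.0,
) -> NonRigidCPDResult:
    """Non-rigid CPD: smooth displacement field as a Gaussian-kernel
    expansion over the source points (kernel width ``beta``,
    regularization weight ``lam``)."""
    X = np.asarray(target, dtype=float)
    Y = np.asarray(source, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("point sets must be (n, D) with matching D")
    Xn, Yn, mu_x, mu_y, s = _normalize(X, Y)
    M, D = Yn.shape
    N = Xn.shape[0]
    G = np.exp(-cdist(Yn, Yn, "sqeuclidean") / (2 * beta**2))
    Wm = np.zeros((M, D))
    sigma2 = (cdist(Yn, Xn, "sqeuclidean")).sum() / (D * M * N)
    nll_hist: list[float] = []
    converged = False
    prev = np.inf
    it = 0
    for it in range(1, max_iters + 1):
        TY = Yn + G @ Wm
        P, nll = _estep(Xn, TY, sigma2, w)
        nll_hist.append(nll)
        P1 = P.sum(axis=1)
        Np = P1.sum()
        A = G * P1[:, None] + lam * sigma2 * np.eye(M)
        rhs = P @ Xn - P1[:, None] * Yn
        Wm = np.linalg.solve(A, rhs)
        TY = Yn + G @ Wm
        trXPX = np.sum(P.sum(axis=0) * (Xn**2).sum(axis=1))
        trTPT = np.sum(P1 * (TY**2).sum(axis=1))
        trXPT = np.einsum("mn,md,nd->", P, TY, Xn)
        sigma2 = max((trXPX - 2 * trXPT + trTPT) / (Np * D), np.finfo(float).eps * 100)
        if abs(prev - nll) < tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = nll
    if not converged:
        warnings.warn("cpd_nonrigid did not converge; returning best iterate", stacklevel=2)
    moved = s * (Yn + G @ Wm) + mu_x
    src = np.asarray(source, dtype=float)
    return NonRigidCPDResult(
        moved=moved,
        displacement=moved - src,
        n_iter=it,
        converged=converged,
        nll_history=nll_hist,
    )


def hungarian_correspondence(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimum-cost bijection A-index -> B-index under Euclidean distance.

    Returns ``(assignment, total_cost)`` where ``assignment[i]`` is the
    B-index matched to A-vertex i; the assignment is globally optimal
    (Hungarian / Jonker-Volgenant), not greedy.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if len(A) != len(B):
        raise ValueError(
            f"point counts differ ({len(A)} vs {len(B)}); re-decimate the "
            "meshes to the template's vertex count before correspondence"
        )
    C = cdist(A, B)
    rows, cols = linear_sum_assignment(C)
    assignment = np.empty(len(A), dtype=np.int64)
    assignment[rows] = cols
    return assignment, float(C[rows, cols].sum())


def register_organ_set(
    meshes: list[trimesh.Trimesh],
    template_index: int | None = None,
    beta: float = 2.0,
    lam: float = 2.0,
    max_iters: int = 100,
    tol: float = 1e-5,
) -> RegisteredOrganSet:
    """Register every mesh of one organ family to a template.

    Pipeline per mesh: affine CPD -> non-rigid CPD -> Hungarian
    correspondence between the moved vertices and the template vertices.
    Output meshes carry the moved geometry with vertices re-indexed so
    vertex k corresponds to template vertex k across the whole set.
    """
    if len(meshes) == 0:
        raise ValueError("no meshes given")
    if template_index is None:
        template_index = select_template(meshes)
    template = meshes[template_index]
    T = np.asarray(template.vertices, dtype=float)
    out_meshes: list[trimesh.Trimesh] = []
    log: list[dict] = []
    for idx, mesh in enumerate(meshes):
        if len(mesh.vertices) != len(T):
            raise ValueError(
                f"mesh {idx} has {len(mesh.vertices)} vertices, template has "
                f"{len(T)}; decimate to identical counts first"
            )
        if idx == template_index:
            out_meshes.append(template.copy())
            log.append({"affine_B": np.eye(3), "affine_t": np.zeros(3),
                        "nonrigid_rms": 0.0, "assignment_cost": 0.0,
                        "converged": True})
            continue
        aff = cpd_affine(mesh.vertices, T, max_iters=max_iters, tol=tol)
        nr = cpd_nonrigid(aff.moved, T, beta=beta, lam=lam, max_iters=max_iters, tol=tol)
        assignment, cost = hungarian_correspondence(T, nr.moved)
        # vertex k of the new mesh = moved vertex matched to template vertex k
        new_vertices = nr.moved[assignment]
        inv = np.empty(len(T), dtype=np.int64)
        inv[assignment] = np.arange(len(T))
        new_faces = inv[np.asarray(mesh.faces)]
        out = trimesh.Trimesh(vertices=new_vertices, faces=new_faces, process=False)
        out_meshes.append(out)
        log.append({
            "affine_B": aff.B, "affine_t": aff.t,
            "nonrigid_rms": float(np.sqrt((nr.displacement**2).sum(axis=1).mean())),
            "assignment_cost": cost,
            "converged": bool(aff.converged and nr.converged),
        })
    return RegisteredOrganSet(template_index=template_index, meshes=out_meshes, transform_log=log)
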