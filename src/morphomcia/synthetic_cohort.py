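"""Seeded synthetic cohorts of star-shaped "organ" surfaces.

Emulates the study design of a multi-organ CT cohort without any image
download: each individual carries a small vector of latent shape factors
shared across organs; each organ is a smooth star-shaped closed surface

    r(u) = R_ellipsoid(u) * (1 + sum_k a_k B_k(u)),    u on the unit sphere,

where the B_k are low-order (degree 2-3) spherical-harmonic-type basis
functions and the coefficients a_k mix the individual's latent factors
through an organ loading plus independent noise.  Planted outliers
(single organ or whole individual) get their deformation amplitude
multiplied by kappa.

All organs and individuals share one Fibonacci-lattice sphere
triangulation, so the generated meshes are in exact vertex
correspondence by construction — useful both for exercising the
registration stage against a known truth and for running the feature /
MCIA stages directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import ConvexHull

__all__ = [
    "OrganSpec",
    "CohortSpec",
    "GroundTruth",
    "fibonacci_sphere_mesh",
    "generate_cohort",
]


@dataclass
class OrganSpec:
    name: str
    radii: tuple[float, float, float] = (1.0, 1.0, 1.0)  # ellipsoid semi-axes, mm
    deform_sigma: float = 0.3     # idiosyncratic coefficient noise (factor units)
    loading: float = 1.0          # how strongly latent factors shape this organ

    def __post_init__(self) -> None:
        if self.deform_sigma < 0:
            raise ValueError("deform_sigma must be >= 0")
        if min(self.radii) <= 0:
            raise ValueError("radii must be positive")


@dataclass
class CohortSpec:
    n_individuals: int = 30
    organ_specs: list[OrganSpec] = field(default_factory=lambda: [
        OrganSpec("liverish", (1.4, 1.0, 0.7)),
        OrganSpec("kidneyish", (0.6, 0.35, 0.3)),
        OrganSpec("spleenish", (0.7, 0.5, 0.4)),
    ])
    latent_dim: int = 2
    amplitude: float = 0.02       # base radial modulation per unit coefficient
    outliers: list[tuple[int, str, float]] = field(default_factory=list)
    n_vertices: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for ind, organ, kappa in self.outliers:
            if kappa < 0:
                raise ValueError("outlier amplitude multiplier must be >= 0")
            if not 0 <= ind < self.n_individuals:
                raise ValueError(f"outlier individual {ind} out of range")
            names = {o.name for o in self.organ_specs} | {"ALL"}
            if organ not in names:
                raise ValueError(f"unknown outlier organ {organ!r}")


@dataclass
class GroundTruth:
    latent: np.ndarray              # n x latent_dim
    outlier_flags: pd.DataFrame     # individuals x organs, bool
    spec: CohortSpec


def fibonacci_sphere_mesh(n_vertices: int = 1000) -> trimesh.Trimesh:
    """Watertight unit-sphere triangulation with exactly ``n_vertices``
    vertices (Fibonacci lattice + convex hull), deterministic."""
    i = np.arange(n_vertices)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_vertices
    r = np.sqrt(1.0 - z * z)
    pts = np.column_stack([r * np.cos(golden * i), r * np.sin(golden * i), z])
    hull = ConvexHull(pts)
    mesh = trimesh.Trimesh(vertices=pts, faces=hull.simplices, process=False)
    mesh.fix_normals()
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# fixed low-order basis: real spherical-harmonic-type polynomials in the
# unit direction (x, y, z); degree 2 and 3 terms, each scaled to max 1
def _basis(directions: np.ndarray) -> np.ndarray:
    x, y, z = directions.T
    B = np.column_stack([
        x * y,
        y * z,
        x * z,
        x**2 - y**2,
        3 * z**2 - 1,
        z * (5 * z**2 - 3),
    ])
    return B / np.abs(B).max(axis=0)


# fixed latent-to-coefficient mixing pattern (K x latent_dim columns used)
_PATTERN = np.array([
    [1.0, 0.0],
    [0.8, 0.5],
    [0.6, -0.7],
    [0.4, 0.6],
    [0.3, -0.4],
    [0.2, 0.3],
])


def generate_cohort(spec: CohortSpec) -> tuple[dict[str, list[trimesh.Trimesh]], GroundTruth]:
    """Generate the cohort meshes and their ground truth, bit-reproducibly.

    Returns ``(meshes, truth)`` with ``meshes[organ][i]`` the surface of
    individual ``i``; all meshes share one sphere triangulation and are
    therefore in exact vertex correspondence.
    """
    rng = np.random.default_rng(spec.seed)
    base = fibonacci_sphere_mesh(spec.n_vertices)
    dirs = np.asarray(base.vertices)
    B = _basis(dirs)
    K = B.shape[1]
    if spec.latent_dim > _PATTERN.shape[1]:
        raise ValueError(f"latent_dim must be <= {_PATTERN.shape[1]}")
    P = _PATTERN[:, : spec.latent_dim]

    latent = rng.standard_normal((spec.n_individuals, spec.latent_dim))
    organ_names = [o.name for o in spec.organ_specs]
    flags = pd.DataFrame(
        False, index=range(spec.n_individuals), columns=organ_names
    )
    kappas = np.ones((spec.n_individuals, len(organ_names)))
    for ind, organ, kappa in spec.outliers:
        cols = organ_names if organ == "ALL" else [organ]
        for c in cols:
            j = organ_names.index(c)
            kappas[ind, j] = kappa
            flags.loc[ind, c] = True

    meshes: dict[str, list[trimesh.Trimesh]] = {}
    for j, organ in enumerate(spec.organ_specs):
        u = dirs
        ell = 1.0 / np.sqrt(
            (u[:, 0] / organ.radii[0]) ** 2
            + (u[:, 1] / organ.radii[1]) ** 2
            + (u[:, 2] / organ.radii[2]) ** 2
        )
        noise = rng.standard_normal((spec.n_individuals, K))
        organ_meshes = []
        for i in range(spec.n_individuals):
            a = spec.amplitude * (
                organ.loading * (P @ latent[i]) + organ.deform_sigma * noise[i]
            )
            a = a * kappas[i, j]
            factor = 1.0 + B @ a
            if factor.min() <= 0.05:
                raise ValueError(
                    f"deformation too large: radius factor "
                    f"{factor.min():.3f} for individual {i}, organ {organ.name}"
                )
            verts = u * (ell * factor)[:, None]
            m = trimesh.Trimesh(vertices=verts, faces=base.faces.copy(), process=False)
            organ_meshes.append(m)
        meshes[organ.name] = organ_meshes

    return meshes, GroundTruth(latent=latent, outlier_flags=flags, spec=spec)
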