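"""End-to-end orchestration: meshes -> registration -> features ->
{MCIA, PCA, t-SNE} -> bagplots -> robustness, from a single config.

Every stage is a pure function of (inputs, config); all randomness
(landmark sampling, t-SNE, simulation) flows from named seeds, so
re-running a config reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import dimred, registration, shape_features, volume_mesh
from .bagplot import compute_bagplot
from .robustness import compare_methods, max_same_region_count
from .synthetic_cohort import CohortSpec, OrganSpec, generate_cohort

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, item: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed on '{item}': {cause}")
        self.stage = stage
        self.item = item
        self.cause = cause


@dataclass
class PipelineConfig:
    mode: str = "simulate"                  # simulate | meshes | nifti | features
    output_dir: str = "morphomcia_out"
    # simulate mode
    simulate: dict = field(default_factory=dict)      # CohortSpec fields
    # meshes mode: {organ: [mesh paths]}
    meshes: dict = field(default_factory=dict)
    # nifti mode: {"files": [...], "organs": {name: code}, "bilateral": [...]}
    nifti: dict = field(default_factory=dict)
    # features mode: {organ: csv path (features x individuals)}
    features: dict = field(default_factory=dict)
    # stages
    target_vertices: int = 1000
    taubin_iters: int = 10
    register: bool = True
    registration_params: dict = field(default_factory=dict)  # beta, lam, ...
    n_pairs: int = 500
    pair_seed: int = 42
    methods: tuple = ("mcia", "pca", "tsne")
    n_axes: int = 2
    tsne_seed: int = 0
    tsne_perplexity: float | None = None
    fence_factor: float = 3.0
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_meshes(cfg: PipelineConfig, log: list[str]) -> dict[str, list[trimesh.Trimesh]]:
    """Stage 1: produce per-organ mesh lists, all decimated and centered."""
    if cfg.mode == "simulate":
        params = dict(cfg.simulate)
        organ_specs = params.pop("organ_specs", None)
        if organ_specs is not None:
            params["organ_specs"] = [
                o if isinstance(o, OrganSpec) else OrganSpec(**o) for o in organ_specs
            ]
        params.setdefault("n_vertices", cfg.target_vertices)
        spec = CohortSpec(**params)
        log.append(f"simulate: seed={spec.seed} n={spec.n_individuals} "
                   f"organs={[o.name for o in spec.organ_specs]}")
        meshes, truth = generate_cohort(spec)
        cfg._ground_truth = truth  # kept for callers; not serialized
        return meshes
    if cfg.mode == "meshes":
        out = {}
        for organ, paths in cfg.meshes.items():
            ms = []
            for p in paths:
                m = trimesh.load(p, force="mesh")
                ms.append(volume_mesh.decimate_smooth_center(
                    m, cfg.target_vertices, cfg.taubin_iters))
            out[organ] = ms
        return out
    if cfg.mode == "nifti":
        organs = cfg.nifti["organs"]
        bilateral = set(cfg.nifti.get("bilateral", []))
        out: dict[str, list] = {}
        for path in cfg.nifti["files"]:
            vol = volume_mesh.LabelVolume.from_nifti(path, organs)
            for organ in organs:
                mask = volume_mesh.clean_mask_slices(vol.mask(organ))
                mesh = volume_mesh.extract_mesh(mask, vol.spacing)
                if organ in bilateral:
                    left, right = volume_mesh.split_bilateral(mesh)
                    for side, part in (("left", left), ("right", right)):
                        key = f"{organ}_{side}"
                        part = volume_mesh.decimate_smooth_center(
                            part, cfg.target_vertices, cfg.taubin_iters)
                        out.setdefault(key, []).append(part)
                else:
                    mesh = volume_mesh.decimate_smooth_center(
                        mesh, cfg.target_vertices, cfg.taubin_iters)
                    out.setdefault(organ, []).append(mesh)
        return out
    raise ValueError(f"unknown mode {cfg.mode!r}")


def _block_from_meshes(cfg: PipelineConfig, organ: str,
                       meshes: list[trimesh.Trimesh], log: list[str]):
    if cfg.register:
        rset = registration.register_organ_set(meshes, **cfg.registration_params)
        log.append(f"{organ}: registered to template {rset.template_index}")
    else:
        rset = registration.RegisteredOrganSet(
            template_index=registration.select_template(meshes),
            meshes=meshes,
        )
        log.append(f"{organ}: registration skipped (meshes assumed in correspondence)")
    V = rset.n_vertices
    pairs = shape_features.sample_landmark_pairs(V, cfg.n_pairs, seed=cfg.pair_seed)
    fm = shape_features.build_feature_matrix(rset, pairs, organ=organ)
    return shape_features.standardize(fm)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; write CSV/JSON outputs under ``cfg.output_dir``.

    Returns a run report (also written to ``report.json``) with the
    robustness counts, the statistical comparison of the methods and the
    log of defaults filled in.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    # --- meshes (features mode skips mesh stages entirely) ---
    mesh_sets = {}
    if cfg.mode != "features":
        try:
            mesh_sets = _load_meshes(cfg, log)
        except PipelineStageError:
            raise
        except Exception as e:
            raise PipelineStageError("meshes", cfg.mode, e) from e

    # --- features ---
    blocks = []
    if cfg.mode == "features":
        for organ, path in cfg.features.items():
            try:
                df = pd.read_csv(path, index_col=0)
                fm = shape_features.FeatureMatrix.from_frame(df, organ=organ)
                blocks.append(shape_features.standardize(fm))
            except Exception as e:
                raise PipelineStageError("features", organ, e) from e
    else:
        for organ, meshes in mesh_sets.items():
            try:
                blocks.append(_block_from_meshes(cfg, organ, meshes, log))
            except Exception as e:
                raise PipelineStageError("features", organ, e) from e
    for b in blocks:
        b.to_frame().to_csv(out / f"features_{b.organ}.csv")
    organs = [b.organ for b in blocks]
    ids = blocks[0].sample_ids

    # --- embeddings ---
    coords: dict[str, dict[str, np.ndarray]] = {}
    mcia_res = None
    for method in cfg.methods:
        try:
            if method == "mcia":
                mcia_res = dimred.mcia_fit(blocks, dimred.MCIAConfig(n_axes=cfg.n_axes))
                coords["mcia"] = {
                    o: mcia_res.block_scores[s][:, :2]
                    for s, o in enumerate(mcia_res.block_names)
                }
                pd.DataFrame(mcia_res.centers, index=ids).to_csv(out / "mcia_centers.csv")
                pd.DataFrame(
                    mcia_res.pseudo_eigenvalues, index=organs
                ).to_csv(out / "mcia_pseudo_eigenvalues.csv")
                pd.DataFrame({
                    "eigenvalue": mcia_res.eigenvalues,
                    "variance_explained": mcia_res.variance_explained,
                }).to_csv(out / "mcia_scree.csv", index_label="axis")
                for s, o in enumerate(organs):
                    pd.DataFrame(
                        mcia_res.loadings[s], index=blocks[s].feature_names
                    ).to_csv(out / f"mcia_loadings_{o}.csv")
                pd.Series(
                    dimred.summed_center_distances(mcia_res), index=ids,
                    name="summed_center_distance",
                ).to_csv(out / "mcia_summed_center_distances.csv")
            elif method == "pca":
                coords["pca"] = {
                    b.organ: dimred.pca_embed(b, cfg.n_axes).coords[:, :2]
                    for b in blocks
                }
            elif method == "tsne":
                coords["tsne"] = {
                    b.organ: dimred.tsne_embed(
                        b, perplexity=cfg.tsne_perplexity, seed=cfg.tsne_seed
                    ).coords
                    for b in blocks
                }
            else:
                raise ValueError(f"unknown method {method!r}")
        except PipelineStageError:
            raise
        except Exception as e:
            raise PipelineStageError("dimred", method, e) from e
        for o, xy in coords[method].items():
            pd.DataFrame(xy, index=ids, columns=["dim1", "dim2"]).to_csv(
                out / f"coords_{method}_{o}.csv"
            )

    # --- bagplots + regions ---
    region_tables: dict[str, pd.DataFrame] = {}
    for method, per_organ in coords.items():
        tbl = pd.DataFrame(index=ids, columns=organs, dtype=object)
        for o, xy in per_organ.items():
            try:
                bp = compute_bagplot(xy, fence_factor=cfg.fence_factor)
            except Exception as e:
                raise PipelineStageError("bagplot", f"{method}/{o}", e) from e
            tbl[o] = bp.regions
            pd.DataFrame({
                "depth": bp.depths, "region": bp.regions
            }, index=ids).to_csv(out / f"regions_{method}_{o}.csv")
        region_tables[method] = tbl
        tbl.to_csv(out / f"region_table_{method}.csv")

    # --- robustness ---
    counts = {m: max_same_region_count(t).to_numpy() for m, t in region_tables.items()}
    counts_df = pd.DataFrame(counts, index=ids)
    counts_df.to_csv(out / "robustness_counts.csv")
    comparison = compare_methods(counts) if len(counts) >= 2 else None
    if comparison is not None:
        with open(out / "robustness_tests.json", "w") as fh:
            json.dump(comparison.to_dict(), fh, indent=2)

    if cfg.make_plots:
        _diagnostic_plots(out, coords, mcia_res, ids)

    report = {
        "organs": organs,
        "n_individuals": len(ids),
        "methods": list(cfg.methods),
        "robustness_counts": {m: v.tolist() for m, v in counts.items()},
        "comparison": comparison.to_dict() if comparison else None,
        "log": log,
        "output_dir": str(out),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _diagnostic_plots(out: Path, coords, mcia_res, ids) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if mcia_res is not None:
        fig, ax = plt.subplots(figsize=(6, 6))
        markers = "osd^vP*X"
        for s, o in enumerate(mcia_res.block_names):
            xy = mcia_res.block_scores[s][:, :2]
            ax.scatter(*xy.T, s=18, marker=markers[s % len(markers)], label=o)
            for i in range(len(ids)):
                ax.plot(
                    [xy[i, 0], mcia_res.centers[i, 0]],
                    [xy[i, 1], mcia_res.centers[i, 1]],
                    color="grey", lw=0.4, zorder=0,
                )
        ax.legend()
        ax.set_xlabel("axis 1")
        ax.set_ylabel("axis 2")
        ax.set_title("MCIA sample space with synthetic centers")
        fig.savefig(out / "mcia_sample_space.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots()
        ax.bar(
            np.arange(len(mcia_res.variance_explained)),
            mcia_res.variance_explained,
        )
        ax.set_xlabel("axis")
        ax.set_ylabel("variance explained")
        fig.savefig(out / "mcia_scree.png", dpi=120)
        plt.close(fig)
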