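"""End-to-end orchestration: preprocessing -> phenotypes -> projection ->
evolution -> pathways -> association, with all artifacts and a run manifest.

Every stage writes its numeric results as CSV/JSON first; figures are
rendered from the same frames afterwards, so each figure has a co-written
CSV with exactly the plotted numbers. The manifest records the config
snapshot, per-stage seeds, input checksums, staged attrition counts and
every output path; re-running with the same manifest seeds reproduces the
CSV artifacts byte for byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import StageError
from .evolution import DEFAULT_MIN_LINK_SHARE, evolve, sankey_links
from .io import (
    hulls_to_json,
    read_cohort,
    read_variable_specs,
    write_cohort,
    write_labels,
    write_manifest,
)
from .variables import write_variable_specs
from .pathways import (
    chi_square_association,
    cluster_deltas,
    compute_deltas,
    mosaic_counts,
    order_and_label,
    pathway_profile,
    spearman_with_pathways,
)
from .phenotyping import SilhouettePAM, cluster_baseline, phenotype_profile
from .preprocess import preprocess
from .projection import compute_factor_map, fit_embedding, project
from . import plots


@dataclass
class PipelineConfig:
    """Run configuration; loadable from YAML."""

    t0_path: str
    t1_path: str
    specs_path: str
    output_dir: str
    seed: int = 0
    engine: str = "umap"
    k_range: tuple[int, int] = (2, 10)
    n_boot: int = 2000
    min_link_share: float = DEFAULT_MIN_LINK_SHARE
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "k_range" in payload:
            payload["k_range"] = tuple(payload["k_range"])
        return cls(**payload)

    def stage_seeds(self) -> dict[str, int]:
        base = int(self.seed) % (2**31 - 7)
        return {
            "phenotype": base,
            "embedding": base + 1,
            "pathways": base + 2,
            "bootstrap": base + 3,
        }


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    version: str
    input_checksums: dict
    attrition_counts: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "seeds": self.seeds,
            "input_checksums": self.input_checksums,
            "attrition_counts": self.attrition_counts,
            "stages": self.stages,
        }


def run_pipeline(config: PipelineConfig | str | Path) -> RunManifest:
    """Execute all stages in order and write artifacts plus the manifest."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest = RunManifest(
        config={
            "t0_path": config.t0_path,
            "t1_path": config.t1_path,
            "specs_path": config.specs_path,
            "output_dir": config.output_dir,
            "seed": config.seed,
            "engine": config.engine,
            "k_range": list(config.k_range),
            "n_boot": config.n_boot,
            "min_link_share": config.min_link_share,
        },
        seeds=seeds,
        version=__version__,
        input_checksums={
            "t0": _sha256(config.t0_path),
            "t1": _sha256(config.t1_path),
            "specs": _sha256(config.specs_path),
        },
    )

    def record(stage: str, **paths):
        manifest.stages[stage] = {k: str(v) for k, v in paths.items()}

    # -- preprocess ---------------------------------------------------------
    try:
        specs = read_variable_specs(config.specs_path)
        t0_raw = read_cohort(config.t0_path, specs, "t0")
        t1_raw = read_cohort(config.t1_path, specs, "t1")
        t0_std, t1_std, counts, scaling = preprocess(t0_raw, t1_raw)
        write_cohort(t0_std, out / "t0_std.csv")
        write_cohort(t1_std, out / "t1_std.csv")
        write_variable_specs(t0_std.specs, out / "variable_specs_processed.csv")
        pd.DataFrame({"mean": scaling.mean, "sd": scaling.sd}).to_csv(
            out / "scaling_model.csv", index_label="variable"
        )
        manifest.attrition_counts = {
            "total": counts.total,
            "complete_t0": counts.complete_t0,
            "complete_both": counts.complete_both,
        }
        record("preprocess", t0_std=out / "t0_std.csv", t1_std=out / "t1_std.csv",
               scaling=out / "scaling_model.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("preprocess", str(e)) from e

    # -- phenotype ----------------------------------------------------------
    try:
        method = SilhouettePAM(k_range=config.k_range)
        assignment = cluster_baseline(t0_std, method=method, seed=seeds["phenotype"])
        write_labels(assignment.labels, out / "phenotype_assignment.csv", "phenotype")
        phenotype_profile(assignment, t0_std).to_csv(out / "phenotype_profiles.csv")
        manifest.stages["phenotype_model"] = {
            "k": assignment.k,
            "method_tag": assignment.method_tag,
            "medoid_ids": {int(c): str(m) for c, m in assignment.medoid_ids.items()},
            "silhouettes": {int(k): float(s) for k, s in method.silhouettes_.items()},
        }
        record("phenotype", assignment=out / "phenotype_assignment.csv",
               profiles=out / "phenotype_profiles.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("phenotype", str(e)) from e

    # -- embed --------------------------------------------------------------
    try:
        model = fit_embedding(t0_std, engine=config.engine, seed=seeds["embedding"])
        coords_t0 = model.training_coords
        coords_t1 = project(model, t1_std)
        coords = pd.concat(
            [coords_t0.assign(timepoint="t0"), coords_t1.assign(timepoint="t1")]
        )[["timepoint", "x", "y"]]
        coords.to_csv(out / "coords.csv", index_label="patient_id")
        factor_map = compute_factor_map(t0_std, coords_t0)
        factor_map.to_csv(out / "factor_map.csv", index=False)
        if config.make_figures:
            plots.plot_embedding(coords_t0, assignment.labels, out / "embedding.png",
                                 f"baseline projection ({config.engine})")
            plots.plot_factor_map(factor_map, out / "factor_map.png")
        record("embed", coords=out / "coords.csv", factor_map=out / "factor_map.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("embed", str(e)) from e

    # -- evolve -------------------------------------------------------------
    try:
        evo = evolve(t0_std, t1_std, assignment, coords_t0, coords_t1)
        links = sankey_links(evo.transitions, min_share=config.min_link_share)
        trans = evo.transitions.counts.stack().rename("count").reset_index()
        trans["share"] = trans["count"] / evo.transitions.n
        trans.to_csv(out / "transitions.csv", index=False)
        links.to_csv(out / "sankey_links.csv", index=False)
        hulls_to_json({**evo.hulls_t0}, out / "core_hulls_t0.json")
        hulls_to_json({**evo.hulls_t1}, out / "core_hulls_t1.json")
        hull_rows = []
        for hulls, coords_tp in ((evo.hulls_t0, coords_t0), (evo.hulls_t1, coords_t1)):
            for c, h in hulls.items():
                mx, my = coords_tp.loc[h.medoid_id, ["x", "y"]]
                for vx, vy in h.vertices:
                    hull_rows.append(
                        {"phenotype": c, "timepoint": h.timepoint, "x": vx, "y": vy,
                         "medoid_x": mx, "medoid_y": my, "area": h.area}
                    )
        hull_records = pd.DataFrame(hull_rows)
        hull_records.to_csv(out / "core_hull_vertices.csv", index=False)
        evo.summary.to_csv(out / "radial_summary.csv", index=False)
        write_labels(evo.t1_labels, out / "phenotype_assignment_t1.csv", "phenotype_t1")
        if config.make_figures:
            plots.plot_core_hulls(hull_records, out / "core_hulls.png")
            plots.plot_transitions(
                links, assignment.sizes, evo.t1_labels.value_counts().sort_index(),
                out / "transitions.png",
            )
            plots.plot_radial_summary(evo.summary, out / "radial_summary.png")
        record("evolve", transitions=out / "transitions.csv",
               sankey_links=out / "sankey_links.csv",
               hulls_t0=out / "core_hulls_t0.json", hulls_t1=out / "core_hulls_t1.json",
               radial_summary=out / "radial_summary.csv",
               t1_assignment=out / "phenotype_assignment_t1.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("evolve", str(e)) from e

    # -- pathways -----------------------------------------------------------
    try:
        deltas = compute_deltas(t0_std, t1_std)
        method = SilhouettePAM(k_range=config.k_range)
        raw = cluster_deltas(deltas, method=method, seed=seeds["pathways"])
        pathway_assignment = order_and_label(raw, deltas)
        labeled = pd.DataFrame(
            {
                "pathway": pathway_assignment.labels,
                "label": pathway_assignment.labels.map(pathway_assignment.label_names),
            }
        )
        labeled.to_csv(out / "pathway_assignment.csv", index_label="patient_id")
        profiles = pathway_profile(deltas, pathway_assignment)
        profiles.to_csv(out / "pathway_profiles.csv")
        spearman_panel = spearman_with_pathways(
            t0_std, pathway_assignment, n_boot=config.n_boot, seed=seeds["bootstrap"]
        )
        spearman_panel.to_csv(out / "spearman_panel.csv", index=False)
        manifest.stages["pathway_model"] = {
            "m": pathway_assignment.m,
            "silhouettes": {int(k): float(s) for k, s in method.silhouettes_.items()},
            "order_stat": {int(k): float(v) for k, v in pathway_assignment.order_stat.items()},
        }
        if config.make_figures:
            plots.plot_pathway_profiles(profiles, out / "pathway_profiles.png")
        record("pathways", assignment=out / "pathway_assignment.csv",
               profiles=out / "pathway_profiles.csv",
               spearman=out / "spearman_panel.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("pathways", str(e)) from e

    # -- association --------------------------------------------------------
    try:
        report = chi_square_association(assignment.labels, pathway_assignment.labels)
        counts_tab, pct = mosaic_counts(assignment.labels, pathway_assignment.labels)
        counts_tab.to_csv(out / "contingency_counts.csv")
        pct.to_csv(out / "contingency_pct.csv")
        manifest.stages["association"] = {
            "chi2": report.chi2,
            "df": report.df,
            "p_value": report.p_value,
        }
        if config.make_figures:
            plots.plot_mosaic(counts_tab, pct, out / "mosaic.png")
        record("report", contingency=out / "contingency_counts.csv",
               contingency_pct=out / "contingency_pct.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("association", str(e)) from e

    write_manifest(manifest.to_dict(), out / "run_manifest.yaml")
    return manifest
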