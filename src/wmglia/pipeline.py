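"""End-to-end pipeline driver: simulate -> qc -> states -> composition -> proximity.

One global seed deterministically spawns per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``; the derived seeds are written to
the manifest so any stage can be rerun in isolation. Identical config and
seed produce byte-identical output files.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, composition, proximity, qc, simulate, states
from .config import PipelineConfig
from .io import write_counts, write_point_patterns, write_qc_table

_STAGES = ("counts", "qc", "spatial", "null")


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2**31) from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on simulated data and write a result bundle.

    Returns the manifest (also written to ``manifest.json``). Stage failures
    propagate as ``RuntimeError`` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    outputs: list[str] = []

    def record(name: str) -> Path:
        outputs.append(name)
        return out / name

    stage = "simulate"
    try:
        design = simulate.default_design(
            n_per_group=config.simulate.n_per_group,
            cells_per_sample=config.simulate.cells_per_sample,
            platform=config.simulate.platform,
            seed=seeds["counts"],
        )
        profiles = simulate.default_profiles(fold=config.simulate.marker_fold)
        adata = simulate.generate_counts(design, profiles, n_genes=config.simulate.n_genes)
        write_counts(adata, out / "counts")
        outputs += ["counts/matrix.mtx", "counts/genes.tsv", "counts/cells.tsv"]

        stage = "qc"
        n_cells = adata.n_obs
        violations = {"reads": config.qc.n_qc_violations // 2,
                      "frac_mito": config.qc.n_qc_violations - config.qc.n_qc_violations // 2}
        qc_table = simulate.generate_qc_table(n_cells, violations, seed=seeds["qc"])
        write_qc_table(qc_table, record("qc_table.csv"))
        thresholds = qc.QCThresholds().replace(
            **{k: tuple(v) for k, v in config.qc.smartseq_thresholds.items()}
        )
        kept, ss_report = qc.apply_smartseq_filters(
            qc_table.drop(columns=["passes_qc"]), thresholds
        )
        ss_report.to_json(record("qc_smartseq_report.json"))

        cleaned = qc.remove_genes(adata)
        droplet_params = qc.DropletFilterParams(
            min_cells_per_gene=config.qc.droplet_min_cells_per_gene,
            min_genes_per_cell=config.qc.droplet_min_genes_per_cell,
            max_frac_mito=config.qc.droplet_max_frac_mito,
            max_umi=config.qc.droplet_max_umi,
            max_genes=config.qc.droplet_max_genes,
        )
        filtered, dr_report = qc.apply_droplet_filters(cleaned, droplet_params)
        dr_report.to_json(record("qc_droplet_report.json"))

        stage = "states"
        norm = states.normalize_log(filtered, scale_factor=config.states.scale_factor)
        sigs = states.default_signatures()
        if config.states.signatures:
            sigs = {
                name: states.SignatureSet(name, tuple(genes))
                for name, genes in config.states.signatures.items()
            }
        scores = states.score_signatures(norm, sigs)
        rules = [(name, config.states.tau) for name in config.states.assign_order]
        assignment = states.assign_states(scores, rules)
        assignment.rename_axis("cell_id").to_csv(record("assignments.csv"))

        labels = assignment["state"].to_numpy()
        overlap: list[str] = []
        marker_tables = {}
        for sig_name in ("IRO", "IRM"):
            if (labels == sig_name).sum() >= 2 and (labels == "unassigned").sum() >= 2:
                table = states.rank_markers(norm, labels, sig_name, "unassigned")
                marker_tables[sig_name] = table
                table.to_csv(record(f"markers_{sig_name}.csv"), index=False)
        if len(marker_tables) == 2:
            overlap = sorted(
                states.top_k_overlap(
                    marker_tables["IRO"], marker_tables["IRM"], k=config.states.top_k
                )
            )
        _dump_json({"k": config.states.top_k, "genes": overlap, "n": len(overlap)},
                   record("marker_overlap.json"))

        stage = "composition"
        assign_df = pd.DataFrame(
            {"sample_id": norm.obs["sample_id"].to_numpy(), "state": labels}
        )
        metadata = (
            norm.obs[["sample_id", "age_months", "genotype", "tissue"]]
            .drop_duplicates()
            .set_index("sample_id")
        )
        comp = composition.proportions_per_sample(assign_df, metadata)
        comp.counts.to_csv(record("composition_counts.csv"))
        summary = composition.boxplot_summary(comp, [config.composition.group_factor])
        summary.to_csv(record("composition_boxplot.csv"), index=False)
        comp_res = composition.test_composition(
            comp, config.composition.group_factor, fdr=config.composition.fdr
        )
        _dump_json(comp_res.to_dict(), record("composition_test.json"))

        stage = "proximity"
        p = config.proximity
        spatial_params = simulate.SpatialSimParams(
            window_width=p.window[0],
            window_height=p.window[1],
            dapi_intensity=p.dapi_intensity,
            n_ref=p.n_ref,
            n_target=p.n_target,
            assoc_prob=p.assoc_prob,
            displacement_sigma=p.displacement_sigma,
            n_sections_per_mouse=p.n_sections_per_mouse,
            n_mice=p.n_mice,
            seed=seeds["spatial"],
        )
        patterns = simulate.generate_point_pattern(spatial_params)
        write_point_patterns(patterns, out / "sections")
        outputs += ["sections/cells.csv", "sections/windows.json"]
        prox_config = proximity.ProximityConfig(
            radius=p.radius, n_null_draws=p.n_null_draws, seed=seeds["null"]
        )
        result = proximity.proximity_analysis(
            patterns, spatial_params.target_category, spatial_params.ref_category,
            prox_config,
        )
        _dump_json(result.to_dict(), record("proximity.json"))
    except Exception as exc:  # noqa: BLE001 - reported with the stage name
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "versions": _library_versions(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": config.model_dump(),
        "config_hash": _config_hash(config),
        "outputs": sorted(outputs),
        "qc": {
            "smartseq_kept": ss_report.n_kept,
            "droplet_kept": dr_report.n_kept,
        },
    }
    _dump_json(manifest, out / "manifest.json")
    return manifest


def _library_versions() -> dict[str, str]:
    from importlib.metadata import version

    return {name: version(name) for name in ("numpy", "scipy", "pandas", "anndata")}
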