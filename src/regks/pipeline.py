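"""Config-driven pipeline tying all stages together reproducibly.

Each stage reads its inputs from, and writes its outputs into, a single
working directory, so stages can be run standalone on the outputs of the
previous one.  ``run_all`` chains them: QC -> normalization -> gene
collapse -> developmental branch (S^2 filter, standardization, clustering)
-> HS branch (per-tissue ANOVA response sets, overlap statistics, 12 h
hippocampal ratio profile, regulated-KS enrichment screen, membership
matrix, pathway-relevant intersection) -> NBQX branch (per-tissue nested
selection, epileptogenic set, Fisher enrichment).  A manifest records the
configuration, seeds and SHA-256 of every output so a run is reproducible
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from regks import __version__, formats, preprocess, diffexpr, enrichment, postprocess
from regks.containers import ExpressionMatrix, TISSUES
from regks.simulate import SimulationConfig, generate_signed_gene_sets, generate_study

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {},
    "qc": {"z_threshold": 5.0, "drop_flagged": True},
    "developmental": {"top_k": 1000, "n_clusters": 5},
    "hs": {"contrast": ["noHS", "HS"], "threshold": {"mode": "fdr", "value": 0.25}},
    "enrichment": {
        "tissue": "hippocampus",
        "time_h": 12,
        "contrast": ["noHS", "HS"],
        "n_perm": 10000,
        "fdr_max": 0.25,
        "c_min": 2.0,
        "min_sets": 2,
    },
    "nbqx": {
        "contrast": ["HS", "HS_NBQX"],
        "thresholds": {
            "hippocampus": {"mode": "fdr", "value": 0.25},
            "cortex": {"mode": "raw_p", "value": 0.01},
        },
        "fisher_p_max": 0.01,
    },
}


def merge_config(overrides: Optional[dict] = None) -> dict:
    """Deep-merge user overrides onto the default pipeline configuration."""

    def merge(base: dict, extra: dict) -> dict:
        out = dict(base)
        for key, value in extra.items():
            if isinstance(value, dict) and isinstance(out.get(key), dict):
                out[key] = merge(out[key], value)
            else:
                out[key] = value
        return out

    return merge(DEFAULT_CONFIG, overrides or {})


def _write_genes(genes: list[str], path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{g}\n" for g in genes))


def _read_genes(path: Path) -> list[str]:
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: dict, workdir: Path) -> None:
    """Generate a synthetic study and write every input artifact."""
    if config.get("simulate") is None:
        raise ValueError("configuration has no simulate block")
    sim_overrides = dict(config["simulate"])
    sim_overrides.setdefault("seed", config.get("seed", 0))
    sim = SimulationConfig(**sim_overrides)
    matrix, design, probe_map, truth = generate_study(sim)
    collection, set_truth = generate_signed_gene_sets(truth, sim)
    workdir.mkdir(parents=True, exist_ok=True)
    formats.write_intensity_matrix(matrix, workdir / "matrix.tsv", workdir / "calls.tsv")
    formats.write_design_table(design, workdir / "design.csv")
    formats.write_probe_gene_map(probe_map, workdir / "annotation.tsv")
    formats.write_signed_gene_sets(collection, workdir / "gene_sets.gmt")
    formats.write_table(truth.genes, workdir / "truth_genes.tsv")
    formats.write_table(set_truth, workdir / "truth_sets.tsv")


def _load_inputs(workdir: Path) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    matrix = formats.read_intensity_matrix(workdir / "matrix.tsv", workdir / "calls.tsv")
    design = formats.read_design_table(workdir / "design.csv")
    probe_map = formats.read_probe_gene_map(workdir / "annotation.tsv")
    return matrix, design, probe_map


def stage_qc(config: dict, workdir: Path) -> None:
    """Chip QC summaries and outlier/tissue-swap flags."""
    matrix, design, _ = _load_inputs(workdir)
    summaries = preprocess.chip_qc_summary(matrix)
    formats.write_table(preprocess.qc_summary_frame(summaries), workdir / "qc.tsv")
    flags = preprocess.flag_outliers(
        summaries, matrix, design, z_threshold=config["qc"]["z_threshold"]
    )
    formats.write_table(flags, workdir / "qc_flags.tsv")


def stage_normalize(config: dict, workdir: Path) -> None:
    """Drop flagged chips, then rescale all chips to a common present-call p75."""
    matrix, design, _ = _load_inputs(workdir)
    flags_path = workdir / "qc_flags.tsv"
    if config["qc"].get("drop_flagged", True) and flags_path.exists():
        flags = pd.read_csv(flags_path, sep="\t")
        keep = flags.loc[~flags["flagged"], "sample_id"]
        dropped = sorted(set(flags["sample_id"]) - set(keep))
        if dropped:
            logger.info("dropping %d flagged sample(s): %s", len(dropped), dropped)
        matrix = matrix.subset_samples(list(keep))
        design = design[design["sample_id"].isin(keep)]
    normalized, factors = preprocess.normalize_to_common_percentile(matrix)
    formats.write_intensity_matrix(
        normalized, workdir / "normalized.tsv", workdir / "normalized_calls.tsv"
    )
    formats.write_design_table(design, workdir / "design_retained.csv")
    formats.write_table(
        factors.rename_axis("sample_id").reset_index(), workdir / "scale_factors.tsv"
    )


def stage_collapse(config: dict, workdir: Path) -> None:
    """Collapse normalized probeset intensities to gene level (max rule)."""
    matrix = formats.read_intensity_matrix(
        workdir / "normalized.tsv", workdir / "normalized_calls.tsv"
    )
    probe_map = formats.read_probe_gene_map(workdir / "annotation.tsv")
    gene_matrix = preprocess.collapse_to_genes(matrix, probe_map)
    formats.write_table(gene_matrix, workdir / "gene_matrix.tsv", index=True)


def _load_gene_matrix(workdir: Path) -> pd.DataFrame:
    return pd.read_csv(workdir / "gene_matrix.tsv", sep="\t", index_col=0)


def _load_retained_design(workdir: Path) -> pd.DataFrame:
    path = workdir / "design_retained.csv"
    if not path.exists():
        path = workdir / "design.csv"
    return formats.read_design_table(path)


def stage_developmental(config: dict, workdir: Path) -> None:
    """Unsupervised variation filter and clustering of baseline profiles."""
    gene_matrix = _load_gene_matrix(workdir)
    design = _load_retained_design(workdir)
    cfg = config["developmental"]
    baseline_samples = design.loc[design["treatment"] == "noHS", "sample_id"]
    sub = gene_matrix.loc[:, list(baseline_samples)]
    s2 = preprocess.variation_statistic(sub)
    top = preprocess.top_k(s2, min(cfg["top_k"], len(s2)))
    z = preprocess.standardize_genes(sub.loc[top])
    labels, order = preprocess.cluster_gene_profiles(
        z, n_clusters=cfg["n_clusters"], seed=config.get("seed", 0)
    )
    out = workdir / "developmental"
    out.mkdir(exist_ok=True)
    formats.write_table(s2.rename_axis("gene").reset_index(), out / "s2.tsv")
    _write_genes(top, out / "top_genes.txt")
    formats.write_table(
        labels.rename_axis("gene").reset_index(), out / "clusters.tsv"
    )
    _write_genes(order, out / "display_order.txt")
    formats.write_table(z.loc[order], out / "heatmap_matrix.tsv", index=True)


def stage_hs_response(config: dict, workdir: Path) -> None:
    """Per-tissue hypoxic-seizure ANOVA response sets and their overlap."""
    matrix = formats.read_intensity_matrix(
        workdir / "normalized.tsv", workdir / "normalized_calls.tsv"
    )
    design = _load_retained_design(workdir)
    probe_map = formats.read_probe_gene_map(workdir / "annotation.tsv")
    cfg = config["hs"]
    out = workdir / "hs"
    out.mkdir(exist_ok=True)
    per_tissue: dict[str, list[str]] = {}
    for tissue in TISSUES:
        genes, table = diffexpr.select_response_set(
            matrix,
            design,
            tissue,
            tuple(cfg["contrast"]),
            cfg["threshold"],
            probe_map=probe_map,
        )
        per_tissue[tissue] = genes
        formats.write_table(table, out / f"anova_{tissue}.tsv")
        _write_genes(genes, out / f"genes_{tissue}.txt")
    universe = probe_map["gene_symbol"].nunique()
    inter, union, sizes = diffexpr.set_algebra(*(per_tissue[t] for t in TISSUES))
    stats = diffexpr.overlap_statistics(
        sizes["A"], sizes["B"], universe, sizes["intersection"]
    )
    formats.write_table(
        pd.DataFrame([dataclasses.asdict(stats)]), out / "overlap.tsv"
    )
    _write_genes(inter, out / "intersection.txt")
    _write_genes(union, out / "union.txt")


def stage_enrich(config: dict, workdir: Path) -> None:
    """Regulated-KS enrichment of the reference differential profile.

    The default target is the HS/noHS log2-ratio profile at 12 h in
    hippocampus, the point of maximum transcriptional modulation.
    """
    matrix = formats.read_intensity_matrix(
        workdir / "normalized.tsv", workdir / "normalized_calls.tsv"
    )
    design = _load_retained_design(workdir)
    probe_map = formats.read_probe_gene_map(workdir / "annotation.tsv")
    collection = formats.read_signed_gene_sets(workdir / "gene_sets.gmt")
    cfg = config["enrichment"]
    out = workdir / "enrich"
    out.mkdir(exist_ok=True)

    ratios = diffexpr.ratio_profile(
        matrix.intensity,
        design,
        cfg["contrast"][0],
        cfg["contrast"][1],
        cfg["tissue"],
        probe_map=probe_map,
        times=[cfg["time_h"]],
    )
    formats.write_table(ratios, out / "ratio_profile.tsv")
    profile = ratios.set_index("gene")["log2_ratio"]

    results = enrichment.screen_collection(
        profile,
        collection,
        fdr_max=cfg["fdr_max"],
        c_min=cfg["c_min"],
        n_perm=cfg["n_perm"],
        seed=config.get("seed", 0),
    )
    formats.write_results_tables(results, out)

    membership = postprocess.build_membership_matrix(
        results, min_sets=cfg["min_sets"], seed=config.get("seed", 0)
    )
    formats.write_table(
        membership.matrix.rename_axis("gene_set"), out / "membership.tsv", index=True
    )
    _write_genes(membership.genes, out / "membership_genes.txt")
    hs_union = _read_genes(workdir / "hs" / "union.txt")
    relevant = postprocess.pathway_relevant_intersection(membership.genes, hs_union)
    _write_genes(relevant, out / "pathway_relevant_genes.txt")


def stage_nbqx(config: dict, workdir: Path) -> None:
    """Nested NBQX selection, epileptogenic set and Fisher enrichment."""
    matrix = formats.read_intensity_matrix(
        workdir / "normalized.tsv", workdir / "normalized_calls.tsv"
    )
    design = _load_retained_design(workdir)
    probe_map = formats.read_probe_gene_map(workdir / "annotation.tsv")
    collection = formats.read_signed_gene_sets(workdir / "gene_sets.gmt")
    cfg = config["nbqx"]
    out = workdir / "nbqx"
    out.mkdir(exist_ok=True)

    nbqx_sets: dict[str, list[str]] = {}
    for tissue in TISSUES:
        genes, table = diffexpr.select_response_set(
            matrix,
            design,
            tissue,
            tuple(cfg["contrast"]),
            cfg["thresholds"][tissue],
            probe_map=probe_map,
        )
        nbqx_sets[tissue] = genes
        formats.write_table(table, out / f"anova_{tissue}.tsv")
        _write_genes(genes, out / f"genes_{tissue}.txt")

    hs_sets = {
        tissue: _read_genes(workdir / "hs" / f"genes_{tissue}.txt") for tissue in TISSUES
    }
    epi = postprocess.derive_epileptogenic_set(hs_sets, nbqx_sets)
    _write_genes(epi.genes, out / "epileptogenic_genes.txt")
    formats.write_table(epi.provenance, out / "epileptogenic_provenance.tsv")

    universe = probe_map["gene_symbol"].nunique()
    rows = []
    for gs in collection:
        members = list(gs.up_genes) + list(gs.down_genes)
        overlap, p, selected = postprocess.fisher_enrichment(
            members, epi.genes, universe, p_max=cfg["fisher_p_max"]
        )
        rows.append(
            {
                "name": gs.name,
                "source": gs.source,
                "size": len(members),
                "overlap": overlap,
                "P": p,
                "selected": selected,
            }
        )
    formats.write_table(pd.DataFrame(rows), out / "fisher.tsv")


STAGES = {
    "qc": stage_qc,
    "normalize": stage_normalize,
    "collapse": stage_collapse,
    "developmental": stage_developmental,
    "hs-response": stage_hs_response,
    "enrich": stage_enrich,
    "nbqx": stage_nbqx,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(config: dict, workdir: Path) -> Path:
    """Record configuration, seeds and SHA-256 of every output file."""
    files = sorted(
        p for p in workdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "regks_version": __version__,
        "config": config,
        "seed": config.get("seed", 0),
        "outputs": {str(p.relative_to(workdir)): _sha256(p) for p in files},
    }
    path = workdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_all(config: Optional[dict] = None, workdir: str | Path = "results") -> Path:
    """Run the full pipeline (simulating inputs if configured) in ``workdir``.

    Returns the manifest path.  Any stage failure aborts with the stage
    name attached.
    """
    config = merge_config(config)
    workdir = Path(workdir)
    if config.get("simulate") is not None and not (workdir / "matrix.tsv").exists():
        stage_simulate(config, workdir)
    for name, stage in STAGES.items():
        try:
            stage(config, workdir)
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return write_manifest(config, workdir)
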