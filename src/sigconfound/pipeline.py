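"""End-to-end driver: filter -> TMM -> logCPM -> PCA -> outlier removal ->
precision weights -> residualization -> differential expression (global +
toxicology subgroups) -> signature scores + group tests -> consensus modules
-> eigengene association -> convergence classification -> enrichment ->
deconvolution -> proportion tests.

Stages communicate via TSV/JSON files in the output directory, so any stage
can be re-run or audited; a manifest records the config snapshot, seed,
stage dimensions, and SHA-256 digests of every output.  Outputs are pure
functions of (inputs, config, seed) and byte-identical across reruns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .consensus import (
    classify_convergence,
    consensus_tom,
    detect_modules,
    eigengene_association,
    module_eigengenes,
    signed_adjacency,
    topological_overlap,
)
from .deconv import build_reference_profiles, compare_proportions, estimate_proportions
from .diffexpr import cross_concordance, fit_contrast, subgroup_contrasts
from .enrich import enrich_collection, gwas_overlap
from .preprocess import detect_outliers, filter_genes, log_cpm, pca_scores, tmm_factors, voom_weights
from .residualize import design_matrix, residualize, select_covariates_sequential
from .signature import group_test_report, signature_scores
from .synthetic import SimulationConfig, simulate_paired_species, simulate_reference

HUMAN_COVARIATES = ["batch", "sex", "age", "effective_mapping_rate",
                    "intergenic_rate", "rin", "pmi", "ph"]
MACAQUE_COVARIATES = ["batch", "sex", "effective_mapping_rate", "intergenic_rate", "rin"]
TECHNICAL_COVARIATES = ["batch", "effective_mapping_rate", "intergenic_rate", "rin", "pmi", "ph"]


def default_config() -> dict:
    return {
        "seed": 0,
        "simulate": {"enabled": True, "n_genes": 1200, "n_de_genes": 120},
        "preprocess": {
            "a": {"cpm_threshold": 1.0, "min_fraction": 0.5, "outlier_sd": 5.0},
            "b": {"cpm_threshold": 1.0, "min_samples": 3, "outlier_sd": 3.0},
            "prior_count": 0.5, "n_pcs": 20,
        },
        "residualize": {"mode": "paper-faithful", "alpha": 0.05, "use_weights": True},
        "de": {"moderation": True, "p_threshold": 0.05},
        "modules": {"beta_power": 12, "min_size": 30, "merge_cut": 0.25,
                    "min_kme": 0.3, "scale_quantile": 0.95, "t_threshold": 2.0},
        "enrich": {"min_hits": 4},
        "deconv": {"enabled": True},
    }


def load_config(path: str | Path | None) -> dict:
    config = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, block in user.items():
            if isinstance(block, dict) and isinstance(config.get(key), dict):
                for sub, val in block.items():
                    if isinstance(val, dict) and isinstance(config[key].get(sub), dict):
                        config[key][sub].update(val)
                    else:
                        config[key][sub] = val
            else:
                config[key] = block
    return config


def simulate_bundle(config: dict, out_dir: Path, seed: int) -> dict[str, Path]:
    """Write a complete synthetic input bundle in the formats the readers accept."""
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_block = {k: v for k, v in config.get("simulate", {}).items() if k != "enabled"}
    sim = SimulationConfig(**sim_block, seed=seed)
    (a_cm, a_meta), (b_cm, b_meta), omap, truth = simulate_paired_species(sim, seed)
    reference, bulk_cm, bulk_meta, ref_truth = simulate_reference(sim, seed)

    paths = {}

    def _write(name: str, writer, *args):
        path = out_dir / name
        writer(*args, path)
        paths[name] = path
        return path

    _write("counts_a.tsv", io.write_counts, a_cm)
    _write("metadata_a.tsv", io.write_metadata, a_meta)
    _write("counts_b.tsv", io.write_counts, b_cm)
    _write("metadata_b.tsv", io.write_metadata, b_meta)
    _write("orthology.tsv", io.write_orthology, omap)
    # planted modules as a GMT collection over dataset-A identifiers
    sets, descs = {}, {}
    for m in range(1, int(truth.module_labels.max()) + 1):
        genes = [g for g, lab in zip(a_cm.gene_ids, truth.module_labels) if lab == m]
        if genes:
            sets[f"planted_M{m}"] = genes
            descs[f"planted_M{m}"] = "planted co-expression module"
    if sets:
        io.write_gene_sets(io.GeneSetCollection(sets, descs), out_dir / "planted_modules.gmt")
        paths["planted_modules.gmt"] = out_dir / "planted_modules.gmt"
        first = next(iter(sets.values()))
        (out_dir / "prioritized_genes.txt").write_text("\n".join(first) + "\n")
        paths["prioritized_genes.txt"] = out_dir / "prioritized_genes.txt"
    # ground truth for audit
    io.write_table(pd.DataFrame({
        "gene_id": a_cm.gene_ids, "true_lfc": truth.true_lfc,
        "de": truth.de_mask.astype(int), "module": truth.module_labels,
    }), out_dir / "truth_genes.tsv", index=False)
    # deconvolution inputs
    ref_df = pd.DataFrame(reference.counts.T, index=reference.gene_ids,
                          columns=[f"cell{i:04d}" for i in range(reference.counts.shape[0])])
    ref_df.to_csv(out_dir / "reference_counts.tsv", sep="\t", index_label="gene_id")
    paths["reference_counts.tsv"] = out_dir / "reference_counts.tsv"
    pd.DataFrame({"cell_id": ref_df.columns, "cell_type": reference.cell_types}).to_csv(
        out_dir / "reference_labels.tsv", sep="\t", index=False)
    paths["reference_labels.tsv"] = out_dir / "reference_labels.tsv"
    _write("bulk_mixtures.tsv", io.write_counts, bulk_cm)
    _write("bulk_metadata.tsv", io.write_metadata, bulk_meta)
    io.write_table(ref_truth.true_proportions, out_dir / "truth_proportions.tsv",
                   index_label="sample_id")
    paths["truth_proportions.tsv"] = out_dir / "truth_proportions.tsv"
    return paths


def preprocess_dataset(counts: io.CountMatrix, meta: io.SampleTable, block: dict,
                       prior_count: float, n_pcs: int):
    """filter -> TMM -> logCPM -> PCA -> outlier removal; returns the kept
    data plus per-stage artifacts."""
    filtered = filter_genes(counts, cpm_threshold=block.get("cpm_threshold", 1.0),
                            min_fraction=block.get("min_fraction"),
                            min_samples=block.get("min_samples"))
    factors = tmm_factors(filtered)
    norm = log_cpm(filtered, factors, prior_count=prior_count)
    pca = pca_scores(norm, n_components=n_pcs)
    outliers = detect_outliers(pca, sd_threshold=block.get("outlier_sd", 5.0))
    keep = [s for s in filtered.sample_ids if s not in outliers]
    if outliers:
        filtered = filtered.subset_samples(keep)
        factors = tmm_factors(filtered)
        norm = log_cpm(filtered, factors, prior_count=prior_count)
        pca = pca_scores(norm, n_components=n_pcs)
    meta = meta.aligned_to(filtered.sample_ids)
    return filtered, meta, norm, pca, outliers


def run_all(config: dict, out_dir: str | Path, seed: int | None = None) -> io.RunManifest:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))
    manifest = io.RunManifest(config=config, seed=seed, version=__version__)
    notes = manifest.notes

    # ---- inputs ------------------------------------------------------------
    if config.get("simulate", {}).get("enabled", False):
        input_paths = simulate_bundle(config, out_dir / "inputs", seed)
    else:
        input_paths = {k: Path(v) for k, v in config["inputs"].items()}
    for name, path in sorted(input_paths.items()):
        if Path(path).exists():
            manifest.input_digests[str(name)] = io.file_digest(path)

    def _path(name: str) -> Path | None:
        for key, p in input_paths.items():
            if Path(key).name == name or Path(p).name == name:
                return Path(p)
        return None

    counts_a = io.read_counts(_path("counts_a.tsv"))
    meta_a = io.read_metadata(_path("metadata_a.tsv")).aligned_to(counts_a.sample_ids)
    counts_b = meta_b = None
    if _path("counts_b.tsv") is not None:
        counts_b = io.read_counts(_path("counts_b.tsv"))
        meta_b = io.read_metadata(_path("metadata_b.tsv")).aligned_to(counts_b.sample_ids)

    # ---- preprocess --------------------------------------------------------
    pp = config["preprocess"]
    a_counts, meta_a, norm_a, pca_a, out_a = preprocess_dataset(
        counts_a, meta_a, pp["a"], pp["prior_count"], pp["n_pcs"])
    manifest.record_stage("filtered_a", a_counts.shape)
    io.write_table(norm_a.logcpm, out_dir / "logcpm_a.tsv", index_label="gene_id")
    io.write_table(pca_a.scores, out_dir / "pca_a.tsv", index_label="sample_id")
    pd.Series(out_a, dtype=str, name="outlier").to_csv(out_dir / "outliers_a.tsv", sep="\t", index=False)
    if counts_b is not None:
        b_counts, meta_b, norm_b, pca_b, out_b = preprocess_dataset(
            counts_b, meta_b, pp["b"], pp["prior_count"], pp["n_pcs"])
        manifest.record_stage("filtered_b", b_counts.shape)
        io.write_table(norm_b.logcpm, out_dir / "logcpm_b.tsv", index_label="gene_id")

    # ---- residualization ---------------------------------------------------
    res_cfg = config["residualize"]
    weights_a = None
    if res_cfg.get("use_weights", True):
        design_a, _ = design_matrix(meta_a, ["diagnosis"])
        weights_a = voom_weights(a_counts, norm_a.tmm_factors, design_a)
    if res_cfg["mode"] == "paper-faithful":
        covs_a = [c for c in HUMAN_COVARIATES if meta_a.frame[c].nunique() > 1]
    else:
        selection = select_covariates_sequential(
            norm_a.logcpm, meta_a, HUMAN_COVARIATES, alpha=res_cfg["alpha"])
        covs_a = selection.selected
        notes.append(f"data-driven covariates (A): {covs_a}")
    resid_a = residualize(norm_a.logcpm, meta_a, covs_a, weights=weights_a)
    io.write_table(resid_a.residuals, out_dir / "residuals_a.tsv", index_label="gene_id")
    manifest.record_stage("residuals_a", resid_a.residuals.shape)
    if counts_b is not None:
        covs_b = [c for c in MACAQUE_COVARIATES if meta_b.frame[c].nunique() > 1]
        resid_b = residualize(norm_b.logcpm, meta_b, covs_b)
        io.write_table(resid_b.residuals, out_dir / "residuals_b.tsv", index_label="gene_id")

    # ---- differential expression -------------------------------------------
    de_cfg = config["de"]
    de_a = fit_contrast(resid_a.residuals, meta_a, ("diagnosis", "case", "control"),
                        moderation=de_cfg["moderation"])
    io.write_table(de_a.table, out_dir / "de_case_vs_control.tsv", index_label="gene_id")
    manifest.record_stage("de_a", de_a.table.shape)
    for level, de_sub in subgroup_contrasts(resid_a.residuals, meta_a,
                                            moderation=de_cfg["moderation"]).items():
        io.write_table(de_sub.table, out_dir / f"de_subgroup_{level}.tsv", index_label="gene_id")

    # ---- signature ----------------------------------------------------------
    scores = signature_scores(resid_a.residuals, de_a, p_threshold=de_cfg["p_threshold"])
    io.write_table(scores.scores.rename("signature").to_frame(),
                   out_dir / "signature_scores.tsv", index_label="sample_id")
    report = group_test_report(scores.scores, meta_a)
    io.write_table(report, out_dir / "signature_tests.tsv", index=False)
    manifest.record_stage("signature", [len(scores.scores), scores.n_genes_used])

    # ---- consensus modules ---------------------------------------------------
    ortho_path = _path("orthology.tsv")
    if counts_b is None or ortho_path is None or not ortho_path.exists():
        notes.append("module stage skipped: no second dataset / orthology map")
    else:
        omap = io.read_orthology(ortho_path)
        a2b = omap.a_to_b
        genes_a = [g for g in resid_a.residuals.index
                   if g in a2b and a2b[g] in resid_b.residuals.index]
        tech_a = residualize(norm_a.logcpm.loc[genes_a], meta_a,
                             [c for c in TECHNICAL_COVARIATES if meta_a.frame[c].nunique() > 1])
        genes_b = [a2b[g] for g in genes_a]
        tech_b_all = residualize(
            norm_b.logcpm.loc[genes_b], meta_b,
            [c for c in TECHNICAL_COVARIATES
             if c in meta_b.frame.columns and meta_b.frame[c].nunique() > 1])
        expr_a = tech_a.residuals
        expr_b = tech_b_all.residuals.set_axis(genes_a, axis=0)  # dataset-A ids

        mod_cfg = config["modules"]
        net_a = signed_adjacency(expr_a, beta_power=mod_cfg["beta_power"])
        net_b = signed_adjacency(expr_b, beta_power=mod_cfg["beta_power"])
        tom_a = topological_overlap(net_a.adjacency)
        tom_b = topological_overlap(net_b.adjacency)
        cons = consensus_tom(tom_a, tom_b, scale_quantile=mod_cfg["scale_quantile"])
        assignment = detect_modules(cons, expr_a, expr_b, min_size=mod_cfg["min_size"],
                                    merge_cut=mod_cfg["merge_cut"], min_kme=mod_cfg["min_kme"])
        io.write_table(assignment.labels.rename("module").to_frame(),
                       out_dir / "module_assignment.tsv", index_label="gene_id")
        manifest.record_stage("modules", [int((assignment.labels != "unassigned").sum()),
                                          len(assignment.module_sizes)])
        if len(assignment.module_sizes):
            eig_a = module_eigengenes(expr_a, assignment.labels)
            eig_b = module_eigengenes(expr_b, assignment.labels)
            io.write_table(eig_a.eigengenes, out_dir / "eigengenes_a.tsv", index_label="module")
            io.write_table(eig_b.eigengenes, out_dir / "eigengenes_b.tsv", index_label="module")
            assoc_a = eigengene_association(eig_a.eigengenes, meta_a, "diagnosis")
            cond_b = "treatment" if "treatment" in meta_b.frame.columns else "diagnosis"
            assoc_b = eigengene_association(eig_b.eigengenes, meta_b, cond_b)
            io.write_table(assoc_a, out_dir / "eigengene_assoc_a.tsv", index=False)
            io.write_table(assoc_b, out_dir / "eigengene_assoc_b.tsv", index=False)
            conv = classify_convergence(assoc_a, assoc_b, t_threshold=mod_cfg["t_threshold"])
            io.write_table(conv, out_dir / "convergence.tsv", index=False)

            de_b = fit_contrast(resid_b.residuals, meta_b,
                                ("diagnosis", "case", "control"),
                                moderation=de_cfg["moderation"])
            r, rho, n_matched = cross_concordance(de_a, de_b, omap)
            (out_dir / "concordance.json").write_text(json.dumps(
                {"pearson_r": r, "spearman_rho": rho, "n_matched": n_matched}, indent=2))

            # enrichment of detected modules against supplied collections
            module_lists = {m: list(assignment.labels.index[assignment.labels == m])
                            for m in assignment.module_sizes.index}
            background = genes_a  # one-to-one orthologs, all expressed
            gmt_path = _path("planted_modules.gmt")
            if gmt_path is not None and gmt_path.exists():
                collection = io.read_gene_sets(gmt_path)
                enr = enrich_collection(module_lists, collection, background,
                                        min_hits=config["enrich"]["min_hits"])
                io.write_table(enr, out_dir / "module_enrichment.tsv", index=False)
            pri_path = _path("prioritized_genes.txt")
            if pri_path is not None and pri_path.exists():
                prioritized = pri_path.read_text().split()
                gw = gwas_overlap(module_lists, prioritized, background)
                io.write_table(gw, out_dir / "gwas_overlap.tsv", index=False)

    # ---- deconvolution -------------------------------------------------------
    if config.get("deconv", {}).get("enabled", True) and _path("bulk_mixtures.tsv"):
        ref_counts = pd.read_csv(_path("reference_counts.tsv"), sep="\t", index_col=0)
        labels = pd.read_csv(_path("reference_labels.tsv"), sep="\t")
        from .deconv import CellTypeReference
        reference = CellTypeReference(
            counts=ref_counts.to_numpy().T, gene_ids=list(ref_counts.index),
            cell_types=list(labels["cell_type"]))
        profiles = build_reference_profiles(reference)
        bulk = io.read_counts(_path("bulk_mixtures.tsv"))
        props = estimate_proportions(bulk, profiles)
        io.write_table(props.proportions, out_dir / "proportions.tsv", index_label="sample_id")
        bulk_meta = io.read_metadata(_path("bulk_metadata.tsv")).aligned_to(bulk.sample_ids)
        prop_tests = compare_proportions(props, bulk_meta)
        io.write_table(prop_tests, out_dir / "proportion_tests.tsv", index=False)
        manifest.record_stage("proportions", props.proportions.shape)

    for out_file in sorted(out_dir.glob("*.tsv")) + sorted(out_dir.glob("*.json")):
        manifest.record_output(out_file.name, out_file)
    manifest.write(out_dir / "manifest.json")
    return manifest
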