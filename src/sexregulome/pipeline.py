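"""End-to-end orchestration: simulate -> differential accessibility -> CRD ->
TRD -> ABC -> enrichment, with a manifest and a plain-text report.

Every stage reads from and writes to plain TSV/BED files under the output
directory, so a run is resumable and each stage is independently auditable.
All randomness flows from the single ``seed`` entry in the config.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from sexregulome import __version__
from sexregulome.abc_model import ContactMap, GenePromoter, abc_all_genes, compare_sex_links, landscape_stats
from sexregulome.crd import call_crds, crds_to_table, residualize_covariates, stagewise_test
from sexregulome.diffacc import (DesignSpec, estimate_precision_weights, filter_low_accessibility,
                                 fit_per_feature_model, normalize_log_cpm, stratify_by_chromosome)
from sexregulome.enrich import ocr_in_crd_enrichment
from sexregulome.fileio import RunManifest, save_config, write_table
from sexregulome.synth import SimConfig, simulate_abc_inputs, simulate_study, write_fixture
from sexregulome.trd import assign_and_summarize, crd_correlation_matrix, gamma_trace_table, select_k

log = logging.getLogger("sexregulome")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "run_out",
    "simulate": {
        "n_individuals": 60,
        "sex_effect_log2fc": 1.0,
        "scz_effect_log2fc": 0.6,
        "sex_scz_effect_correlation": 0.5,
        "n_ocrs_autosome": 210,
        "n_ocrs_X": 60,
        "n_ocrs_Y": 10,
        "crd_blocks": [["chr1", 6, 0.75], ["chr1", 5, 0.75], ["chr2", 6, 0.75],
                       ["chr3", 5, 0.75], ["chrX", 6, 0.75], ["chrX", 5, 0.75]],
        "trd_groups": [[[0, 2], 0.55], [[4, 5], 0.55]],
        "sex_effect_block_ids": [0, 2, 4, 5],
    },
    "diffacc": {"min_cpm": 1.0, "min_sample_fraction": 0.25, "fdr": 0.05,
                "covariates": ["sex", "diagnosis", "region", "frip", "gc_content"]},
    "crd": {"max_pair_distance_bp": 250_000, "min_mean_abs_corr": 0.3,
            "min_members": 2, "alpha": 0.05},
    "trd": {"k_min": 2, "k_max": 20},
    "abc": {"window": 5e6, "threshold": 0.02},
}


def _merged_config(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def run_pipeline(config: dict | None = None) -> RunManifest:
    """Run every stage on a simulated study and write all outputs.

    Returns the run manifest (checksums of every emitted file).
    """
    cfg = _merged_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, outdir / "config_used.yaml")
    emitted: list[Path] = [outdir / "config_used.yaml"]

    sim_kwargs = dict(cfg["simulate"])
    sim_kwargs["crd_blocks"] = tuple(tuple(b) for b in sim_kwargs.get("crd_blocks", ()))
    sim_kwargs["trd_groups"] = tuple((tuple(m), r) for m, r in sim_kwargs.get("trd_groups", ()))
    sim_kwargs["sex_effect_block_ids"] = tuple(sim_kwargs.get("sex_effect_block_ids", ()))
    sim = SimConfig(seed=int(cfg["seed"]), **sim_kwargs)
    log.info("simulating study: %d individuals, %d OCRs", sim.n_individuals,
             sim.n_ocrs_autosome + sim.n_ocrs_X + sim.n_ocrs_Y)
    study = simulate_study(sim)
    emitted += list(write_fixture(study, outdir / "fixture").values())

    # --- differential accessibility, sex and diagnosis contrasts
    da = cfg["diffacc"]
    retained = filter_low_accessibility(study.counts, da["min_cpm"], da["min_sample_fraction"])
    counts = study.counts.loc[retained]
    logcpm = normalize_log_cpm(counts)
    st = study.sample_table
    results = {}
    for contrast in ("sex", "diagnosis"):
        design = DesignSpec(fixed_covariates=tuple(da["covariates"]), contrast=contrast,
                            grouping="individual")
        X, _, _ = design.build_matrix(st)
        w = estimate_precision_weights(logcpm, X)
        res = fit_per_feature_model(logcpm, w, st, design, fdr_threshold=da["fdr"],
                                    ocr_bed=study.ocr_bed)
        results[contrast] = res
        write_table(res.reset_index(drop=True), outdir / f"diffacc_{contrast}.tsv")
        emitted.append(outdir / f"diffacc_{contrast}.tsv")
    strat = stratify_by_chromosome(results["sex"])
    log.info("sex-specific OCRs: %s", strat)

    # --- CRDs on covariate-corrected log-CPM (sex signal retained)
    cc = cfg["crd"]
    nuisance = tuple(c for c in da["covariates"] if c not in ("sex",))
    design_sex = DesignSpec(fixed_covariates=tuple(da["covariates"]), contrast="sex",
                            grouping="individual")
    corrected = residualize_covariates(logcpm, st, nuisance, design=DesignSpec(
        fixed_covariates=tuple(da["covariates"]), contrast="sex"))
    bed_retained = study.ocr_bed[study.ocr_bed["name"].isin(retained)]
    crds = call_crds(corrected, bed_retained, cc["max_pair_distance_bp"],
                     cc["min_mean_abs_corr"], cc["min_members"])
    stage = stagewise_test(results["sex"], crds, corrected, st, design_sex, cc["alpha"])
    write_table(crds_to_table(crds), outdir / "crds.tsv")
    emitted.append(outdir / "crds.tsv")

    # --- TRDs from sex-specific CRDs (falls back to all CRDs on tiny runs)
    tc = cfg["trd"]
    sex_crds = [c for c in crds if c.sex_label != "ns"]
    trd_source = sex_crds if len(sex_crds) >= 3 else crds
    summaries, assignment = [], None
    if len(trd_source) >= 3:
        scores = pd.DataFrame(np.vstack([c.per_sample_score for c in trd_source]),
                              index=[c.crd_id for c in trd_source], columns=corrected.columns)
        corr = crd_correlation_matrix(scores)
        assignment = select_k(corr, tc["k_min"], tc["k_max"])
        summaries = assign_and_summarize(assignment, trd_source, results["sex"],
                                         results["diagnosis"])
        write_table(pd.DataFrame([{"crd_id": k, "trd_id": v}
                                  for k, v in assignment.labels.items()]),
                    outdir / "trd_assignment.tsv")
        write_table(gamma_trace_table(assignment), outdir / "trd_gamma_trace.tsv")
        write_table(pd.DataFrame([s.__dict__ for s in summaries]), outdir / "trd_summary.tsv")
        emitted += [outdir / "trd_assignment.tsv", outdir / "trd_gamma_trace.tsv",
                    outdir / "trd_summary.tsv"]

    # --- ABC per sex on toy activity/contact inputs
    ac = cfg["abc"]
    abc_in = simulate_abc_inputs(sim)
    cmap = ContactMap.from_table(abc_in.contacts, abc_in.resolution)
    genes = [GenePromoter(r.gene_id, r.chrom, int(r.tss), r.strand, bool(r.ubiquitous))
             for r in abc_in.genes.itertuples(index=False)]
    links = {}
    for sex in ("female", "male"):
        elems = abc_in.elements.rename(columns={f"activity_{sex}": "activity"})
        links[sex] = abc_all_genes(elems, genes, cmap, ac["window"], ac["threshold"])
        write_table(links[sex], outdir / f"abc_links_{sex}.tsv")
        emitted.append(outdir / f"abc_links_{sex}.tsv")
    sharing = compare_sex_links(links["female"], links["male"])

    # --- enrichment: sex-specific OCRs inside sex-specific CRDs
    membership = pd.Series({o: c.crd_id for c in crds for o in c.member_ocr_ids})
    sex_flags = results["sex"]["sex_label"] != "ns"
    enr = None
    if membership.reindex(sex_flags.index).notna().any():
        enr = ocr_in_crd_enrichment(sex_flags, membership,
                                    {c.crd_id for c in sex_crds})

    report_text = report(strat=strat, crds=crds, stage=stage, assignment=assignment,
                         summaries=summaries, sharing=sharing,
                         links=links, enrichment=enr)
    (outdir / "report.md").write_text(report_text, encoding="utf-8")
    emitted.append(outdir / "report.md")

    manifest = RunManifest.collect(__version__, cfg, emitted)
    manifest.save(outdir / "manifest.json")
    return manifest


def report(strat: dict, crds, stage, assignment, summaries, sharing,
           links, enrichment) -> str:
    """Markdown summary of one run; every count is recomputed from the
    stage outputs passed in, so the report reconciles with the TSVs."""
    lines = ["# sexregulome run report", ""]
    lines += ["## Differential accessibility (sex contrast)", ""]
    lines.append(f"- significant OCRs: {strat['total']}")
    for cls in ("X", "Y", "autosome"):
        lines.append(f"  - {cls}: {strat['counts'][cls]} ({strat['percentages'][cls]}%)")
    lines += ["", "## Cis-regulatory domains", ""]
    n_sex_crd = sum(c.sex_label != "ns" for c in crds)
    lines.append(f"- CRDs called: {len(crds)}")
    lines.append(f"- screened (stage 1, FDR < {stage.alpha}): {len(stage.screened_ids)}")
    lines.append(f"- sex-specific (stage 2 p < {stage.alpha}): {n_sex_crd}")
    lines.append(f"  - female-specific: {sum(c.sex_label == 'female-specific' for c in crds)}")
    lines.append(f"  - male-specific: {sum(c.sex_label == 'male-specific' for c in crds)}")
    lines += ["", "## Trans-regulatory domains", ""]
    if assignment is not None:
        lines.append(f"- k selected by Gamma index: {assignment.k_selected}")
        trace = ", ".join(f"k={g.k}: {g.gamma:.3f}" for g in assignment.gamma_trace[:8])
        lines.append(f"- gamma trace (head): {trace}")
        for s in summaries:
            lines.append(f"  - TRD{s.trd_id}: {s.n_crds_female}F/{s.n_crds_male}M CRDs, "
                         f"{s.n_sex_ocrs_female}F/{s.n_sex_ocrs_male}M sex-specific OCRs")
    else:
        lines.append("- too few CRDs to cluster (section skipped)")
    lines += ["", "## Enhancer-promoter links (ABC)", ""]
    lines.append(f"- links: female {sharing['n_female']}, male {sharing['n_male']}, "
                 f"shared {sharing['n_shared']} "
                 f"(shared fraction {sharing['shared_fraction']:.2f})")
    lines.append(f"- ABC score Spearman rho: union {sharing['spearman_union']:.2f}, "
                 f"intersection {sharing['spearman_intersection']:.2f}")
    for sex in ("female", "male"):
        if not links[sex].empty:
            ls = landscape_stats(links[sex])
            lines.append(f"- {sex}: {ls['n_links']} links, "
                         f"{100 * ls['frac_within_100kb']:.0f}% within 100 kb of the TSS, "
                         f"{100 * ls['frac_nearest_gene']:.0f}% to the nearest gene")
    lines += ["", "## Enrichment", ""]
    if enrichment is not None:
        t = enrichment.table
        lines.append(f"- sex-specific OCRs inside sex-specific CRDs: "
                     f"OR = {enrichment.odds_ratio:.2f}, p = {enrichment.p:.3g} "
                     f"(table a={t.a}, b={t.b}, c={t.c}, d={t.d})")
    else:
        lines.append("- no CRD membership available (section skipped)")
    lines.append("")
    return "\n".join(lines)
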