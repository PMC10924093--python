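"""End-to-end orchestration of the discovery workflow.

Stage order: simulate/load -> genotype QC -> per-SNP CCA (and the
summary-statistic engine when summary inputs are present) -> direction
filter -> significance -> replication -> clumping -> colocalisation ->
overlap enrichment -> differential expression / allele-frequency
follow-up. Each enabled stage writes a TSV next to the manifest, and
the manifest records per-stage counts plus the fully resolved
configuration, so a run is auditable and exactly repeatable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import discovery, downstream, enrichment
from .cca import SnpCcaScan
from .containers import DomainError
from .io import write_results_table
from .metacca import MetaCcaScan
from .qc import filter_variants_qc
from .simulate import (
    CohortSpec,
    simulate_eqtl_pair,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_summary_stats,
)
from .coloc import coloc_abf, extract_region

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

#: Defaults for every stage, matching the analysis conventions the
#: package implements (QC thresholds, genome-wide and nominal levels,
#: clumping r2 values, coloc window/priors, DE and AF gates).
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "pipeline_out",
    "cohort": {
        "n_samples": 1000,
        "n_snps": 5000,
        "n_causal": 20,
        "effect_size": 0.15,
        "direction_mode": "opposite",
        "pheno_corr": -0.5,
        "ld_block_size": 10,
        "ld_rho": 0.4,
        "case_fraction": 0.5,
        "missing_rate": 0.0,
    },
    "qc": {"maf_min": 0.01, "max_missing": 0.015, "hwe_alpha": 1e-5},
    "cca": {"adjust": "bonferroni_by_count", "alpha": 0.05},
    "discovery": {
        "direction_filter": True,
        "replication_alpha": 0.05,
        "r2_indep": 0.6,
        "r2_lead": 0.1,
        "merge_kb": 250,
    },
    "coloc": {
        "enabled": True,
        "window_bp": 200_000,
        "p1": 1e-4,
        "p2": 1e-4,
        "p12": 1e-6,
        "pp4_threshold": 0.8,
    },
    "overlap": {"enabled": True},
    "expression": {
        "enabled": True,
        "n_genes": 500,
        "n_case": 10,
        "n_control": 10,
        "de_fraction": 0.05,
        "true_lfc": 1.2,
        "sigma": 0.2,
        "lfc_threshold": 1.0,
        "alpha": 0.05,
    },
    "af": {"shortlist_diff": 0.10, "report_diff": 0.15},
}


def _merge_validate(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        if key not in base:
            raise DomainError(f"unknown configuration key: {path}{key}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise DomainError(f"configuration section {path}{key} must be a mapping")
            out[key] = _merge_validate(base[key], val, f"{path}{key}.")
        else:
            out[key] = val
    return out


def load_config(path_or_dict) -> dict:
    """Resolve a user YAML/dict config against the defaults, validating keys."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    return _merge_validate(DEFAULT_CONFIG, user)


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the full synthetic-cohort workflow; returns the manifest."""
    cfg = load_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    counts: dict = {}

    spec = CohortSpec(seed=seed, **cfg["cohort"])
    g_raw = simulate_genotypes(spec)
    counts["simulated_variants"] = g_raw.n_variants
    counts["simulated_samples"] = g_raw.n_samples

    g, qc_report = filter_variants_qc(g_raw, **cfg["qc"])
    counts["qc"] = qc_report.as_dict()

    sim_ph = simulate_phenotypes(g, spec)
    pheno = sim_ph.phenotypes

    scan = SnpCcaScan(g, pheno).fit(adjust=cfg["cca"]["adjust"])
    write_results_table(scan.table, out_dir / "cca.tsv")
    counts["cca_tested"] = len(scan.table)

    sumstats = simulate_summary_stats(g, pheno)
    meta = MetaCcaScan(sumstats).fit(adjust=cfg["cca"]["adjust"])
    write_results_table(meta.table, out_dir / "metacca.tsv")
    counts["metacca_tested"] = len(meta.table)

    sig = scan.significant(alpha=cfg["cca"]["alpha"]).reset_index(drop=True)
    counts["significant"] = len(sig)

    key = ["chrom", "pos", "ref", "ea"]
    sig_dir = sig.merge(
        sumstats[key + ["beta_egfr", "beta_bun"]], on=key, how="left"
    )
    if cfg["discovery"]["direction_filter"]:
        sig_dir = discovery.opposite_direction_filter(sig_dir)
    counts["direction_filtered"] = len(sig_dir)
    write_results_table(sig_dir, out_dir / "significant.tsv") if len(sig_dir) else None

    replicated, untestable = discovery.replicate_nominal(
        sig_dir, {"metacca": meta.table}, alpha=cfg["discovery"]["replication_alpha"]
    )
    counts["replicated"] = len(replicated)
    counts["untestable"] = len(untestable)

    if len(sig_dir):
        loci = discovery.clump_lead_snps(
            sig_dir, g,
            r2_indep=cfg["discovery"]["r2_indep"],
            r2_lead=cfg["discovery"]["r2_lead"],
            merge_kb=cfg["discovery"]["merge_kb"],
        )
        write_results_table(loci.to_frame(), out_dir / "loci.tsv")
        counts["independent_significant"] = int(sum(len(l.independent) for l in loci.loci))
        counts["leads"] = len(loci.loci)
    else:
        counts["independent_significant"] = 0
        counts["leads"] = 0

    if cfg["coloc"]["enabled"]:
        r_gwas, r_eqtl = simulate_eqtl_pair(shared=True, seed=seed)
        res = coloc_abf(
            r_gwas, r_eqtl,
            p1=cfg["coloc"]["p1"], p2=cfg["coloc"]["p2"], p12=cfg["coloc"]["p12"],
            pp4_threshold=cfg["coloc"]["pp4_threshold"],
        )
        counts["coloc"] = res.as_dict()

    if cfg["overlap"]["enabled"] and len(sig):
        set_a = set(sig["rsid"])
        set_b = set(meta.significant(alpha=cfg["cca"]["alpha"])["rsid"])
        obs = len(set_a & set_b)
        if set_a and set_b:
            ov = enrichment.overlap_test(obs, (len(set_a), len(set_b)), counts["cca_tested"])
            counts["overlap"] = ov.as_dict()

    if cfg["expression"]["enabled"]:
        ecfg = cfg["expression"]
        expr, groups, truth = simulate_expression(
            n_genes=ecfg["n_genes"], n_case=ecfg["n_case"], n_control=ecfg["n_control"],
            de_fraction=ecfg["de_fraction"], true_lfc=ecfg["true_lfc"],
            sigma=ecfg["sigma"], seed=seed,
        )
        de = downstream.differential_expression(
            expr, groups, lfc_threshold=ecfg["lfc_threshold"], alpha=ecfg["alpha"]
        )
        write_results_table(de, out_dir / "de.tsv")
        counts["de_pass"] = int(de["passes"].sum())
        counts["de_truth"] = int(truth.sum())

    # allele-frequency follow-up on the top surviving SNP, cases vs a
    # pseudo-reference built from the whole cohort
    if len(sig_dir):
        top = sig_dir.nsmallest(1, "p").iloc[0]
        j = int(
            np.flatnonzero(
                (g.variants["chrom"] == top["chrom"]) & (g.variants["pos"] == top["pos"])
            )[0]
        )
        cases = [s for s, c in zip(pheno.samples, pheno.case_indicator) if c == 1]
        cohort_af = downstream.allele_freq(g, j, subgroup=cases)
        ref_af = downstream.allele_freq(g, j)
        cmp_res = downstream.af_comparison(
            cohort_af, ref_af,
            shortlist_diff=cfg["af"]["shortlist_diff"],
            report_diff=cfg["af"]["report_diff"],
        )
        counts["af_comparison"] = {
            "af_diff": cmp_res.af_diff,
            "shortlisted": cmp_res.shortlisted,
            "significant": cmp_res.significant,
        }

    manifest = {"config": cfg, "counts": counts}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
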