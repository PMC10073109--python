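"""End-to-end orchestration: preprocess -> differential calls (both
studies) -> directional intersection -> promoter-region means ->
classification/association -> signature derivation/scoring/association.

``run_analysis`` works on in-memory objects and returns a nested report
dict; ``run_pipeline`` is the file-based wrapper that loads inputs,
executes the same stages, writes every intermediate artifact plus a JSON
report, and is byte-reproducible for a fixed config and seed (the report
carries no timestamps).  ``reversal_recovery``, ``signature_recovery``
and ``null_calibration`` evaluate the pipeline against the synthetic
generator's planted truth and back the package's operating
characteristics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import io as mio
from . import stats as mstats
from .datatypes import AnalysisConfig, BetaMatrix
from .diffmeth import DifferentialTable, call_differential
from .errors import MethrevError
from .preprocess import apply_detection_mask, filter_probes
from .reversal import (
    RegionSpec,
    assign_tss_regions,
    intersect_reversal,
    rank_by_delta,
    region_mean_beta,
)
from .signature import (
    derive_signature,
    evaluate_signature_associations,
    score_signature,
)
from .simulate import (
    DMR_TRANSCRIPT,
    GROUP_MEL,
    GROUP_METASTATIC,
    GROUP_NCC,
    GROUP_PRIMARY,
    MethylationStudy,
    SimConfig,
    simulate_expression,
    simulate_methylation_study,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def preprocess_study(beta: BetaMatrix, detection_p, manifest,
                     config: AnalysisConfig) -> BetaMatrix:
    """Detection masking followed by sex-chromosome/SNP probe removal."""
    if detection_p is not None:
        beta = apply_detection_mask(beta, detection_p, config.detection_alpha)
    return filter_probes(beta, manifest)


def run_methylation_arm(sim: MethylationStudy, config: AnalysisConfig):
    """Preprocess both studies, call differentials, and intersect."""
    clean_a = preprocess_study(sim.beta_a, sim.detection_a, sim.manifest, config)
    clean_b = preprocess_study(sim.beta_b, sim.detection_b, sim.manifest, config)
    dm_a = call_differential(clean_a, sim.sheet, GROUP_NCC, GROUP_MEL,
                             config.delta_min_a, config.q_max,
                             config.min_samples_per_group)
    dm_b = call_differential(clean_b, sim.sheet, GROUP_METASTATIC,
                             GROUP_PRIMARY, config.delta_min_b, config.q_max,
                             config.min_samples_per_group)
    catalog = intersect_reversal(dm_a, dm_b)
    return clean_a, clean_b, dm_a, dm_b, catalog


def run_analysis(sim: MethylationStudy, config: AnalysisConfig,
                 with_expression: bool = True,
                 sim_config: SimConfig | None = None) -> dict:
    """Run every stage on in-memory synthetic data; return the report."""
    clean_a, clean_b, dm_a, dm_b, catalog = run_methylation_arm(sim, config)
    ranked = rank_by_delta(catalog, config.min_combined_delta)
    report: dict = {
        "version": __version__,
        "seed": config.rng_seed,
        "thresholds": {
            "delta_min_a": config.delta_min_a,
            "delta_min_b": config.delta_min_b,
            "q_max": config.q_max,
            "detection_alpha": config.detection_alpha,
            "hypo_cutoff": config.hypo_cutoff,
            "tss_window": list(config.tss_window),
        },
        "differential": {
            "study_a": {
                "groups": [GROUP_NCC, GROUP_MEL],
                "n_tested": int(len(dm_a.table)),
                "n_informative": dm_a.n_informative,
                "n_hyper": len(dm_a.probes_with_direction("hyper")),
                "n_hypo": len(dm_a.probes_with_direction("hypo")),
            },
            "study_b": {
                "groups": [GROUP_METASTATIC, GROUP_PRIMARY],
                "n_tested": int(len(dm_b.table)),
                "n_informative": dm_b.n_informative,
                "n_hyper": len(dm_b.probes_with_direction("hyper")),
                "n_hypo": len(dm_b.probes_with_direction("hypo")),
            },
        },
        "reversal": {
            "n_hyper_in_both": len(catalog.hyper_in_both),
            "n_hypo_in_both": len(catalog.hypo_in_both),
            "top_ranked": ranked[:10],
        },
    }
    logger.info("study A: %d hyper / %d hypo informative CpGs",
                report["differential"]["study_a"]["n_hyper"],
                report["differential"]["study_a"]["n_hypo"])
    logger.info("study B: %d hyper / %d hypo informative CpGs",
                report["differential"]["study_b"]["n_hyper"],
                report["differential"]["study_b"]["n_hypo"])
    logger.info("reversal catalog: %d hyper, %d hypo CpGs in both studies",
                len(catalog.hyper_in_both), len(catalog.hypo_in_both))

    regions = assign_tss_regions(sim.manifest, sim.annotation,
                                 config.tss_window)
    region = next((r for r in regions if r.transcript_id == DMR_TRANSCRIPT
                   and r.member_probes), None)
    if region is None:
        report["region"] = {"note": "no promoter region with member probes"}
        return report

    means_b = region_mean_beta(clean_b, region)
    classes = mstats.classify_hypomethylated(means_b, config.hypo_cutoff)
    groups = sim.sheet.table["group"]
    table = mstats.contingency_by_group(classes, groups,
                                        GROUP_METASTATIC, GROUP_PRIMARY)
    fisher = mstats.fisher_exact_two_sided(*table.ravel())
    row_tot = table.sum(axis=1)
    pct = np.where(row_tot > 0, 100.0 * table[:, 0] / np.maximum(row_tot, 1),
                   np.nan)
    report["region"] = {
        "transcript": region.transcript_id,
        "n_member_probes": len(region.member_probes),
        "contingency": table.tolist(),
        "pct_hypomethylated": {
            GROUP_METASTATIC: round(float(pct[0]), 1),
            GROUP_PRIMARY: round(float(pct[1]), 1),
        },
        "fisher_p": fisher.p_value,
        "odds_ratio": fisher.odds_ratio,
    }
    logger.info("hypomethylated: %s %.1f%%, %s %.1f%% (Fisher p=%.3g)",
                GROUP_METASTATIC, pct[0], GROUP_PRIMARY, pct[1],
                fisher.p_value)

    if not with_expression:
        return report
    sim_config = sim_config or SimConfig(rng_seed=config.rng_seed)
    expr = simulate_expression(sim_config, means_b.dropna(), sim.truth)
    signature = derive_signature(expr.de_tables, config.signature_p_max,
                                 config.signature_max_genes)
    scores = score_signature(expr.expression, signature)
    assoc = evaluate_signature_associations(
        scores,
        region_means=means_b,
        isoform_expression=expr.isoform_expression,
        groups=groups,
        group_pair=(GROUP_METASTATIC, GROUP_PRIMARY),
        hypo_cutoff=config.hypo_cutoff,
    )
    report["signature"] = {
        "n_genes": len(signature),
        "contexts": signature.contexts,
        "associations": assoc,
    }
    # keep heavyweight objects available to callers without json-ifying them
    report["_objects"] = {
        "dm_a": dm_a, "dm_b": dm_b, "catalog": catalog,
        "region_means": means_b, "classes": classes,
        "signature": signature, "scores": scores, "expression": expr,
    }
    return report


# ---------------------------------------------------------------------------
# planted-truth evaluation


def recovery_metrics(catalog, truth) -> dict:
    """Sensitivity and precision of reversal-CpG recovery, direction-aware."""
    called_ok = 0
    for direction in ("hyper", "hypo"):
        called = catalog.hyper_in_both if direction == "hyper" else \
            catalog.hypo_in_both
        called_ok += len(called & truth.planted_with_direction(direction))
    n_called = len(catalog)
    n_true = len(truth.planted_probes)
    return {
        "sensitivity": called_ok / n_true if n_true else float("nan"),
        "precision": called_ok / n_called if n_called else float("nan"),
        "n_called": n_called,
        "n_true": n_true,
    }


def reversal_recovery(seeds, sim_config: SimConfig | None = None,
                      config: AnalysisConfig | None = None) -> dict:
    """Mean sensitivity/precision of end-to-end reversal recovery over
    seeds (precision counts seeds with no calls as perfect-precision
    vacuously and is averaged over seeds that made calls)."""
    config = config or AnalysisConfig()
    sens, prec = [], []
    for seed in seeds:
        sc = (sim_config or SimConfig())
        sc = SimConfig(**{**asdict(sc), "rng_seed": int(seed)})
        sim = simulate_methylation_study(sc)
        *_, catalog = run_methylation_arm(sim, config)
        m = recovery_metrics(catalog, sim.truth)
        sens.append(m["sensitivity"])
        if m["n_called"]:
            prec.append(m["precision"])
    return {
        "sensitivity": float(np.mean(sens)),
        "precision": float(np.mean(prec)) if prec else float("nan"),
        "n_seeds": len(list(seeds)),
    }


def signature_recovery(seed: int, sim_config: SimConfig | None = None,
                       config: AnalysisConfig | None = None) -> dict:
    """Fraction of planted signature genes recovered and of false members."""
    config = config or AnalysisConfig()
    sc = SimConfig(**{**asdict(sim_config or SimConfig()),
                      "rng_seed": int(seed)})
    sim = simulate_methylation_study(sc)
    clean_b = preprocess_study(sim.beta_b, sim.detection_b, sim.manifest, config)
    regions = assign_tss_regions(sim.manifest, sim.annotation, config.tss_window)
    region = next(r for r in regions if r.transcript_id == DMR_TRANSCRIPT)
    means_b = region_mean_beta(clean_b, region)
    expr = simulate_expression(sc, means_b.dropna(), sim.truth)
    signature = derive_signature(expr.de_tables, config.signature_p_max,
                                 config.signature_max_genes)
    planted = set(sim.truth.signature_genes)
    derived = set(signature.genes)
    return {
        "recovered_fraction": len(derived & planted) / len(planted),
        "false_fraction": len(derived - planted) / len(derived) if derived
        else 0.0,
        "n_derived": len(derived),
        "n_planted": len(planted),
    }


def null_calibration(seeds, sim_config: SimConfig | None = None,
                     config: AnalysisConfig | None = None) -> dict:
    """Null behavior with no planted effects: raw-p calibration in the
    large (progression) comparison and the rate of empty reversal
    catalogs at default thresholds."""
    config = config or AnalysisConfig()
    base = asdict(sim_config or SimConfig())
    base.update(n_reversal=0, n_dmr_probes=0)
    fractions, empty = [], 0
    for seed in seeds:
        sc = SimConfig(**{**base, "rng_seed": int(seed)})
        sim = simulate_methylation_study(sc)
        *_, dm_b, catalog = run_methylation_arm(sim, config)
        p = dm_b.table["p_value"].dropna()
        fractions.append(float((p <= 0.05).mean()))
        if len(catalog) == 0:
            empty += 1
    n = len(list(seeds))
    return {
        "raw_p_le_05_fraction": float(np.mean(fractions)),
        "empty_catalog_fraction": empty / n,
        "n_seeds": n,
    }


# ---------------------------------------------------------------------------
# file-based pipeline


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(outdir: str, config: AnalysisConfig,
                 sim_config: SimConfig | None = None) -> dict:
    """Simulate inputs, run every stage, write artifacts and the report.

    All stage outputs land under ``outdir`` as TSV/BED plus
    ``report.json``; any stage failure leaves a ``<stage>.failed`` marker
    naming the stage, and partial outputs are retained.
    """
    mio.ensure_dir(outdir)
    sim_config = sim_config or SimConfig(rng_seed=config.rng_seed)
    stage = "simulate"
    try:
        sim = simulate_methylation_study(sim_config)
        mio.write_beta_matrix(sim.beta_a, os.path.join(outdir, "beta_a.tsv"))
        mio.write_beta_matrix(sim.beta_b, os.path.join(outdir, "beta_b.tsv"))
        mio.write_detection_p(sim.detection_a,
                              os.path.join(outdir, "detection_a.tsv"))
        mio.write_detection_p(sim.detection_b,
                              os.path.join(outdir, "detection_b.tsv"))
        mio.write_probe_manifest(sim.manifest,
                                 os.path.join(outdir, "manifest.tsv"))
        mio.write_sample_sheet(sim.sheet, os.path.join(outdir, "samples.tsv"))
        mio.write_annotation_bed(sim.annotation,
                                 os.path.join(outdir, "annotation.bed"))
        sim.truth.planted.to_csv(os.path.join(outdir, "truth_planted.tsv"),
                                 sep="\t")

        stage = "analysis"
        report = run_analysis(sim, config, sim_config=sim_config)
        objects = report.pop("_objects", None)
        if objects is not None:
            objects["dm_a"].to_tsv(os.path.join(outdir, "dm_a.tsv"))
            objects["dm_b"].to_tsv(os.path.join(outdir, "dm_b.tsv"))
            objects["catalog"].to_tsv(os.path.join(outdir, "reversal.tsv"))
            probes = sorted(objects["catalog"].probe_ids)
            if probes:
                mio.write_probe_bed(sim.manifest, probes,
                                    os.path.join(outdir, "reversal.bed"))
            objects["region_means"].to_csv(
                os.path.join(outdir, "region_means.tsv"), sep="\t")
            objects["signature"].to_tsv(
                os.path.join(outdir, "signature_genes.tsv"))
            objects["scores"].to_tsv(os.path.join(outdir, "scores.tsv"))

        stage = "truth-evaluation"
        report["recovery"] = recovery_metrics(objects["catalog"], sim.truth) \
            if objects is not None else None
        report["config_hash"] = _config_hash(config)
        with open(os.path.join(outdir, "report.json"), "w") as handle:
            json.dump(report, handle, indent=2, sort_keys=True)
        return report
    except MethrevError:
        with open(os.path.join(outdir, f"{stage}.failed"), "w") as handle:
            handle.write(f"stage {stage} failed\n")
        raise
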