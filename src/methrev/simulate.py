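"""Synthetic two-study methylation data with planted reversal CpGs.

The generator emulates the statistical structure the analysis assumes:
two 450K-style beta matrices — a small developmental comparison (NCC vs
melanocyte cultures) and a larger progression comparison (primary vs
metastatic tumors) — over a shared probe manifest.  Marginal beta values
are bimodal, drawn from Beta distributions parameterized by (mean,
concentration) with states near 0.1 and 0.9 (concentration 20 gives
sd ~ 0.065 at mean 0.1).  Background probes share one state across groups
and studies; planted reversal probes flip between a high and a low state
between group1 (the state of interest: NCC / metastatic) and group2,
consistently in BOTH studies, with study-specific effect sizes centred on
0.5 (means 0.5 +/- delta/2).

A handful of planted hypomethylated-reversal probes are placed inside one
transcript's promoter window (-300..+63 bp from its TSS) to emulate the
isoform-2 promoter region; a decoy transcript on another chromosome
collects only background probes.  Detection p-values are near zero except
for a configured fraction of cells pushed above the masking threshold,
and the manifest carries configured fractions of sex-chromosome and
SNP-flagged probes (never overlapping planted probes).

Expression data are coupled to methylation: isoform expression decreases
linearly in the region mean beta, planted signature genes track isoform
expression positively, and paired knockdown DE tables give planted genes
a significant negative log2 fold change in every context while background
genes stay null.

A single seed fans out to per-component child streams, so generated
components never perturb each other's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    BetaMatrix,
    ProbeManifest,
    SampleSheet,
    TranscriptAnnotation,
)
from .errors import ConfigurationError
from .signature import DifferentialExpressionTable

GROUP_NCC = "NCC"
GROUP_MEL = "melanocyte"
GROUP_PRIMARY = "primary"
GROUP_METASTATIC = "metastatic"
STUDY_DEV = "development"
STUDY_PROG = "progression"
DMR_TRANSCRIPT = "ISO2"
DECOY_TRANSCRIPT = "CTRL"
KD_CONTEXTS = ("4L", "12-273BM")

_DMR_CHROM = "chr15"
_DMR_TSS = 96_874_100  # + strand
_DECOY_CHROM = "chr1"
_DECOY_TSS = 50_000_000  # - strand


@dataclass
class SimConfig:
    """Generator settings; the defaults define the study conditions.

    Group sizes default to 4 NCC vs 8 melanocyte cultures and a
    progression cohort scaled to 30 primary vs 60 metastatic
    (``full_scale=True`` restores 109 vs 364).  40 reversal CpGs are
    planted with |delta beta| 0.8 in the developmental and 0.35 in the
    progression comparison, half hyper- and half hypomethylated in the
    state of interest.
    """

    n_probes: int = 2000
    n_reversal: int = 40
    delta_a: float = 0.8
    delta_b: float = 0.35
    n_ncc: int = 4
    n_melanocyte: int = 8
    n_primary: int = 30
    n_metastatic: int = 60
    full_scale: bool = False
    low_mean: float = 0.10
    high_mean: float = 0.90
    concentration: float = 20.0
    missing_frac: float = 0.02
    sex_frac: float = 0.03
    snp_frac: float = 0.05
    detection_alpha: float = 0.01
    n_dmr_probes: int = 5
    n_genes: int = 1000
    n_signature: int = 200
    iso_intercept: float = 6.0
    iso_slope: float = 4.0
    iso_noise_sd: float = 0.5
    coupling_slope: float = 1.0
    expr_noise_sd: float = 0.5
    de_p_planted_max: float = 0.04
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reversal > self.n_probes:
            raise ConfigurationError("planted count exceeds probe count")
        for name in ("missing_frac", "sex_frac", "snp_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("delta_a", "delta_b"):
            if not (0 < getattr(self, name) <= 1):
                raise ConfigurationError(f"{name} must be in (0, 1]")
        if not (0 < self.low_mean < self.high_mean < 1):
            raise ConfigurationError("need 0 < low_mean < high_mean < 1")
        if self.n_dmr_probes > max(self.n_reversal // 2, 0) and self.n_reversal:
            raise ConfigurationError("n_dmr_probes exceeds planted hypo probes")
        if self.n_signature > self.n_genes:
            raise ConfigurationError("planted signature larger than gene count")
        if self.full_scale:
            self.n_primary, self.n_metastatic = 109, 364

    @property
    def group_sizes(self) -> dict[str, int]:
        return {
            GROUP_NCC: self.n_ncc,
            GROUP_MEL: self.n_melanocyte,
            GROUP_PRIMARY: self.n_primary,
            GROUP_METASTATIC: self.n_metastatic,
        }


@dataclass
class SimTruth:
    """Planted ground truth: the acceptance oracle for synthetic runs."""

    planted: pd.DataFrame  # probe_id x (direction, delta_a, delta_b)
    dmr_transcript: str
    dmr_probes: list[str]
    sample_region_mean: pd.Series  # generating (noise-free) region mean
    sample_hypomethylated: pd.Series  # bool per progression sample
    signature_genes: list[str] = field(default_factory=list)

    @property
    def planted_probes(self) -> set[str]:
        return set(self.planted.index)

    def planted_with_direction(self, direction: str) -> set[str]:
        return set(self.planted.index[self.planted["direction"] == direction])


@dataclass
class MethylationStudy:
    """Everything the methylation arm of the pipeline consumes."""

    beta_a: BetaMatrix
    beta_b: BetaMatrix
    detection_a: pd.DataFrame
    detection_b: pd.DataFrame
    manifest: ProbeManifest
    sheet: SampleSheet
    annotation: TranscriptAnnotation
    truth: SimTruth


def _beta_draw(rng: np.random.Generator, mean: np.ndarray,
               concentration: float) -> np.ndarray:
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return rng.beta(a, b)


def _child(seed: int, label: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(entropy=seed, spawn_key=(label,))))


def simulate_methylation_study(config: SimConfig) -> MethylationStudy:
    """Generate both study beta matrices, manifest, sheet, detection
    p-values, a two-transcript annotation, and the planted truth."""
    n = config.n_probes
    probe_ids = pd.Index([f"cg{i:06d}" for i in range(1, n + 1)],
                         name="probe_id")

    rng_manifest = _child(config.rng_seed, 0)
    rng_baseline = _child(config.rng_seed, 1)
    rng_a = _child(config.rng_seed, 2)
    rng_b = _child(config.rng_seed, 3)
    rng_det = _child(config.rng_seed, 4)

    # --- manifest flags; planted probes stay autosomal and SNP-free ---
    is_sex = rng_manifest.random(n) < config.sex_frac
    has_snp = rng_manifest.random(n) < config.snp_frac
    eligible = np.flatnonzero(~is_sex & ~has_snp)
    if len(eligible) < config.n_reversal:
        raise ConfigurationError("not enough clean probes to plant reversals")
    planted_idx = np.sort(rng_manifest.choice(eligible, size=config.n_reversal,
                                              replace=False))
    n_hyper = config.n_reversal // 2
    hyper_idx = planted_idx[:n_hyper]
    hypo_idx = planted_idx[n_hyper:]
    dmr_idx = hypo_idx[:config.n_dmr_probes]

    chrom = np.where(is_sex,
                     rng_manifest.choice(["chrX", "chrY"], size=n),
                     rng_manifest.choice([f"chr{i}" for i in range(1, 23)],
                                         size=n))
    position = rng_manifest.integers(1, 200_000_000, size=n)
    # keep random probes out of the two promoter windows
    for win_chrom, tss, strand in ((_DMR_CHROM, _DMR_TSS, "+"),
                                   (_DECOY_CHROM, _DECOY_TSS, "-")):
        d = np.where(strand == "+", position - tss, tss - position)
        clash = (chrom == win_chrom) & (d >= -300) & (d <= 63)
        position = np.where(clash, position + 10_000, position)
    # plant the DMR probes inside the + strand window
    offsets = np.linspace(-300, 63, num=len(dmr_idx)).astype(int) \
        if len(dmr_idx) else np.array([], dtype=int)
    chrom[dmr_idx] = _DMR_CHROM
    position[dmr_idx] = _DMR_TSS + offsets

    manifest = ProbeManifest(pd.DataFrame(
        {"chromosome": chrom, "position": position,
         "snp_in_last_10_bases": has_snp}, index=probe_ids))

    annotation = TranscriptAnnotation(pd.DataFrame(
        {
            "chromosome": [_DMR_CHROM, _DECOY_CHROM],
            "strand": ["+", "-"],
            "tss_position": [_DMR_TSS, _DECOY_TSS],
        },
        index=pd.Index([DMR_TRANSCRIPT, DECOY_TRANSCRIPT],
                       name="transcript_id"),
    ))

    # --- per-probe generating means ---
    state = rng_baseline.choice([config.low_mean, 0.5, config.high_mean],
                                size=n, p=[0.45, 0.10, 0.45])
    means = {}
    for grp in (GROUP_NCC, GROUP_MEL, GROUP_PRIMARY, GROUP_METASTATIC):
        means[grp] = state.copy()
    # group1 of each comparison is the state of interest (NCC, metastatic)
    hi_a, lo_a = 0.5 + config.delta_a / 2, 0.5 - config.delta_a / 2
    hi_b, lo_b = 0.5 + config.delta_b / 2, 0.5 - config.delta_b / 2
    means[GROUP_NCC][hyper_idx], means[GROUP_MEL][hyper_idx] = hi_a, lo_a
    means[GROUP_NCC][hypo_idx], means[GROUP_MEL][hypo_idx] = lo_a, hi_a
    means[GROUP_METASTATIC][hyper_idx], means[GROUP_PRIMARY][hyper_idx] = hi_b, lo_b
    means[GROUP_METASTATIC][hypo_idx], means[GROUP_PRIMARY][hypo_idx] = lo_b, hi_b

    sizes = config.group_sizes
    prefixes = {GROUP_NCC: "NCC", GROUP_MEL: "MEL",
                GROUP_PRIMARY: "PRI", GROUP_METASTATIC: "MET"}
    sample_ids = {g: [f"{prefixes[g]}_{i:03d}" for i in range(1, sizes[g] + 1)]
                  for g in prefixes}

    def _study_matrix(rng, groups) -> BetaMatrix:
        cols, data = [], []
        for g in groups:
            for _ in sample_ids[g]:
                data.append(_beta_draw(rng, means[g], config.concentration))
            cols.extend(sample_ids[g])
        values = pd.DataFrame(np.column_stack(data), index=probe_ids,
                              columns=cols)
        return BetaMatrix(values)

    beta_a = _study_matrix(rng_a, (GROUP_NCC, GROUP_MEL))
    beta_b = _study_matrix(rng_b, (GROUP_METASTATIC, GROUP_PRIMARY))

    def _detection(rng, n_samples, columns) -> pd.DataFrame:
        p = rng.uniform(0.0, 0.005, size=(n, n_samples))
        fail = rng.random((n, n_samples)) < config.missing_frac
        p[fail] = rng.uniform(config.detection_alpha, 1.0, size=int(fail.sum()))
        return pd.DataFrame(p, index=probe_ids, columns=columns)

    detection_a = _detection(rng_det, beta_a.shape[1], beta_a.sample_ids)
    detection_b = _detection(rng_det, beta_b.shape[1], beta_b.sample_ids)

    sheet_rows = []
    for g, study in ((GROUP_NCC, STUDY_DEV), (GROUP_MEL, STUDY_DEV),
                     (GROUP_METASTATIC, STUDY_PROG), (GROUP_PRIMARY, STUDY_PROG)):
        for s in sample_ids[g]:
            sheet_rows.append({"sample_id": s, "group": g, "study": study})
    sheet = SampleSheet(pd.DataFrame(sheet_rows).set_index("sample_id"))

    directions = np.array(["hyper"] * len(hyper_idx) + ["hypo"] * len(hypo_idx))
    planted = pd.DataFrame(
        {
            "direction": directions,
            "delta_a": config.delta_a,
            "delta_b": config.delta_b,
        },
        index=probe_ids[planted_idx],
    )
    dmr_probes = list(probe_ids[dmr_idx])
    prog_samples = sample_ids[GROUP_METASTATIC] + sample_ids[GROUP_PRIMARY]
    latent = pd.Series(
        [lo_b if s.startswith("MET") else hi_b for s in prog_samples],
        index=pd.Index(prog_samples, name="sample_id"), dtype=float,
        name="generating_region_mean",
    ) if dmr_probes else pd.Series(dtype=float)
    truth = SimTruth(
        planted=planted,
        dmr_transcript=DMR_TRANSCRIPT,
        dmr_probes=dmr_probes,
        sample_region_mean=latent,
        sample_hypomethylated=(latent < 0.33).rename("true_hypomethylated"),
    )
    return MethylationStudy(beta_a=beta_a, beta_b=beta_b,
                            detection_a=detection_a, detection_b=detection_b,
                            manifest=manifest, sheet=sheet,
                            annotation=annotation, truth=truth)


@dataclass
class ExpressionData:
    """Expression matrix, isoform expression, and knockdown DE tables."""

    expression: pd.DataFrame  # genes x samples
    isoform_expression: pd.Series
    de_tables: list[DifferentialExpressionTable]


def simulate_expression(config: SimConfig, region_means: pd.Series,
                        truth: SimTruth) -> ExpressionData:
    """Generate expression coupled to region methylation plus DE tables.

    Isoform expression = intercept - slope * region mean + Gaussian noise;
    planted signature genes follow the isoform positively; knockdown DE
    tables mark exactly the planted genes as significantly down-regulated
    in every context.  Fills ``truth.signature_genes``.
    """
    rng = _child(config.rng_seed, 5)
    samples = region_means.index
    rm = region_means.to_numpy(dtype=float)
    iso = config.iso_intercept - config.iso_slope * rm + \
        rng.normal(0.0, config.iso_noise_sd, size=len(rm))
    iso_s = pd.Series(iso, index=samples, name="isoform_expression")

    gene_ids = pd.Index([f"g{i:05d}" for i in range(1, config.n_genes + 1)],
                        name="gene_id")
    sig_idx = np.sort(rng.choice(config.n_genes, size=config.n_signature,
                                 replace=False))
    sig_mask = np.zeros(config.n_genes, dtype=bool)
    sig_mask[sig_idx] = True
    base = rng.normal(5.0, 1.0, size=config.n_genes)

    expr = np.empty((config.n_genes, len(samples)))
    centered_iso = iso - iso.mean()
    for i in range(config.n_genes):
        if sig_mask[i]:
            expr[i] = base[i] + config.coupling_slope * centered_iso + \
                rng.normal(0.0, config.expr_noise_sd, size=len(samples))
        else:
            expr[i] = base[i] + rng.normal(0.0, 1.0, size=len(samples))
    expression = pd.DataFrame(expr, index=gene_ids, columns=samples)

    de_tables = []
    for ctx in KD_CONTEXTS:
        log2fc = rng.normal(0.0, 0.8, size=config.n_genes)
        p = rng.uniform(0.0, 1.0, size=config.n_genes)
        log2fc[sig_mask] = -rng.uniform(0.5, 3.0, size=config.n_signature)
        p[sig_mask] = rng.uniform(1e-6, config.de_p_planted_max,
                                  size=config.n_signature)
        de_tables.append(DifferentialExpressionTable(
            context=ctx,
            table=pd.DataFrame({"log2_fold_change": log2fc, "p_value": p},
                               index=gene_ids.copy()),
        ))
    truth.signature_genes = list(gene_ids[sig_mask])
    return ExpressionData(expression=expression, isoform_expression=iso_s,
                          de_tables=de_tables)
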