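"""Core data containers for 450K-style methylation analysis.

All tabular objects are thin wrappers around :class:`pandas.DataFrame` /
:class:`pandas.Series` that validate their domain invariants on
construction.  Missing methylation values are represented as ``NaN``
throughout; on disk they are empty cells, never sentinel numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

SEX_CHROMOSOMES = frozenset({"chrX", "chrY"})


def normalize_chromosome(name: str) -> str:
    """Normalize a chromosome name to the ``chr``-prefixed dialect.

    Accepts both the Illumina-manifest style (``X``, ``7``) and the
    UCSC/BED style (``chrX``, ``chr7``); everything is stored with the
    ``chr`` prefix so that downstream comparisons use a single dialect.
    """
    name = str(name).strip()
    if not name:
        raise ValidationError("empty chromosome name")
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions (beta values).

    ``values`` is a float DataFrame indexed by probe id with one column per
    sample; ``NaN`` marks a masked/missing measurement.  Every non-missing
    value must lie in [0, 1].
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(df.index, "probe ids")
        _check_unique(df.columns, "sample ids")
        arr = df.to_numpy(dtype=float, copy=False)
        bad = (arr < 0.0) | (arr > 1.0)
        if bool(np.any(bad & ~np.isnan(arr))):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )
        self.values = df.astype(float)
        self.values.index.name = "probe_id"

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[probe_ids])

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[:, sample_ids])


@dataclass
class SignalPairMatrix:
    """Methylated/unmethylated intensity pairs with detection p-values.

    The three frames share an identical probe index and sample columns.
    Intensities are non-negative; detection p-values lie in [0, 1].
    """

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.methylated.index, "probe ids")
        _check_unique(self.methylated.columns, "sample ids")
        for name, df in (("methylated", self.methylated),
                         ("unmethylated", self.unmethylated)):
            arr = df.to_numpy(dtype=float)
            if bool(np.any(arr < 0)):
                raise ValidationError(f"negative {name} signal")
        if not self.methylated.index.equals(self.unmethylated.index) or \
                not self.methylated.columns.equals(self.unmethylated.columns):
            raise ValidationError("methylated/unmethylated shapes or ids differ")
        if self.detection_p is not None:
            dp = self.detection_p
            if not dp.index.equals(self.methylated.index) or \
                    not dp.columns.equals(self.methylated.columns):
                raise ValidationError("detection_p ids do not match signals")
            arr = dp.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                if bool(np.any((arr < 0) | (arr > 1))):
                    raise ValidationError("detection p outside [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.methylated.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.methylated.columns


@dataclass
class ProbeManifest:
    """Per-probe annotation: genomic location and SNP flag.

    ``table`` is indexed by probe id with columns ``chromosome`` (stored in
    the ``chr``-prefixed dialect), ``position`` (1-based coordinate of the
    interrogated CpG) and ``snp_in_last_10_bases`` (bool).
    """

    table: pd.DataFrame

    REQUIRED = ("chromosome", "position", "snp_in_last_10_bases")

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "probe ids")
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"manifest missing column {col!r}")
        t = t.copy()
        t["chromosome"] = [normalize_chromosome(c) for c in t["chromosome"]]
        pos = pd.to_numeric(t["position"], errors="raise")
        if bool((pos < 1).any()):
            raise ValidationError("manifest position < 1")
        t["position"] = pos.astype(np.int64)
        t["snp_in_last_10_bases"] = t["snp_in_last_10_bases"].astype(bool)
        t.index.name = "probe_id"
        self.table = t

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def is_sex_chromosome(self) -> pd.Series:
        return self.table["chromosome"].isin(SEX_CHROMOSOMES)


@dataclass
class SampleSheet:
    """Sample metadata: group label and study membership per sample."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "sample ids")
        if "group" not in t.columns:
            raise ValidationError("sample sheet missing 'group' column")
        if "study" not in t.columns:
            t = t.copy()
            t["study"] = ""
        if bool(t["group"].isna().any()):
            raise ValidationError("empty group label in sample sheet")
        groups = t["group"].astype(str)
        if bool((groups.str.len() == 0).any()):
            raise ValidationError("empty group label in sample sheet")
        t = t.copy()
        t["group"] = groups
        t.index.name = "sample_id"
        self.table = t

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_in_group(self, group: str) -> list[str]:
        sel = self.table.index[self.table["group"] == group]
        if len(sel) == 0:
            raise ConfigurationError(f"no samples with group label {group!r}")
        return list(sel)


@dataclass
class TranscriptAnnotation:
    """Transcription start sites, one row per transcript.

    ``table`` is indexed by transcript id with columns ``chromosome``,
    ``strand`` (``+``/``-``) and ``tss_position`` (1-based coordinate of
    the TSS base).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "transcript ids")
        for col in ("chromosome", "strand", "tss_position"):
            if col not in t.columns:
                raise ValidationError(f"annotation missing column {col!r}")
        t = t.copy()
        t["chromosome"] = [normalize_chromosome(c) for c in t["chromosome"]]
        bad = ~t["strand"].isin(["+", "-"])
        if bool(bad.any()):
            raise ValidationError(
                f"invalid strand {t['strand'][bad].iloc[0]!r} (must be + or -)")
        t["tss_position"] = pd.to_numeric(t["tss_position"],
                                          errors="raise").astype(np.int64)
        t.index.name = "transcript_id"
        self.table = t

    @property
    def transcript_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the analysis, with study defaults.

    delta_min_a / delta_min_b are the effect-size gates for the
    developmental (NCC vs melanocyte) and progression (primary vs
    metastatic) comparisons respectively; the remaining fields follow the
    thresholds printed throughout the analysis (beta offset 100, detection
    alpha 0.01, FDR 0.01, hypomethylation cutoff 0.33, promoter window
    -300..+63 bp, signature p < 0.05 capped at 500 genes).
    """

    beta_offset: float = 100.0
    detection_alpha: float = 0.01
    delta_min_a: float = 0.66
    delta_min_b: float = 0.20
    q_max: float = 0.01
    hypo_cutoff: float = 0.33
    tss_window: tuple[int, int] = (-300, 63)
    min_combined_delta: float = 0.30
    signature_p_max: float = 0.05
    signature_max_genes: int = 500
    min_samples_per_group: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_offset < 0:
            raise ConfigurationError("beta_offset must be >= 0")
        if not (0 < self.detection_alpha <= 1):
            raise ConfigurationError("detection_alpha must be in (0, 1]")
        for name in ("delta_min_a", "delta_min_b", "q_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigurationError(f"{name} must be in (0, 1]")
        if not (0 < self.hypo_cutoff < 1):
            raise ConfigurationError("hypo_cutoff must be in (0, 1)")
        up, down = self.tss_window
        if not (up <= 0 <= down):
            raise ConfigurationError("tss_window must satisfy upstream <= 0 <= downstream")
        self.tss_window = (int(up), int(down))
        if not (0 <= self.min_combined_delta <= 1):
            raise ConfigurationError("min_combined_delta must be in [0, 1]")
        if not (0 < self.signature_p_max <= 1):
            raise ConfigurationError("signature_p_max must be in (0, 1]")
        if self.signature_max_genes < 1:
            raise ConfigurationError("signature_max_genes must be >= 1")
        if self.min_samples_per_group < 2:
            raise ConfigurationError("min_samples_per_group must be >= 2")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(data)
        if "tss_window" in kwargs:
            kwargs["tss_window"] = tuple(kwargs["tss_window"])
        return cls(**kwargs)

    def updated(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)
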