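"""Readers and writers for the pipeline's tabular formats.

All methylation tables travel as TSV: the beta matrix as probe_id plus one
column per sample (empty cell = missing), the probe manifest as
``probe_id  chromosome  position  snp_in_last_10_bases``, the sample sheet
as ``sample_id  group  study``, and transcript annotations as BED6 where
the TSS is the interval start for + strand transcripts and ``end - 1`` for
- strand ones (BED is 0-based half-open; manifest positions are 1-based).
Configuration files are YAML (JSON being a YAML subset is accepted too).

Writing then reading any valid object reproduces it exactly: floats are
serialized with their shortest round-tripping representation and missing
values as empty cells.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    AnalysisConfig,
    BetaMatrix,
    ProbeManifest,
    SampleSheet,
    TranscriptAnnotation,
)
from .errors import FormatError, ValidationError


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#",
                           float_precision="round_trip", **kwargs)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def _check_header_unique(path, what: str) -> None:
    # pandas silently mangles duplicate header names, so inspect the raw line
    with open(path) as handle:
        for line in handle:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")[1:]
            if len(fields) != len(set(fields)):
                raise FormatError(f"duplicate {what} in header of {path}")
            return


def read_beta_matrix(path) -> BetaMatrix:
    """Read a probe x sample beta-value TSV; empty cells become missing."""
    _check_header_unique(path, "sample ids")
    df = _read_tsv(path, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate probe ids in {path}: {dups[:5]}")
    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric beta value in {path}: {exc}") from exc
    return BetaMatrix(values)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.values.to_csv(path, sep="\t", na_rep="")


def read_probe_manifest(path) -> ProbeManifest:
    """Read a probe manifest TSV, normalizing chromosome names to chr*."""
    df = _read_tsv(path, dtype={0: str})
    required = ["probe_id", "chromosome", "position", "snp_in_last_10_bases"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} missing columns {missing}")
    if df["probe_id"].duplicated().any():
        raise FormatError(f"duplicate probe ids in manifest {path}")
    try:
        position = pd.to_numeric(df["position"], errors="raise")
        if not np.allclose(position, np.round(position)):
            raise ValueError("non-integer position")
        snp = df["snp_in_last_10_bases"].map(_parse_bool)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"bad manifest value in {path}: {exc}") from exc
    table = pd.DataFrame(
        {
            "chromosome": df["chromosome"].astype(str).values,
            "position": position.astype(np.int64).values,
            "snp_in_last_10_bases": snp.values,
        },
        index=pd.Index(df["probe_id"], name="probe_id"),
    )
    return ProbeManifest(table)


_BOOL_TOKENS = {
    "1": True, "0": False, "true": True, "false": False,
    "t": True, "f": False, "yes": True, "no": False,
}


def _parse_bool(token) -> bool:
    if isinstance(token, (bool, np.bool_)):
        return bool(token)
    key = str(token).strip().lower()
    if key not in _BOOL_TOKENS:
        raise ValueError(f"cannot interpret {token!r} as a boolean flag")
    return _BOOL_TOKENS[key]


def write_probe_manifest(manifest: ProbeManifest, path) -> None:
    out = manifest.table.copy()
    out["snp_in_last_10_bases"] = out["snp_in_last_10_bases"].astype(int)
    out.to_csv(path, sep="\t")


def read_sample_sheet(path) -> SampleSheet:
    df = _read_tsv(path, dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise FormatError(f"sample sheet {path} needs sample_id and group columns")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"duplicate sample ids in {path}")
    table = df.set_index("sample_id")
    return SampleSheet(table)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t")


def read_annotation_bed(path) -> TranscriptAnnotation:
    """Read a BED6 transcript annotation and recover 1-based TSS positions."""
    df = _read_tsv(path, header=None,
                   names=["chrom", "start", "end", "name", "score", "strand"])
    try:
        start = pd.to_numeric(df["start"], errors="raise").astype(np.int64)
        end = pd.to_numeric(df["end"], errors="raise").astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-integer BED coordinate in {path}: {exc}") from exc
    if bool((end <= start).any()):
        raise FormatError(f"empty or inverted BED interval in {path}")
    strand = df["strand"].astype(str)
    # 0-based start -> 1-based TSS; minus-strand TSS sits at the interval end.
    tss = np.where(strand == "+", start + 1, end)
    table = pd.DataFrame(
        {
            "chromosome": df["chrom"].astype(str).values,
            "strand": strand.values,
            "tss_position": tss,
        },
        index=pd.Index(df["name"].astype(str), name="transcript_id"),
    )
    return TranscriptAnnotation(table)


def write_annotation_bed(annotation: TranscriptAnnotation, path) -> None:
    t = annotation.table
    rows = pd.DataFrame(
        {
            "chrom": t["chromosome"],
            "start": t["tss_position"] - 1,
            "end": t["tss_position"],
            "name": t.index,
            "score": 0,
            "strand": t["strand"],
        }
    )
    rows.to_csv(path, sep="\t", header=False, index=False)


def write_probe_bed(manifest: ProbeManifest, probe_ids, path) -> None:
    """Write selected manifest probes as a BED6 track (1-bp intervals)."""
    missing = [p for p in probe_ids if p not in manifest.table.index]
    if missing:
        raise ValidationError(f"probes absent from manifest: {missing[:5]}")
    sub = manifest.table.loc[list(probe_ids)]
    rows = pd.DataFrame(
        {
            "chrom": sub["chromosome"],
            "start": sub["position"] - 1,
            "end": sub["position"],
            "name": sub.index,
            "score": 0,
            "strand": ".",
        }
    )
    rows.to_csv(path, sep="\t", header=False, index=False)


def read_analysis_config(path) -> AnalysisConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise FormatError(f"config {path} must be a mapping")
    return AnalysisConfig.from_mapping(data)


def write_analysis_config(config: AnalysisConfig, path) -> None:
    data = {
        "beta_offset": config.beta_offset,
        "detection_alpha": config.detection_alpha,
        "delta_min_a": config.delta_min_a,
        "delta_min_b": config.delta_min_b,
        "q_max": config.q_max,
        "hypo_cutoff": config.hypo_cutoff,
        "tss_window": list(config.tss_window),
        "min_combined_delta": config.min_combined_delta,
        "signature_p_max": config.signature_p_max,
        "signature_max_genes": config.signature_max_genes,
        "min_samples_per_group": config.min_samples_per_group,
        "rng_seed": config.rng_seed,
    }
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=False)


def read_detection_p(path) -> pd.DataFrame:
    """Read a detection p-value matrix (same layout as the beta matrix)."""
    df = _read_tsv(path, index_col=0)
    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric detection p in {path}: {exc}") from exc
    arr = values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if bool(np.any((arr < 0) | (arr > 1))):
            raise ValidationError(f"detection p outside [0, 1] in {path}")
    return values


def write_detection_p(detection_p: pd.DataFrame, path) -> None:
    detection_p.to_csv(path, sep="\t", na_rep="")


def ensure_dir(path) -> None:
    os.makedirs(path, exist_ok=True)
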