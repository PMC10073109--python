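"""Directional intersection of two comparisons and TSS-window aggregation.

A *reversal CpG* is differentially methylated in the same group1-relative
direction in two independent comparisons — e.g. hypomethylated both in
NCCs (vs melanocytes) and in metastatic melanoma (vs primary).  The
catalog records, per CpG, the effect size and FDR from both comparisons.

CpGs are mapped to promoter regions by their signed offset from a
transcription start site in transcript orientation: d = position - TSS on
the + strand and TSS - position on the - strand, with the window endpoints
inclusive (offset 0 is the TSS base itself; the default window is
-300..+63 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, ProbeManifest, TranscriptAnnotation
from .errors import ValidationError


@dataclass
class ReversalCatalog:
    """CpGs informative in the same direction in both comparisons.

    ``table`` is indexed by probe id with columns ``direction``,
    ``delta_beta_a``, ``delta_beta_b``, ``q_value_a``, ``q_value_b``.
    """

    table: pd.DataFrame

    @property
    def hyper_in_both(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == "hyper"])

    @property
    def hypo_in_both(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == "hypo"])

    @property
    def probe_ids(self) -> set[str]:
        return set(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "ReversalCatalog":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class RegionSpec:
    """A TSS-relative promoter window and the CpG probes inside it."""

    transcript_id: str
    window: tuple[int, int]
    member_probes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        up, down = self.window
        if up > down:
            raise ValidationError("region window upstream must be <= downstream")


def intersect_reversal(dm_a, dm_b) -> ReversalCatalog:
    """Intersect two differential tables on informative probes with
    matching direction.

    Both tables must use the same group1 semantics (state of interest vs
    reference) for "same direction" to be meaningful.  The operation is
    symmetric up to the a/b column labels.
    """
    records = []
    for direction in ("hyper", "hypo"):
        shared = dm_a.probes_with_direction(direction) & \
            dm_b.probes_with_direction(direction)
        for probe in sorted(shared):
            records.append(
                {
                    "probe_id": probe,
                    "direction": direction,
                    "delta_beta_a": dm_a.table.at[probe, "delta_beta"],
                    "delta_beta_b": dm_b.table.at[probe, "delta_beta"],
                    "q_value_a": dm_a.table.at[probe, "q_value"],
                    "q_value_b": dm_b.table.at[probe, "q_value"],
                }
            )
    columns = ["probe_id", "direction", "delta_beta_a", "delta_beta_b",
               "q_value_a", "q_value_b"]
    table = pd.DataFrame(records, columns=columns).set_index("probe_id")
    return ReversalCatalog(table)


def rank_by_delta(catalog: ReversalCatalog,
                  min_combined_delta: float = 0.30) -> list[str]:
    """Rank reversal CpGs by min(|delta_a|, |delta_b|), descending.

    A reversal CpG is only as strong as its weaker comparison, so the rank
    key is the smaller of the two absolute effect sizes; probes whose key
    falls below ``min_combined_delta`` are excluded.  Ties break by probe
    id for determinism.
    """
    if not (0 <= min_combined_delta <= 1):
        raise ValidationError("min_combined_delta must be in [0, 1]")
    t = catalog.table
    if t.empty:
        return []
    key = np.minimum(t["delta_beta_a"].abs(), t["delta_beta_b"].abs())
    kept = key[key >= min_combined_delta]
    order = sorted(kept.items(), key=lambda kv: (-kv[1], kv[0]))
    return [probe for probe, _ in order]


def assign_tss_regions(manifest: ProbeManifest,
                       annotation: TranscriptAnnotation,
                       window: tuple[int, int] = (-300, 63)) -> list[RegionSpec]:
    """Assign manifest CpGs to each transcript's TSS-relative window.

    A probe belongs to a transcript iff it is on the same chromosome and
    its strand-aware offset d satisfies upstream <= d <= downstream.
    Probes keep manifest order within each region.
    """
    up, down = int(window[0]), int(window[1])
    if up > down:
        raise ValidationError("window upstream must be <= downstream")
    regions = []
    positions = manifest.table["position"]
    chroms = manifest.table["chromosome"]
    for tid, row in annotation.table.iterrows():
        on_chrom = chroms == row["chromosome"]
        if row["strand"] == "+":
            d = positions - row["tss_position"]
        else:
            d = row["tss_position"] - positions
        inside = on_chrom & (d >= up) & (d <= down)
        regions.append(RegionSpec(transcript_id=str(tid), window=(up, down),
                                  member_probes=list(manifest.table.index[inside])))
    return regions


def region_mean_beta(beta: BetaMatrix, region: RegionSpec) -> pd.Series:
    """Per-sample arithmetic mean beta over the region's member probes.

    Complete-case per sample: missing member values are ignored, and a
    sample with no observed member probe gets a missing mean.
    """
    members = [p for p in region.member_probes if p in beta.probe_ids]
    if not members:
        raise ValidationError(
            f"region {region.transcript_id} has no member probes in the matrix")
    sub = beta.values.loc[members]
    means = sub.mean(axis=0, skipna=True)
    means.name = region.transcript_id
    return means
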