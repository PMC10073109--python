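"""Differential methylation calling for one two-group comparison.

A CpG is called *informative* when |delta beta| >= delta_min (0.66 for the
developmental NCC-vs-melanocyte comparison, 0.20 for the primary-vs-
metastatic comparison) AND its Benjamini-Hochberg adjusted one-way ANOVA
p-value is <= 0.01.  Both thresholds are inclusive, exactly as printed.
Tests run directly on beta values (the effect-size gate is itself on the
beta scale); with two groups the one-way fixed-effects F statistic equals
the square of the pooled-variance t statistic.

Direction is stated relative to ``group1`` (the state of interest): a CpG
is ``hyper`` when the group1 mean exceeds the group2 mean, ``hypo`` when
it is lower.  So with group1 = NCC, ``hypo`` means hypomethylated in NCCs.
Probes with too few non-missing samples in either group get missing
statistics and ``informative = False`` — they are accounted for, never
silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import BetaMatrix, SampleSheet
from .errors import ConfigurationError, ValidationError

_HEADER_KEYS = ("group1", "group2", "delta_min", "q_max")

COLUMNS = [
    "mean_group1", "mean_group2", "n_group1", "n_group2",
    "delta_beta", "f_statistic", "p_value", "q_value",
    "direction", "informative",
]


@dataclass
class DifferentialTable:
    """Per-probe differential methylation results for one comparison.

    ``table`` is indexed by probe id with columns: group means and
    non-missing counts, ``delta_beta`` (group2 mean - group1 mean), the F
    statistic, raw p, BH q, ``direction`` (hyper/hypo/none, group1-
    relative, set only for informative probes) and the ``informative``
    flag.
    """

    table: pd.DataFrame
    group1: str
    group2: str
    delta_min: float
    q_max: float

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"differential table missing columns {missing}")

    @property
    def informative(self) -> pd.DataFrame:
        return self.table[self.table["informative"]]

    @property
    def n_informative(self) -> int:
        return int(self.table["informative"].sum())

    def probes_with_direction(self, direction: str) -> set[str]:
        mask = self.table["informative"] & (self.table["direction"] == direction)
        return set(self.table.index[mask])

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(f"# group1={self.group1}\n# group2={self.group2}\n")
            handle.write(f"# delta_min={self.delta_min!r}\n# q_max={self.q_max!r}\n")
            handle.write("# direction convention: hyper = group1 mean > group2 mean\n")
            self.table.to_csv(handle, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "DifferentialTable":
        meta: dict[str, str] = {}
        with open(path) as handle:
            for line in handle:
                if not line.startswith("#"):
                    break
                if "=" in line:
                    key, _, value = line[1:].strip().partition("=")
                    meta[key.strip()] = value.strip()
        missing = [k for k in _HEADER_KEYS if k not in meta]
        if missing:
            raise ValidationError(f"differential TSV header missing {missing}")
        table = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        table["informative"] = table["informative"].astype(bool)
        table["direction"] = table["direction"].fillna("none")
        return cls(table=table, group1=meta["group1"], group2=meta["group2"],
                   delta_min=float(meta["delta_min"]), q_max=float(meta["q_max"]))


def anova_f_test(values, groups, min_samples_per_group: int = 2):
    """One-way fixed-effects ANOVA on one probe's beta values.

    Missing values are dropped together with their group labels.  Returns
    ``(f, p)``; both are ``nan`` when fewer than two groups reach
    ``min_samples_per_group`` non-missing values.  When the within-group
    variance is exactly zero and the group means differ, the test is
    infinitely significant and ``(inf, 0.0)`` is returned.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must have equal length")
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    samples = [values[groups == g] for g in pd.unique(groups)]
    samples = [s for s in samples if len(s) >= min_samples_per_group]
    k = len(samples)
    if k < 2:
        return (math.nan, math.nan)
    n = sum(len(s) for s in samples)
    grand = sum(s.sum() for s in samples) / n
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ssw == 0.0:
        if ssb == 0.0:
            return (0.0, 1.0)
        return (math.inf, 0.0)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(sps.f.sf(f, k - 1, n - k))
    return (float(f), p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1 and restored to
    the input order; m counts non-missing entries, and missing entries
    pass through as missing.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    valid = ~np.isnan(p)
    with np.errstate(invalid="ignore"):
        if bool(np.any((p[valid] < 0) | (p[valid] > 1))):
            raise ValidationError("p-value outside [0, 1]")
    q = np.full_like(p, np.nan)
    m = int(valid.sum())
    if m == 0:
        return q
    pv = p[valid]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    q[valid] = out
    return q


def call_differential(beta: BetaMatrix, sheet: SampleSheet, group1: str,
                      group2: str, delta_min: float, q_max: float,
                      min_samples_per_group: int = 2) -> DifferentialTable:
    """Call informative CpGs between two groups with the delta/FDR gate.

    Per probe: group means over non-missing samples, delta beta
    (group2 - group1), one-way ANOVA F and p, BH q over all tested probes;
    ``informative = |delta| >= delta_min and q <= q_max`` (inclusive ties).
    """
    if not (0 < delta_min <= 1) or not (0 < q_max <= 1):
        raise ConfigurationError("delta_min and q_max must be in (0, 1]")
    cols1 = sheet.samples_in_group(group1)
    cols2 = sheet.samples_in_group(group2)
    missing_cols = [s for s in cols1 + cols2 if s not in beta.sample_ids]
    if missing_cols:
        raise ConfigurationError(
            f"samples in sheet but not in beta matrix: {missing_cols[:5]}")

    x1 = beta.values[cols1].to_numpy(dtype=float)
    x2 = beta.values[cols2].to_numpy(dtype=float)
    n1 = np.sum(~np.isnan(x1), axis=1)
    n2 = np.sum(~np.isnan(x2), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean1 = np.where(n1 > 0, np.nansum(x1, axis=1) / n1, np.nan)
        mean2 = np.where(n2 > 0, np.nansum(x2, axis=1) / n2, np.nan)

    tested = (n1 >= min_samples_per_group) & (n2 >= min_samples_per_group)
    n = n1 + n2
    grand = (np.nan_to_num(mean1 * n1) + np.nan_to_num(mean2 * n2)) / np.maximum(n, 1)
    ssb = n1 * (mean1 - grand) ** 2 + n2 * (mean2 - grand) ** 2
    ssw = np.nansum((x1 - mean1[:, None]) ** 2, axis=1) + \
        np.nansum((x2 - mean2[:, None]) ** 2, axis=1)

    f_stat = np.full(len(beta.probe_ids), np.nan)
    p_val = np.full(len(beta.probe_ids), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = tested & (ssw > 0)
        f_stat[ok] = ssb[ok] / (ssw[ok] / (n[ok] - 2))
        p_val[ok] = sps.f.sf(f_stat[ok], 1, n[ok] - 2)
    # zero within-group spread: infinitely significant unless means agree
    degen = tested & (ssw == 0)
    same = degen & (mean1 == mean2)
    f_stat[degen & ~same], p_val[degen & ~same] = np.inf, 0.0
    f_stat[same], p_val[same] = 0.0, 1.0

    q_val = bh_adjust(p_val)
    delta = mean2 - mean1
    informative = np.zeros(len(beta.probe_ids), dtype=bool)
    with np.errstate(invalid="ignore"):
        informative[tested] = (np.abs(delta[tested]) >= delta_min) & \
            (q_val[tested] <= q_max)
    direction = np.where(informative,
                         np.where(mean1 > mean2, "hyper", "hypo"), "none")

    table = pd.DataFrame(
        {
            "mean_group1": mean1, "mean_group2": mean2,
            "n_group1": n1, "n_group2": n2,
            "delta_beta": delta, "f_statistic": f_stat,
            "p_value": p_val, "q_value": q_val,
            "direction": direction, "informative": informative,
        },
        index=beta.probe_ids.copy(),
    )
    return DifferentialTable(table=table, group1=group1, group2=group2,
                             delta_min=delta_min, q_max=q_max)
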