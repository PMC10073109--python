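"""Bisulfite-sequencing clone scoring.

After bisulfite conversion, cloning and Sanger sequencing, each clone
yields a methylated/unmethylated call at every CpG of the amplicon.  The
per-CpG methylation score is the percentage of methylated calls among
informative (non-missing) clones; CpGs covered by fewer informative
clones than the minimum (default 8, the clone-selection rule) are flagged
low-coverage but still reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

METHYLATED = "M"
UNMETHYLATED = "U"
MISSING_TOKENS = {".", "", "na", "nan", "none"}


@dataclass
class CloneMatrix:
    """Clones x CpGs matrix of methylation calls (M / U / missing).

    CpG columns are ordered along the amplicon and that order is
    preserved.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if self.calls.shape[0] < 1:
            raise ValidationError("clone matrix needs >= 1 clone")
        if self.calls.index.has_duplicates or self.calls.columns.has_duplicates:
            raise ValidationError("duplicate clone or CpG ids")
        ok = self.calls.isin([METHYLATED, UNMETHYLATED]) | self.calls.isna()
        if not bool(ok.all().all()):
            bad = self.calls.where(~ok).stack().iloc[0]
            raise ValidationError(f"invalid methylation call {bad!r} (use M/U)")

    @classmethod
    def from_tsv(cls, path) -> "CloneMatrix":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                             keep_default_na=False)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise FormatError(f"cannot parse clone matrix {path}: {exc}") from exc
        cleaned = df.apply(lambda col: col.str.strip())
        cleaned = cleaned.mask(
            cleaned.apply(lambda col: col.str.lower().isin(MISSING_TOKENS)))
        return cls(cleaned)


def clone_methylation_percent(clones: CloneMatrix,
                              min_clones: int = 8) -> pd.DataFrame:
    """Percent methylation per CpG across clones.

    Returns a frame indexed by CpG id with columns ``percent_methylated``
    (100 * methylated / informative; missing when no informative call),
    ``n_informative`` and ``low_coverage`` (informative count below
    ``min_clones``).
    """
    if min_clones < 1:
        raise ValidationError("min_clones must be >= 1")
    calls = clones.calls
    n_meth = (calls == METHYLATED).sum(axis=0)
    n_info = n_meth + (calls == UNMETHYLATED).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        percent = np.where(n_info > 0, 100.0 * n_meth / n_info, np.nan)
    out = pd.DataFrame(
        {
            "percent_methylated": percent,
            "n_informative": n_info.astype(int),
            "low_coverage": (n_info < min_clones).to_numpy(),
        },
        index=calls.columns.copy(),
    )
    out.index.name = "cpg_id"
    return out
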