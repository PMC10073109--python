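"""Knockdown-derived gene signature: derivation, scoring, associations.

The signature collects genes consistently down-regulated after isoform
knockdown in every cell-line context (log2 fold change < 0 and p < 0.05 in
each); when more genes qualify than the cap (default 500), the genes with
the most negative mean log2 fold change are kept, ties broken by gene id.

The per-sample signature score is the scaled average expression: each
signature gene is standardized across samples (z-score with the n-1
standard deviation; zero-variance genes are dropped with a warning) and
the score is the per-sample mean of the standardized values.  Expression
input is assumed normalized/log-scaled; a log2(x+1) pre-transform is
available for raw counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as mstats
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DifferentialExpressionTable:
    """Knockdown-vs-control DE results for one cell-line context."""

    context: str
    table: pd.DataFrame  # indexed by gene_id: log2_fold_change, p_value

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValidationError(
                f"duplicate gene ids in DE table for context {self.context!r}")
        for col in ("log2_fold_change", "p_value"):
            if col not in t.columns:
                raise ValidationError(f"DE table missing column {col!r}")
        p = t["p_value"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if bool(np.any((p < 0) | (p > 1))):
                raise ValidationError("DE p-value outside [0, 1]")
        t.index.name = "gene_id"

    @classmethod
    def from_tsv(cls, context: str, path) -> "DifferentialExpressionTable":
        df = pd.read_csv(path, sep="\t")
        if "gene_id" not in df.columns:
            raise ValidationError(f"DE table {path} missing gene_id column")
        return cls(context=context, table=df.set_index("gene_id"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


@dataclass
class SignatureGeneSet:
    """Signature genes with per-context provenance and derivation settings."""

    genes: list[str]
    provenance: pd.DataFrame  # gene x (log2FC, p per context, mean log2FC)
    p_max: float
    max_genes: int
    contexts: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(f"# p_max={self.p_max!r}\n")
            handle.write(f"# max_genes={self.max_genes}\n")
            handle.write(f"# contexts={','.join(self.contexts)}\n")
            self.provenance.to_csv(handle, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SignatureGeneSet":
        meta = {}
        with open(path) as handle:
            for line in handle:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
        prov = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(genes=list(prov.index), provenance=prov,
                   p_max=float(meta.get("p_max", "nan")),
                   max_genes=int(meta.get("max_genes", "0") or 0),
                   contexts=[c for c in meta.get("contexts", "").split(",") if c])


def derive_signature(tables: list[DifferentialExpressionTable],
                     p_max: float = 0.05,
                     max_genes: int = 500) -> SignatureGeneSet:
    """Select genes down-regulated (log2FC < 0, p < p_max) in EVERY context.

    Genes absent from any context are excluded.  If more than
    ``max_genes`` qualify, the ``max_genes`` with the most negative mean
    log2 fold change are kept (deterministic tie-break by gene id).
    Deterministic and order-invariant in the input tables.
    """
    if len(tables) < 2:
        raise ValidationError("signature derivation needs >= 2 contexts")
    if not (0 < p_max <= 1):
        raise ValidationError("p_max must be in (0, 1]")
    contexts = sorted(t.context for t in tables)
    if len(set(contexts)) != len(contexts):
        raise ValidationError("duplicate context labels")
    by_context = {t.context: t.table for t in tables}

    shared = None
    for ctx in contexts:
        ids = set(by_context[ctx].index)
        shared = ids if shared is None else shared & ids
    qualifying = []
    for gene in shared:
        ok = all(
            by_context[ctx].at[gene, "log2_fold_change"] < 0
            and by_context[ctx].at[gene, "p_value"] < p_max
            for ctx in contexts
        )
        if ok:
            qualifying.append(gene)
    if not qualifying:
        logger.warning("no gene qualifies for the signature")
    prov = pd.DataFrame(index=pd.Index(sorted(qualifying), name="gene_id"))
    for ctx in contexts:
        prov[f"log2fc_{ctx}"] = by_context[ctx].loc[prov.index, "log2_fold_change"]
        prov[f"p_{ctx}"] = by_context[ctx].loc[prov.index, "p_value"]
    fc_cols = [f"log2fc_{ctx}" for ctx in contexts]
    prov["mean_log2fc"] = prov[fc_cols].mean(axis=1) if len(prov) else \
        pd.Series(dtype=float)
    # index is pre-sorted by gene id; a stable sort makes id the tie-break
    prov = prov.sort_values("mean_log2fc", ascending=True, kind="mergesort")
    prov = prov.iloc[:max_genes]
    return SignatureGeneSet(genes=list(prov.index), provenance=prov,
                            p_max=p_max, max_genes=max_genes,
                            contexts=contexts)


@dataclass
class ScoreTable:
    """Per-sample signature scores with optional covariates."""

    table: pd.DataFrame  # indexed by sample_id; column signature_score

    @property
    def scores(self) -> pd.Series:
        return self.table["signature_score"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", na_rep="")


def score_signature(expression: pd.DataFrame, signature: SignatureGeneSet,
                    log_transform: bool = False,
                    scale_after_mean: bool = False) -> ScoreTable:
    """Scaled average expression of the signature genes per sample.

    Default: z-score each present signature gene across samples, then
    average per sample.  ``scale_after_mean=True`` averages raw expression
    first and z-scores the per-sample means instead (differs only by a
    per-cohort affine map).  Zero-variance genes are dropped with a
    warning; signature genes absent from the matrix are logged and
    skipped.
    """
    if expression.shape[1] < 2:
        raise ValidationError("scoring needs >= 2 samples")
    present = [g for g in signature.genes if g in expression.index]
    absent = len(signature.genes) - len(present)
    if not present:
        raise ValidationError("no signature gene present in the expression matrix")
    if absent:
        logger.info("%d signature genes absent from the matrix, skipped", absent)
    sub = expression.loc[present].astype(float)
    if log_transform:
        if bool((sub < 0).any().any()):
            raise ValidationError("log transform requires non-negative values")
        sub = np.log2(sub + 1.0)
    if scale_after_mean:
        means = sub.mean(axis=0)
        sd = means.std(ddof=1)
        if sd == 0:
            raise ValidationError("per-sample means have zero variance")
        scores = (means - means.mean()) / sd
    else:
        sd = sub.std(axis=1, ddof=1)
        zero_var = sd == 0
        if bool(zero_var.any()):
            logger.warning("dropping %d zero-variance genes", int(zero_var.sum()))
            sub, sd = sub[~zero_var], sd[~zero_var]
            if sub.empty:
                raise ValidationError("all signature genes have zero variance")
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        scores = z.mean(axis=0)
    table = pd.DataFrame({"signature_score": scores})
    table.index.name = "sample_id"
    return ScoreTable(table)


def evaluate_signature_associations(scores: ScoreTable,
                                    region_means: pd.Series | None = None,
                                    isoform_expression: pd.Series | None = None,
                                    groups: pd.Series | None = None,
                                    group_pair: tuple[str, str] | None = None,
                                    hypo_cutoff: float = 0.33) -> dict:
    """Associate the signature score with methylation, isoform expression
    and sample groups.

    Returns a dict with Spearman(score, isoform expression),
    Spearman(score, region mean beta), and Mann-Whitney comparisons of
    the score between the two group labels and between methylation
    classes (hypomethylated vs not, at ``hypo_cutoff``).
    """
    s = scores.scores
    report: dict = {"n_samples": int(len(s))}

    def _aligned(other: pd.Series) -> tuple[np.ndarray, np.ndarray]:
        shared = s.index.intersection(other.index)
        if len(shared) < 3:
            raise ValidationError("fewer than 3 shared samples")
        return s.loc[shared].to_numpy(), other.loc[shared]

    if isoform_expression is not None:
        a, b = _aligned(pd.Series(isoform_expression, dtype=float))
        r = mstats.spearman(a, b.to_numpy())
        report["score_vs_isoform"] = {"rho": r.rho, "p": r.p_value, "n": r.n}
    if region_means is not None:
        a, b = _aligned(pd.Series(region_means, dtype=float))
        r = mstats.spearman(a, b.to_numpy())
        report["score_vs_methylation"] = {"rho": r.rho, "p": r.p_value, "n": r.n}
        classes = mstats.classify_hypomethylated(b, cutoff=hypo_cutoff)
        hypo = a[(classes == mstats.HYPO).to_numpy()]
        not_hypo = a[(classes == mstats.NOT_HYPO).to_numpy()]
        if hypo.size and not_hypo.size:
            mw = mstats.mann_whitney(hypo, not_hypo)
            report["score_by_methylation_class"] = {
                "U": mw.statistic, "p": mw.p_value, "n": mw.n}
    if groups is not None and group_pair is not None:
        a, g = _aligned(pd.Series(groups))
        g1, g2 = group_pair
        x = a[(g == g1).to_numpy()]
        y = a[(g == g2).to_numpy()]
        if x.size == 0 or y.size == 0:
            raise ValidationError(f"group pair {group_pair} not found in groups")
        mw = mstats.mann_whitney(x, y)
        report["score_by_group"] = {"U": mw.statistic, "p": mw.p_value,
                                    "n": mw.n, "groups": [g1, g2]}
    return report
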