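"""Signature derivation, scaled-average scoring, and associations."""

import numpy as np
import pandas as pd
import pytest

from methrev.errors import ValidationError
from methrev.signature import (
    DifferentialExpressionTable,
    SignatureGeneSet,
    derive_signature,
    evaluate_signature_associations,
    score_signature,
)


def _de(context, rows):
    table = pd.DataFrame(
        [{"log2_fold_change": fc, "p_value": p} for _, fc, p in rows],
        index=pd.Index([r[0] for r in rows], name="gene_id"))
    return DifferentialExpressionTable(context=context, table=table)


class TestDerive:
    def test_consistent_downregulation_required(self):
        a = _de("lineA", [("g1", -1.2, 0.01), ("g2", -0.5, 0.2),
                          ("g3", 0.4, 0.01), ("g4", -2.0, 0.04)])
        b = _de("lineB", [("g1", -0.8, 0.03), ("g2", -0.9, 0.01),
                          ("g3", -1.0, 0.01), ("g4", -0.1, 0.049)])
        sig = derive_signature([a, b], p_max=0.05, max_genes=500)
        # g2 fails p in lineA; g3 is up-regulated in lineA
        assert sig.genes == sorted(["g1", "g4"],
                                   key=lambda g: sig.provenance.at[g, "mean_log2fc"])
        assert set(sig.genes) == {"g1", "g4"}

    def test_gene_absent_from_any_context_excluded(self):
        a = _de("lineA", [("g1", -1.0, 0.01), ("g2", -1.0, 0.01)])
        b = _de("lineB", [("g1", -1.0, 0.01)])
        sig = derive_signature([a, b])
        assert sig.genes == ["g1"]

    def test_cap_keeps_most_downregulated_with_id_tie_break(self):
        genes = [f"g{i:03d}" for i in range(30)]
        fc = [-(i % 10) - 1.0 for i in range(30)]  # ties every 10 genes
        a = _de("A", list(zip(genes, fc, [0.01] * 30)))
        b = _de("B", list(zip(genes, fc, [0.01] * 30)))
        sig = derive_signature([a, b], max_genes=5)
        assert len(sig) == 5
        # the most negative mean log2FC is -10, shared by g009, g019, g029
        assert sig.genes[:3] == ["g009", "g019", "g029"]

    def test_order_invariant_and_deterministic(self):
        a = _de("A", [("g1", -1.0, 0.01), ("g2", -2.0, 0.01)])
        b = _de("B", [("g1", -1.5, 0.02), ("g2", -0.5, 0.03)])
        assert derive_signature([a, b]).genes == derive_signature([b, a]).genes

    def test_zero_qualifying_genes_is_empty_not_error(self):
        a = _de("A", [("g1", 1.0, 0.01)])
        b = _de("B", [("g1", 1.0, 0.01)])
        assert derive_signature([a, b]).genes == []

    def test_requires_two_contexts(self):
        with pytest.raises(ValidationError):
            derive_signature([_de("A", [("g1", -1, 0.01)])])

    def test_tsv_round_trip(self, tmp_path):
        a = _de("A", [("g1", -1.0, 0.01), ("g2", -2.0, 0.02)])
        b = _de("B", [("g1", -1.5, 0.02), ("g2", -0.5, 0.03)])
        sig = derive_signature([a, b])
        path = tmp_path / "sig.tsv"
        sig.to_tsv(path)
        back = SignatureGeneSet.from_tsv(path)
        assert back.genes == sig.genes
        assert back.p_max == sig.p_max and back.contexts == sig.contexts


def _expr(data, samples=None):
    df = pd.DataFrame(data).T if isinstance(data, dict) else data
    if samples is not None:
        df.columns = samples
    return df


def _sig(genes):
    return SignatureGeneSet(genes=list(genes), provenance=pd.DataFrame(),
                            p_max=0.05, max_genes=500, contexts=["A", "B"])


class TestScore:
    def test_single_gene_z_scores(self):
        expr = _expr({"g1": [0.0, 2.0]}, samples=["s1", "s2"])
        scores = score_signature(expr, _sig(["g1"]))
        assert scores.scores.tolist() == pytest.approx(
            [-0.7071067811865475, 0.7071067811865475])

    def test_uniformly_highest_sample_gets_highest_score(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 6))
        base[:, 2] = base.max(axis=1) + 1.0
        expr = pd.DataFrame(base, index=[f"g{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(6)])
        scores = score_signature(expr, _sig(expr.index))
        assert scores.scores.idxmax() == "s2"

    def test_affine_invariance_per_gene(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(4, 8)),
                            index=list("abcd"),
                            columns=[f"s{i}" for i in range(8)])
        scores = score_signature(expr, _sig(expr.index)).scores
        expr2 = expr.copy()
        expr2.loc["b"] = 3.0 * expr2.loc["b"] + 7.0
        scores2 = score_signature(expr2, _sig(expr.index)).scores
        assert scores2.tolist() == pytest.approx(scores.tolist(), rel=1e-12)

    def test_sample_permutation_commutes(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(4, 8)),
                            index=list("abcd"),
                            columns=[f"s{i}" for i in range(8)])
        perm = rng.permutation(expr.columns)
        s1 = score_signature(expr, _sig(expr.index)).scores
        s2 = score_signature(expr[perm], _sig(expr.index)).scores
        assert s2.loc[s1.index].tolist() == pytest.approx(s1.tolist())

    def test_absent_genes_skipped_and_all_absent_errors(self):
        expr = _expr({"g1": [0.0, 1.0, 2.0]}, samples=["a", "b", "c"])
        scores = score_signature(expr, _sig(["g1", "missing"]))
        assert len(scores.table) == 3
        with pytest.raises(ValidationError):
            score_signature(expr, _sig(["missing"]))

    def test_zero_variance_genes_dropped(self):
        expr = pd.DataFrame({"s1": [1.0, 0.0], "s2": [1.0, 2.0]},
                            index=["flat", "ok"])
        scores = score_signature(expr, _sig(["flat", "ok"]))
        expected = score_signature(expr, _sig(["ok"]))
        assert scores.scores.tolist() == expected.scores.tolist()

    def test_scale_after_mean_is_affine_of_default_for_one_gene(self):
        expr = _expr({"g1": [0.0, 1.0, 3.0]}, samples=["a", "b", "c"])
        z_then_mean = score_signature(expr, _sig(["g1"])).scores
        mean_then_z = score_signature(expr, _sig(["g1"]),
                                      scale_after_mean=True).scores
        assert mean_then_z.tolist() == pytest.approx(z_then_mean.tolist())


class TestAssociations:
    def test_coupled_synthetic_data_yield_expected_signs(self):
        rng = np.random.default_rng(10)
        n = 100
        samples = [f"s{i}" for i in range(n)]
        meth = pd.Series(rng.uniform(0, 1, n), index=samples)
        iso = pd.Series(5 - 4 * meth + rng.normal(0, 0.3, n), index=samples)
        expr = pd.DataFrame(
            {s: [iso[s] + rng.normal(0, 0.3) for _ in range(5)]
             for s in samples},
            index=[f"g{i}" for i in range(5)])
        scores = score_signature(expr, _sig(expr.index))
        groups = pd.Series(["met" if i < 50 else "pri" for i in range(n)],
                           index=samples)
        report = evaluate_signature_associations(
            scores, region_means=meth, isoform_expression=iso,
            groups=groups, group_pair=("met", "pri"))
        assert report["score_vs_isoform"]["rho"] > 0
        assert report["score_vs_isoform"]["p"] < 0.05
        assert report["score_vs_methylation"]["rho"] < 0
        assert report["score_vs_methylation"]["p"] < 0.05

    def test_shuffled_scores_show_no_association(self):
        rng = np.random.default_rng(12)
        n = 60
        samples = [f"s{i}" for i in range(n)]
        meth = pd.Series(rng.uniform(0, 1, n), index=samples)
        shuffled = pd.Series(rng.permutation(meth.values), index=samples)
        expr = pd.DataFrame([shuffled + rng.normal(0, 0.1, n)],
                            index=["g1"], columns=samples)
        expr.loc["g2"] = shuffled + rng.normal(0, 0.1, n)
        scores = score_signature(expr, _sig(["g1", "g2"]))
        report = evaluate_signature_associations(scores, region_means=meth)
        assert abs(report["score_vs_methylation"]["rho"]) < 0.3
        assert report["score_vs_methylation"]["p"] > 0.05

    def test_identical_group_distributions_p_one(self):
        samples = [f"s{i}" for i in range(8)]
        expr = pd.DataFrame([np.tile([1.0, 2.0, 3.0, 4.0], 2)],
                            index=["g1"], columns=samples)
        scores = score_signature(expr, _sig(["g1"]))
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=samples)
        report = evaluate_signature_associations(
            scores, groups=groups, group_pair=("a", "b"))
        assert report["score_by_group"]["p"] == pytest.approx(1.0)

    def test_too_few_shared_samples_errors(self):
        expr = _expr({"g1": [0.0, 1.0]}, samples=["a", "b"])
        scores = score_signature(expr, _sig(["g1"]))
        with pytest.raises(ValidationError):
            evaluate_signature_associations(
                scores, region_means=pd.Series({"a": 0.2, "b": 0.4}))
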