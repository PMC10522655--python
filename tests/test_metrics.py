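import numpy as np
import pandas as pd
import pytest

from itrap import (SimilarityScores, annotate_expected_binders,
                   binding_concordance, classify_outliers,
                   clonotype_specificities, intra_inter_scores, metrics_report,
                   similarity_auc)
from itrap.errors import ConfigError

from conftest import gem_frame, make_capture, make_gem


def assigned_table(assignments, ct="c1"):
    """GEMs of one clonotype assigned per the list of feature ids."""
    rows = []
    for i, feat in enumerate(assignments):
        row = make_gem(i, captures=[make_capture(feat, 8)])
        row.update({"ct_id": ct, "assigned_pmhc": feat,
                    "cdr3_a": "CAVF", "cdr3_b": "CASSF"})
        rows.append(row)
    return pd.DataFrame(rows)


class TestConcordance:
    def test_entries_sum_to_one_per_clonotype(self):
        table = assigned_table(["X"] * 7 + ["Y"] * 3)
        entries, _ = binding_concordance(table)
        assert entries.concordance.sum() == pytest.approx(1.0, abs=1e-12)
        assert dict(zip(entries.pmhc, entries.concordance)) == \
            pytest.approx({"X": 0.7, "Y": 0.3})

    def test_unanimous_average_is_100(self):
        t1 = assigned_table(["X"] * 5, ct="c1")
        t2 = assigned_table(["Y"] * 3, ct="c2")
        _, avg = binding_concordance(pd.concat([t1, t2], ignore_index=True))
        assert avg == pytest.approx(100.0)

    def test_gem_weighted_average(self):
        table = assigned_table(["X"] * 7 + ["Y"] * 3)
        _, avg = binding_concordance(table)
        assert avg == pytest.approx(58.0)
        _, avg_unweighted = binding_concordance(table, gem_weighted=False)
        assert avg_unweighted == pytest.approx(50.0)

    def test_multi_clonotype_sums(self, sim_small):
        from itrap.pipeline import ItrapDenoiser
        table, truth = sim_small
        d = ItrapDenoiser(haplotypes=truth["haplotypes"])
        out = d.fit_transform(table)
        entries, _ = binding_concordance(out)
        sums = entries.groupby("ct_id").concordance.sum()
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestSimilarityAuc:
    def test_perfect_separation(self):
        assert similarity_auc(SimilarityScores(intra=[2.0] * 5, inter=[0.1] * 5)) \
            == pytest.approx(100.0)

    def test_exchangeable_lists(self):
        s = [0.3, 0.9, 1.5, 1.9]
        assert similarity_auc(SimilarityScores(intra=s, inter=list(s))) \
            == pytest.approx(50.0)

    def test_pair_counting_example(self):
        assert similarity_auc(SimilarityScores(intra=[2.0, 1.0], inter=[1.5, 0.5])) \
            == pytest.approx(75.0)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(6)
        intra = list(rng.uniform(0, 2, 17))
        inter = list(rng.uniform(0, 2, 23))
        brute = np.mean([(1.0 if a > b else 0.5 if a == b else 0.0)
                         for a in intra for b in inter]) * 100
        assert similarity_auc(SimilarityScores(intra=intra, inter=inter)) \
            == pytest.approx(brute)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        intra = list(rng.uniform(0.5, 2, 12))
        inter = list(rng.uniform(0, 1.5, 12))
        base = similarity_auc(SimilarityScores(intra=intra, inter=inter))
        for f in (np.exp, lambda v: np.asarray(v) ** 3, lambda v: 5 * np.asarray(v) - 1):
            transformed = similarity_auc(SimilarityScores(
                intra=list(f(np.array(intra))), inter=list(f(np.array(inter)))))
            assert transformed == pytest.approx(base)

    def test_empty_list_rejected(self):
        with pytest.raises(ConfigError):
            similarity_auc(SimilarityScores(intra=[], inter=[1.0]))


class TestIntraInter:
    def clonotypes(self):
        return pd.DataFrame([
            {"ct_id": "c1", "cdr3_a": "CAVF", "cdr3_b": "CASSF", "specificity": "X"},
            {"ct_id": "c2", "cdr3_a": "CAVF", "cdr3_b": "CASSF", "specificity": "X"},
            {"ct_id": "c3", "cdr3_a": "CWQYF", "cdr3_b": "CWWPWF", "specificity": "Y"},
            {"ct_id": "c4", "cdr3_a": "CWQYF", "cdr3_b": "CWWPWF", "specificity": "Y"},
        ])

    def test_identical_plateau_mates_score_two(self):
        scores = intra_inter_scores(self.clonotypes(), seed=0)
        assert all(s == pytest.approx(2.0) for s in scores.intra)
        assert len(scores.intra) == 4

    def test_seed_determinism(self):
        s1 = intra_inter_scores(self.clonotypes(), seed=42)
        s2 = intra_inter_scores(self.clonotypes(), seed=42)
        assert s1.intra == s2.intra and s1.inter == s2.inter

    def test_singleton_plateau_skipped(self):
        cts = self.clonotypes().iloc[[0, 1, 2]]   # Y has a single clonotype
        scores = intra_inter_scores(cts, seed=0)
        assert len(scores.intra) == 2


class TestOutliers:
    def build(self):
        # c1: 12 GEMs, 10 to X (expected binder), 2 assigned to Y while X is
        # present at lower UMI -> cross-reactivity pattern
        rows = []
        for i in range(10):
            row = make_gem(i, captures=[make_capture("X", 9)])
            row.update({"ct_id": "c1", "assigned_pmhc": "X"})
            rows.append(row)
        for i in range(10, 12):
            row = make_gem(i, captures=[make_capture("Y", 9, allele="B*08:01"),
                                        make_capture("X", 3)])
            row.update({"ct_id": "c1", "assigned_pmhc": "Y"})
            rows.append(row)
        # c2: small clonotype without expected binder, split assignments
        for i in range(12, 15):
            row = make_gem(i, captures=[make_capture(f"Z{i}", 4)])
            row.update({"ct_id": "c2", "assigned_pmhc": f"Z{i}"})
            rows.append(row)
        return pd.DataFrame(rows)

    def test_categories(self):
        table = self.build()
        anns = annotate_expected_binders(table)
        entries, _ = binding_concordance(table)
        out = classify_outliers(table, entries, anns)
        by_ct = out.groupby("ct_id").category.unique()
        assert list(by_ct["c1"]) == ["cross_reactivity"]
        assert list(by_ct["c2"]) == ["no_expected_binder"]
        assert out[out.ct_id == "c1"].hla_divergent.all()

    def test_unanimous_clonotype_has_no_outliers(self):
        table = assigned_table(["X"] * 10)
        anns = annotate_expected_binders(table)
        entries, _ = binding_concordance(table)
        assert classify_outliers(table, entries, anns).empty


def test_metrics_report_schema_and_bounds(sim_small):
    from itrap.pipeline import ItrapDenoiser
    table, truth = sim_small
    d = ItrapDenoiser(haplotypes=truth["haplotypes"])
    out = d.fit_transform(table)
    rep = metrics_report(out, len(table), d.annotator_.annotations_, seed=3)
    assert 0 <= rep.retention_pct <= 100
    assert 0 <= rep.accuracy_pct <= 100
    assert 0 <= rep.avg_concordance_pct <= 100
    assert 0 <= rep.similarity_auc_pct <= 100
    assert rep.n_gems == len(out)
    d2 = rep.as_dict()
    assert set(d2) >= {"retention_pct", "accuracy_pct", "avg_concordance_pct",
                       "similarity_auc_pct", "seed"}
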