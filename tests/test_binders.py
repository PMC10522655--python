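import itertools

import numpy as np
import pandas as pd
import pytest

from itrap import annotate_expected_binders, compute_accuracy, rank_sum_greater

from conftest import gem_frame, make_capture, make_gem


def enumeration_oracle(x, y):
    """Exact one-sided p-value by enumerating all label assignments, with U
    computed by direct pairwise counting (independent of the rank-sum route)."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(xs, ys):
        return sum((1.0 if a > b else 0.5 if a == b else 0.0)
                   for a in xs for b in ys)

    obs = u_stat(x, y)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if u_stat(xs, ys) >= obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


def clonotype_table(umi_lists, ct_id="ct1", donor="d1"):
    """One clonotype whose i-th GEM captures {feature: umi} from umi_lists[i]."""
    rows = []
    for i, caps in enumerate(umi_lists):
        rows.append(make_gem(i, donor=donor, captures=[
            make_capture(feat, umi) for feat, umi in caps.items()]))
    table = gem_frame(rows)
    table["ct_id"] = ct_id
    return table


class TestRankSum:
    def test_exact_path_matches_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            n1 = int(rng.integers(1, 8))
            n2 = int(rng.integers(1, 13 - n1))
            x = rng.integers(0, 6, n1)
            y = rng.integers(0, 6, n2)
            assert rank_sum_greater(x, y) == pytest.approx(
                enumeration_oracle(x, y), abs=1e-12)

    def test_separated_vectors_significant(self):
        a = [20, 22, 19, 25, 21, 18, 23, 20, 24, 22]
        b = [1, 2, 1, 1, 2, 1, 1, 2, 1, 1]
        assert rank_sum_greater(a, b) < 0.05

    def test_indistinguishable_vectors_not_significant(self):
        a = [3, 4, 3, 5, 4, 3, 4, 5, 3, 4]
        b = [4, 3, 5, 3, 4, 4, 3, 5, 4, 3]
        assert rank_sum_greater(a, b) >= 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_greater([], [1, 2])


class TestAnnotation:
    def test_clearly_dominant_pmhc_is_annotated(self):
        umis = [{"A": u, "B": b} for u, b in
                zip([20, 22, 19, 25, 21, 18, 23, 20, 24, 22],
                    [1, 2, 1, 1, 2, 1, 1, 2, 1, 1])]
        anns = annotate_expected_binders(clonotype_table(umis))
        assert len(anns) == 1 and anns[0].expected_pmhc == "A"
        assert all(p < 0.05 for p in anns[0].p_values.values())

    def test_indistinguishable_competitors_give_none(self):
        umis = [{"A": a, "B": b} for a, b in
                zip([3, 4, 3, 5, 4, 3, 4, 5, 3, 4],
                    [4, 3, 5, 3, 4, 4, 3, 5, 4, 3])]
        anns = annotate_expected_binders(clonotype_table(umis))
        assert anns[0].expected_pmhc is None

    def test_single_detected_pmhc_annotated_directly(self):
        umis = [{"A": 3}] * 12
        anns = annotate_expected_binders(clonotype_table(umis))
        assert anns[0].expected_pmhc == "A" and anns[0].p_values == {}

    def test_small_clonotypes_skipped(self):
        umis = [{"A": 20, "B": 1}] * 9
        assert annotate_expected_binders(clonotype_table(umis)) == []

    def test_raising_alpha_never_loses_annotations(self):
        rng = np.random.default_rng(7)
        tables = []
        for c in range(8):
            umis = [{f"F{i}": int(rng.integers(1, 20)) for i in
                     rng.choice(5, size=rng.integers(1, 4), replace=False)}
                    for _ in range(12)]
            tables.append(clonotype_table(umis, ct_id=f"ct{c}"))
        table = pd.concat(tables, ignore_index=True)
        counts = []
        for alpha in (0.01, 0.05, 0.2, 0.5):
            anns = annotate_expected_binders(table, alpha=alpha)
            counts.append(sum(a.expected_pmhc is not None for a in anns))
        assert counts == sorted(counts)


class TestAccuracy:
    def test_pooled_fraction(self):
        t1 = clonotype_table([{"A": 9, "B": 1}] * 8 + [{"B": 7}] * 2, ct_id="c1")
        t2 = clonotype_table([{"C": 20, "B": 1}] * 6 + [{"C": 2, "B": 3}] * 4,
                             ct_id="c2")
        table = pd.concat([t1, t2], ignore_index=True)
        anns = annotate_expected_binders(table)
        assert {a.ct_id: a.expected_pmhc for a in anns} == {"c1": "A", "c2": "C"}
        acc, breakdown = compute_accuracy(table, anns)
        assert acc == pytest.approx(14 / 20)

    def test_all_match_is_one(self):
        table = clonotype_table([{"A": 9}] * 10)
        anns = annotate_expected_binders(table)
        acc, _ = compute_accuracy(table, anns)
        assert acc == 1.0

    def test_top_capture_tie_counts_as_miss(self):
        table = clonotype_table([{"A": 9, "B": 2}] * 9 + [{"A": 5, "B": 5}])
        anns = annotate_expected_binders(table)
        acc, _ = compute_accuracy(table, anns)
        assert acc == pytest.approx(9 / 10)

    def test_empty_denominator_is_none(self):
        table = clonotype_table([{"A": 9}] * 3)   # too small to annotate
        acc, breakdown = compute_accuracy(table, annotate_expected_binders(table))
        assert acc is None and breakdown.empty

    def test_invariant_under_feature_relabeling(self):
        table = clonotype_table([{"A": 9, "B": 1}] * 12)
        relabeled = table.copy(deep=True)
        relabeled["captures"] = [
            [{**c, "feature_id": c["feature_id"] + "_x"} for c in caps]
            for caps in relabeled["captures"]]
        acc1, _ = compute_accuracy(table, annotate_expected_binders(table))
        acc2, _ = compute_accuracy(relabeled, annotate_expected_binders(relabeled))
        assert acc1 == acc2
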