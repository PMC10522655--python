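import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itrap import (ClonotypeAssigner, impute_missing_chain, redefine_clonotypes,
                   resolve_multiplet_chains)

from conftest import gem_frame, make_chain, make_gem


def paired_gem(i, cdr3_a="CAVF", cdr3_b="CASSF", **kw):
    return make_gem(i, chains=[
        make_chain("alpha", "TRAV1", "TRAJ1", cdr3_a, umi=2),
        make_chain("beta", "TRBV1", "TRBJ1", cdr3_b, umi=3),
    ], **kw)


class TestMultipletResolution:
    def test_most_abundant_chain_selected(self):
        table = gem_frame([make_gem(0, chains=[
            make_chain("alpha", "TRAV1", "TRAJ1", "CAVF", umi=5),
            make_chain("alpha", "TRAV2", "TRAJ2", "CAVVF", umi=2),
            make_chain("beta", "TRBV1", "TRBJ1", "CASSF", umi=3),
        ])])
        out = resolve_multiplet_chains(table)
        row = out.iloc[0]
        assert (row.cdr3_a, row.umi_a) == ("CAVF", 5)
        assert row.cdr3_b == "CASSF"
        assert [c["cdr3_aa"] for c in row.extra_chains] == ["CAVVF"]

    def test_single_pair_unchanged(self):
        out = resolve_multiplet_chains(gem_frame([paired_gem(0)]))
        row = out.iloc[0]
        assert (row.cdr3_a, row.cdr3_b) == ("CAVF", "CASSF")
        assert row.extra_chains == []

    def test_umi_tie_breaks_lexicographically(self):
        chains = [make_chain("beta", "TRBV9", "TRBJ1", "CASSZF"[:5], umi=3),
                  make_chain("beta", "TRBV2", "TRBJ1", "CASSF", umi=3)]
        out = resolve_multiplet_chains(gem_frame([make_gem(0, chains=chains)]))
        assert out.iloc[0].v_b == "TRBV2"

    @given(st.permutations(range(4)))
    @settings(max_examples=20, deadline=None)
    def test_selection_is_order_invariant(self, order):
        chains = [make_chain("beta", f"TRBV{i}", "TRBJ1", "CASSF", umi=[3, 3, 1, 2][i])
                  for i in range(4)]
        shuffled = [chains[i] for i in order]
        out = resolve_multiplet_chains(gem_frame([make_gem(0, chains=shuffled)]))
        assert out.iloc[0].v_b == "TRBV0"   # tie between TRBV0/TRBV1 at umi=3


class TestRedefinition:
    def test_identical_six_tuples_group(self):
        table = resolve_multiplet_chains(gem_frame([paired_gem(i) for i in range(3)]))
        out, summary = redefine_clonotypes(table)
        assert out.ct_id.nunique() == 1
        assert summary["size"].tolist() == [3]

    def test_distinct_cdr3a_separates(self):
        table = resolve_multiplet_chains(gem_frame([
            paired_gem(0, cdr3_a="CAVF"), paired_gem(1, cdr3_a="CAVYF")]))
        out, summary = redefine_clonotypes(table)
        assert out.ct_id.nunique() == 2

    def test_empty_table(self):
        table = resolve_multiplet_chains(gem_frame([]))
        out, summary = redefine_clonotypes(table)
        assert summary.empty and out.empty

    def test_sizes_sum_to_assigned_gems(self, sim_small):
        table, _ = sim_small
        assigner = ClonotypeAssigner()
        out = assigner.fit_transform(table)
        assert assigner.clonotypes_["size"].sum() == out.ct_id.notna().sum()


class TestImputation:
    def base(self):
        rows = [paired_gem(i) for i in range(2)]
        rows.append(make_gem(10, chains=[
            make_chain("beta", "TRBV1", "TRBJ1", "CASSF", umi=2)]))
        return gem_frame(rows)

    def test_unique_half_key_imputed(self):
        table, summary = redefine_clonotypes(resolve_multiplet_chains(self.base()))
        out = impute_missing_chain(table, summary)
        row = out.iloc[2]
        assert row.imputed_a and row.cdr3_a == "CAVF" and row.umi_a == 0
        assert row.ct_id == out.iloc[0].ct_id

    def test_ambiguous_half_key_not_imputed(self):
        rows = [paired_gem(0, cdr3_a="CAVF"), paired_gem(1, cdr3_a="CAVF"),
                paired_gem(2, cdr3_a="CAVYF"),
                make_gem(10, chains=[make_chain("beta", "TRBV1", "TRBJ1",
                                                "CASSF", umi=2)])]
        table, summary = redefine_clonotypes(resolve_multiplet_chains(gem_frame(rows)))
        out = impute_missing_chain(table, summary)
        assert pd.isna(out.iloc[3].cdr3_a) and pd.isna(out.iloc[3].ct_id)

    def test_unseen_half_key_not_imputed(self):
        rows = [paired_gem(0),
                make_gem(10, chains=[make_chain("beta", "TRBV9", "TRBJ9",
                                                "CASSWF", umi=2)])]
        table, summary = redefine_clonotypes(resolve_multiplet_chains(gem_frame(rows)))
        out = impute_missing_chain(table, summary)
        assert pd.isna(out.iloc[1].ct_id)

    def test_imputation_never_changes_existing_pairs(self, sim_small):
        table, _ = sim_small
        resolved, summary = redefine_clonotypes(resolve_multiplet_chains(table))
        out = impute_missing_chain(resolved, summary)
        before = resolved[resolved.cdr3_a.notna() & resolved.cdr3_b.notna()]
        after = out.loc[before.index]
        pd.testing.assert_frame_equal(
            before[["cdr3_a", "cdr3_b", "v_a", "v_b"]],
            after[["cdr3_a", "cdr3_b", "v_a", "v_b"]])


def test_redefine_after_impute_is_fixed_point(sim_small):
    table, _ = sim_small
    out = ClonotypeAssigner().fit_transform(table)
    paired = out[out.cdr3_a.notna() & out.cdr3_b.notna()]
    again, _ = redefine_clonotypes(out)
    # the partition is unchanged: same groups of barcodes
    key = ["v_a", "j_a", "cdr3_a", "v_b", "j_b", "cdr3_b"]
    g1 = paired.groupby("ct_id")["barcode_full"].apply(frozenset)
    g2 = again[again.ct_id.notna()].groupby("ct_id")["barcode_full"].apply(frozenset)
    assert set(g1) == set(g2)


def test_partition_invariant_under_gem_order(sim_small):
    table, _ = sim_small
    out1 = ClonotypeAssigner().fit_transform(table)
    shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
    out2 = ClonotypeAssigner().fit_transform(shuffled)
    g1 = out1[out1.ct_id.notna()].groupby("ct_id")["barcode_full"].apply(frozenset)
    g2 = out2[out2.ct_id.notna()].groupby("ct_id")["barcode_full"].apply(frozenset)
    assert set(g1) == set(g2)
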