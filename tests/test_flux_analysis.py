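"""Fold-change algebra, ranking, clustering, subsystem tallies and cofactor
views."""

import numpy as np
import pandas as pd
import pytest

from entroflux.flux_analysis import (
    cluster_models_and_reactions,
    cut_columns,
    fold_changes,
    flux_table,
    linkage_to_newick,
    select_cofactor_reactions,
    shared_reactions,
    subsystem_tally,
    top_k_reactions,
)
from entroflux.model_core import MetabolicModel, Metabolite, Reaction
from entroflux.synthetic_data import SyntheticScenario, make_toy_network


def table_from(rows: dict, conditions: dict) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.index.name = "reaction"
    df.attrs["conditions"] = conditions
    return df


COND = {"d1": "disease", "c1": "control", "c2": "control", "c3": "control"}


class TestSharedReactions:
    def test_identical_models_full_set(self, toy):
        model, _ = toy
        assert shared_reactions([model, model.copy()]) == set(model.reaction_ids())

    def test_missing_reaction_excluded(self, toy):
        model, _ = toy
        keep = [r for r in model.reaction_ids() if r != "r_hex"]
        sub = model.subset(keep, name="partial")
        shared = shared_reactions([model, sub])
        assert "r_hex" not in shared
        assert shared == set(keep)

    def test_empty_intersection_is_error(self):
        mets = [Metabolite("x[c]")]
        m1 = MetabolicModel("a", mets, [Reaction("r1", {"x[c]": -1.0})])
        m2 = MetabolicModel("b", mets, [Reaction("r2", {"x[c]": -1.0})])
        with pytest.raises(ValueError):
            shared_reactions([m1, m2])


class TestFoldChanges:
    def test_basic_arithmetic(self):
        table = table_from({"r1": {"d1": 3.0, "c1": 2.0, "c2": 2.0, "c3": 2.0}},
                           COND)
        fc = fold_changes(table, ["c1", "c2", "c3"])
        assert fc.values.loc["r1", "d1"] == pytest.approx(0.5)
        assert fc.values.loc["r1", "c1"] == pytest.approx(0.0)

    def test_identical_columns_all_zero(self):
        table = table_from({"r1": {"d1": 2.0, "c1": 2.0, "c2": 2.0, "c3": 2.0},
                            "r2": {"d1": -4.0, "c1": -4.0, "c2": -4.0, "c3": -4.0}},
                           COND)
        fc = fold_changes(table, ["c1", "c2", "c3"])
        assert (fc.values.to_numpy() == 0.0).all()

    def test_zero_control_mean_masked_not_divided(self):
        cond = {"d1": "disease", "c1": "control", "c2": "control"}
        table = table_from({"r1": {"d1": 3.0, "c1": 1.0, "c2": -1.0}}, cond)
        fc = fold_changes(table, ["c1", "c2"])
        assert fc.mask.loc["r1"].all()
        assert fc.values.loc["r1"].isna().all()

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(12, 4)) + 2.0
        table = pd.DataFrame(base, columns=list(COND),
                             index=[f"r{i}" for i in range(12)])
        table.attrs["conditions"] = COND
        scaled = table * 7.5
        scaled.attrs["conditions"] = COND
        fc_a = fold_changes(table, ["c1", "c2", "c3"])
        fc_b = fold_changes(scaled, ["c1", "c2", "c3"])
        pd.testing.assert_frame_equal(fc_a.values, fc_b.values)

    def test_control_ids_must_exist(self):
        table = table_from({"r1": {"d1": 1.0}}, {"d1": "disease"})
        with pytest.raises(ValueError):
            fold_changes(table, ["ghost"])


class TestTopK:
    def test_k_larger_than_table_returns_all_ranked(self):
        table = table_from({"r1": {"d1": 3.0, "c1": 2.0, "c2": 2.0, "c3": 2.0},
                            "r2": {"d1": 1.0, "c1": 2.0, "c2": 2.0, "c3": 2.0}},
                           COND)
        fc = fold_changes(table, ["c1", "c2", "c3"])
        top = top_k_reactions(fc, k=50)
        # both reactions tie at |FC| = 0.5; lexicographic tie-break
        assert list(top.index) == ["r1", "r2"]

    def test_absolute_value_ranks_negative_first(self):
        values = pd.DataFrame({"m1": [1.5, -2.0]}, index=["ra", "rb"])
        top = top_k_reactions(values, k=2)
        assert list(top.index) == ["rb", "ra"]
        assert top.loc["rb", "score"] == pytest.approx(2.0)

    def test_deterministic_and_tie_broken_lexicographically(self):
        values = pd.DataFrame({"m1": [1.0, 1.0, 0.5]}, index=["rz", "ra", "rm"])
        top1 = top_k_reactions(values, k=2)
        top2 = top_k_reactions(values.copy(), k=2)
        assert list(top1.index) == ["ra", "rz"]
        assert list(top1.index) == list(top2.index)

    def test_masked_entries_ignored(self):
        values = pd.DataFrame({"m1": [np.nan, 0.1]}, index=["ra", "rb"])
        top = top_k_reactions(values, k=5)
        # rows with no defined entry are excluded entirely
        assert list(top.index) == ["rb"]
        values_all_nan = pd.DataFrame({"m1": [np.nan], "m2": [np.nan]},
                                      index=["ra"])
        with pytest.raises(ValueError):
            top_k_reactions(values_all_nan, k=1)

    def test_aggregate_selectable(self):
        values = pd.DataFrame({"m1": [3.0, 1.0], "m2": [0.0, 1.0]},
                              index=["ra", "rb"])
        assert list(top_k_reactions(values, 2, "max").index) == ["ra", "rb"]
        assert list(top_k_reactions(values, 2, "mean").index) == ["ra", "rb"]
        values2 = pd.DataFrame({"m1": [3.0, 2.0], "m2": [0.0, 2.0]},
                               index=["ra", "rb"])
        assert list(top_k_reactions(values2, 2, "mean").index) == ["rb", "ra"]


class TestClustering:
    def test_duplicated_column_groups_split_at_zero_height(self):
        rng = np.random.default_rng(1)
        block = rng.normal(size=(8, 1))
        X = pd.DataFrame(
            np.hstack([block, block, block + 5, block + 5]),
            columns=["a1", "a2", "b1", "b2"],
            index=[f"r{i}" for i in range(8)],
        )
        clust = cluster_models_and_reactions(X)
        link = clust["col_linkage"]
        # first two merges happen at height 0 (identical columns)
        assert link[0, 2] == pytest.approx(0.0)
        assert link[1, 2] == pytest.approx(0.0)
        cut = cut_columns(clust, 2)
        assert cut["a1"] == cut["a2"] != cut["b1"] == cut["b2"]

    def test_column_permutation_gives_same_tree(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(10, 4)),
                         columns=["m1", "m2", "m3", "m4"],
                         index=[f"r{i}" for i in range(10)])
        c1 = cluster_models_and_reactions(X)
        c2 = cluster_models_and_reactions(X[["m3", "m1", "m4", "m2"]])
        cut1, cut2 = cut_columns(c1, 2), cut_columns(c2, 2)
        groups1 = {frozenset(k for k, v in cut1.items() if v == g)
                   for g in set(cut1.values())}
        groups2 = {frozenset(k for k, v in cut2.items() if v == g)
                   for g in set(cut2.values())}
        assert groups1 == groups2

    def test_constant_matrix_warns(self):
        X = pd.DataFrame(np.zeros((3, 3)), columns=list("abc"),
                         index=["r1", "r2", "r3"])
        with pytest.warns(UserWarning):
            cluster_models_and_reactions(X)

    def test_newick_output_parses(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("wxyz"),
                         index=[f"r{i}" for i in range(6)])
        clust = cluster_models_and_reactions(X)
        newick = linkage_to_newick(clust["col_linkage"], clust["col_labels"])
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set("wxyz")


class TestSubsystemTally:
    def _model(self):
        mets = [Metabolite("x[c]")]
        rxns = [
            Reaction("r1", {"x[c]": -1.0}, subsystem="Gly"),
            Reaction("r2", {"x[c]": -1.0}, subsystem="Gly"),
            Reaction("r3", {"x[c]": -1.0}, subsystem="TCA"),
            Reaction("r4", {"x[c]": -1.0}, subsystem="Lip"),
            Reaction("r5", {"x[c]": -1.0}, subsystem="Lip"),
            Reaction("r6", {"x[c]": -1.0}, subsystem="Lip"),
        ]
        return MetabolicModel("tally", mets, rxns)

    def test_singleton_merged_into_others(self):
        tally = subsystem_tally(["r1", "r2", "r3"], self._model())
        assert tally["counts"] == {"Gly": 2, "others": 1}

    def test_single_subsystem_no_others(self):
        tally = subsystem_tally(["r4", "r5", "r6"], self._model())
        assert tally["counts"] == {"Lip": 3}

    def test_top_five_cutoff_and_ordering(self):
        mets = [Metabolite("x[c]")]
        rxns, expected = [], []
        for s, n in zip("ABCDEF", (10, 9, 8, 7, 6, 5)):
            for i in range(n):
                rxns.append(Reaction(f"r_{s}{i}", {"x[c]": -1.0}, subsystem=s))
        model = MetabolicModel("six", mets, rxns)
        tally = subsystem_tally([r.id for r in rxns], model, top_n=5)
        assert [s for s, _ in tally["top"]] == list("ABCDE")
        assert tally["counts"]["F"] == 5  # present in counts, not in top five


class TestCofactorViews:
    def test_mitochondrial_nad_reactions_match_ground_truth(self, toy):
        model, truth = toy
        rids = select_cofactor_reactions(model, ("nad", "nadh"), "m")
        assert rids == set(truth.cofactor_reactions_m)

    def test_cytosolic_nad_reactions_match_ground_truth(self, toy):
        model, truth = toy
        rids = select_cofactor_reactions(model, ("nad", "nadh"), "c")
        assert rids == set(truth.cofactor_reactions_c)

    def test_extracellular_compartment_has_no_cofactor(self, toy):
        model, _ = toy
        assert select_cofactor_reactions(model, ("nad", "nadh"), "e") == set()

    def test_subsystem_mode(self, toy):
        model, _ = toy
        rids = select_cofactor_reactions(model, subsystem="NAD metabolism")
        assert rids == {"r_nadsyn", "r_naddeg"}

    def test_unknown_compartment_is_error(self, toy):
        model, _ = toy
        with pytest.raises(ValueError):
            select_cofactor_reactions(model, ("nad",), "z")


class TestFluxTable:
    def test_requires_control_column(self):
        with pytest.raises(ValueError):
            flux_table({"m1": {"r1": 1.0}}, {"m1": "disease"})

    def test_restricts_to_common_reactions(self):
        sols = {"m1": {"r1": 1.0, "r2": 2.0}, "m2": {"r1": 3.0}}
        table = flux_table(sols, {"m1": "disease", "m2": "control"})
        assert list(table.index) == ["r1"]
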