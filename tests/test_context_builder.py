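"""Context-specific model extraction: thresholding, uptake bounds, evidence
merging and flux-consistency pruning."""

import numpy as np
import pandas as pd
import pytest

from entroflux.context_builder import (
    CultureMeasurement,
    CurationSpec,
    ExtractionConfig,
    ExtractionError,
    OmicsEvidence,
    apply_exchange_constraints,
    cell_dry_weight,
    classify_genes,
    compute_uptake_bound,
    extract_context_model,
    find_blocked_reactions,
    resolve_conflicts,
)
from entroflux.model_core import MetabolicModel, Metabolite, Reaction
from entroflux.synthetic_data import (
    SyntheticScenario,
    make_fixture_chain,
    make_toy_network,
)


class TestClassifyGenes:
    def test_threshold_is_inclusive(self):
        active, inactive = classify_genes({"g1": 5.0, "g2": 1.9, "g3": 2.0}, 2.0)
        assert active == {"g1", "g3"}
        assert inactive == {"g2"}

    def test_all_zero_expression(self):
        active, inactive = classify_genes({"g1": 0.0, "g2": 0.0}, 2.0)
        assert active == set()
        assert inactive == {"g1", "g2"}

    def test_lower_threshold_activates(self):
        active, _ = classify_genes({"g2": 1.9}, 0.5)
        assert active == {"g2"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        tpm = {f"g{i}": float(rng.uniform(0, 10)) for i in range(50)}
        previous = None
        for threshold in (0.5, 1.0, 2.0, 4.0, 8.0):
            active, _ = classify_genes(tpm, threshold)
            if previous is not None:
                assert active <= previous
            previous = active

    def test_dataframe_uses_mean_across_samples(self):
        df = pd.DataFrame({"s1": [1.0], "s2": [5.0]}, index=["g1"])
        active, _ = classify_genes(df, 2.0)  # mean 3.0
        assert active == {"g1"}

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            classify_genes({}, 2.0)


class TestUptakeBounds:
    def test_dry_weight_from_protein_fraction(self):
        assert cell_dry_weight(0.5593, 0.5593) == pytest.approx(1.0)
        assert cell_dry_weight(0.0) == 0.0
        assert cell_dry_weight(2.5, 1.0) == pytest.approx(2.5)
        with pytest.raises(ValueError):
            cell_dry_weight(1.0, 0.0)

    def test_worked_uptake_example(self):
        m = CultureMeasurement(
            metabolite="glc", concentration=100.0, media_volume=0.002,
            interval=48.0, protein_mass=5.593e-4, protein_fraction=0.5593,
        )
        assert compute_uptake_bound(m) == pytest.approx(0.2 / (1e-3 * 48))
        assert compute_uptake_bound(m) == pytest.approx(4.1667, abs=1e-4)

    def test_zero_concentration_zero_uptake(self):
        m = CultureMeasurement("glc", 0.0, 0.002, 48.0, 5.593e-4)
        assert compute_uptake_bound(m) == 0.0

    def test_scaling_laws(self):
        base = CultureMeasurement("glc", 100.0, 0.002, 48.0, 5.593e-4)
        u = compute_uptake_bound(base)
        double_conc = CultureMeasurement("glc", 200.0, 0.002, 48.0, 5.593e-4)
        double_interval = CultureMeasurement("glc", 100.0, 0.002, 96.0, 5.593e-4)
        double_protein = CultureMeasurement("glc", 100.0, 0.002, 48.0, 2 * 5.593e-4)
        assert compute_uptake_bound(double_conc) == pytest.approx(2 * u)
        assert compute_uptake_bound(double_interval) == pytest.approx(u / 2)
        assert compute_uptake_bound(double_protein) == pytest.approx(u / 2)

    def test_literal_mode_divides_by_protein(self):
        m = CultureMeasurement("glc", 100.0, 0.002, 48.0, 5.593e-4)
        literal = compute_uptake_bound(m, literal_protein_term=True)
        assert literal == pytest.approx(compute_uptake_bound(m) / 5.593e-4)


def _exchange_model():
    mets = [Metabolite("A[e]"), Metabolite("h[e]"), Metabolite("B[e]"),
            Metabolite("A[c]")]
    rxns = [
        Reaction("EX_A", {"A[e]": -1.0}, -1000, 1000),
        Reaction("EX_h", {"h[e]": -1.0}, -1000, 1000),
        Reaction("EX_B", {"B[e]": -1.0}, -1000, 1000),
        Reaction("t_A", {"A[e]": -1.0, "A[c]": 1.0}, -1000, 1000),
    ]
    return MetabolicModel("ex", mets, rxns)


class TestExchangeConstraints:
    def test_media_uptake_sets_negative_lower_bound(self):
        model, report = apply_exchange_constraints(
            _exchange_model(), {"A": 4.1667}, ExtractionConfig()
        )
        ex = model.get_reaction("EX_A")
        assert ex.lower_bound == pytest.approx(-4.1667)
        assert ex.upper_bound == 1000.0
        assert report == []

    def test_ion_exchange_closed(self):
        model, _ = apply_exchange_constraints(_exchange_model(), {},
                                              ExtractionConfig())
        ex = model.get_reaction("EX_h")
        assert (ex.lower_bound, ex.upper_bound) == (0.0, 0.0)

    def test_absent_metabolite_closed_to_export_only(self):
        model, _ = apply_exchange_constraints(_exchange_model(), {"A": 1.0},
                                              ExtractionConfig())
        ex = model.get_reaction("EX_B")
        assert (ex.lower_bound, ex.upper_bound) == (0.0, 1000.0)

    def test_strict_mode_fixes_rate(self):
        cfg = ExtractionConfig(strict_uptakes=True)
        model, _ = apply_exchange_constraints(_exchange_model(), {"A": 2.0}, cfg)
        ex = model.get_reaction("EX_A")
        assert (ex.lower_bound, ex.upper_bound) == (-2.0, -2.0)

    def test_uptake_without_exchange_warns(self):
        with pytest.warns(UserWarning):
            _, report = apply_exchange_constraints(
                _exchange_model(), {"ghost": 1.0}, ExtractionConfig()
            )
        assert any("ghost" in w for w in report)


class TestResolveConflicts:
    def test_experimental_priority_wins(self):
        omics = OmicsEvidence({"g1": 0.5}, set(), {"g1"})
        curation = CurationSpec(active_genes={"g1"})
        merged, log = resolve_conflicts(omics, curation,
                                        ("experimental", "curation"))
        assert "g1" in merged["inactive_genes"]
        assert any("overridden" in entry for entry in log)

    def test_reversed_priority_curation_wins(self):
        omics = OmicsEvidence({"g1": 0.5}, set(), {"g1"})
        curation = CurationSpec(active_genes={"g1"})
        merged, _ = resolve_conflicts(omics, curation,
                                      ("curation", "experimental"))
        assert "g1" in merged["active_genes"]

    def test_no_conflict_is_union(self):
        omics = OmicsEvidence({"g1": 5.0}, {"g1"}, set())
        curation = CurationSpec(active_genes={"g2"},
                                active_reactions={"r9"})
        merged, log = resolve_conflicts(omics, curation)
        assert merged["active_genes"] == {"g1", "g2"}
        assert merged["active_reactions"] == {"r9"}
        assert log == []


class TestBlockedReactions:
    def test_toy_dead_branch_matches_ground_truth(self, toy):
        model, truth = toy
        constrained, _ = apply_exchange_constraints(
            model,
            {"glc": 10.0, "ncam": 1.0, "tyr_L": 1.0},
            ExtractionConfig(),
        )
        blocked = find_blocked_reactions(constrained)
        # dead branch plus the closed sodium pair
        assert blocked == set(truth.blocked_reactions) | {"EX_na1", "t_na1"}

    def test_open_chain_nothing_blocked(self):
        model = make_fixture_chain(2, uptake=0.0)
        model.get_reaction("EX_A").lower_bound = -10.0
        model.get_reaction("EX_A").upper_bound = 0.0
        assert find_blocked_reactions(model) == set()

    def test_all_exchanges_closed_blocks_everything(self):
        model = make_fixture_chain(2, uptake=0.0)
        for rid in ("EX_A", "EX_B"):
            rxn = model.get_reaction(rid)
            rxn.lower_bound = rxn.upper_bound = 0.0
        blocked = find_blocked_reactions(model)
        assert blocked == set(model.reaction_ids())

    def test_agrees_with_cobrapy_on_toy_network(self, toy):
        """Independent cross-check of the FVA-based blocked set."""
        cobra = pytest.importorskip("cobra")
        from entroflux.model_core import _to_cobra

        model, _ = toy
        constrained, _ = apply_exchange_constraints(
            model, {"glc": 10.0, "ncam": 1.0, "tyr_L": 1.0}, ExtractionConfig()
        )
        mine = find_blocked_reactions(constrained)
        cm = _to_cobra(constrained)
        theirs = set(cobra.flux_analysis.find_blocked_reactions(cm))
        assert mine == theirs


class TestExtraction:
    def _merged(self, model, active_genes):
        genes = model.genes
        return {
            "active_genes": set(active_genes),
            "inactive_genes": genes - set(active_genes),
            "active_reactions": set(),
            "inactive_reactions": set(),
            "fixed_rates": {},
        }

    def test_inactive_branch_removed_others_intact(self, toy):
        model, truth = toy
        constrained, _ = apply_exchange_constraints(
            model, {"glc": 10.0, "ncam": 1.0, "tyr_L": 1.0}, ExtractionConfig()
        )
        vulnerable_genes = {f"g_{rid}" for rid in truth.vulnerable_reactions}
        active = model.genes - vulnerable_genes - set(
            truth.inactive_genes_by_design
        )
        context, report = extract_context_model(
            constrained, self._merged(model, active)
        )
        removed = set(constrained.reaction_ids()) - set(context.reaction_ids())
        expected = (set(truth.vulnerable_reactions)
                    | set(truth.blocked_reactions) | {"EX_na1", "t_na1"})
        assert removed == expected
        assert find_blocked_reactions(context) == set()

    def test_identity_when_everything_active(self):
        model = make_fixture_chain(2, uptake=0.0)
        model.get_reaction("EX_A").lower_bound = -10.0
        model.get_reaction("EX_A").upper_bound = 0.0
        merged = {"active_genes": set(), "inactive_genes": set(),
                  "active_reactions": set(), "inactive_reactions": set(),
                  "fixed_rates": {}}
        context, report = extract_context_model(model, merged)
        assert set(context.reaction_ids()) == set(model.reaction_ids())
        assert report["unsatisfiable_active_genes"] == []

    def test_active_gene_with_only_blocked_reaction_reported(self):
        mets = [Metabolite("a[c]"), Metabolite("dead[c]")]
        rxns = [
            Reaction("EX_a", {"a[c]": -1.0}, -10, 10),
            Reaction("r_dead", {"a[c]": -1.0, "dead[c]": 1.0}, 0, 10,
                     gpr="g_dead"),
        ]
        model = MetabolicModel("m", mets, rxns)
        merged = {"active_genes": {"g_dead"}, "inactive_genes": set(),
                  "active_reactions": set(), "inactive_reactions": set(),
                  "fixed_rates": {}}
        context, report = extract_context_model(model, merged)
        assert report["unsatisfiable_active_genes"] == ["g_dead"]
        assert "r_dead" not in context.reaction_ids()

    def test_designated_active_blocked_reaction_is_error(self):
        mets = [Metabolite("a[c]"), Metabolite("dead[c]")]
        rxns = [
            Reaction("EX_a", {"a[c]": -1.0}, -10, 10),
            Reaction("r_dead", {"a[c]": -1.0, "dead[c]": 1.0}, 0, 10),
        ]
        model = MetabolicModel("m", mets, rxns)
        merged = {"active_genes": set(), "inactive_genes": set(),
                  "active_reactions": {"r_dead"}, "inactive_reactions": set(),
                  "fixed_rates": {}}
        with pytest.raises(ExtractionError):
            extract_context_model(model, merged)

    def test_inactive_reaction_retained_when_required(self):
        """A GPR-inactive reaction on the only path to a designated-active
        one must be kept and logged."""
        model = make_fixture_chain(2, uptake=0.0)
        model.get_reaction("EX_A").lower_bound = -10.0
        model.get_reaction("EX_A").upper_bound = 0.0
        model.get_reaction("R1").gpr = "g_off"
        merged = {"active_genes": set(), "inactive_genes": {"g_off"},
                  "active_reactions": {"R2"}, "inactive_reactions": set(),
                  "fixed_rates": {}}
        context, report = extract_context_model(model, merged)
        assert "R2" in context.reaction_ids()
        assert "R1" in report["retained_inactive_gpr"]

    def test_extraction_deterministic(self, toy):
        model, truth = toy
        constrained, _ = apply_exchange_constraints(
            model, {"glc": 10.0, "ncam": 1.0, "tyr_L": 1.0}, ExtractionConfig()
        )
        merged = self._merged(model, model.genes)
        a, _ = extract_context_model(constrained, merged)
        b, _ = extract_context_model(constrained, merged)
        assert a == b
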