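import numpy as np
import pytest

from contextcore import fixtures
from contextcore.consistency import EpsilonPolicy, fastcc
from contextcore.expression import consensus_frame, discretize_frame
from contextcore.fastcore import CoreSets
from contextcore.gpr_mapping import map_scores
from contextcore.workflow import (CONF_HIGH, CONF_LOW, CONF_MODERATE,
                                  EXCL_MULTI, EXCL_SINGLE, MediumSpec,
                                  apply_medium, build_core_sets, crossvalidate,
                                  exchange_reactions, reconstruct)

POLICY = EpsilonPolicy()


class TestBuildCoreSets:
    def test_direct_rule_application(self, toy1_consistent):
        scores = {"R1": 1, "R_TA": 1, "R3": -1}
        sets = build_core_sets(toy1_consistent, scores,
                               transporters={"R_TA"})
        assert sets.core == {"R1"}
        assert sets.non_penalized == {"R_TA"}
        assert sets.inactive == {"R3"}

    def test_all_zero_scores_empty_core(self, toy1_consistent):
        sets = build_core_sets(toy1_consistent, {"R1": 0, "R2": 0})
        assert sets.core == set() and sets.inactive == set()

    def test_transporter_only_core_stays_empty(self, toy1_consistent):
        sets = build_core_sets(toy1_consistent, {"R_TA": 1},
                               transporters={"R_TA"})
        assert sets.core == set()
        assert sets.non_penalized == {"R_TA"}

    def test_transporters_autodetected(self, toy1_consistent):
        sets = build_core_sets(toy1_consistent, {"R_TA": 1})
        assert sets.non_penalized == {"R_TA"}


class TestApplyMedium:
    def test_single_medium_metabolite(self, toy1_model):
        out = apply_medium(toy1_model, MediumSpec(["A_e"]), POLICY)
        j = out.reaction_index("R_EXA")
        assert out.lb[j] < 0  # uptake of A stays open

    def test_full_medium_is_identity_up_to_fastcc(self, toy1_model):
        extracellular = [m for m, c in toy1_model.compartment.items()
                         if c == "e"]
        out = apply_medium(toy1_model, MediumSpec(extracellular), POLICY)
        assert set(out.reaction_ids) == fastcc(toy1_model, POLICY)

    def test_unknown_metabolite_warns_and_skips(self, toy1_model):
        with pytest.warns(UserWarning, match="skipped"):
            apply_medium(toy1_model, MediumSpec(["A_e", "nope_e"]), POLICY)

    def test_missing_carbon_source_blocks_core(self, toy1_model):
        out = apply_medium(toy1_model, MediumSpec([]), POLICY)
        # nothing can be taken up: the whole network is blocked
        assert "R1" not in out.reaction_ids

    def test_missing_exchange_added_on_demand(self, toy1_model):
        model = toy1_model.restrict(
            [r for r in toy1_model.reaction_ids if r != "R_EXA"])
        out = apply_medium(model, MediumSpec(["A_e"]), POLICY)
        added = [r for r in out.reaction_ids if r.startswith("EX_A_e")]
        assert added and "R1" in out.reaction_ids

    def test_exchange_detection(self, toy1_model):
        assert exchange_reactions(toy1_model) == {
            "R_EXA": "A_e", "R_EXC": "C_c", "R_EXD": "D_c"}


class TestReconstruct:
    def test_core_r2_support_path(self, toy1_consistent):
        ctx = reconstruct(toy1_consistent, CoreSets(core={"R2"}), policy=POLICY)
        assert ctx.retained == {"R_EXA", "R_TA", "R1", "R2", "R_EXC"}

    def test_empty_core_warns_and_returns_empty(self, toy1_consistent):
        with pytest.warns(UserWarning, match="empty"):
            ctx = reconstruct(toy1_consistent, CoreSets(), policy=POLICY)
        assert ctx.retained == set()

    def test_inactive_bounds_removed_before_extraction(self, toy1_consistent):
        ctx = reconstruct(toy1_consistent,
                          CoreSets(core={"R2"}, inactive={"R3"}),
                          policy=POLICY)
        assert "R3" not in ctx.retained

    def test_biomass_two_pass(self):
        model, _ = fixtures.biomass_toy()
        ctx = reconstruct(model, CoreSets(core={"R_B"}), biomass="BIOMASS",
                          policy=POLICY)
        assert {"BIOMASS", "R_B", "R_C", "R_TA", "R_EXA"} <= ctx.retained

    def test_biomass_only_minimal_subnetwork(self):
        model, _ = fixtures.biomass_toy()
        ctx = reconstruct(model, CoreSets(), biomass="BIOMASS", policy=POLICY)
        assert ctx.retained == {"BIOMASS", "R_B", "R_C", "R_TA", "R_EXA"}

    def test_non_core_support_labelled_low(self, toy1_consistent):
        ctx = reconstruct(toy1_consistent, CoreSets(core={"R2"}),
                          policy=POLICY)
        assert ctx.confidence["R_EXA"] == CONF_LOW
        assert ctx.confidence["R2"] == CONF_MODERATE

    def test_retained_set_is_consistent(self, toy1_consistent):
        ctx = reconstruct(toy1_consistent, CoreSets(core={"R2", "R3"}),
                          policy=POLICY)
        sub = toy1_consistent.restrict(ctx.retained)
        assert fastcc(sub, POLICY) == ctx.retained

    def test_determinism(self, toy1_consistent):
        sets = CoreSets(core={"R2", "R3"})
        a = reconstruct(toy1_consistent, sets, policy=POLICY)
        b = reconstruct(toy1_consistent, sets, policy=POLICY)
        assert a.retained == b.retained


class TestCrossvalidate:
    def test_mutually_supporting_chain_high(self, toy1_consistent):
        ctx = crossvalidate(toy1_consistent, CoreSets(core={"R1", "R2"}),
                            policy=POLICY)
        assert ctx.confidence["R1"] == CONF_HIGH
        assert ctx.confidence["R2"] == CONF_HIGH

    def test_dead_side_branch_core_moderate(self, toy1_consistent):
        # R3 shares nothing with the R2 path: leaving it out drops it
        ctx = crossvalidate(toy1_consistent, CoreSets(core={"R2", "R3"}),
                            policy=POLICY)
        assert ctx.confidence["R3"] == CONF_MODERATE

    def test_single_core_support_low(self, toy1_consistent):
        ctx = crossvalidate(toy1_consistent, CoreSets(core={"R2", "R3"}),
                            policy=POLICY)
        # R_EXD is pulled in by R3 alone
        assert ctx.confidence["R_EXD"] == CONF_LOW

    def test_partition_exhaustive_exclusive(self, toy1_consistent):
        ctx = crossvalidate(toy1_consistent, CoreSets(core={"R2", "R3"}),
                            policy=POLICY)
        assert set(ctx.confidence) == ctx.retained
        assert set(ctx.confidence.values()) <= {CONF_HIGH, CONF_MODERATE,
                                                CONF_LOW}

    def test_excluded_reaction_labels(self, toy1_consistent):
        sets = CoreSets(core={"R2"}, inactive={"R3"})
        ctx = crossvalidate(toy1_consistent, sets, policy=POLICY)
        assert ctx.excluded_support["R3"] in (EXCL_MULTI, EXCL_SINGLE)

    def test_max_folds_subsampling_deterministic(self, toy1_consistent):
        sets = CoreSets(core={"R1", "R2", "R3"})
        a = crossvalidate(toy1_consistent, sets, policy=POLICY,
                          max_folds=2, seed=11)
        b = crossvalidate(toy1_consistent, sets, policy=POLICY,
                          max_folds=2, seed=11)
        assert a.confidence == b.confidence


class TestEndToEndRecovery:
    def test_pipeline_recovers_intended_active(self):
        model, truth = fixtures.toy1()
        cons = model.restrict(fastcc(model, POLICY))
        spec = fixtures.FixtureSpec(seed=5, n_samples=4)
        z = fixtures.simulate_expression(model, truth["active_genes"], spec)
        scores = discretize_frame(z)
        gene_scores = consensus_frame(scores, 0.75).to_dict()
        sets = build_core_sets(cons, map_scores(cons, gene_scores))
        ctx = reconstruct(cons, sets, policy=POLICY)
        assert truth["intended_active"] <= ctx.retained
        assert not (truth["blocked"] & ctx.retained)

    def test_retained_invariant_under_sample_permutation(self):
        model, truth = fixtures.toy1()
        cons = model.restrict(fastcc(model, POLICY))
        spec = fixtures.FixtureSpec(seed=5, n_samples=4)
        z = fixtures.simulate_expression(model, truth["active_genes"], spec)
        shuffled = z[list(z.columns[::-1])]
        results = []
        for table in (z, shuffled):
            scores = discretize_frame(table)
            gene_scores = consensus_frame(scores, 0.75).to_dict()
            sets = build_core_sets(cons, map_scores(cons, gene_scores))
            results.append(reconstruct(cons, sets, policy=POLICY).retained)
        assert results[0] == results[1]
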