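"""FVA range-overlap conflict detection and pFBA subsystem demand
fold-changes, validated on the analytic branch-point fixture."""

import math

import pytest

from mgeburden.conflict import (conflict_table, find_conflicts,
                                subsystem_conflict_fraction,
                                subsystem_demand_fold_change)
from mgeburden.core import (FluxRange, FluxSolution, MetabolicModel,
                            Metabolite, Reaction, fva)
from mgeburden.errors import ValidationError
from mgeburden.synth import make_conflict_fixture


def _ranges(**kw):
    return {rid: FluxRange(rid, lo, hi) for rid, (lo, hi) in kw.items()}


class TestFindConflicts:
    def test_disjoint_ranges_conflict(self):
        rep = find_conflicts(_ranges(r=(0, 1)), _ranges(r=(2, 3)))
        assert rep.conflict_reactions == {"r"}

    def test_shared_endpoint_is_not_conflict(self):
        rep = find_conflicts(_ranges(r=(0, 2)), _ranges(r=(2, 3)))
        assert rep.conflict_reactions == set()

    def test_symmetry(self):
        a = _ranges(r=(0, 1), s=(5, 6))
        b = _ranges(r=(2, 3), s=(5.5, 7))
        assert (find_conflicts(a, b).conflict_reactions
                == find_conflicts(b, a).conflict_reactions)

    def test_tolerance_monotonicity(self):
        a = _ranges(r=(0, 1.0))
        b = _ranges(r=(1.0000005, 2))
        wide = find_conflicts(a, b, tol=1e-6).conflict_reactions
        tight = find_conflicts(a, b, tol=1e-9).conflict_reactions
        assert wide <= tight

    def test_mismatched_reaction_sets_rejected(self):
        with pytest.raises(ValidationError):
            find_conflicts(_ranges(r=(0, 1)), _ranges(s=(0, 1)))

    def test_fixture_conflict_set_matches_certified_truth(self):
        model, mge_rxn, truth = make_conflict_fixture()
        host = model.copy()
        host.objective = {"BIOMASS": 1.0}
        mge = model.copy()
        mge.objective = {mge_rxn.id: 1.0}
        rep = find_conflicts(fva(host), fva(mge), model=model)
        assert rep.conflict_reactions == truth.conflict_reactions
        assert rep.total_reactions == truth.total_reactions
        assert rep.fraction_of_total == pytest.approx(truth.fraction_of_total)

    def test_identical_objectives_no_conflict(self):
        model, mge_rxn, truth = make_conflict_fixture(identical_objectives=True)
        assert truth.conflict_reactions == set()
        ranges = fva(model)
        rep = find_conflicts(ranges, ranges, model=model)
        assert rep.conflict_reactions == set()


class TestSubsystemFractions:
    def test_fixture_fractions_match_certified_truth(self):
        model, mge_rxn, truth = make_conflict_fixture()
        host = model.copy()
        host.objective = {"BIOMASS": 1.0}
        mge = model.copy()
        mge.objective = {mge_rxn.id: 1.0}
        rep = find_conflicts(fva(host), fva(mge), model=model)
        assert subsystem_conflict_fraction(rep) == pytest.approx(
            subsystem_conflict_fraction(truth))

    def test_no_conflicts_all_zero(self):
        a = _ranges(r=(0, 1), s=(0, 1))
        rep = find_conflicts(a, a, model={"r": "S1", "s": "S2"})
        fracs = subsystem_conflict_fraction(rep)
        assert fracs == {"S1": 0.0, "S2": 0.0}

    def test_half_of_subsystem_in_conflict(self):
        subsys = {f"r{i}": "AA biosynthesis" for i in range(4)}
        a = _ranges(r0=(0, 1), r1=(0, 1), r2=(0, 1), r3=(0, 1))
        b = _ranges(r0=(2, 3), r1=(2, 3), r2=(0, 1), r3=(0, 1))
        rep = find_conflicts(a, b, model=subsys)
        assert subsystem_conflict_fraction(rep) == {"AA biosynthesis": 0.5}

    def test_fractions_within_unit_interval(self):
        model, mge_rxn, _ = make_conflict_fixture()
        host = model.copy()
        host.objective = {"BIOMASS": 1.0}
        mge = model.copy()
        mge.objective = {mge_rxn.id: 1.0}
        rep = find_conflicts(fva(host), fva(mge), model=model)
        assert all(0.0 <= f <= 1.0 for f in subsystem_conflict_fraction(rep).values())


def _labelled_model(labels):
    mets = [Metabolite("x_c", compartment="c")]
    rxns = [Reaction(rid, {"x_c": 1}, -1000, 1000, subsystem=sub)
            for rid, sub in labels.items()]
    return MetabolicModel(metabolites=mets, reactions=rxns, objective={})


class TestDemandFoldChange:
    def test_identical_states_zero_everywhere(self):
        model = _labelled_model({"r1": "S1", "r2": "S2"})
        sol = FluxSolution("optimal", 1.0, {"r1": 2.0, "r2": 3.0})
        sd = subsystem_demand_fold_change(sol, sol, model)
        assert all(v == pytest.approx(0.0) for v in sd.log2_fold_change.values())
        assert sd.dropped_reactions == set()

    def test_hand_example_doubling_share_gives_one(self):
        """Subsystem at 2/10 of total flux in host, 4/10 in MGE state -> log2 FC 1."""
        labels = {"a1": "Target", "a2": "Target", "b1": "Rest"}
        model = _labelled_model(labels)
        host = FluxSolution("optimal", 1.0, {"a1": 1.0, "a2": 1.0, "b1": 8.0})
        mge = FluxSolution("optimal", 1.0, {"a1": 2.0, "a2": 2.0, "b1": 6.0})
        sd = subsystem_demand_fold_change(mge, host, model)
        assert sd.log2_fold_change["Target"] == pytest.approx(1.0)

    def test_direction_change_reactions_dropped(self):
        model = _labelled_model({"flip": "S1", "keep": "S1", "rest": "S2"})
        host = FluxSolution("optimal", 1.0, {"flip": 1.0, "keep": 2.0, "rest": 5.0})
        mge = FluxSolution("optimal", 1.0, {"flip": -1.0, "keep": 2.0, "rest": 5.0})
        sd = subsystem_demand_fold_change(mge, host, model)
        assert sd.dropped_reactions == {"flip"}
        assert sd.sum_host["S1"] == pytest.approx(2.0)
        assert sd.sum_mge["S1"] == pytest.approx(2.0)

    def test_zero_in_one_state_flagged_undefined(self):
        model = _labelled_model({"a": "S1", "b": "S2"})
        host = FluxSolution("optimal", 1.0, {"a": 0.0, "b": 5.0})
        mge = FluxSolution("optimal", 1.0, {"a": 2.0, "b": 5.0})
        sd = subsystem_demand_fold_change(mge, host, model)
        assert "S1" in sd.undefined
        assert math.isnan(sd.log2_fold_change["S1"])

    def test_subsystem_shares_sum_to_one(self):
        model = _labelled_model({"a": "S1", "b": "S2", "c": "S3"})
        host = FluxSolution("optimal", 1.0, {"a": 1.0, "b": 2.0, "c": 3.0})
        mge = FluxSolution("optimal", 1.0, {"a": 2.0, "b": 1.0, "c": 4.0})
        sd = subsystem_demand_fold_change(mge, host, model)
        assert sum(sd.sum_mge.values()) == pytest.approx(sd.total_mge)
        assert sum(sd.sum_host.values()) == pytest.approx(sd.total_host)

    def test_below_tolerance_fluxes_are_not_direction_changes(self):
        model = _labelled_model({"tiny": "S1", "rest": "S2"})
        host = FluxSolution("optimal", 1.0, {"tiny": 1e-12, "rest": 5.0})
        mge = FluxSolution("optimal", 1.0, {"tiny": -1e-12, "rest": 5.0})
        sd = subsystem_demand_fold_change(mge, host, model)
        assert sd.dropped_reactions == set()


def test_conflict_table_is_sorted_and_flagged():
    model, mge_rxn, truth = make_conflict_fixture()
    host = model.copy()
    host.objective = {"BIOMASS": 1.0}
    mge = model.copy()
    mge.objective = {mge_rxn.id: 1.0}
    df = conflict_table(fva(host), fva(mge), model=model)
    assert list(df["reaction_id"]) == sorted(df["reaction_id"])
    assert set(df[df["conflict"]]["reaction_id"]) == truth.conflict_reactions
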