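"""Threshold selection, presets, and greedy training vs an exhaustive oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cport import (
    PREDICTORS,
    RankTable,
    ResidueLabels,
    ResidueId,
    SyntheticSpec,
    ThresholdSet,
    ValidationError,
    greedy_train,
    pooled_partition_ranks,
    predict_consensus,
    preset,
    rank_per_chain,
    select_at_threshold,
    simulate_scores,
)
from cport.scores import POOLED_PREDICTORS

from conftest import rid


def make_rank_table(name, ranks, cap=30):
    return RankTable(name, {rid(c, n): k for (c, n), k in ranks.items()}, cap)


def labels_for(interface, universe):
    iface = {rid(c, n) for c, n in interface}
    surf = {rid(c, n) for c, n in universe} - iface
    return ResidueLabels.from_sets(iface, surf)


def rank_all(tables):
    return {
        name: pooled_partition_ranks(t) if name in POOLED_PREDICTORS else rank_per_chain(t)
        for name, t in tables.items()
    }


class TestSelectAtThreshold:
    @pytest.fixture
    def ranks(self):
        return {
            "WHISCY": make_rank_table("WHISCY", {("A", 1): 1, ("A", 2): 3, ("A", 3): 5}),
            "PINUP": make_rank_table("PINUP", {("A", 1): 2, ("A", 2): 1, ("A", 3): 4}),
        }

    def test_all_zero_selects_nothing(self, ranks):
        pred = select_at_threshold(ranks, ThresholdSet.from_dict({"WHISCY": 0, "PINUP": 0}))
        assert len(pred) == 0

    def test_rank_equal_to_threshold_selected(self, ranks):
        pred = select_at_threshold(ranks, ThresholdSet.from_dict({"WHISCY": 3, "PINUP": 0}))
        assert pred.residues == {rid("A", 1), rid("A", 2)}

    def test_union_with_provenance(self, ranks):
        pred = select_at_threshold(ranks, ThresholdSet.from_dict({"WHISCY": 1, "PINUP": 2}))
        assert pred.residues == {rid("A", 1), rid("A", 2)}
        assert pred.provenance[rid("A", 1)] == {"WHISCY", "PINUP"}

    def test_unknown_predictor_is_error(self, ranks):
        with pytest.raises(ValidationError):
            select_at_threshold(ranks, ThresholdSet.from_dict({"NOPE": 1}))

    @given(st.data())
    def test_monotone_in_thresholds(self, data):
        """Componentwise larger thresholds can only grow the prediction."""
        ranks = {}
        for name in ("WHISCY", "PINUP", "SPPIDER"):
            n = data.draw(st.integers(1, 20))
            ranks[name] = RankTable(
                name, {ResidueId("A", i + 1): data.draw(st.integers(1, 30)) for i in range(n)}
            )
        t1 = {name: data.draw(st.integers(0, 30)) for name in ranks}
        t2 = {name: t1[name] + data.draw(st.integers(0, 5)) for name in ranks}
        p1 = select_at_threshold(ranks, ThresholdSet.from_dict(t1))
        p2 = select_at_threshold(ranks, ThresholdSet.from_dict(t2))
        assert p1.residues <= p2.residues


class TestPresets:
    def test_heavy_is_default_and_values(self):
        heavy = preset()
        assert heavy.label == "heavy"
        assert heavy.as_dict() == {
            "WHISCY": 14, "PIER": 20, "ProMate": 19, "PINUP": 21, "cons-PPISP": 14, "SPPIDER": 6,
        }

    def test_balanced_and_slight(self):
        assert preset("balanced").as_dict() == {
            "WHISCY": 4, "PIER": 3, "ProMate": 6, "PINUP": 12, "cons-PPISP": 0, "SPPIDER": 6,
        }
        assert preset("slight").as_dict() == {
            "WHISCY": 6, "PIER": 7, "ProMate": 11, "PINUP": 13, "cons-PPISP": 11, "SPPIDER": 6,
        }

    def test_unknown_preset(self):
        with pytest.raises(ValidationError):
            preset("maximal")

    def test_presets_are_nested(self):
        assert preset("balanced") <= preset("slight") <= preset("heavy")


class TestPredictConsensus:
    def test_all_available_equals_select(self, small_scores):
        tables, _ = small_scores
        ranks = rank_all(tables)
        t = preset("heavy")
        assert predict_consensus(ranks, t).residues == select_at_threshold(ranks, t).residues

    def test_missing_predictor_fallback(self, small_scores):
        tables, _ = small_scores
        ranks = rank_all(tables)
        available = set(PREDICTORS) - {"SPPIDER"}
        pred = predict_consensus(ranks, preset("heavy"), available=available)
        for contributors in pred.provenance.values():
            assert "SPPIDER" not in contributors

    def test_single_predictor_degenerate(self, small_scores):
        tables, _ = small_scores
        ranks = rank_all(tables)
        pred = predict_consensus(ranks, preset("heavy"), available={"WHISCY"})
        expected = {r for r, k in ranks["WHISCY"].entries.items() if k <= 14}
        assert pred.residues == expected


def brute_force_greedy(rank_tables, interface, universe):
    """Exhaustive per-step enumeration oracle for the greedy trainer.

    At every step, all candidate unit increments are evaluated from
    scratch by rebuilding the selected set; the maximum-specificity
    candidate is chosen, ties broken by the canonical predictor order.
    """
    order = [p for p in PREDICTORS if p in rank_tables] + [
        p for p in sorted(rank_tables) if p not in PREDICTORS
    ]
    max_rank = {
        name: max((k for r, k in t.entries.items() if r in universe), default=0)
        for name, t in rank_tables.items()
    }

    def selected_at(cutoffs):
        out = set()
        for name, t in rank_tables.items():
            out |= {r for r, k in t.entries.items() if r in universe and k <= cutoffs[name]}
        return out

    cutoffs = {name: 0 for name in rank_tables}
    history = [dict(cutoffs)]
    while len(selected_at(cutoffs)) < len(universe):
        best = None
        for name in order:
            if cutoffs[name] >= max_rank[name]:
                continue
            trial = dict(cutoffs)
            trial[name] += 1
            sel = selected_at(trial)
            if not sel:
                continue
            spec = len(sel & interface) / len(sel)
            if best is None or spec > best[0]:
                best = (spec, name)
        if best is None:
            raise AssertionError("oracle stuck")
        cutoffs[best[1]] += 1
        history.append(dict(cutoffs))
    return history


class TestGreedyTrain:
    def test_hand_set_two_predictor_case(self):
        ranks = {
            "WHISCY": make_rank_table("WHISCY", {("A", 1): 1, ("A", 2): 2, ("A", 3): 3, ("A", 4): 4}),
            "PINUP": make_rank_table("PINUP", {("A", 1): 2, ("A", 2): 4, ("A", 3): 1, ("A", 4): 3}),
        }
        labels = labels_for([("A", 1), ("A", 3)], [("A", i) for i in range(1, 5)])
        labels = ResidueLabels.from_sets({rid("A", 1), rid("A", 3)}, {rid("A", 2), rid("A", 4)})
        traj = greedy_train(ranks, labels)
        expected = brute_force_greedy(
            ranks, {rid("A", 1), rid("A", 3)}, {rid("A", i) for i in range(1, 5)}
        )
        assert [s.thresholds.as_dict() for s in traj] == expected
        # first step must pick an interface residue: specificity 1
        assert traj[1].specificity == 1.0

    def test_single_predictor_increments_linearly(self):
        ranks = {"WHISCY": make_rank_table("WHISCY", {("A", i): i for i in range(1, 6)})}
        labels = labels_for([("A", 1)], [("A", i) for i in range(1, 6)])
        traj = greedy_train(ranks, labels)
        assert [s.thresholds.as_dict()["WHISCY"] for s in traj] == [0, 1, 2, 3, 4, 5]

    def test_all_interface_degenerate(self):
        ranks = {
            "WHISCY": make_rank_table("WHISCY", {("A", 1): 1, ("A", 2): 2}),
            "PINUP": make_rank_table("PINUP", {("A", 1): 2, ("A", 2): 1}),
        }
        labels = labels_for([("A", 1), ("A", 2)], [("A", 1), ("A", 2)])
        traj = greedy_train(ranks, labels)
        assert all(s.specificity == 1.0 for s in traj.steps[1:])
        # tie-break: WHISCY precedes PINUP in the canonical order
        assert traj[1].thresholds.as_dict() == {"WHISCY": 1, "PINUP": 0}

    def test_no_interface_is_error(self):
        ranks = {"WHISCY": make_rank_table("WHISCY", {("A", 1): 1})}
        labels = ResidueLabels.from_sets(set(), {rid("A", 1)})
        with pytest.raises(ValidationError):
            greedy_train(ranks, labels)

    def test_universe_restricted_to_common_residues(self):
        # residue A2 is unranked by PINUP and must be discarded from training
        ranks = {
            "WHISCY": make_rank_table("WHISCY", {("A", 1): 1, ("A", 2): 2}),
            "PINUP": make_rank_table("PINUP", {("A", 1): 1}),
        }
        labels = labels_for([("A", 1)], [("A", 1), ("A", 2)])
        traj = greedy_train(ranks, labels)
        assert traj.steps[-1].n_selected == 1

    def test_trajectory_invariants(self, small_scores):
        tables, labels = small_scores
        traj = greedy_train(rank_all(tables), labels)
        for prev, step in zip(traj.steps, traj.steps[1:]):
            diffs = [
                step.thresholds.as_dict()[p] - prev.thresholds.as_dict()[p]
                for p in step.thresholds.as_dict()
            ]
            assert sorted(diffs) == [0] * (len(diffs) - 1) + [1]
            assert step.n_selected >= prev.n_selected

    @settings(max_examples=60)
    @given(st.data())
    def test_matches_exhaustive_oracle_on_random_instances(self, data):
        """Every greedy step agrees with per-step exhaustive enumeration."""
        n_pred = data.draw(st.integers(1, 6))
        n_res = data.draw(st.integers(2, 40))
        universe = {ResidueId("A", i + 1) for i in range(n_res)}
        rank_tables = {}
        for p in range(n_pred):
            name = PREDICTORS[p]
            perm = data.draw(st.permutations(sorted(universe)))
            rank_tables[name] = RankTable(
                name, {r: min(i + 1, 30) for i, r in enumerate(perm)}
            )
        n_iface = data.draw(st.integers(1, n_res))
        interface = set(sorted(universe)[:n_iface])
        labels = ResidueLabels.from_sets(interface, universe - interface)
        traj = greedy_train(rank_tables, labels)
        expected = brute_force_greedy(rank_tables, interface, universe)
        assert [s.thresholds.as_dict() for s in traj] == expected


class TestSyntheticSignalProperties:
    def test_early_specificity_beats_base_rate(self):
        """Informative predictors concentrate interface residues early in
        the trajectory, beating the 15% base rate (aggregate over seeds)."""
        wins = 0
        for seed in range(20):
            tables, labels = simulate_scores(
                SyntheticSpec(n_chains=2, chain_length=60, signal=0.8, seed=seed)
            )
            traj = greedy_train(rank_all(tables), labels)
            step = traj.at_size(10)
            base_rate = 0.15
            wins += step.specificity > base_rate
        assert wins >= 18

    def test_prediction_size_shrinks_with_agreement(self):
        """At a fixed ThresholdSet, strongly agreeing predictors yield a
        smaller consensus than disagreeing ones."""
        sizes = {}
        for corr in (0.95, 0.0):
            n = []
            for seed in range(5):
                tables, _ = simulate_scores(
                    SyntheticSpec(n_chains=2, chain_length=80, signal=0.7, correlation=corr, seed=seed)
                )
                n.append(len(predict_consensus(rank_all(tables), preset("heavy"))))
            sizes[corr] = np.mean(n)
        assert sizes[0.95] < sizes[0.0]
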