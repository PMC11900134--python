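"""Target assignment, k-of-3 consensus, and precision evaluation."""

import itertools
import math

import numpy as np
import pytest

from gpcrscreen.chem_io import SiteMode
from gpcrscreen.decision import (CompoundProfile, ConsensusDecision,
                                 ProfileEntry, assign_targets,
                                 compare_to_known, evaluate)


def entry(receptor, cls=4, pchembl=8.0, dock=-8.0,
          mode=SiteMode.ORTHOSTERIC, probs=None):
    if probs is None:
        probs = [0.0] * 6
        probs[cls] = 1.0
    return ProfileEntry(receptor_id=receptor, site_mode=mode,
                        class_probs=tuple(probs), predicted_class=cls,
                        predicted_pchembl=pchembl, docking_score=dock)


def decision(legs, cid="q"):
    """Build a ConsensusDecision naming the given receptors per leg."""
    targets = dict(zip(("classifier", "regressor", "docking"), legs))
    counts = {}
    for t in targets.values():
        if t is not None:
            counts[t] = counts.get(t, 0) + 1
    k = max(counts.values()) if counts else 0
    leaders = sorted(t for t, c in counts.items() if c == k)
    return ConsensusDecision(
        compound_id=cid, leg_targets=targets,
        leg_target_classes={leg: ("A" if t == "CCR6" else "B") if t else None
                            for leg, t in targets.items()},
        consensus_target=leaders[0] if k >= 2 else None, agreement_k=k)


class TestAssignTargets:
    def test_unanimous(self):
        profile = CompoundProfile("q", (
            entry("CCR6", cls=5, pchembl=8.5, dock=-10.0),
            entry("GLP1R", cls=1, pchembl=4.0, dock=-4.0),
        ))
        d = assign_targets(profile)
        assert d.leg_targets == {"classifier": "CCR6", "regressor": "CCR6",
                                 "docking": "CCR6"}
        assert d.consensus_target == "CCR6"
        assert d.agreement_k == 3
        assert d.leg_target_classes["classifier"] == "A"

    def test_two_of_three(self):
        profile = CompoundProfile("q", (
            entry("CCR6", cls=5, pchembl=8.5, dock=-4.0),
            entry("GLP1R", cls=1, pchembl=4.0, dock=-10.0),
        ))
        d = assign_targets(profile)
        assert d.consensus_target == "CCR6"
        assert d.agreement_k == 2
        assert d.leg_targets["docking"] == "GLP1R"

    def test_three_way_disagreement_no_consensus(self):
        profile = CompoundProfile("q", (
            entry("CCR1", cls=5, pchembl=4.0, dock=-5.0),
            entry("CCR2", cls=1, pchembl=9.0, dock=-5.5),
            entry("CCR3", cls=1, pchembl=4.5, dock=-11.0),
        ))
        d = assign_targets(profile)
        assert d.consensus_target is None
        assert d.agreement_k == 1

    def test_classifier_tie_broken_by_active_probability_mass(self):
        profile = CompoundProfile("q", (
            entry("CCR1", cls=4, probs=[0.2, 0.0, 0.0, 0.0, 0.8, 0.0]),
            entry("CCR2", cls=4, probs=[0.05, 0.0, 0.0, 0.0, 0.95, 0.0]),
        ))
        assert assign_targets(profile).leg_targets["classifier"] == "CCR2"

    def test_full_tie_broken_lexicographically(self):
        profile = CompoundProfile("q", (
            entry("CCR2", cls=4, pchembl=8.0, dock=-8.0),
            entry("CCR1", cls=4, pchembl=8.0, dock=-8.0),
        ))
        d = assign_targets(profile)
        assert d.leg_targets == {"classifier": "CCR1", "regressor": "CCR1",
                                 "docking": "CCR1"}

    def test_docking_absent_everywhere_is_no_call(self):
        profile = CompoundProfile("q", (
            entry("CCR6", dock=None), entry("GLP1R", cls=1, pchembl=4.0,
                                            dock=None)))
        d = assign_targets(profile)
        assert d.leg_targets["docking"] is None
        assert d.agreement_k == 2  # the two ML legs can still agree

    def test_receptor_collapses_to_most_active_site(self):
        """Ortho/allo entries of one receptor are merged per leg."""
        profile = CompoundProfile("q", (
            entry("CCR6", cls=2, pchembl=5.0, dock=-3.0,
                  mode=SiteMode.ORTHOSTERIC),
            entry("CCR6", cls=5, pchembl=9.0, dock=-11.0,
                  mode=SiteMode.ALLOSTERIC),
            entry("GLP1R", cls=4, pchembl=8.0, dock=-8.0),
        ))
        d = assign_targets(profile)
        assert d.leg_targets["classifier"] == "CCR6"
        assert d.leg_targets["regressor"] == "CCR6"
        assert d.leg_targets["docking"] == "CCR6"

    def test_deterministic(self):
        profile = CompoundProfile("q", (
            entry("CCR6"), entry("GLP1R", cls=1, pchembl=4.0)))
        assert assign_targets(profile) == assign_targets(profile)


class TestEvaluate:
    def test_precision_arithmetic(self):
        """9 correct and 11 wrong single-leg calls give precision 0.45."""
        ds = [(decision(["CCR6"] * 3, cid=f"c{i}"), "CCR6", "A")
              for i in range(9)]
        ds += [(decision(["GLP1R"] * 3, cid=f"w{i}"), "CCR6", "A")
               for i in range(11)]
        report = evaluate(ds)
        assert report.tp("all3") == 9
        assert report.precision("all3") == pytest.approx(0.45)

    def test_all_correct_under_atleast1(self):
        ds = [(decision(["CCR6", "GLP1R", "GLP1R"], cid=f"c{i}"),
               "CCR6", "A") for i in range(5)]
        assert evaluate(ds).precision("atleast1") == 1.0

    def test_tp_nesting_against_brute_force(self):
        """TP(all3) <= TP(atleast2) <= TP(atleast1) on random decision sets."""
        rng = np.random.default_rng(0)
        receptors = ["CCR6", "GLP1R", "CCR1"]
        for trial in range(100):
            ds = []
            for i in range(rng.integers(1, 12)):
                legs = [receptors[j] for j in rng.integers(0, 3, size=3)]
                truth = receptors[rng.integers(0, 3)]
                ds.append((decision(legs, cid=f"t{trial}c{i}"), truth,
                           "A" if truth.startswith("CC") else "B"))
            report = evaluate(ds)
            # brute-force counts straight from the leg lists
            def n_correct(d, truth):
                return sum(t == truth for t in d.leg_targets.values())
            brute = {k: sum(1 for d, t, _ in ds if n_correct(d, t) >= k)
                     for k in (1, 2, 3)}
            assert report.tp("all3") == brute[3]
            assert report.tp("atleast2") == brute[2]
            assert report.tp("atleast1") == brute[1]
            assert brute[3] <= brute[2] <= brute[1]

    def test_per_leg_rules(self):
        ds = [(decision(["CCR6", "GLP1R", "CCR6"]), "CCR6", "A")]
        report = evaluate(ds)
        assert report.precision("classifier") == 1.0
        assert report.precision("regressor") == 0.0
        assert report.precision("docking") == 1.0

    def test_class_level_scores_registry_class(self):
        # CCR1 is wrong as a target but right as class A
        ds = [(decision(["CCR1", "CCR1", "CCR1"]), "CCR6", "A")]
        report = evaluate(ds)
        assert report.precision("all3", level="target") == 0.0
        assert report.precision("all3", level="class") == 1.0

    def test_permutation_invariance(self):
        ds = [(decision(["CCR6"] * 3, cid="a"), "CCR6", "A"),
              (decision(["GLP1R"] * 3, cid="b"), "CCR6", "A"),
              (decision(["CCR6", "CCR6", "GLP1R"], cid="c"), "CCR6", "A")]
        fwd = evaluate(ds).table
        rev = evaluate(ds[::-1]).table
        assert fwd == rev

    def test_stratified_report(self):
        ds = [(decision(["CCR6"] * 3, cid="o1"), "CCR6", "A"),
              (decision(["GLP1R"] * 3, cid="a1"), "CCR6", "A")]
        report = evaluate(ds, strata={"o1": "orthosteric",
                                      "a1": "allosteric"})
        assert report.precision("all3", stratum="orthosteric") == 1.0
        assert report.precision("all3", stratum="allosteric") == 0.0

    def test_unknown_target_rejected(self):
        ds = [(decision(["CCR6"] * 3), "NOT_A_RECEPTOR", "A")]
        with pytest.raises(ValueError, match="registry"):
            evaluate(ds)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate([])


class TestCompareToKnown:
    def make_profile(self, cid, pchembl):
        return CompoundProfile(cid, (entry("CCR6", pchembl=pchembl),))

    def test_percentile_of_known_member(self):
        refs = [self.make_profile(f"r{i}", p)
                for i, p in enumerate([5.0, 6.0, 7.0, 8.0])]
        table = compare_to_known(self.make_profile("q", 6.0), refs)
        assert table.percentile.iloc[0] == pytest.approx(50.0)

    def test_query_above_all_references(self):
        refs = [self.make_profile(f"r{i}", p) for i, p in enumerate([5, 6, 7])]
        table = compare_to_known(self.make_profile("q", 9.0), refs)
        assert table.percentile.iloc[0] == 100.0
        assert table.z_score.iloc[0] > 1.0

    def test_no_references_empty_table(self):
        table = compare_to_known(self.make_profile("q", 6.0), [])
        assert table.empty
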