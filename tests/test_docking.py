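"""Docking-box geometry, ligand preparation, backends, and score parsing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpcrscreen.chem_io import CompoundRecord, SiteMode
from gpcrscreen.docking import (BackendUnavailableError, BindingSite,
                                DockingBox, DockingResult, dock, dock_all,
                                make_box, parse_vina_log, prepare_ligand,
                                stub_score)


def site(coords, receptor="CCR6", mode=SiteMode.ORTHOSTERIC):
    return BindingSite(receptor, mode, None, tuple(coords))


class TestMakeBox:
    def test_single_atom_center_default_edge(self):
        box = make_box(site([(1.0, 2.0, 3.0)]))
        assert box.center == (1.0, 2.0, 3.0)
        assert box.edge == 30.0

    @pytest.mark.parametrize("coords, center", [
        ([(1, 0, 0), (-1, 0, 0)], (0.0, 0.0, 0.0)),
        ([(0, 0, 0), (2, 4, 6)], (1.0, 2.0, 3.0)),
        ([(0, 0, 0), (1, 1, 1), (2, 2, 2)], (1.0, 1.0, 1.0)),
    ])
    def test_centroid_arithmetic(self, coords, center):
        assert make_box(site(coords)).center == center

    @given(st.lists(st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
                    min_size=1, max_size=8),
           st.tuples(*[st.floats(-20, 20) for _ in range(3)]))
    @settings(max_examples=50, deadline=None)
    def test_translation_equivariance(self, coords, shift):
        base = make_box(site(coords)).center
        moved = make_box(site([tuple(c + s for c, s in zip(p, shift))
                               for p in coords])).center
        assert np.allclose(np.array(moved), np.array(base) + np.array(shift),
                           atol=1e-9)

    def test_empty_coordinates_rejected(self):
        with pytest.raises(ValueError):
            site([])

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            site([(float("nan"), 0, 0)])

    def test_edge_must_be_positive(self):
        with pytest.raises(ValueError):
            DockingBox(center=(0, 0, 0), edge=0)


class TestPrepareLigand:
    def test_ethanol_pdbqt(self, tmp_path):
        rec = CompoundRecord.create("eth", "CCO")
        path = prepare_ligand(rec, tmp_path / "eth.pdbqt")
        text = path.read_text()
        atom_lines = [l for l in text.splitlines() if l.startswith("ATOM")]
        assert len(atom_lines) == 9  # C2H6O with explicit hydrogens
        assert "TORSDOF" in text
        assert int(text.split("TORSDOF")[1].split()[0]) >= 1

    def test_hexapeptide_prepared_as_small_molecule(self, tmp_path):
        from gpcrscreen.peptide import peptide_record

        rec = peptide_record("HAEGTF", "glp6")
        path = prepare_ligand(rec, tmp_path / "pep.pdbqt")
        assert path.exists()
        assert "ROOT" in path.read_text()


class TestStubBackend:
    def test_deterministic(self):
        rec = CompoundRecord.create("c", "CCO")
        s = site([(0, 0, 0)])
        a = dock(rec, s, backend="stub")
        b = dock(rec, s, backend="stub")
        assert a.best_score == b.best_score
        assert a.backend == "stub"

    def test_scores_within_range_and_nondegenerate(self):
        """Stub scores spread over the affinity range, no constant output."""
        rng = np.random.default_rng(0)
        smiles = [f"{'C' * int(rng.integers(1, 20))}O" for _ in range(200)]
        scores = [stub_score(s, "CCR6", SiteMode.ORTHOSTERIC)
                  for s in set(smiles)]
        assert all(-12.0 <= s <= -2.0 for s in scores)
        assert len(set(scores)) > len(scores) // 2
        assert np.std(scores) > 0.5

    def test_score_depends_on_receptor_and_site(self):
        a = stub_score("CCO", "CCR6", SiteMode.ORTHOSTERIC)
        b = stub_score("CCO", "GLP1R", SiteMode.ORTHOSTERIC)
        c = stub_score("CCO", "CCR6", SiteMode.ALLOSTERIC)
        assert len({a, b, c}) == 3


class TestVinaParsing:
    VINA_LOG = """\
mode |   affinity | dist from best mode
     | (kcal/mol) | rmsd l.b.| rmsd u.b.
-----+------------+----------+----------
   1       -7.1          0.000      0.000
   2       -6.9          1.302      2.104
   3       -6.5          2.230      4.008
"""

    def test_parses_all_modes_best_first(self):
        scores = parse_vina_log(self.VINA_LOG)
        assert scores == [-7.1, -6.9, -6.5]

    def test_round_trip_k_modes(self):
        header = "mode |   affinity\n"
        body = "".join(f"   {i}       {-9.0 + 0.5 * i:.1f}          0.000      0.000\n"
                       for i in range(1, 6))
        assert len(parse_vina_log(header + body)) == 5

    def test_missing_engine_instructs_stub(self, tmp_path):
        rec = CompoundRecord.create("c", "CCO")
        s = BindingSite("CCR6", SiteMode.ORTHOSTERIC,
                        tmp_path / "r.pdbqt", ((0, 0, 0),))
        with pytest.raises(BackendUnavailableError, match="stub"):
            dock(rec, s, backend="vina",
                 vina_binary="definitely-not-a-real-binary")


class TestDockAll:
    def make_sites(self, n):
        return [site([(i, 0, 0)], receptor=f"R{i:02d}") for i in range(n)]

    def test_one_result_per_site(self):
        rec = CompoundRecord.create("c", "CCO")
        results, failures = dock_all(rec, self.make_sites(4))
        assert len(results) == 4
        assert not failures

    def test_order_independence(self):
        rec = CompoundRecord.create("c", "CCO")
        sites = self.make_sites(5)
        fwd, _ = dock_all(rec, sites)
        rev, _ = dock_all(rec, sites[::-1])
        assert {(r.receptor_id, r.best_score) for r in fwd} == \
            {(r.receptor_id, r.best_score) for r in rev}

    def test_39_sites_fast(self):
        import time

        rec = CompoundRecord.create("c", "CCO")
        t0 = time.time()
        results, _ = dock_all(rec, self.make_sites(39))
        assert len(results) == 39
        assert time.time() - t0 < 1.0

    def test_per_site_failure_recorded_not_fatal(self, monkeypatch):
        import gpcrscreen.docking as docking_mod

        rec = CompoundRecord.create("c", "CCO")
        sites = self.make_sites(4)
        original = docking_mod.stub_score

        def flaky(smiles, receptor_id, site_mode):
            if receptor_id == "R02":
                raise RuntimeError("boom")
            return original(smiles, receptor_id, site_mode)

        monkeypatch.setattr(docking_mod, "stub_score", flaky)
        results, failures = dock_all(rec, sites)
        assert len(results) == 3
        assert len(failures) == 1 and failures[0].receptor_id == "R02"

    def test_all_failing_raises(self):
        rec = CompoundRecord.create("c", "CCO")
        with pytest.raises((RuntimeError, ValueError)):
            dock_all(rec, [])

    def test_result_invariants(self):
        with pytest.raises(ValueError):
            DockingResult("R", SiteMode.ORTHOSTERIC, -5.0,
                          ((-4.0, "a"), (-5.0, "b")), "stub")
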