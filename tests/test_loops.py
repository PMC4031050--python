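"""Fragment libraries, insertion locality, CCD closure, rebuild protocol."""

import numpy as np
import pytest

from tmrebuild import (build_fragment_library, insert_fragment, ccd_close,
                       rebuild_region, remodel_bend, RebuildWindow,
                       LoopClosureError, ideal_helix, make_loop_problem,
                       KinkSpec)
from tmrebuild.loops import Fragment, FragmentLibrary, parse_fragment_file
from tmrebuild.internal import (backbone_torsions, rebuild_forward,
                                ccd_optimal_angle, rotation_about_axis,
                                ccd_close_window, bond_angle, wrap_angle)
from tmrebuild.structure import N, CA, C


class TestFragmentLibrary:
    def test_ideal_library_contains_helical_ninemer(self):
        lib = build_fragment_library("ideal")
        found = False
        for frag in lib.fragments[9]:
            arr = frag.as_array()
            if np.allclose(arr[:, 0], -57.8) and np.allclose(arr[:, 1], -47.0):
                found = True
        assert found

    def test_all_omegas_trans(self):
        lib = build_fragment_library("ideal")
        for size in (3, 9):
            for frag in lib.fragments[size]:
                om = np.abs(wrap_angle(frag.as_array()[:, 2]))
                assert np.all(om >= 170.0)

    def test_ramachandran_library_deterministic_under_seed(self):
        a = build_fragment_library("ramachandran", np.random.default_rng(5))
        b = build_fragment_library("ramachandran", np.random.default_rng(5))
        for size in (3, 9):
            for fa, fb in zip(a.fragments[size], b.fragments[size]):
                assert fa.torsions == fb.torsions

    def test_file_source_round_trip(self):
        text = "\n".join(
            [f"f1 {i+1} A -60.0 -40.0 180.0" for i in range(3)]
            + [f"f2 {i+1} G -120.0 130.0 179.0" for i in range(9)])
        lib = build_fragment_library("file", text=text)
        assert len(lib.fragments[3]) == 1 and len(lib.fragments[9]) == 1

    def test_malformed_file_reports_line_number(self):
        text = "f1 1 A -60.0 -40.0 180.0\nf1 2 A oops -40.0 180.0\n"
        with pytest.raises(ValueError, match="line 2"):
            parse_fragment_file(text)

    def test_cis_omega_rejected(self):
        with pytest.raises(ValueError):
            FragmentLibrary({3: [Fragment(((-60.0, -40.0, 0.0),) * 3)],
                             9: [Fragment(((-60.0, -40.0, 180.0),) * 9)]})


class TestInsertFragment:
    def test_identity_insertion_leaves_coordinates(self):
        h = ideal_helix(20)
        w = RebuildWindow(8, 13)
        tors = backbone_torsions(h)
        frag = Fragment(tuple(map(tuple, tors[8:11])))  # residues 9-11
        out = insert_fragment(h, w, frag, position=9)
        np.testing.assert_allclose(out.coords[:, :3, :], h.coords[:, :3, :],
                                   atol=1e-6)

    def test_helical_fragment_sets_helical_torsions(self):
        rng = np.random.default_rng(0)
        broken, w, ref = make_loop_problem(rng, 6)
        frag = Fragment(((-57.8, -47.0, 180.0),) * 3)
        out = insert_fragment(broken, w, frag, position=w.first)
        tors = backbone_torsions(out)
        i0 = out.row(w.first)
        np.testing.assert_allclose(tors[i0:i0 + 3, 0], -57.8, atol=1e-6)
        np.testing.assert_allclose(tors[i0:i0 + 3, 1], -47.0, atol=1e-6)

    def test_atoms_outside_moving_segment_untouched(self):
        rng = np.random.default_rng(1)
        lib = build_fragment_library("ideal")
        for _ in range(100):
            h = ideal_helix(20)
            w = RebuildWindow(int(rng.integers(5, 10)),
                              int(rng.integers(12, 16)))
            frag = lib.pick(3, rng)
            pos = int(rng.integers(w.first, w.break_position - 2))
            out = insert_fragment(h, w, frag, position=pos)
            i0, i1 = h.row(w.first), h.row(w.break_position)
            np.testing.assert_array_equal(out.coords[:i0 - 1],
                                          h.coords[:i0 - 1])
            np.testing.assert_array_equal(out.coords[i1 + 1:],
                                          h.coords[i1 + 1:])

    def test_oversized_fragment_rejected(self):
        h = ideal_helix(20)
        frag = Fragment(((-57.8, -47.0, 180.0),) * 9)
        with pytest.raises(ValueError):
            insert_fragment(h, RebuildWindow(8, 11), frag)


class TestCCD:
    def test_already_closed_window_reports_zero_gap(self):
        h = ideal_helix(20)
        out, gap = ccd_close(h, RebuildWindow(8, 12))
        assert gap == pytest.approx(0.0, abs=1e-9)

    def test_single_torsion_matches_grid_search(self):
        """The analytic CCD angle equals (to high precision) the argmin of a
        dense grid search over the same torsion."""
        rng = np.random.default_rng(2)
        for _ in range(25):
            pivot = rng.normal(size=3)
            axis = rng.normal(size=3)
            moving = rng.normal(size=(3, 3)) * 4
            target = rng.normal(size=(3, 3)) * 4
            theta = ccd_optimal_angle(pivot, axis, moving, target)

            def cost(t):
                R = rotation_about_axis(axis, t)
                moved = (moving - pivot) @ R.T + pivot
                return np.sum((moved - target) ** 2)

            grid = np.linspace(-np.pi, np.pi, 20001)
            best = grid[np.argmin([cost(t) for t in grid])]
            assert cost(theta) <= cost(best) + 1e-9

    def test_single_free_torsion_closes_in_one_cycle(self):
        """A break created by perturbing one psi is exactly undone by the
        analytic update in a single CCD cycle."""
        h = ideal_helix(20)
        tors = backbone_torsions(h)
        w = tors[11:12].copy()
        w[0, 1] += 35.0
        broken = rebuild_forward(h, 12, 12, w)
        res = ccd_close_window(broken, 12, 12, tolerance=0.01)
        assert res.converged and res.cycles == 1
        assert res.gap == pytest.approx(0.0, abs=1e-9)

    def test_per_cycle_overlap_deviation_non_increasing(self):
        """Each analytic torsion update cannot increase the flank-atom
        squared deviation, so the overlap SSD is monotone over cycles."""
        h = ideal_helix(20)
        tors = backbone_torsions(h)
        w = tors[7:13].copy() + np.array([40.0, -30.0, 0.0])
        broken = rebuild_forward(h, 8, 13, w)
        ssds = []
        for cycles in (1, 2, 4, 8, 16, 32):
            r = ccd_close_window(broken, 8, 13, max_cycles=cycles,
                                 tolerance=1e-12)
            ssds.append(r.overlap_ssd)
        assert all(b <= a + 1e-9 for a, b in zip(ssds, ssds[1:]))

    def test_infeasible_span_reports_gap_without_exception(self):
        h = ideal_helix(20)
        stretched = h.copy()
        stretched.coords[11:] += np.array([40.0, 0.0, 0.0])  # residues 12+
        res = ccd_close_window(stretched, 9, 11, max_cycles=30,
                               tolerance=0.05)
        assert not res.converged and res.gap > 0.05

    def test_ideal_covalent_geometry_preserved(self):
        rng = np.random.default_rng(3)
        broken, w, ref = make_loop_problem(rng, 8)
        out, gap = ccd_close(broken, w, max_cycles=200)
        X = out.coords
        for i in range(out.row(w.first), out.row(w.last) + 1):
            assert np.linalg.norm(X[i, CA] - X[i, N]) == pytest.approx(
                1.458, rel=0.05)
            assert np.linalg.norm(X[i, C] - X[i, CA]) == pytest.approx(
                1.525, rel=0.05)
            assert bond_angle(X[i, N], X[i, CA], X[i, C]) == pytest.approx(
                111.2, abs=111.2 * 0.05)


class TestRebuildRegion:
    def test_feasible_loops_close_within_protocol(self, frag_lib):
        """>= 95% of feasible loop windows close to within the 0.2 A break
        threshold inside 12 steps and at most 2 expansions."""
        rng = np.random.default_rng(4)
        closed = 0
        n = 40
        for _ in range(n):
            broken, w, ref = make_loop_problem(rng, int(rng.integers(6, 13)))
            try:
                out = rebuild_region(broken, w, frag_lib, rng,
                                     max_expansions=2)
                closed += 1
                assert out.chain_breaks() == []
            except LoopClosureError:
                pass
        assert closed / n >= 0.95

    def test_flanking_helices_untouched_without_expansion(self, frag_lib):
        rng = np.random.default_rng(5)
        broken, w, ref = make_loop_problem(rng, 8)
        out = rebuild_region(broken, w, frag_lib, rng, max_expansions=0,
                             bounds=(w.first, w.last))
        i0, i1 = broken.row(w.first), broken.row(w.last)
        np.testing.assert_array_equal(out.coords[:i0 - 1],
                                      broken.coords[:i0 - 1])
        np.testing.assert_array_equal(out.coords[i1 + 2:],
                                      broken.coords[i1 + 2:])

    def test_seeded_rebuild_is_deterministic(self, frag_lib):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(6)
            broken, w, ref = make_loop_problem(rng, 7)
            outs.append(rebuild_region(broken, w, frag_lib, rng))
        np.testing.assert_array_equal(outs[0].coords, outs[1].coords)

    def test_expansion_cap_raises_with_best_attempt(self, frag_lib):
        h = ideal_helix(20)
        stretched = h.copy()
        stretched.coords[11:] += np.array([60.0, 0.0, 0.0])  # residues 12+
        rng = np.random.default_rng(7)
        with pytest.raises(LoopClosureError) as exc:
            rebuild_region(stretched, RebuildWindow(9, 11), frag_lib, rng,
                           max_expansions=1)
        assert exc.value.best_gap is None or exc.value.best_gap > 0.2


class TestRemodelBend:
    def _bend_case(self, frag_lib, window_size=None):
        rng = np.random.default_rng(8)
        broken, w, ref = make_loop_problem(rng, 4)
        spec = KinkSpec(f_range=(w.last + 1, 24), m_range=(1, w.first - 1),
                        bend_range=(w.first, w.last),
                        ref_residue=w.last + 1)
        return remodel_bend(broken, spec, frag_lib, rng,
                            window_size=window_size), broken, spec

    def test_default_window_is_the_bend(self, frag_lib):
        out, broken, spec = self._bend_case(frag_lib)
        i0 = broken.row(spec.bend_range[0])
        np.testing.assert_array_equal(out.coords[:i0 - 1],
                                      broken.coords[:i0 - 1])
        assert out.chain_breaks() == []

    def test_enlarged_window_fixes_flanks_outside(self, frag_lib):
        out, broken, spec = self._bend_case(frag_lib, window_size=8)
        lo = spec.bend_range[0] - 2
        i0 = broken.row(lo)
        np.testing.assert_array_equal(out.coords[:i0 - 1],
                                      broken.coords[:i0 - 1])
        assert out.chain_breaks() == []

    def test_torsions_valid_after_rebuild(self, frag_lib):
        out, broken, spec = self._bend_case(frag_lib)
        tors = backbone_torsions(out)
        window = tors[out.row(spec.bend_range[0]):
                      out.row(spec.bend_range[1]) + 1]
        assert np.all(window > -180.0) and np.all(window <= 180.0)

    def test_invalid_window_size_rejected(self, frag_lib):
        with pytest.raises(ValueError):
            self._bend_case(frag_lib, window_size=12)
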