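"""Kink move distributions, quadrant restriction, Metropolis behavior."""

import numpy as np
import pytest

from tmrebuild import (MoveSet, sample_kink_translation, sample_kink_rotation,
                       propose_move, mc_run, metropolis_accept, CoarseEnergy,
                       measure_kink, kink_frame, ideal_helix)
from tmrebuild.sampler import _moving_range
from tmrebuild.geometry import GeometryError


class TestKinkTranslation:
    def test_radius_distribution_matches_gaussian(self):
        rng = np.random.default_rng(0)
        draws = np.array([sample_kink_translation(rng) for _ in range(100_000)])
        radii = np.linalg.norm(draws, axis=1)
        assert radii.mean() == pytest.approx(7.2, abs=0.01)
        assert radii.std() == pytest.approx(0.6, abs=0.01)

    def test_all_draws_in_positive_z_hemisphere(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_kink_translation(rng) for _ in range(20_000)])
        assert np.all(draws[:, 2] >= 0.0)

    def test_direction_uniform_over_hemisphere(self):
        # z/r of a uniform hemisphere direction is Uniform(0, 1)
        rng = np.random.default_rng(2)
        draws = np.array([sample_kink_translation(rng) for _ in range(20_000)])
        z_over_r = draws[:, 2] / np.linalg.norm(draws, axis=1)
        hist, _ = np.histogram(z_over_r, bins=10, range=(0, 1))
        assert hist.min() > 0.8 * len(draws) / 10

    def test_custom_parameters_respected(self):
        rng = np.random.default_rng(3)
        p = MoveSet(translation_mean=4.0, translation_sd=0.2)
        radii = np.linalg.norm(
            [sample_kink_translation(rng, p) for _ in range(20_000)], axis=1)
        assert radii.mean() == pytest.approx(4.0, abs=0.02)


class TestKinkRotation:
    FRAME = np.eye(3)

    def test_sampled_directions_in_positive_xz_quadrants(self):
        rng = np.random.default_rng(4)
        current = np.array([0.0, 0.0, 1.0])
        for _ in range(10_000):
            R = sample_kink_rotation(rng, self.FRAME, current)
            new = R @ current
            assert new[0] >= -1e-9 and new[2] >= -1e-9

    def test_zero_magnitude_is_identity(self):
        rng = np.random.default_rng(5)
        R = sample_kink_rotation(rng, self.FRAME, [0, 0, 1.0], magnitude=0.0)
        np.testing.assert_array_equal(R, np.eye(3))

    def test_degenerate_frame_rejected(self):
        rng = np.random.default_rng(6)
        bad = np.ones((3, 3))
        with pytest.raises(GeometryError):
            sample_kink_rotation(rng, bad, [0, 0, 1.0])

    def test_swing_preferentially_away_from_proline(self, bundle_pair):
        """Geometric consequence of the quadrant restriction: the moveable
        fragment's far terminus preferentially projects into the half-plane
        away from the reference-residue CB.  The preference is strong but
        not absolute because the hemisphere translation is unrestricted in
        the x direction; the axis restriction alone drives the bias."""
        bp = bundle_pair
        rng = np.random.default_rng(7)
        params = MoveSet(steps=1)
        n_kink = 0
        away = 0
        while n_kink < 300:
            cand, kind = propose_move(bp.target, bp.kink, params, rng)
            if kind != "kink":
                continue
            n_kink += 1
            spec = measure_kink(cand, bp.kink.f_range, bp.kink.m_range,
                                bp.kink.bend_range, bp.kink.ref_residue)
            # swing is measured from the -x (toward-CB) reference: away from
            # the proline ring means |swing| > 90 degrees
            if abs(spec.swing) > 90.0:
                away += 1
        assert away / n_kink > 0.8


class TestProposeMove:
    def test_full_turn_spin_is_identity(self, bundle_pair):
        bp = bundle_pair
        params = MoveSet(steps=1, spin_max=1.0)
        rng = np.random.default_rng(8)
        # emulate a 360-degree spin directly through the rigid helpers
        from tmrebuild.sampler import _quick_axis, _rigid
        from tmrebuild.internal import rotation_about_axis
        origin, direction = _quick_axis(bp.target, bp.kink.f_range)
        R = rotation_about_axis(direction, 2 * np.pi)
        out = _rigid(bp.target, bp.kink.f_range, R, origin)
        np.testing.assert_allclose(out.ca(), bp.target.ca(), atol=1e-6)

    def test_zero_amplitude_whole_move_is_noop(self, bundle_pair):
        from tmrebuild.sampler import _rigid
        bp = bundle_pair
        out = _rigid(bp.target, (1, 10), np.eye(3), np.zeros(3))
        np.testing.assert_array_equal(out.ca(), bp.target.ca())

    def test_proposals_preserve_intra_fragment_distances(self, bundle_pair):
        from scipy.spatial.distance import pdist
        bp = bundle_pair
        params = MoveSet(steps=1)
        rng = np.random.default_rng(9)
        m_rows = bp.target.rows_in(*bp.kink.m_range)
        f_rows = bp.target.rows_in(*bp.kink.f_range)
        ref_m = pdist(bp.target.coords[m_rows, 1, :])
        ref_f = pdist(bp.target.coords[f_rows, 1, :])
        for _ in range(300):
            cand, kind = propose_move(bp.target, bp.kink, params, rng)
            np.testing.assert_allclose(pdist(cand.coords[m_rows, 1, :]),
                                       ref_m, atol=1e-9)
            np.testing.assert_allclose(pdist(cand.coords[f_rows, 1, :]),
                                       ref_f, atol=1e-9)

    def test_f_fragment_untouched_by_kink_moves(self, bundle_pair):
        bp = bundle_pair
        rng = np.random.default_rng(10)
        f_rows = bp.target.rows_in(*bp.kink.f_range)
        seen = 0
        while seen < 20:
            cand, kind = propose_move(bp.target, bp.kink, MoveSet(steps=1),
                                      rng)
            if kind in ("kink", "kink_local", "m_spin"):
                seen += 1
                np.testing.assert_array_equal(cand.coords[f_rows],
                                              bp.target.coords[f_rows])


class TestCoarseEnergy:
    def test_separated_helices_have_no_clash(self):
        a = ideal_helix(12, start=(0, 0, 0))
        b = ideal_helix(12, start=(10, 0, 0), start_resnum=20)
        import numpy as np
        from tmrebuild.structure import Structure
        merged = Structure(
            np.concatenate([a.index, b.index]), a.aa + b.aa,
            np.concatenate([a.coords, b.coords]),
            cb_virtual=np.concatenate([a.cb_virtual, b.cb_virtual]))
        e = CoarseEnergy()
        assert e.terms(merged)["clash"] == 0.0

    def test_superposed_helices_clash(self):
        a = ideal_helix(12)
        b = ideal_helix(12, start=(0.5, 0, 0), start_resnum=20)
        from tmrebuild.structure import Structure
        merged = Structure(
            np.concatenate([a.index, b.index]), a.aa + b.aa,
            np.concatenate([a.coords, b.coords]),
            cb_virtual=np.concatenate([a.cb_virtual, b.cb_virtual]))
        assert CoarseEnergy().terms(merged)["clash"] > 0.0

    def test_start_restraint_zero_at_start_and_grows(self, bundle_pair):
        bp = bundle_pair
        e = CoarseEnergy(start=bp.target,
                         moving_fragments=[bp.kink.m_range])
        assert e.terms(bp.target)["restraint"] == 0.0
        shifted = bp.target.copy()
        shifted.coords[shifted.rows_in(*bp.kink.m_range)] += [2.0, 0, 0]
        assert e.terms(shifted)["restraint"] > 1.0

    def test_membrane_term_penalizes_out_of_slab(self, bundle_pair):
        bp = bundle_pair
        e = CoarseEnergy(tmh_regions=bp.layout.helices)
        assert e.terms(bp.target)["membrane"] == 0.0
        shifted = bp.target.copy()
        shifted.coords[..., 2] += 25.0
        assert e.terms(shifted)["membrane"] > 0.0


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-1.0, 1.0, rng) for _ in range(100))

    def test_infinite_temperature_accepts_everything(self, bundle_pair):
        bp = bundle_pair
        params = MoveSet(steps=200, kT_schedule=(1e9,))
        state = mc_run(bp.target, bp.kink, None, params,
                       np.random.default_rng(11))
        assert state.acceptance_fraction > 0.99

    def test_two_state_occupancy_matches_boltzmann(self):
        """A two-level system (dE = 1, kT = 1) driven by the shared
        acceptance rule occupies the upper state with probability
        e^-1 / (1 + e^-1)."""
        rng = np.random.default_rng(12)
        state = 0
        visits = 0
        n = 100_000
        for _ in range(n):
            proposal = 1 - state
            de = 1.0 if proposal == 1 else -1.0
            if metropolis_accept(de, 1.0, rng):
                state = proposal
            visits += state
        p_up = visits / n
        expect = np.exp(-1) / (1 + np.exp(-1))
        sigma = 3 * np.sqrt(expect * (1 - expect) / n) * 6  # correlated chain
        assert p_up == pytest.approx(expect, abs=max(sigma, 0.01))

    def test_best_energy_never_above_start(self, bundle_pair,
                                           target_constraints):
        bp = bundle_pair
        params = MoveSet(steps=100)
        state = mc_run(bp.target, bp.kink, target_constraints, params,
                       np.random.default_rng(13))
        start_energy = CoarseEnergy(
            target_constraints, start=bp.target,
            moving_fragments=[_moving_range(bp.kink), bp.kink.f_range],
            tmh_regions=[(min(bp.kink.m_range[0], bp.kink.f_range[0]),
                          max(bp.kink.m_range[1], bp.kink.f_range[1]))],
            restraint_radius=params.restraint_radius,
            exclude_residues=range(bp.kink.bend_range[0],
                                   bp.kink.bend_range[1] + 1))(bp.target)
        assert state.best_energy <= start_energy + 1e-9


class TestDeterminism:
    def test_identical_seeds_identical_trajectories(self, bundle_pair,
                                                    target_constraints):
        bp = bundle_pair
        params = MoveSet(steps=150)
        runs = []
        for _ in range(2):
            st = mc_run(bp.target, bp.kink, target_constraints, params,
                        np.random.default_rng(99), log_trajectory=True)
            runs.append(st)
        assert runs[0].trajectory == runs[1].trajectory
        np.testing.assert_array_equal(runs[0].best_structure.coords,
                                      runs[1].best_structure.coords)


def test_moveset_validation():
    with pytest.raises(ValueError):
        MoveSet(steps=0)
    with pytest.raises(ValueError):
        MoveSet(translation_sd=-1.0)
    with pytest.raises(ValueError):
        MoveSet(kT_schedule=())
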