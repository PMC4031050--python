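"""Accuracy metrics: Kabsch vs quaternion oracle, GDT counting, dihedral
deviations, TM-score bounds and small-instance oracle."""

import numpy as np
import pytest

from tmrebuild import (kabsch_rmsd, gdt_scores, pct_within,
                       bend_dihedral_deviation, tm_score, score_model,
                       ideal_helix, apply_rigid_transform)
from tmrebuild.metrics import tm_d0, AccuracyReport
from tmrebuild.internal import rotation_about_axis, rebuild_forward, \
    backbone_torsions


def quaternion_superpose_rmsd(A, B):
    """Independent oracle: optimal RMSD via the Horn quaternion method."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    ac = A - A.mean(axis=0)
    bc = B - B.mean(axis=0)
    M = bc.T @ ac
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(K)[-1]
    ssd = np.sum(ac ** 2) + np.sum(bc ** 2) - 2.0 * lam
    return np.sqrt(max(ssd, 0.0) / len(A))


def random_rigid(rng):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return rotation_about_axis(axis, rng.uniform(0, 2 * np.pi)), \
        rng.normal(size=3) * 10


class TestKabsch:
    def test_identical_sets_zero(self):
        A = np.random.default_rng(0).normal(size=(10, 3))
        rmsd, R, t = kabsch_rmsd(A, A)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(15, 3)) * 5
        R, t = random_rigid(rng)
        rmsd, _, _ = kabsch_rmsd(A, A @ R.T + t)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        # near-planar points invite reflections; determinant must stay +1
        A = rng.normal(size=(8, 3)) * [5, 5, 0.01]
        B = rng.normal(size=(8, 3)) * [5, 5, 0.01]
        _, R, _ = kabsch_rmsd(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(4, 20))
            A = rng.normal(size=(n, 3)) * rng.uniform(1, 10)
            B = rng.normal(size=(n, 3)) * rng.uniform(1, 10)
            rmsd, _, _ = kabsch_rmsd(A, B)
            assert rmsd == pytest.approx(quaternion_superpose_rmsd(A, B),
                                         abs=1e-9)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((5, 3)), np.zeros((6, 3)))


class TestGDT:
    def test_identical_structures_score_one(self):
        A = np.random.default_rng(4).normal(size=(30, 3)) * 8
        for mode in ("ha", "standard"):
            for sup in ("none", "kabsch", "multiseed"):
                assert gdt_scores(A, A, mode, sup) == pytest.approx(1.0)

    def test_fixed_frame_uniform_displacement_hand_count(self):
        """Every residue displaced exactly 0.75 A: GDT-HA counts
        (0 + 1 + 1 + 1)/4, standard GDT counts 4/4."""
        A = np.random.default_rng(5).normal(size=(20, 3)) * 8
        rng = np.random.default_rng(6)
        dirs = rng.normal(size=(20, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        B = A + 0.75 * dirs
        assert gdt_scores(B, A, "ha", "none") == pytest.approx(0.75)
        assert gdt_scores(B, A, "standard", "none") == pytest.approx(1.0)

    def test_ha_never_exceeds_standard(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            A = rng.normal(size=(25, 3)) * 8
            B = A + rng.normal(size=(25, 3)) * rng.uniform(0.2, 3.0)
            assert gdt_scores(B, A, "ha") <= gdt_scores(B, A, "standard") + 1e-12

    def test_superposition_modes_are_nested(self):
        """Maximizing over more superpositions can only help."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            A = rng.normal(size=(30, 3)) * 8
            B = A + rng.normal(size=(30, 3)) * 1.5
            R, t = random_rigid(rng)
            B = B @ R.T + t
            none = gdt_scores(B, A, "ha", "none")
            kab = gdt_scores(B, A, "ha", "kabsch")
            multi = gdt_scores(B, A, "ha", "multiseed")
            assert multi >= kab - 1e-12


class TestPctWithin:
    def test_identical_is_hundred(self):
        A = np.random.default_rng(9).normal(size=(12, 3))
        assert pct_within(A, A, 2.0) == pytest.approx(100.0)

    def test_fixed_frame_counting(self):
        A = np.zeros((10, 3))
        B = A.copy()
        B[:5, 0] = 3.0  # half displaced by 3 A
        assert pct_within(B, A, 2.0, superpose=False) == pytest.approx(50.0)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(10)
        A = rng.normal(size=(40, 3)) * 8
        B = A + rng.normal(size=(40, 3))
        vals = [pct_within(B, A, c) for c in (0.5, 1.0, 2.0, 4.0)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestBendDihedrals:
    def test_identical_structures_zero(self):
        h = ideal_helix(15)
        dphi, dpsi = bend_dihedral_deviation(h, h, (5, 9))
        assert dphi == pytest.approx(0.0, abs=1e-9)
        assert dpsi == pytest.approx(0.0, abs=1e-9)

    def test_circular_wrapping(self):
        h = ideal_helix(15)
        tors = backbone_torsions(h)
        w = tors[6:8].copy()
        w[:, 0] += 350.0  # nominal 350 = effective -10
        pert = rebuild_forward(h, 7, 8, w)
        dphi, dpsi = bend_dihedral_deviation(pert, h, (7, 8))
        assert dphi == pytest.approx(10.0, abs=1e-6)

    def test_invariant_under_global_rigid_motion(self, rng):
        h = ideal_helix(15)
        tors = backbone_torsions(h)
        pert = rebuild_forward(h, 6, 10,
                               tors[5:10] + rng.normal(0, 20, (5, 3)))
        d0 = bend_dihedral_deviation(pert, h, (6, 9))
        R, t = random_rigid(rng)
        moved = apply_rigid_transform(pert, (1, 15), R, t)
        d1 = bend_dihedral_deviation(moved, h, (6, 9))
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_window_at_terminus_errors(self):
        h = ideal_helix(15)
        with pytest.raises(ValueError):
            bend_dihedral_deviation(h, h, (1, 4))


class TestTMScore:
    def test_identical_structures_score_one(self):
        A = ideal_helix(30).ca()
        assert tm_score(A, A) == pytest.approx(1.0, abs=1e-9)

    def test_score_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            A = rng.normal(size=(25, 3)) * 8
            B = rng.normal(size=(25, 3)) * 8
            s = tm_score(B, A)
            assert 0.0 < s <= 1.0

    def test_short_chain_errors(self):
        A = np.zeros((10, 3))
        with pytest.raises(ValueError):
            tm_score(A, A)
        with pytest.raises(ValueError):
            tm_d0(15)

    def test_unrelated_decoys_score_low_and_beat_window_oracle(self):
        """Random compact decoys vs an unrelated fold score < 0.3, and the
        iterative search never falls below an exhaustive window-seeded
        superposition oracle on 20-residue toys."""
        rng = np.random.default_rng(12)
        native = ideal_helix(20).ca()
        for _ in range(10):
            decoy = np.cumsum(rng.normal(scale=2.2, size=(20, 3)), axis=0)
            s = tm_score(decoy, native)
            assert s < 0.5
            # exhaustive contiguous-window Kabsch oracle
            d0 = tm_d0(20)
            best = 0.0
            for w in range(3, 21):
                for start in range(0, 21 - w):
                    sl = slice(start, start + w)
                    _, R, t = kabsch_rmsd(native[sl], decoy[sl])
                    moved = decoy @ R.T + t
                    d = np.linalg.norm(moved - native, axis=1)
                    best = max(best, float(np.mean(1 / (1 + (d / d0) ** 2))))
            assert s >= best - 1e-9

    def test_rigid_motion_invariance(self, rng):
        A = ideal_helix(25).ca()
        B = A + rng.normal(size=(25, 3)) * 0.8
        s0 = tm_score(B, A)
        R, t = random_rigid(rng)
        s1 = tm_score(B @ R.T + t, A)
        assert s1 == pytest.approx(s0, abs=1e-6)


class TestReport:
    def test_full_report_on_fixture_pair(self, bundle_pair):
        bp = bundle_pair
        aln = bp.fx.alignment
        corr = [(aln.template_map[c], aln.target_map[c])
                for c in aln.mutual_columns()
                if aln.target_map[c] in set(bp.tm_residues)]
        report = score_model(bp.fx.structure, bp.target,
                             correspondence=corr, region="TMH")
        assert report.gdt_ha <= report.gdt
        assert 0 < report.tm_score <= 1
        assert report.ca_rmsd > 0
        assert 0 <= report.pct_within_1A <= report.pct_within_2A <= 100

    def test_inconsistent_gdt_pair_rejected(self):
        with pytest.raises(ValueError):
            AccuracyReport(region="full", ca_rmsd=1.0, gdt=0.5, gdt_ha=0.6,
                           pct_within_1A=10, pct_within_2A=20, tm_score=0.5)
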