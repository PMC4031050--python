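"""Constrained rigid-body sampling of kinked transmembrane helices.

The moveable (m) fragment of a kinked TMH is re-posed by (a) translating its
bend-side terminus to a random point on a +z hemisphere of Gaussian radius
7.2 +/- 0.6 A centered at the fixed (f) fragment's bend-side terminus, and
(b) re-orienting its axis toward a random direction restricted to the +z/+x
quadrants of the kink frame, so the m fragment tips away from the
bend-inducing proline ring.  Axial spins of each fragment and rigid moves of
the whole kinked unit complete the move set.  Moves are scored with a
coarse-grained surrogate energy and accepted by the Metropolis criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure import N, CA, C, O, CB, Structure
from .geometry import KinkSpec, kink_frame, _fragment_axis, GeometryError
from .internal import rotation_about_axis, rotation_between
from .alignment import ConstraintSet, constraint_energy

HEMISPHERE_RADIUS_MEAN = 7.2  # A, Gaussian radius of the kink translation
HEMISPHERE_RADIUS_SD = 0.6


@dataclass
class MoveSet:
    """Move amplitudes and Monte Carlo schedule for TMH rebuilding.

    ``steps`` in the 1000-5000 range is the production protocol; smaller
    values are accepted for cheap exploratory runs.  ``restraint_radius`` is
    the scale (1-1.5 A) of the Gaussian restraint tying each fragment to its
    starting pose.
    """

    translation_mean: float = HEMISPHERE_RADIUS_MEAN
    translation_sd: float = HEMISPHERE_RADIUS_SD
    restraint_radius: float = 1.25
    steps: int = 1000
    spin_max: float = 30.0           # deg, axial spin amplitude
    whole_helix_moves: bool = True
    whole_translation: float = 0.5   # A, rms of whole-unit translation
    whole_rotation: float = 5.0      # deg, whole-unit rotation amplitude
    local_translation: float = 0.3   # A, small jump-perturbation shift
    local_rotation: float = 3.0      # deg, small jump-perturbation tilt
    kT_schedule: tuple[float, ...] = (1.0,)

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        for name in ("translation_mean", "translation_sd", "restraint_radius",
                     "spin_max", "whole_translation", "whole_rotation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.kT_schedule:
            raise ValueError("kT_schedule must be non-empty")

    def kT_at(self, step: int) -> float:
        frac = step / max(self.steps, 1)
        i = min(int(frac * len(self.kT_schedule)), len(self.kT_schedule) - 1)
        return self.kT_schedule[i]


@dataclass
class SamplerState:
    structure: Structure
    energy: float
    best_structure: Structure
    best_energy: float
    rng_seed: int | None = None
    accepted: int = 0
    proposed: int = 0
    trajectory: list = field(default_factory=list)

    @property
    def acceptance_fraction(self) -> float:
        return self.accepted / self.proposed if self.proposed else 0.0


def metropolis_accept(delta_e: float, kT: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(-dE/kT))."""
    if delta_e <= 0:
        return True
    if kT <= 0:
        return False
    return bool(rng.random() < np.exp(-delta_e / kT))


# ---------------------------------------------------------------------------
# Elementary move samplers
# ---------------------------------------------------------------------------

def sample_kink_translation(rng: np.random.Generator,
                            params: MoveSet | None = None) -> np.ndarray:
    """Random displacement to the +z hemisphere surface, in the f-helix frame.

    Direction uniform over the z >= 0 hemisphere; radius Gaussian with the
    configured mean/sd (truncated at zero).
    """
    p = params or MoveSet()
    z = rng.uniform(0.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    rho = np.sqrt(max(0.0, 1.0 - z * z))
    direction = np.array([rho * np.cos(phi), rho * np.sin(phi), z])
    r = rng.normal(p.translation_mean, p.translation_sd)
    while r <= 0.0:
        r = rng.normal(p.translation_mean, p.translation_sd)
    return r * direction


def sample_kink_rotation(rng: np.random.Generator, frame: np.ndarray,
                         current_axis: np.ndarray,
                         magnitude: float = 1.0) -> np.ndarray:
    """Rotation re-orienting the m axis into the +z/+x quadrants of ``frame``.

    ``frame`` has columns (x, y, z) with -x pointing at the reference-residue
    CB; the sampled target direction has non-negative x and z components, so
    the moveable fragment tips into the half-space away from the proline
    ring.  ``magnitude`` in [0, 1] scales the rotation angle toward the
    target (0 returns the identity).
    """
    R = np.asarray(frame, float)
    if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
        raise GeometryError("frame must be an orthonormal 3x3 matrix")
    if magnitude == 0.0:
        return np.eye(3)
    v = rng.normal(size=3)
    local = np.array([abs(v[0]), v[1], abs(v[2])])
    local /= np.linalg.norm(local)
    target = R @ local
    full = rotation_between(np.asarray(current_axis, float), target)
    if magnitude >= 1.0:
        return full
    # scale the rotation angle by interpolating in axis-angle form
    tr = np.clip((np.trace(full) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.arccos(tr)
    if angle < 1e-12:
        return np.eye(3)
    axis = np.array([full[2, 1] - full[1, 2], full[0, 2] - full[2, 0],
                     full[1, 0] - full[0, 1]]) / (2.0 * np.sin(angle))
    return rotation_about_axis(axis, magnitude * angle)


# ---------------------------------------------------------------------------
# Structure-level proposals
# ---------------------------------------------------------------------------

def _quick_axis(s: Structure, rng_range: tuple[int, int]):
    """Fast helix axis estimate (half-centroid difference) for proposals.

    Accurate to ~1 degree on quasi-ideal fragments; measurement code uses the
    full least-squares fit instead.
    """
    rows = s.rows_in(*rng_range)
    ca = s.coords[rows, CA, :]
    k = max(len(ca) // 2, 2)
    d = ca[-k:].mean(axis=0) - ca[:k].mean(axis=0)
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise GeometryError("degenerate fragment axis")
    return ca.mean(axis=0), d / n


def _moving_range(spec: KinkSpec) -> tuple[int, int]:
    """The m fragment plus the bend ride together; f stays fixed."""
    lo = min(spec.m_range[0], spec.bend_range[0])
    hi = max(spec.m_range[1], spec.bend_range[1])
    return lo, hi


def _rigid(s: Structure, res_range, R, pivot) -> Structure:
    from .geometry import apply_rigid_transform
    t = np.asarray(pivot) - R @ np.asarray(pivot)
    return apply_rigid_transform(s, res_range, R, t)


def propose_move(s: Structure, spec: KinkSpec, params: MoveSet,
                 rng: np.random.Generator) -> tuple[Structure, str]:
    """One random rigid-body proposal; returns (candidate, move_kind).

    The bend region rides with the m fragment and is left as a flagged chain
    break for the loop builder to close.
    """
    kinds = ["kink", "kink_local", "f_spin", "m_spin"]
    if params.whole_helix_moves:
        kinds.append("whole")
    kind = kinds[rng.integers(len(kinds))]
    mv = _moving_range(spec)

    if kind == "kink_local":
        # small Gaussian perturbation of the jump: shift + tilt of the m
        # fragment about its bend-side terminus
        pivot = s.coords[s.row(spec.m_bend_end), CA].copy()
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.radians(rng.normal(0.0, params.local_rotation))
        R = rotation_about_axis(axis, angle)
        cand = _rigid(s, mv, R, pivot)
        cand.coords[cand.rows_in(*mv)] += rng.normal(
            0.0, params.local_translation, 3)
        return cand, kind

    if kind == "kink":
        _, f_dir = _quick_axis(s, spec.f_range)
        origin, frame = kink_frame(s, spec, f_direction=f_dir)
        # translation: bend-side terminus of m onto the hemisphere
        local = sample_kink_translation(rng, params)
        target_pt = origin + frame @ local
        shift = target_pt - s.coords[s.row(spec.m_bend_end), CA]
        cand = _rigid(s, mv, np.eye(3), np.zeros(3))
        cand.coords[cand.rows_in(*mv)] += shift
        # rotation: m axis into the allowed quadrants, pivot at the moved
        # bend-side terminus
        _, m_dir = _quick_axis(cand, spec.m_range)
        away = m_dir if not spec.m_before_f else -m_dir
        R = sample_kink_rotation(rng, frame, away)
        pivot = cand.coords[cand.row(spec.m_bend_end), CA]
        return _rigid(cand, mv, R, pivot), kind

    if kind in ("f_spin", "m_spin"):
        rng_range = spec.f_range if kind == "f_spin" else spec.m_range
        origin, direction = _quick_axis(s, rng_range)
        angle = np.radians(rng.uniform(-params.spin_max, params.spin_max))
        R = rotation_about_axis(direction, angle)
        move = rng_range if kind == "f_spin" else mv
        return _rigid(s, move, R, origin), kind

    # whole-unit move over m + bend + f
    lo = min(spec.m_range[0], spec.bend_range[0], spec.f_range[0])
    hi = max(spec.m_range[1], spec.bend_range[1], spec.f_range[1])
    rows = s.rows_in(lo, hi)
    centroid = s.coords[rows, CA, :].mean(axis=0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-params.whole_rotation,
                                   params.whole_rotation))
    R = rotation_about_axis(axis, angle)
    cand = _rigid(s, (lo, hi), R, centroid)
    cand.coords[rows] += rng.normal(0.0, params.whole_translation, 3)
    return cand, kind


# ---------------------------------------------------------------------------
# Surrogate coarse-grained energy
# ---------------------------------------------------------------------------

@dataclass
class EnergyWeights:
    clash: float = 1.0
    constraint: float = 1.0
    restraint: float = 1.0
    membrane: float = 0.5


class CoarseEnergy:
    """Surrogate for a membrane-protein low-resolution score.

    Terms: soft-sphere CA/CB clashes, the flat-bottom constraint energy, a
    Gaussian restraint on each moving fragment's rigid displacement from its
    start pose (scale = ``restraint_radius``), and a hydrophobic-slab term
    penalizing TMH residues outside |z| <= ``slab_half_width``.
    """

    CLASH_CA = 4.0   # A, soft-sphere contact distances
    CLASH_OTHER = 3.5

    def __init__(self, constraints: ConstraintSet | None = None,
                 start: Structure | None = None,
                 moving_fragments=(), tmh_regions=(),
                 weights: EnergyWeights | None = None,
                 restraint_radius: float = 1.25,
                 slab_half_width: float = 15.0,
                 exclude_residues=()):
        self.constraints = constraints or ConstraintSet()
        self.weights = weights or EnergyWeights()
        self.restraint_radius = restraint_radius
        self.slab_half_width = slab_half_width
        self.start = start
        self.moving_fragments = [tuple(f) for f in moving_fragments]
        self.tmh_regions = [tuple(r) for r in tmh_regions]
        self._excl = set(exclude_residues)
        self._prepared_for = None

    def _prepare(self, s: Structure):
        n = len(s)
        resnum = s.index
        keep = np.array([r not in self._excl for r in resnum])
        rows = np.nonzero(keep)[0]
        # atoms: CA then CB of the kept residues
        self._atom_rows = rows
        sep = np.abs(resnum[rows][:, None] - resnum[rows][None, :])
        m = sep >= 3
        big = np.block([[m, m], [m, m]])
        nk = len(rows)
        r0 = np.full((2 * nk, 2 * nk), self.CLASH_OTHER)
        r0[:nk, :nk] = self.CLASH_CA
        self._pair_mask = np.triu(big, k=1)
        self._r0 = r0
        tmh_rows = []
        for lo, hi in self.tmh_regions:
            tmh_rows.extend(list(s.rows_in(lo, hi)))
        self._tmh_rows = np.array(sorted(set(tmh_rows)), dtype=int)
        # cached constraint index arrays for fast evaluation
        if len(self.constraints):
            self._cons_i = np.array([s.row(c.res_i)
                                     for c in self.constraints])
            self._cons_j = np.array([s.row(c.res_j)
                                     for c in self.constraints])
            self._cons_d0 = np.array([c.d0 for c in self.constraints])
            self._cons_w = np.array([c.width for c in self.constraints])
            self._cons_wt = np.array([c.weight for c in self.constraints])
        else:
            self._cons_i = None
        self._start_frag_ca = None
        if self.start is not None:
            self._start_frag_ca = [
                self.start.coords[self.start.rows_in(lo, hi), CA, :]
                for lo, hi in self.moving_fragments]
        self._prepared_for = (n, tuple(resnum))

    def terms(self, s: Structure) -> dict[str, float]:
        key = (len(s), tuple(s.index))
        if self._prepared_for != key:
            self._prepare(s)
        rows = self._atom_rows
        pts = np.vstack([s.coords[rows, CA, :], s.coords[rows, CB, :]])
        d = cdist(pts, pts)
        viol = (self._r0 - d)
        clash = float(np.sum((viol[self._pair_mask & (viol > 0)]) ** 2))

        if self._cons_i is not None:
            dd = np.linalg.norm(s.coords[self._cons_i, CA, :]
                                - s.coords[self._cons_j, CA, :], axis=1)
            excess = np.maximum(np.abs(dd - self._cons_d0) - self._cons_w,
                                0.0)
            cons = float(np.sum(self._cons_wt * excess ** 2))
        else:
            cons = 0.0

        restraint = 0.0
        if self._start_frag_ca is not None:
            for (lo, hi), ref in zip(self.moving_fragments,
                                     self._start_frag_ca):
                cur = s.coords[s.rows_in(lo, hi), CA, :]
                rms = float(np.sqrt(np.mean(np.sum((cur - ref) ** 2, axis=1))))
                restraint += (rms / self.restraint_radius) ** 2

        membrane = 0.0
        if len(self._tmh_rows):
            z = np.abs(s.coords[self._tmh_rows, CA, 2])
            out = np.maximum(z - self.slab_half_width, 0.0)
            membrane = float(np.sum(out ** 2))

        return {"clash": clash, "constraint": cons,
                "restraint": restraint, "membrane": membrane}

    def __call__(self, s: Structure) -> float:
        t = self.terms(s)
        w = self.weights
        return (w.clash * t["clash"] + w.constraint * t["constraint"]
                + w.restraint * t["restraint"] + w.membrane * t["membrane"])


def coarse_energy(s: Structure, constraints: ConstraintSet | None = None,
                  **kwargs) -> float:
    """Convenience one-shot evaluation of :class:`CoarseEnergy`."""
    return CoarseEnergy(constraints, **kwargs)(s)


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo driver
# ---------------------------------------------------------------------------

def mc_run(start: Structure, spec: KinkSpec, constraints: ConstraintSet | None,
           params: MoveSet, rng: np.random.Generator,
           energy: CoarseEnergy | None = None,
           log_trajectory: bool = False) -> SamplerState:
    """Metropolis Monte Carlo over the kink move set.

    Identical seeds give bit-identical trajectories.  The returned state
    carries the best-energy structure seen (including the start).
    """
    if energy is None:
        energy = CoarseEnergy(
            constraints, start=start,
            moving_fragments=[_moving_range(spec), spec.f_range],
            tmh_regions=[(min(spec.m_range[0], spec.f_range[0]),
                          max(spec.m_range[1], spec.f_range[1]))],
            restraint_radius=params.restraint_radius,
            exclude_residues=range(spec.bend_range[0], spec.bend_range[1] + 1))
    current = start.copy()
    e_cur = energy(current)
    state = SamplerState(current, e_cur, current.copy(), e_cur)
    for step in range(params.steps):
        cand, kind = propose_move(state.structure, spec, params, rng)
        e_new = energy(cand)
        state.proposed += 1
        kT = params.kT_at(step)
        ok = metropolis_accept(e_new - state.energy, kT, rng)
        if ok:
            state.structure = cand
            state.energy = e_new
            state.accepted += 1
            if e_new < state.best_energy:
                state.best_energy = e_new
                state.best_structure = cand.copy()
        if log_trajectory:
            state.trajectory.append((step, kind, float(e_new), ok))
    return state


def trajectory_tsv(state: SamplerState) -> str:
    lines = ["step\tmove_kind\tenergy\taccepted"]
    for step, kind, e, ok in state.trajectory:
        lines.append(f"{step}\t{kind}\t{e:.4f}\t{int(ok)}")
    return "\n".join(lines) + "\n"
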