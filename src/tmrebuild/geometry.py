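"""Helix construction, axis fitting, and kink descriptors.

A kinked transmembrane helix is described by three contiguous regions: a
moveable (m) and a fixed (f) quasi-straight helical fragment separated by a
short distorted bend (4-6 residues).  The reference residue (typically the
bend-inducing proline) is the f-fragment residue adjacent to the bend; its CB
defines the -x direction of the sampling frame, so that "+x" points away from
the proline ring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import N, CA, C, O, CB, Structure, ideal_cb
from .internal import (
    rebuild_forward, rotation_between, rotation_about_axis, place_atom,
    BOND_N_CA, BOND_CA_C, ANG_N_CA_C,
)

# canonical alpha-helix torsions; give ~1.5 A rise and ~100 deg twist
HELIX_PHI, HELIX_PSI, HELIX_OMEGA = -57.8, -47.0, 180.0


class GeometryError(ValueError):
    pass


@dataclass
class HelixAxis:
    """Least-squares helical axis, oriented N->C along the chain."""

    origin: np.ndarray
    direction: np.ndarray
    rise_per_residue: float

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        d = np.asarray(self.direction, float)
        self.direction = d / np.linalg.norm(d)


@dataclass
class KinkSpec:
    """Kinked-helix decomposition and measured kink descriptors.

    Ranges are closed residue intervals (first, last).  ``ref_residue`` is the
    bend-inducing residue (e.g. proline) at the bend-side end of the f
    fragment.  ``kink_angle`` is the angle between the m and f axes (degrees),
    ``translation`` the CA-CA distance across the bend (A), ``swing`` the
    azimuth of the m far terminus in the plane orthogonal to the f axis,
    measured right-handed about f from the -x (toward-proline-CB) reference.
    """

    f_range: tuple[int, int]
    m_range: tuple[int, int]
    bend_range: tuple[int, int]
    ref_residue: int
    kink_angle: float = 0.0
    translation: float = 0.0
    swing: float = 0.0

    def __post_init__(self):
        for name, (a, b) in (("f", self.f_range), ("m", self.m_range),
                             ("bend", self.bend_range)):
            if a > b:
                raise GeometryError(f"{name}_range reversed: ({a}, {b})")
        m, bd, f = self.m_range, self.bend_range, self.f_range
        forward = m[1] + 1 == bd[0] and bd[1] + 1 == f[0]
        backward = f[1] + 1 == bd[0] and bd[1] + 1 == m[0]
        if not (forward or backward):
            raise GeometryError("m, bend, f ranges must be contiguous")
        self.m_before_f = forward
        if not (0.0 <= self.kink_angle < 180.0):
            raise GeometryError("kink_angle outside [0, 180)")
        ref_ok = (self.ref_residue == (f[0] if forward else f[1]))
        if not ref_ok:
            raise GeometryError(
                "ref_residue must be the f-fragment residue adjacent to the bend")

    @property
    def bend_length(self) -> int:
        return self.bend_range[1] - self.bend_range[0] + 1

    # bend-side / far termini used by the sampler frame
    @property
    def m_bend_end(self) -> int:
        return self.m_range[1] if self.m_before_f else self.m_range[0]

    @property
    def m_far_end(self) -> int:
        return self.m_range[0] if self.m_before_f else self.m_range[1]

    def validate_bend_length(self, lo: int = 4, hi: int = 6) -> None:
        if not (lo <= self.bend_length <= hi):
            raise GeometryError(
                f"bend length {self.bend_length} outside [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# Ideal helix
# ---------------------------------------------------------------------------

def ideal_helix(n: int, start=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0),
                sequence: str | None = None, start_resnum: int = 1,
                chain_id: str = "A") -> Structure:
    """Canonical alpha-helix backbone of ``n`` residues.

    The fitted helical axis points along ``direction`` and the first CA sits
    at ``start``.
    """
    if n < 1:
        raise GeometryError("n must be >= 1")
    if sequence is None:
        sequence = "A" * n
    if len(sequence) != n:
        raise GeometryError("sequence length != n")
    coords = np.full((n, 5, 3), np.nan)
    # seed residue in a local frame
    coords[0, N] = np.array([0.0, 0.0, 0.0])
    coords[0, CA] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - ANG_N_CA_C)
    coords[0, C] = coords[0, CA] + BOND_CA_C * np.array(
        [np.cos(ang), np.sin(ang), 0.0])
    coords[0, CB] = ideal_cb(coords[0, N], coords[0, CA], coords[0, C])
    s = Structure(np.arange(start_resnum, start_resnum + n), list(sequence),
                  coords, chain_id=chain_id,
                  cb_virtual=np.ones(n, dtype=bool))
    if n > 1:
        # N of residue 2 from psi(1); rebuild_forward keeps N(first) fixed
        from .internal import BOND_C_N, ANG_CA_C_N
        s.coords[1, N] = place_atom(s.coords[0, N], s.coords[0, CA],
                                    s.coords[0, C], BOND_C_N, ANG_CA_C_N,
                                    HELIX_PSI)
        tors = np.tile([HELIX_PHI, HELIX_PSI, HELIX_OMEGA], (n - 1, 1))
        s = rebuild_forward(s, start_resnum + 1, start_resnum + n - 1, tors)
        # O of the first/last residues from helical psi
        from .internal import _place_o
        _place_o(s.coords, 0, HELIX_PSI)
        _place_o(s.coords, n - 1, HELIX_PSI)
    # orient along the requested direction
    target_dir = np.asarray(direction, float)
    target_dir = target_dir / np.linalg.norm(target_dir)
    if n >= 4:
        axis = fit_helix_axis(s.coords[:, CA, :])
        R = rotation_between(axis.direction, target_dir)
    else:
        R = np.eye(3)
    flat = s.coords.reshape(-1, 3)
    flat = flat @ R.T
    s.coords = flat.reshape(n, 5, 3)
    s.coords += np.asarray(start, float) - s.coords[0, CA]
    return s


# ---------------------------------------------------------------------------
# Axis fitting
# ---------------------------------------------------------------------------

def fit_helix_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Fit the helical axis through >= 4 CA positions.

    Direction comes from averaged cross products of consecutive local
    bisectors (each interior CA's bisector points at the axis); the axis
    origin from a least-squares circle fit of the CAs projected onto the
    orthogonal plane.  Exact on ideal helices, stable on 4-residue fragments.
    """
    P = np.asarray(ca_coords, float)
    if P.ndim != 2 or P.shape[0] < 4 or P.shape[1] != 3:
        raise GeometryError("fit_helix_axis needs >= 4 CA coordinates")
    nres = P.shape[0]
    # interior bisectors
    b = (P[:-2] - P[1:-1]) + (P[2:] - P[1:-1])
    bn = np.linalg.norm(b, axis=1)
    if np.any(bn < 1e-8):
        raise GeometryError("degenerate (collinear) CA geometry")
    b = b / bn[:, None]
    d = np.cross(b[:-1], b[1:])
    dn = np.linalg.norm(d, axis=1)
    if np.all(dn < 1e-6):
        raise GeometryError("degenerate CA geometry: no helical curvature")
    d = d[dn > 1e-6] / dn[dn > 1e-6, None]
    chain = P[-1] - P[0]
    sign = np.where(d @ chain >= 0, 1.0, -1.0)
    direction = (d * sign[:, None]).mean(axis=0)
    nrm = np.linalg.norm(direction)
    if nrm < 1e-8:
        raise GeometryError("inconsistent local axis estimates")
    direction = direction / nrm

    # orthonormal basis of the orthogonal plane
    e1 = np.cross(direction, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(direction, [0.0, 1.0, 0.0])
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    x = P @ e1
    y = P @ e2
    # Kasa algebraic circle fit via normal equations (3x3 solve)
    A = np.column_stack([2 * x, 2 * y, np.ones(nres)])
    rhs = x ** 2 + y ** 2
    sol = np.linalg.solve(A.T @ A, A.T @ rhs)
    a, bb = sol[0], sol[1]
    t = P @ direction
    origin = a * e1 + bb * e2 + t.mean() * direction
    # rise: slope of axial position vs residue index
    idx = np.arange(nres)
    rise = float(np.cov(idx, t, bias=True)[0, 1] / np.var(idx))
    return HelixAxis(origin=origin, direction=direction, rise_per_residue=rise)


# ---------------------------------------------------------------------------
# Kink measurement and rigid transforms
# ---------------------------------------------------------------------------

def _fragment_axis(s: Structure, rng: tuple[int, int]) -> HelixAxis:
    rows = s.rows_in(*rng)
    if len(rows) < 4:
        raise GeometryError(f"fragment {rng} has fewer than 4 residues")
    return fit_helix_axis(s.coords[rows, CA, :])


def kink_frame(s: Structure, spec: KinkSpec, f_direction=None):
    """Orthonormal sampling frame (origin, R) of the kinked helix.

    Columns of R are (x, y, z): z is the f axis oriented from the f body out
    through its bend-side terminus; -x points from the m bend-side terminus CA
    toward the reference residue's CB (the proline ring); y = z cross x.
    ``f_direction`` (the f fragment's N->C axis) may be supplied by callers
    that already computed it.
    """
    if f_direction is None:
        f_direction = _fragment_axis(s, spec.f_range).direction
    z = f_direction if not spec.m_before_f else -np.asarray(f_direction)
    # f N->C points away from the bend when f follows the bend in sequence;
    # flip so z always points from the f body toward the bend side
    ref_row = s.row(spec.ref_residue)
    cb = s.coords[ref_row, CB]
    if np.any(np.isnan(cb)):
        cb = ideal_cb(s.coords[ref_row, N], s.coords[ref_row, CA],
                      s.coords[ref_row, C])
    m_bend_ca = s.coords[s.row(spec.m_bend_end), CA]
    minus_x = cb - m_bend_ca
    minus_x = minus_x - np.dot(minus_x, z) * z
    nrm = np.linalg.norm(minus_x)
    if nrm < 1e-6:
        raise GeometryError("reference CB collinear with the f axis")
    minus_x = minus_x / nrm
    x = -minus_x
    y = np.cross(z, x)
    origin = s.coords[s.row(spec.f_range[0] if spec.m_before_f
                            else spec.f_range[1]), CA]
    return origin, np.column_stack([x, y, z])


def measure_kink(s: Structure, f_range, m_range, bend_range,
                 ref_residue) -> KinkSpec:
    """Measure kink angle, translation, and swing of a kinked helix."""
    spec = KinkSpec(tuple(f_range), tuple(m_range), tuple(bend_range),
                    int(ref_residue))
    f_ax = _fragment_axis(s, spec.f_range)
    m_ax = _fragment_axis(s, spec.m_range)
    cosang = float(np.clip(np.dot(f_ax.direction, m_ax.direction), -1, 1))
    spec.kink_angle = float(np.degrees(np.arccos(cosang)))
    f_bend_end = spec.f_range[0] if spec.m_before_f else spec.f_range[1]
    spec.translation = float(np.linalg.norm(
        s.coords[s.row(spec.m_bend_end), CA]
        - s.coords[s.row(f_bend_end), CA]))
    # swing azimuth of the m far terminus about the f axis
    origin, R = kink_frame(s, spec)
    z = R[:, 2]
    minus_x = -R[:, 0]
    ref_ca = s.coords[s.row(spec.ref_residue), CA]
    p = s.coords[s.row(spec.m_far_end), CA] - ref_ca
    proj = p - np.dot(p, z) * z
    if np.linalg.norm(proj) < 1e-9:
        spec.swing = 0.0
    else:
        spec.swing = float(np.degrees(np.arctan2(
            np.dot(z, np.cross(minus_x, proj)), np.dot(minus_x, proj))))
    return spec


def apply_rigid_transform(s: Structure, res_range: tuple[int, int],
                          rotation: np.ndarray, translation) -> Structure:
    """Apply x' = R x + t to all atoms of residues in the closed range."""
    out = s.copy()
    rows = out.rows_in(*res_range)
    if len(rows) == 0:
        raise GeometryError(f"no residues in range {res_range}")
    R = np.asarray(rotation, float)
    t = np.asarray(translation, float)
    blk = out.coords[rows]
    shape = blk.shape
    moved = blk.reshape(-1, 3) @ R.T + t
    out.coords[rows] = moved.reshape(shape)
    return out
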