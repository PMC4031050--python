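"""Backbone internal-coordinate machinery.

Torsion extraction, NeRF atom placement, forward rebuilding of a residue
window from (phi, psi, omega), and the cyclic-coordinate-descent (CCD)
analytic torsion update used for chain closure.  All torsions are in degrees
in (-180, 180]; bond lengths/angles use ideal peptide values, so a rebuilt
window always carries ideal covalent geometry and only torsions vary.
"""

from __future__ import annotations

import numpy as np

from .structure import N, CA, C, O, CB, Structure, ideal_cb

# ideal peptide geometry (Engh-Huber-like)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.5


def wrap_angle(a):
    """Wrap degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -((-a + 180.0) % 360.0 - 180.0)
    return w if w.ndim else float(w)


def _cross3(a, b):
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = _cross3(b0, b1)
    n2 = _cross3(b1, b2)
    m1 = _cross3(n1, b1 / np.sqrt(b1 @ b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


def dihedral_batch(p0, p1, p2, p3) -> np.ndarray:
    """Vectorized signed dihedrals over (n, 3) point arrays, degrees."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1n)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.degrees(np.arctan2(y, x))


def bond_angle(p0, p1, p2) -> float:
    v1 = p0 - p1
    v2 = p2 - p1
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF: position of atom d with given c-d bond, b-c-d angle, a-b-c-d torsion."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in place_atom")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        -bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(u, theta_rad: float) -> np.ndarray:
    """Rotation matrix about unit axis u (Rodrigues)."""
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(theta_rad) * K + (1 - np.cos(theta_rad)) * (K @ K)


def rotation_between(a, b) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, np.pi)
    return rotation_about_axis(v / s, np.arctan2(s, c))


# ---------------------------------------------------------------------------
# Torsion extraction / application
# ---------------------------------------------------------------------------

def backbone_torsions(s: Structure) -> np.ndarray:
    """(n, 3) array of (phi, psi, omega) per residue; NaN where undefined."""
    n = len(s)
    t = np.full((n, 3), np.nan)
    if n < 2:
        return t
    X = s.coords
    t[1:, 0] = dihedral_batch(X[:-1, C], X[1:, N], X[1:, CA], X[1:, C])
    t[1:, 2] = dihedral_batch(X[:-1, CA], X[:-1, C], X[1:, N], X[1:, CA])
    t[:-1, 1] = dihedral_batch(X[:-1, N], X[:-1, CA], X[:-1, C], X[1:, N])
    return t


def _place_o(X, i, psi):
    X[i, O] = place_atom(X[i, N], X[i, CA], X[i, C], BOND_C_O, ANG_CA_C_O,
                         wrap_angle(psi + 180.0))


def rebuild_forward(s: Structure, first: int, last: int,
                    torsions: np.ndarray) -> Structure:
    """Re-derive coordinates of residues [first, last] from torsions.

    ``torsions`` is an (last-first+1, 3) array of (phi, psi, omega) for those
    residues.  Residue first-1 must exist and is the fixed upstream anchor;
    N(first) is re-placed at ideal bond geometry along the current
    psi(first-1) direction (an identity on intact ideal chains, a healing
    step on broken junctions).  Atoms after ``last`` are untouched, so the
    junction last|last+1 may become a chain break to be closed by CCD.
    """
    out = s.copy()
    X = out.coords
    i0 = s.row(first)
    i1 = s.row(last)
    if i0 == 0:
        raise ValueError("rebuild window cannot start at the chain N-terminus")
    torsions = np.asarray(torsions, dtype=float)
    if torsions.shape != (i1 - i0 + 1, 3):
        raise ValueError("torsion array shape mismatch with window")
    psi_prev = dihedral(X[i0 - 1, N], X[i0 - 1, CA], X[i0 - 1, C], X[i0, N]) \
        if np.all(np.isfinite(X[i0, N])) else -47.0
    if not np.isfinite(psi_prev):
        psi_prev = -47.0
    X[i0, N] = place_atom(X[i0 - 1, N], X[i0 - 1, CA], X[i0 - 1, C],
                          BOND_C_N, ANG_CA_C_N, psi_prev)
    for j, i in enumerate(range(i0, i1 + 1)):
        phi, psi, omega = torsions[j]
        if j > 0:
            # N(i) from psi(i-1)
            X[i, N] = place_atom(X[i - 1, N], X[i - 1, CA], X[i - 1, C],
                                 BOND_C_N, ANG_CA_C_N, torsions[j - 1, 1])
        X[i, CA] = place_atom(X[i - 1, CA], X[i - 1, C], X[i, N],
                              BOND_N_CA, ANG_C_N_CA, omega)
        X[i, C] = place_atom(X[i - 1, C], X[i, N], X[i, CA],
                             BOND_CA_C, ANG_N_CA_C, phi)
        _place_o(X, i, psi)
        X[i, CB] = ideal_cb(X[i, N], X[i, CA], X[i, C])
        out.cb_virtual[i] = True
    return out


# ---------------------------------------------------------------------------
# CCD closure
# ---------------------------------------------------------------------------

def ccd_optimal_angle(pivot, axis, moving, target) -> float:
    """Analytic rotation angle (radians) about (pivot, axis) minimizing the
    summed squared distance between ``moving`` points and ``target`` points.
    """
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    M = np.atleast_2d(moving)
    F = np.atleast_2d(target)
    proj = (M - pivot) @ u
    Oc = pivot + proj[:, None] * u
    r = M - Oc
    rn = np.linalg.norm(r, axis=1)
    ok = rn > 1e-9
    if not np.any(ok):
        return 0.0
    shat = r[ok] / rn[ok, None]
    that = np.cross(u, shat)
    f = F[ok] - Oc[ok]
    a = float(np.sum(rn[ok] * np.einsum("ij,ij->i", f, shat)))
    b = float(np.sum(rn[ok] * np.einsum("ij,ij->i", f, that)))
    if a == 0.0 and b == 0.0:
        return 0.0
    return float(np.arctan2(b, a))


class CCDResult:
    def __init__(self, structure, gap, cycles, converged, overlap_ssd=0.0):
        self.structure = structure
        self.gap = float(gap)
        self.cycles = int(cycles)
        self.converged = bool(converged)
        # summed squared deviation of the three overlap atoms (N', CA', C');
        # this is the quantity each analytic torsion update cannot increase
        self.overlap_ssd = float(overlap_ssd)


def _ccd_iterate_py(A, target, nres, max_cycles, tolerance):
    """Reference implementation of the CCD cycle loop (see _ccd_iterate)."""
    nv = 3 * nres
    converged = False
    cycles = 0
    last_check = -1.0
    for cycle in range(1, max_cycles + 1):
        cycles = cycle
        bonds = [(3 * j + k, 3 * j + k + 1, 3 * j + k + 2)
                 for j in range(nres) for k in (0, 1)]
        for (p0, p1, start) in bonds:
            pivot = A[p0]
            axis = A[p1] - pivot
            theta = ccd_optimal_angle(pivot, axis, A[nv:], target)
            if theta != 0.0:
                Rm = rotation_about_axis(axis, theta)
                A[start:] = (A[start:] - pivot) @ Rm.T + pivot
        pivot = A[nv]
        axis = A[nv + 1] - pivot
        theta = ccd_optimal_angle(pivot, axis, A[nv + 2:], target[2:])
        if theta != 0.0:
            Rm = rotation_about_axis(axis, theta)
            A[nv + 2] = (A[nv + 2] - pivot) @ Rm.T + pivot
        g = float(np.linalg.norm(A[nv] - target[0]))
        if g <= tolerance:
            converged = True
            break
        if cycle % 10 == 0:
            if last_check >= 0.0 and last_check - g < 0.005 * last_check:
                break
            last_check = g
    gap = float(np.linalg.norm(A[nv] - target[0]))
    return gap, cycles, converged


def _make_ccd_kernel():
    """Numba-compiled CCD cycle loop; falls back to numpy if unavailable."""
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is normally present
        return None

    @njit(cache=True)
    def kernel(A, target, nres, max_cycles, tolerance):  # pragma: no cover
        nv = 3 * nres
        natoms = A.shape[0]
        converged = False
        cycles = 0
        last_check = -1.0
        for cycle in range(1, max_cycles + 1):
            cycles = cycle
            for b in range(2 * nres + 1):
                if b < 2 * nres:
                    j = b // 2
                    k = b % 2
                    p0 = 3 * j + k
                    p1 = p0 + 1
                    start = p0 + 2
                    mlo, mhi = nv, nv + 3
                    tlo = 0
                else:
                    p0 = nv
                    p1 = nv + 1
                    start = nv + 2
                    mlo, mhi = nv + 2, nv + 3
                    tlo = 2
                # unit axis
                ux = A[p1, 0] - A[p0, 0]
                uy = A[p1, 1] - A[p0, 1]
                uz = A[p1, 2] - A[p0, 2]
                un = (ux * ux + uy * uy + uz * uz) ** 0.5
                if un < 1e-12:
                    continue
                ux /= un
                uy /= un
                uz /= un
                # optimal angle over moving atoms [mlo, mhi) vs target[tlo..]
                aa = 0.0
                bb = 0.0
                for m in range(mlo, mhi):
                    mx = A[m, 0] - A[p0, 0]
                    my = A[m, 1] - A[p0, 1]
                    mz = A[m, 2] - A[p0, 2]
                    proj = mx * ux + my * uy + mz * uz
                    ox = A[p0, 0] + proj * ux
                    oy = A[p0, 1] + proj * uy
                    oz = A[p0, 2] + proj * uz
                    rx = A[m, 0] - ox
                    ry = A[m, 1] - oy
                    rz = A[m, 2] - oz
                    rn = (rx * rx + ry * ry + rz * rz) ** 0.5
                    if rn < 1e-9:
                        continue
                    sx, sy, sz = rx / rn, ry / rn, rz / rn
                    tx = uy * sz - uz * sy
                    ty = uz * sx - ux * sz
                    tz = ux * sy - uy * sx
                    t = tlo + (m - mlo)
                    fx = target[t, 0] - ox
                    fy = target[t, 1] - oy
                    fz = target[t, 2] - oz
                    aa += rn * (fx * sx + fy * sy + fz * sz)
                    bb += rn * (fx * tx + fy * ty + fz * tz)
                if aa == 0.0 and bb == 0.0:
                    continue
                theta = np.arctan2(bb, aa)
                if theta == 0.0:
                    continue
                c = np.cos(theta)
                s = np.sin(theta)
                for m in range(start, natoms):
                    px = A[m, 0] - A[p0, 0]
                    py = A[m, 1] - A[p0, 1]
                    pz = A[m, 2] - A[p0, 2]
                    dot = px * ux + py * uy + pz * uz
                    # Rodrigues rotation of p about u
                    cx = uy * pz - uz * py
                    cy = uz * px - ux * pz
                    cz = ux * py - uy * px
                    qx = px * c + cx * s + ux * dot * (1.0 - c)
                    qy = py * c + cy * s + uy * dot * (1.0 - c)
                    qz = pz * c + cz * s + uz * dot * (1.0 - c)
                    A[m, 0] = A[p0, 0] + qx
                    A[m, 1] = A[p0, 1] + qy
                    A[m, 2] = A[p0, 2] + qz
            gx = A[nv, 0] - target[0, 0]
            gy = A[nv, 1] - target[0, 1]
            gz = A[nv, 2] - target[0, 2]
            g = (gx * gx + gy * gy + gz * gz) ** 0.5
            if g <= tolerance:
                converged = True
                break
            if cycle % 10 == 0:
                if last_check >= 0.0 and last_check - g < 0.005 * last_check:
                    break
                last_check = g
        gx = A[nv, 0] - target[0, 0]
        gy = A[nv, 1] - target[0, 1]
        gz = A[nv, 2] - target[0, 2]
        gap = (gx * gx + gy * gy + gz * gz) ** 0.5
        return gap, cycles, converged

    return kernel


_CCD_KERNEL = _make_ccd_kernel()


def _ccd_iterate(A, target, nres, max_cycles, tolerance):
    """Run CCD cycles in place on the flat atom array A."""
    if _CCD_KERNEL is not None and A.flags["C_CONTIGUOUS"]:
        return _CCD_KERNEL(A, np.ascontiguousarray(target), nres,
                           max_cycles, tolerance)
    return _ccd_iterate_py(A, target, nres, max_cycles, tolerance)


def ccd_close_window(s: Structure, first: int, brk: int,
                     max_cycles: int = 60, tolerance: float = 0.05) -> CCDResult:
    """Close the chain break between residues ``brk`` and ``brk``+1 by CCD.

    Degrees of freedom are phi/psi of residues [first, brk] plus the torsions
    placing the ideal continuation (overlap) atoms N', CA', C' of residue
    brk+1 off residue brk.  The reported gap is the distance between the ideal
    continuation position N' and the actual N of residue brk+1 (equivalently
    the C-N peptide-bond deviation at the break).
    """
    out = s.copy()
    X = out.coords
    i0, ib = s.row(first), s.row(brk)
    if i0 > ib:
        raise ValueError("first > break position")
    if ib + 1 >= len(s):
        raise ValueError("break position has no downstream anchor residue")
    if i0 == 0:
        raise ValueError("window cannot start at the chain N-terminus")

    target = np.array([X[ib + 1, N], X[ib + 1, CA], X[ib + 1, C]])

    # initial psi/phi of the overlap triplet from current geometry (they are
    # CCD degrees of freedom); omega is held ideal so exact closure implies a
    # planar trans peptide bond at the healed junction
    psi_b = dihedral(X[ib, N], X[ib, CA], X[ib, C], X[ib + 1, N])
    phi_v = dihedral(X[ib, C], X[ib + 1, N], X[ib + 1, CA], X[ib + 1, C])
    omega_v = 180.0
    if not np.isfinite(psi_b):
        psi_b = -47.0
    if not np.isfinite(phi_v):
        phi_v = -57.8

    vN = place_atom(X[ib, N], X[ib, CA], X[ib, C], BOND_C_N, ANG_CA_C_N, psi_b)
    vCA = place_atom(X[ib, CA], X[ib, C], vN, BOND_N_CA, ANG_C_N_CA, omega_v)
    vC = place_atom(X[ib, C], vN, vCA, BOND_CA_C, ANG_N_CA_C, phi_v)

    # flat work array: N, CA, C per window residue, then the virtual triplet;
    # every torsion's moving set is a suffix slice of this array
    nres = ib - i0 + 1
    A = np.empty((3 * nres + 3, 3))
    A[:3 * nres] = X[i0:ib + 1, (N, CA, C), :].reshape(-1, 3)
    A[3 * nres:] = [vN, vCA, vC]
    nv = 3 * nres  # start of virtual triplet
    gap, cycles, converged = _ccd_iterate(A, target, nres, max_cycles,
                                          float(tolerance))
    overlap_ssd = float(np.sum((A[nv:] - target) ** 2))

    X[i0:ib + 1, (N, CA, C), :] = A[:3 * nres].reshape(nres, 3, 3)
    # re-derive O and CB inside the window from the final geometry
    for i in range(i0, ib + 1):
        nxt = A[nv] if i == ib else X[i + 1, N]
        psi = dihedral(X[i, N], X[i, CA], X[i, C], nxt)
        _place_o(X, i, psi)
        X[i, CB] = ideal_cb(X[i, N], X[i, CA], X[i, C])
        out.cb_virtual[i] = True
    return CCDResult(out, gap, cycles, converged, overlap_ssd)
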