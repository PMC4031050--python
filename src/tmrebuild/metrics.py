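"""Model accuracy metrics: Cα RMSD, GDT/GDT-HA, residue fractions within
distance cutoffs, bend dihedral deviations, and TM-score.

GDT here approximates the full LGA search from below: per-threshold residue
fractions are maximized over superpositions seeded from all 4/8/16-residue
sequence windows plus the global least-squares fit.  TM-score uses the
standard d0(L) = 1.24 (L-15)^(1/3) - 1.8 normalization with an iterative
subset-superposition search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import N, CA, C, Structure
from .internal import dihedral, wrap_angle

GDT_HA_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
GDT_TS_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)


def _as_points(x) -> np.ndarray:
    p = np.asarray(x, float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("expected (n, 3) coordinates")
    return p


def kabsch_rmsd(A, B) -> tuple[float, np.ndarray, np.ndarray]:
    """Optimal least-squares superposition of B onto A.

    Returns ``(rmsd, R, t)`` with ``B @ R.T + t`` superposed onto A; R is a
    proper rotation (det +1).
    """
    A = _as_points(A)
    B = _as_points(B)
    if A.shape != B.shape:
        raise ValueError(f"length mismatch: {A.shape[0]} vs {B.shape[0]}")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points")
    ca_, cb_ = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb_).T @ (A - ca_)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca_ - R @ cb_
    moved = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - A) ** 2, axis=1))))
    return rmsd, R, t


def _superpose(A, B):
    _, R, t = kabsch_rmsd(A, B)
    return B @ R.T + t


def _window_superpositions(model, native, sizes=(4, 8, 16)):
    """Candidate model coordinates superposed from sliding-window seeds."""
    n = len(model)
    cands = [_superpose(native, model)]
    for w in sizes:
        if w > n:
            continue
        for start in range(0, n - w + 1):
            sl = slice(start, start + w)
            try:
                _, R, t = kabsch_rmsd(native[sl], model[sl])
            except ValueError:
                continue
            cands.append(model @ R.T + t)
    return cands


def gdt_scores(model, native, mode: str = "ha",
               superposition: str = "multiseed") -> float:
    """Geometric Distance Test score in [0, 1].

    Mean over four distance thresholds (HA: 0.5/1/2/4 A, standard:
    1/2/4/8 A) of the residue fraction within each threshold.
    ``superposition``: ``none`` evaluates distances in the given frame,
    ``kabsch`` applies the single global superposition, ``multiseed``
    maximizes each threshold's fraction over window-seeded superpositions.
    """
    model = _as_points(model)
    native = _as_points(native)
    if model.shape != native.shape:
        raise ValueError("model/native length mismatch")
    thresholds = GDT_HA_THRESHOLDS if mode == "ha" else GDT_TS_THRESHOLDS
    if mode not in ("ha", "standard"):
        raise ValueError("mode must be 'ha' or 'standard'")
    if superposition == "none":
        cands = [model]
    elif superposition == "kabsch":
        cands = [_superpose(native, model)]
    elif superposition == "multiseed":
        cands = _window_superpositions(model, native)
    else:
        raise ValueError("superposition must be none|kabsch|multiseed")
    fracs = np.zeros(len(thresholds))
    for cand in cands:
        d = np.linalg.norm(cand - native, axis=1)
        for k, thr in enumerate(thresholds):
            fracs[k] = max(fracs[k], float(np.mean(d <= thr)))
    return float(fracs.mean())


def pct_within(model, native, cutoff: float, superpose: bool = True) -> float:
    """Percentage of residues with Cα within ``cutoff`` after superposition."""
    model = _as_points(model)
    native = _as_points(native)
    if superpose:
        model = _superpose(native, model)
    d = np.linalg.norm(model - native, axis=1)
    return float(np.mean(d <= cutoff) * 100.0)


def bend_dihedral_deviation(model: Structure, native: Structure,
                            window: tuple[int, int]) -> tuple[float, float]:
    """Mean absolute phi/psi deviation (degrees) over a residue window.

    Differences are circular (wrapped to [-180, 180]); the window must have
    flanking residues in both structures so phi and psi are defined.
    """
    lo, hi = window
    dphi, dpsi = [], []
    for r in (lo, hi):
        for s, name in ((model, "model"), (native, "native")):
            if not (s.has_residue(r)):
                raise ValueError(f"{name} missing residue {r}")
    for s, name in ((model, "model"), (native, "native")):
        if not (s.has_residue(lo - 1) and s.has_residue(hi + 1)):
            raise ValueError(
                f"{name}: window [{lo}, {hi}] lacks flanking residues")
    for r in range(lo, hi + 1):
        angs = []
        for s in (model, native):
            i = s.row(r)
            X = s.coords
            phi = dihedral(X[i - 1, C], X[i, N], X[i, CA], X[i, C])
            psi = dihedral(X[i, N], X[i, CA], X[i, C], X[i + 1, N])
            angs.append((phi, psi))
        dphi.append(abs(wrap_angle(angs[0][0] - angs[1][0])))
        dpsi.append(abs(wrap_angle(angs[0][1] - angs[1][1])))
    return float(np.mean(dphi)), float(np.mean(dpsi))


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

def tm_d0(L: int) -> float:
    if L < 16:
        raise ValueError("TM-score d0 undefined for L < 16")
    return 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8


def tm_score(model, native, normalization_length: int | None = None) -> float:
    """Standard TM-score of aligned Cα coordinate sets.

    Maximizes (1/L) sum 1/(1 + (di/d0)^2) over superpositions found by an
    iterative extension search from sliding-window seeds.
    """
    model = _as_points(model)
    native = _as_points(native)
    if model.shape != native.shape:
        raise ValueError("model/native length mismatch")
    n = model.shape[0]
    L = normalization_length if normalization_length is not None else n
    d0 = tm_d0(L)

    def score_of(coords):
        d = np.linalg.norm(coords - native, axis=1)
        return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)) * n / L)

    best = 0.0
    seeds = []
    if n <= 40:
        # small chains: exhaustive window seeds (all sizes >= 3, stride 1)
        sizes = range(3, n + 1)
    else:
        sizes = sorted({n, max(n // 2, 4), max(n // 4, 4), 4})
    for w in sizes:
        if w > n or w < 3:
            continue
        stride = max(1, w // 2) if n > 40 else 1
        for start in range(0, n - w + 1, stride):
            seeds.append(slice(start, start + w))
    d_cut = max(d0, 4.5)
    for sl in seeds:
        try:
            _, R, t = kabsch_rmsd(native[sl], model[sl])
        except ValueError:
            continue
        coords = model @ R.T + t
        best = max(best, score_of(coords))
        prev_sel = None
        for _ in range(20):
            d = np.linalg.norm(coords - native, axis=1)
            sel = d < d_cut
            if sel.sum() < 3:
                order = np.argsort(d)
                sel = np.zeros(n, bool)
                sel[order[:3]] = True
            key = sel.tobytes()
            if key == prev_sel:
                break
            prev_sel = key
            _, R, t = kabsch_rmsd(native[sel], model[sel])
            coords = model @ R.T + t
            best = max(best, score_of(coords))
    return best


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    region: str
    ca_rmsd: float
    gdt: float
    gdt_ha: float
    pct_within_1A: float
    pct_within_2A: float
    tm_score: float
    mean_dphi: float | None = None
    mean_dpsi: float | None = None

    def __post_init__(self):
        if self.gdt_ha > self.gdt + 1e-12:
            raise ValueError("gdt_ha cannot exceed gdt")

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def score_model(model: Structure, native: Structure, residues=None,
                region: str = "full", correspondence=None,
                bend_window: tuple[int, int] | None = None) -> AccuracyReport:
    """Full accuracy report of ``model`` against ``native``.

    ``residues``: residue numbers to score, shared numbering (must exist in
    both); default all shared residues.  Alternatively ``correspondence`` is
    an explicit list of (model_residue, native_residue) pairs, as derived
    from a target-template alignment when numbering differs.
    ``bend_window`` adds mean phi/psi deviations (shared numbering only).
    """
    if correspondence is not None:
        model_res = [m for m, _ in correspondence]
        native_res = [nr for _, nr in correspondence]
    else:
        if residues is None:
            residues = [int(r) for r in model.index
                        if native.has_residue(r)]
        model_res = native_res = residues
    A = native.ca(native_res)
    B = model.ca(model_res)
    residues = native_res
    rmsd, _, _ = kabsch_rmsd(A, B)
    report = AccuracyReport(
        region=region,
        ca_rmsd=rmsd,
        gdt=gdt_scores(B, A, mode="standard"),
        gdt_ha=gdt_scores(B, A, mode="ha"),
        pct_within_1A=pct_within(B, A, 1.0),
        pct_within_2A=pct_within(B, A, 2.0),
        tm_score=tm_score(B, A) if len(residues) >= 16 else float("nan"),
    )
    if bend_window is not None:
        report.mean_dphi, report.mean_dpsi = bend_dihedral_deviation(
            model, native, bend_window)
    return report
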