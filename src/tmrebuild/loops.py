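"""De novo loop and bend rebuilding: fragment insertion + CCD closure.

A rebuild window carries a chain break at its C-terminal end.  Each rebuilding
step inserts a random torsion fragment (size 9 when the window allows it,
else 3), closes the break by cyclic coordinate descent, and accepts or
rejects by Metropolis on a score that includes a chain-break penalty whose
weight ramps up geometrically.  If after twelve steps the break still exceeds
0.2 A the window is expanded by one residue on both sides and the process
repeats, up to an expansion cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .structure import N, CA, C, O, CB, Structure
from .internal import (backbone_torsions, rebuild_forward, ccd_close_window,
                       wrap_angle)
from .sampler import metropolis_accept

FRAGMENT_SIZES = (3, 9)
BREAK_THRESHOLD = 0.2          # A, residual deviation counting as a break
REBUILD_STEPS = 12             # insertions before a window expansion

# torsion basins for generated fragments (phi, psi, sd_phi, sd_psi)
_BASINS = {
    "helix": (-63.0, -43.0, 8.0, 8.0),
    "sheet": (-120.0, 135.0, 20.0, 20.0),
    "alphaL": (60.0, 45.0, 10.0, 10.0),
}


class LoopClosureError(RuntimeError):
    def __init__(self, message, best_structure=None, best_gap=None):
        super().__init__(message)
        self.best_structure = best_structure
        self.best_gap = best_gap


@dataclass(frozen=True)
class Fragment:
    torsions: tuple  # ((phi, psi, omega), ...) degrees
    ss: str = "L"

    def __len__(self):
        return len(self.torsions)

    def as_array(self) -> np.ndarray:
        return np.array(self.torsions, dtype=float)


@dataclass
class FragmentLibrary:
    fragments: dict[int, list[Fragment]]

    def __post_init__(self):
        for size in FRAGMENT_SIZES:
            if not self.fragments.get(size):
                raise ValueError(f"fragment library missing size {size}")
        for size, frags in self.fragments.items():
            for f in frags:
                arr = f.as_array()
                if arr.shape != (size, 3):
                    raise ValueError("fragment length mismatch")
                if np.any(np.abs(wrap_angle(arr[:, 2]) ) < 170.0):
                    raise ValueError("fragment omega deviates > 10 deg from trans")

    def pick(self, size: int, rng: np.random.Generator) -> Fragment:
        frags = self.fragments[size]
        return frags[rng.integers(len(frags))]


@dataclass
class RebuildWindow:
    first: int
    last: int
    break_position: int | None = None  # defaults to ``last``
    attempts: int = 0

    def __post_init__(self):
        if self.break_position is None:
            self.break_position = self.last
        if not (self.first <= self.break_position <= self.last):
            raise ValueError("break_position outside window")
        if self.attempts < 0:
            raise ValueError("attempts must be >= 0")

    @property
    def length(self) -> int:
        return self.last - self.first + 1

    def expanded(self) -> "RebuildWindow":
        return RebuildWindow(self.first - 1, self.last + 1,
                             self.last + 1, self.attempts)


# ---------------------------------------------------------------------------
# Fragment libraries
# ---------------------------------------------------------------------------

def _ideal_fragments(size: int) -> list[Fragment]:
    helix = (-57.8, -47.0, 180.0)
    ten = (-49.0, -26.0, 180.0)    # 3-10 helix
    pi = (-57.0, -70.0, 180.0)
    ext = (-120.0, 130.0, 180.0)
    ppii = (-75.0, 145.0, 180.0)
    turn1 = (-60.0, -30.0, 180.0)
    turn2 = (80.0, 0.0, 180.0)
    frags = [
        Fragment(tuple([helix] * size), "H"),
        Fragment(tuple([ten] * size), "G"),
        Fragment(tuple([pi] * size), "I"),
        Fragment(tuple([ext] * size), "E"),
        Fragment(tuple([ppii] * size), "P"),
    ]
    # type I'-like turn embedded in helix, at each feasible offset
    for off in range(size - 1):
        t = [helix] * size
        t[off] = turn1
        t[off + 1] = turn2
        frags.append(Fragment(tuple(t), "T"))
    # helix-to-extended and extended-to-helix junctions
    for split in range(1, size):
        frags.append(Fragment(tuple([helix] * split + [ext] * (size - split)), "HE"))
        frags.append(Fragment(tuple([ext] * split + [helix] * (size - split)), "EH"))
    return frags


def _ramachandran_fragments(size: int, rng: np.random.Generator,
                            n: int) -> list[Fragment]:
    names = list(_BASINS)
    probs = np.array([0.50, 0.35, 0.15])
    out = []
    for _ in range(n):
        tors = []
        for _ in range(size):
            b = names[rng.choice(len(names), p=probs)]
            phi0, psi0, sphi, spsi = _BASINS[b]
            phi = wrap_angle(rng.normal(phi0, sphi))
            psi = wrap_angle(rng.normal(psi0, spsi))
            omega = float(np.clip(rng.normal(180.0, 2.0), 171.0, 189.0))
            tors.append((phi, psi, wrap_angle(omega)))
        out.append(Fragment(tuple(tors), "R"))
    return out


def parse_fragment_file(text: str) -> FragmentLibrary:
    """Whitespace TSV: frag_id, position, aa, phi, psi, omega."""
    raw: dict[str, list[tuple[int, float, float, float]]] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("frag_id"):
            continue
        p = line.split()
        if len(p) != 6:
            raise ValueError(f"fragment file line {ln}: expected 6 fields")
        try:
            pos = int(p[1])
            phi, psi, omega = float(p[3]), float(p[4]), float(p[5])
        except ValueError as exc:
            raise ValueError(f"fragment file line {ln}: {exc}") from None
        raw.setdefault(p[0], []).append((pos, phi, psi, omega))
    fragments: dict[int, list[Fragment]] = {s: [] for s in FRAGMENT_SIZES}
    for fid, rows in raw.items():
        rows.sort()
        size = len(rows)
        if size not in FRAGMENT_SIZES:
            raise ValueError(f"fragment {fid}: size {size} not in {FRAGMENT_SIZES}")
        fragments[size].append(Fragment(
            tuple((r[1], r[2], r[3]) for r in rows), "F"))
    return FragmentLibrary(fragments)


def build_fragment_library(source: str = "ideal",
                           rng: np.random.Generator | None = None,
                           n_per_size: int = 60,
                           text: str | None = None) -> FragmentLibrary:
    """Torsion fragment libraries of sizes 9 and 3.

    ``ideal``: enumerated helical/extended/turn templates; ``ramachandran``:
    basin-sampled torsions (requires ``rng``); ``file``: parse a user-supplied
    fragment table passed as ``text``.
    """
    if source == "ideal":
        return FragmentLibrary({s: _ideal_fragments(s) for s in FRAGMENT_SIZES})
    if source == "ramachandran":
        if rng is None:
            raise ValueError("ramachandran source requires an rng")
        return FragmentLibrary({
            s: _ideal_fragments(s) + _ramachandran_fragments(s, rng, n_per_size)
            for s in FRAGMENT_SIZES})
    if source == "file":
        if text is None:
            raise ValueError("file source requires text")
        return parse_fragment_file(text)
    raise ValueError(f"unknown fragment source {source!r}")


# ---------------------------------------------------------------------------
# Insertion and closure
# ---------------------------------------------------------------------------

def insert_fragment(s: Structure, window: RebuildWindow, frag: Fragment,
                    position: int | None = None) -> Structure:
    """Replace torsions of ``len(frag)`` residues starting at ``position``.

    The whole window up to its chain break is re-derived from internal
    coordinates (with the fragment's torsions substituted at ``position``),
    which also heals any non-ideal junction geometry inside the window;
    residues upstream of the window and the fixed side beyond the break are
    untouched.
    """
    k = len(frag)
    brk = window.break_position
    if k > brk - window.first + 1:
        raise ValueError(
            f"fragment of size {k} does not fit in window "
            f"[{window.first}, {brk}]")
    if position is None:
        position = window.first
    if position < window.first or position + k - 1 > brk:
        raise ValueError("fragment placement outside window")
    tors = backbone_torsions(s)
    i0, ib = s.row(window.first), s.row(brk)
    seg = tors[i0:ib + 1].copy()
    # fall back to helical values where torsions are undefined (chain ends)
    seg[np.isnan(seg[:, 0]), 0] = -57.8
    seg[np.isnan(seg[:, 1]), 1] = -47.0
    seg[np.isnan(seg[:, 2]), 2] = 180.0
    off = position - window.first
    seg[off:off + k] = frag.as_array()
    return rebuild_forward(s, window.first, brk, seg)


def ccd_close(s: Structure, window: RebuildWindow, max_cycles: int = 60,
              tolerance: float = 0.05) -> tuple[Structure, float]:
    """Close the window's chain break by CCD over its phi/psi torsions."""
    res = ccd_close_window(s, window.first, window.break_position,
                           max_cycles=max_cycles, tolerance=tolerance)
    return res.structure, res.gap


def _local_clash(s: Structure, window: RebuildWindow, pad: int = 6) -> float:
    """Soft-sphere CA clash of window residues against their neighborhood."""
    lo = window.first - pad
    hi = window.last + pad
    rows = s.rows_in(lo, hi)
    win_rows = s.rows_in(window.first, window.last)
    if len(win_rows) == 0:
        return 0.0
    d = cdist(s.coords[win_rows, CA, :], s.coords[rows, CA, :])
    sep = np.abs(s.index[win_rows][:, None] - s.index[rows][None, :])
    viol = (4.0 - d)
    mask = (sep >= 3) & (viol > 0)
    return float(np.sum(viol[mask] ** 2) / 2.0)


def rebuild_region(s: Structure, window: RebuildWindow, lib: FragmentLibrary,
                   rng: np.random.Generator,
                   energy=None, constraints=None,
                   break_threshold: float = BREAK_THRESHOLD,
                   steps_per_round: int = REBUILD_STEPS,
                   max_expansions: int = 5, kT: float = 1.0,
                   penalty_start: float = 1.0,
                   penalty_factor: float = 2.0,
                   ccd_cycles: int = 60,
                   bounds: tuple[int, int] | None = None) -> Structure:
    """Fragment-insertion + CCD rebuilding with penalty ramping.

    Scores candidates with ``energy(structure)`` if given (else a local
    soft-sphere clash term, plus the flat-bottom constraint energy when
    ``constraints`` is provided) plus ``penalty * gap**2``; the chain-break
    penalty doubles every step.  After ``steps_per_round`` insertions with a
    residual break above ``break_threshold`` the window grows by one residue
    on both sides.  Returns the lowest-score closed structure.
    """
    from .alignment import constraint_energy

    def base_score(st: Structure, w: RebuildWindow) -> float:
        if energy is not None:
            return float(energy(st))
        sc = _local_clash(st, w)
        if constraints is not None:
            sc += constraint_energy(st, constraints)
        return sc

    w = replace(window)
    best_any, best_any_gap = None, np.inf
    for expansion in range(max_expansions + 1):
        current = s
        cur_gap = np.inf
        cur_score = np.inf
        best_closed, best_closed_score = None, np.inf
        penalty = penalty_start
        for step in range(steps_per_round):
            w.attempts += 1
            try:
                if rng.random() < 0.35:
                    # full-window multi-fragment insertion: a decorrelated
                    # restart covering every window position
                    cand = current
                    pos = w.first
                    while w.break_position - pos + 1 >= 3:
                        size = 9 if w.break_position - pos + 1 >= 9 else 3
                        cand = insert_fragment(cand, w, lib.pick(size, rng),
                                               pos)
                        pos += size
                else:
                    size = 9 if (9 <= w.break_position - w.first + 1) else 3
                    if rng.random() < 0.3:
                        size = 3
                    frag = lib.pick(size, rng)
                    max_start = w.break_position - size + 1
                    position = int(rng.integers(w.first, max_start + 1))
                    cand = insert_fragment(current, w, frag, position)
            except ValueError:
                continue
            cand, gap = ccd_close(cand, w, max_cycles=ccd_cycles)
            score = base_score(cand, w) + penalty * gap * gap
            if metropolis_accept(score - cur_score, kT, rng):
                current, cur_score, cur_gap = cand, score, gap
            if gap <= break_threshold:
                closed_score = base_score(cand, w)
                if closed_score < best_closed_score:
                    best_closed, best_closed_score = cand, closed_score
            if gap < best_any_gap:
                best_any, best_any_gap = cand, gap
            penalty *= penalty_factor
        if best_closed is not None:
            return best_closed
        # expand the rebuild window by one residue on both sides
        grown = w.expanded()
        i_first = s.row(w.first)
        if i_first <= 1 or not s.has_residue(grown.last + 1):
            break
        if bounds is not None and (grown.first < bounds[0]
                                   or grown.last > bounds[1]):
            break
        w = grown
    raise LoopClosureError(
        f"window [{window.first}, {window.last}] not closed within "
        f"{max_expansions} expansions (best gap {best_any_gap:.3f} A)",
        best_structure=best_any, best_gap=best_any_gap)


def remodel_bend(s: Structure, spec, lib: FragmentLibrary,
                 rng: np.random.Generator, window_size: int | None = None,
                 **kwargs) -> Structure:
    """Rebuild the bend of a kinked helix.

    By default the bend is re-modeled as the annotated (typically 4-residue)
    loop insertion; passing ``window_size`` in [5, 8] enlarges the rebuilt
    window symmetrically around the bend for distorted cases.
    """
    lo, hi = spec.bend_range
    if window_size is not None:
        if not (5 <= window_size <= 8):
            raise ValueError("window_size must be in [5, 8]")
        extra = window_size - (hi - lo + 1)
        left = extra // 2 + extra % 2
        right = extra // 2
        lo, hi = lo - left, hi + right
    window = RebuildWindow(lo, hi)
    return rebuild_region(s, window, lib, rng, **kwargs)
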