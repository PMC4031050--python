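"""Synthetic kinked-bundle fixtures: target structures, perturbed templates,
alignments and annotations with controlled kink geometry and sequence
divergence.

Bundles place idealized TMHs on a circle (~10 A inter-axis spacing,
antiparallel alternation) in a membrane frame whose normal is z, connect them
with de-novo-closed loops, and optionally kink individual helices by a given
angle at a proline-marked bend.  Templates are derived from targets by
straightening kinks, deleting loop residues (alignment gaps), adding
coordinate noise, and mutating the sequence down to a requested identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import (N, CA, C, O, CB, Structure, SegmentAnnotation,
                        ideal_cb)
from .geometry import (ideal_helix, KinkSpec, apply_rigid_transform,
                       measure_kink)
from .internal import (rotation_about_axis, rebuild_forward, place_atom,
                       backbone_torsions, BOND_C_N, ANG_CA_C_N)
from .alignment import PairAlignment, make_alignment, residues_similar
from .loops import (FragmentLibrary, build_fragment_library, RebuildWindow,
                    rebuild_region, LoopClosureError)

RISE = 1.5           # A per residue, ideal helix
SPACING = 10.0       # A between adjacent helix axes
BEND_LENGTH = 4      # residues in a kink bend window

HYDROPHOBIC = "AILVFMWGS"
POLAR = "GSTNQDEKR"


@dataclass(frozen=True)
class Kink:
    helix_id: int        # 1-based
    bend_position: int   # 1-based offset of the first bend residue in the helix
    kink_angle: float    # degrees
    swing: float = 0.0   # degrees, azimuth of the kink rotation axis


@dataclass
class BundleSpec:
    n_helices: int = 3
    helix_length: int = 18
    kinks: tuple[Kink, ...] = ()
    loop_lengths: int = 8
    seq_identity_target: float = 1.0
    perturbation: float = 0.0      # A, per-atom template noise
    seed: int = 0
    # template derivation controls
    straighten: tuple[int, ...] = ()       # helix ids whose kink to remove
    loop_delete: int = 0                   # residues removed per loop
    remove_proline: bool = True            # mutate bend proline when straightening

    def __post_init__(self):
        if self.n_helices < 1:
            raise ValueError("n_helices must be >= 1")
        if self.helix_length < 10:
            raise ValueError("helix_length must be >= 10")
        self.kinks = tuple(Kink(*k) if not isinstance(k, Kink) else k
                           for k in self.kinks)
        for k in self.kinks:
            if not (0.0 <= k.kink_angle <= 90.0):
                raise ValueError("kink_angle must be in [0, 90]")
            if not (1 <= k.helix_id <= self.n_helices):
                raise ValueError("kink helix_id out of range")
            if k.bend_position < 5 or \
                    k.bend_position + BEND_LENGTH + 3 > self.helix_length:
                raise ValueError(
                    "bend_position leaves < 4 residues in a helix fragment")
        if not (0.0 < self.seq_identity_target <= 1.0):
            raise ValueError("seq_identity_target must be in (0, 1]")


@dataclass
class BundleLayout:
    helices: list[tuple[int, int]]
    loops: list[tuple[int, int]]
    kink_specs: dict[int, KinkSpec]  # helix_id -> ranges (angles unset)
    n_residues: int


def _construction_library(seed: int) -> FragmentLibrary:
    """Ramachandran-augmented fragment library for fixture construction.

    The enumerated ideal fragments alone are too sparse to close tight bend
    windows reliably; basin-sampled torsions (deterministically seeded from
    the bundle seed) give the insertion restarts enough diversity.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 4242)))
    return build_fragment_library("ramachandran", rng, n_per_size=120)


def bundle_layout(spec: BundleSpec) -> BundleLayout:
    helices, loops = [], []
    pos = 1
    for h in range(spec.n_helices):
        helices.append((pos, pos + spec.helix_length - 1))
        pos += spec.helix_length
        if h < spec.n_helices - 1:
            loops.append((pos, pos + spec.loop_lengths - 1))
            pos += spec.loop_lengths
    kink_specs = {}
    for k in spec.kinks:
        h0, _ = helices[k.helix_id - 1]
        bend_first = h0 + k.bend_position - 1
        bend = (bend_first, bend_first + BEND_LENGTH - 1)
        m = (h0, bend_first - 1)
        f = (bend[1] + 1, helices[k.helix_id - 1][1])
        kink_specs[k.helix_id] = KinkSpec(
            f_range=f, m_range=m, bend_range=bend, ref_residue=f[0])
    return BundleLayout(helices, loops, kink_specs, pos - 1)


def _bundle_sequence(spec: BundleSpec, layout: BundleLayout,
                     rng: np.random.Generator) -> list[str]:
    seq = []
    loop_set = set()
    for lo, hi in layout.loops:
        loop_set.update(range(lo, hi + 1))
    refs = {ks.ref_residue for ks in layout.kink_specs.values()}
    for r in range(1, layout.n_residues + 1):
        if r in refs:
            seq.append("P")
        elif r in loop_set:
            seq.append(POLAR[rng.integers(len(POLAR))])
        else:
            aa = HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))]
            seq.append(aa if aa != "P" else "A")
    return seq


def _helix_placement(spec: BundleSpec, h: int):
    """(base point, direction) of helix h (0-based) in the membrane frame."""
    if spec.n_helices == 1:
        center = np.zeros(2)
    else:
        radius = SPACING / (2.0 * np.sin(np.pi / spec.n_helices)) \
            if spec.n_helices > 2 else SPACING / 2.0
        ang = 2.0 * np.pi * h / spec.n_helices
        center = radius * np.array([np.cos(ang), np.sin(ang)])
    up = h % 2 == 0
    half = (spec.helix_length - 1) * RISE / 2.0
    z0 = -half if up else half
    direction = np.array([0.0, 0.0, 1.0 if up else -1.0])
    return np.array([center[0], center[1], z0]), direction


def make_kinked_bundle(spec: BundleSpec,
                       lib: FragmentLibrary | None = None,
                       max_retries: int = 5):
    """Build the target bundle; returns ``(structure, annotations)``.

    Kinks are applied by rotating everything C-terminal of the bend by the
    requested angle about an axis at the requested azimuth, then re-closing
    the bend de novo; loops are built de novo between consecutive helices.
    Same seed, same output.
    """
    layout = bundle_layout(spec)
    lib = lib or _construction_library(spec.seed)
    last_err: Exception | None = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence(
            (spec.seed, attempt)))
        try:
            s = _build_bundle_once(spec, layout, rng, lib)
        except LoopClosureError as exc:
            last_err = exc
            continue
        annotations = [SegmentAnnotation(f"H{h + 1}", lo, hi, "TMH")
                       for h, (lo, hi) in enumerate(layout.helices)]
        annotations += [SegmentAnnotation(f"L{i + 1}", lo, hi, "loop")
                        for i, (lo, hi) in enumerate(layout.loops)]
        for seg in annotations:
            for r in range(seg.first, seg.last + 1):
                s.segment_labels[r] = seg.segment_id
        s.validate(allow_breaks=False)
        return s, annotations
    raise LoopClosureError(
        f"bundle construction failed after {max_retries} retries: {last_err}")


def _kink_axis(spec: BundleSpec, layout: BundleLayout, hid: int,
               swing: float) -> np.ndarray:
    """Rotation axis tipping the m fragment away from the proline ring.

    Reconstructs the straight ideal helix at its bundle placement (helix
    geometry is deterministic), builds the proline-CB kink frame (z = f axis
    toward the bend, -x toward the ref-residue CB), and returns the axis
    y' = z cross x rotated about z by ``swing``.  Rotating the m away-axis
    about y' by a positive angle moves it into the +x/+z quadrants -- the
    region native kinks occupy and the rigid-body sampler searches.
    """
    base, direction = _helix_placement(spec, hid - 1)
    hlo, hhi = layout.helices[hid - 1]
    ks = layout.kink_specs[hid]
    helix = ideal_helix(hhi - hlo + 1, start=base, direction=direction,
                        start_resnum=hlo)
    z = -direction if ks.m_before_f else direction
    cb = helix.coords[helix.row(ks.ref_residue), CB]
    m_bend_ca = helix.coords[helix.row(ks.m_bend_end), CA]
    minus_x = cb - m_bend_ca
    minus_x = minus_x - np.dot(minus_x, z) * z
    minus_x /= np.linalg.norm(minus_x)
    x = -minus_x
    y = np.cross(z, x)
    return rotation_about_axis(z, np.radians(swing)) @ y


def _apply_kink_rotation(s: Structure, spec: BundleSpec,
                         layout: BundleLayout, hid: int, k: Kink,
                         sign: float) -> None:
    """Rotate the two fragments of helix ``hid`` by +/- kink_angle/2 about
    the bend midpoint, creating (sign=+1) or removing (sign=-1) the kink.

    Splitting the rotation keeps both helix termini close to their straight
    positions so the flanking loops stay closable.
    """
    ks = layout.kink_specs[hid]
    axis = _kink_axis(spec, layout, hid, k.swing)
    half = sign * np.radians(k.kink_angle) / 2.0
    pivot_res = ks.bend_range[0] + 1
    pivot = s.coords[s.row(pivot_res), CA].copy()
    hlo, hhi = layout.helices[hid - 1]
    m_side = (hlo, pivot_res - 1) if ks.m_before_f else (pivot_res + 1, hhi)
    f_side = (pivot_res + 1, hhi) if ks.m_before_f else (hlo, pivot_res - 1)
    for res_range, theta in ((m_side, +half), (f_side, -half)):
        R = rotation_about_axis(axis, theta)
        rows = s.rows_in(*res_range)
        blk = s.coords[rows].reshape(-1, 3)
        s.coords[rows] = ((blk - pivot) @ R.T + pivot).reshape(-1, 5, 3)


def _build_bundle_once(spec: BundleSpec, layout: BundleLayout,
                       rng: np.random.Generator,
                       lib: FragmentLibrary) -> Structure:
    seq = _bundle_sequence(spec, layout, rng)
    nres = layout.n_residues
    coords = np.full((nres, 5, 3), np.nan)
    s = Structure(np.arange(1, nres + 1), seq, coords,
                  cb_virtual=np.ones(nres, dtype=bool))

    for h, (lo, hi) in enumerate(layout.helices):
        base, direction = _helix_placement(spec, h)
        helix = ideal_helix(hi - lo + 1, start=base, direction=direction,
                            sequence="".join(seq[lo - 1:hi]), start_resnum=lo)
        s.coords[lo - 1:hi] = helix.coords

    # apply kink rotations
    kink_by_helix = {k.helix_id: k for k in spec.kinks}
    for hid, k in kink_by_helix.items():
        if k.kink_angle == 0.0:
            continue
        _apply_kink_rotation(s, spec, layout, hid, k, +1.0)

    # build initial loop coordinates forward from each preceding helix
    for (lo, hi) in layout.loops:
        i_prev = s.row(lo - 1)
        X = s.coords
        X[i_prev + 1, N] = place_atom(X[i_prev, N], X[i_prev, CA],
                                      X[i_prev, C], BOND_C_N, ANG_CA_C_N,
                                      -47.0)
        tors = np.tile([-120.0, 130.0, 180.0], (hi - lo + 1, 1))
        s = rebuild_forward(s, lo, hi, tors)

    # close loops and bends de novo; loop expansions may not eat into the
    # helices, bends may grow one residue into their flanks if needed
    for (lo, hi) in layout.loops:
        s = rebuild_region(s, RebuildWindow(lo, hi), lib, rng,
                           max_expansions=2, bounds=(lo, hi),
                           ccd_cycles=250)
    # bend-only windows with extra insertion restarts keep the helical
    # fragments bit-exact so constructed kink angles are exact
    for hid in kink_by_helix:
        ks = layout.kink_specs[hid]
        s = rebuild_region(s, RebuildWindow(*ks.bend_range), lib, rng,
                           steps_per_round=60, max_expansions=0,
                           bounds=ks.bend_range, ccd_cycles=400)
    return s


# ---------------------------------------------------------------------------
# Template derivation
# ---------------------------------------------------------------------------

@dataclass
class TemplateFixture:
    structure: Structure
    alignment: PairAlignment
    proline_profile: dict[int, float]
    annotations: list[SegmentAnnotation]
    deleted_target_residues: list[int] = field(default_factory=list)


def _perturb(s: Structure, magnitude: float,
             rng: np.random.Generator) -> Structure:
    """Chain-smoothed Gaussian displacement of rms ``magnitude`` per atom.

    The displacement field is correlated along the chain (moving average over
    +/- 2 residues) so covalent geometry stays valid, emulating low-frequency
    structural divergence rather than thermal jitter; CB is re-derived from
    the perturbed backbone.
    """
    out = s.copy()
    n = len(out)
    field_ = rng.normal(0.0, 1.0, (n, 3))
    kernel = np.ones(5) / 5.0
    sm = np.column_stack([
        np.convolve(field_[:, k], kernel, mode="same") for k in range(3)])
    rms = np.sqrt(np.mean(np.sum(sm ** 2, axis=1)))
    sm *= magnitude / max(rms, 1e-12)
    out.coords = out.coords + sm[:, None, :]
    for i in range(n):
        out.coords[i, CB] = ideal_cb(out.coords[i, N], out.coords[i, CA],
                                     out.coords[i, C])
        out.cb_virtual[i] = True
    return out


_MUTATION_POOL = "GAHCW"  # fallback residues outside most similarity classes


def _mutate_away(aa: str, rng: np.random.Generator) -> str:
    for _ in range(20):
        cand = _MUTATION_POOL[rng.integers(len(_MUTATION_POOL))]
        if cand != aa and not residues_similar(cand, aa):
            return cand
    return "G" if aa != "G" else "A"


def make_template_from_target(target: Structure, spec: BundleSpec,
                              lib: FragmentLibrary | None = None,
                              max_retries: int = 3) -> TemplateFixture:
    """Derive a homolog-like template plus a consistent alignment/profile.

    Applies, in order: kink straightening (with optional proline loss),
    chain-smoothed Gaussian coordinate noise, loop deletions (producing
    alignment gaps), and sequence mutations realizing
    ``seq_identity_target`` while sparing constraint-eligible conserved pairs
    when possible.
    """
    lib = lib or _construction_library(spec.seed)
    last_err: Exception | None = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence(
            (spec.seed, 9091, attempt)))
        try:
            return _make_template_once(target, spec, lib, rng)
        except LoopClosureError as exc:
            last_err = exc
    raise LoopClosureError(
        f"template derivation failed after {max_retries} retries: {last_err}")


def _make_template_once(target: Structure, spec: BundleSpec,
                        lib: FragmentLibrary,
                        rng: np.random.Generator) -> TemplateFixture:
    layout = bundle_layout(spec)
    tpl = target.copy()

    kink_by_helix = {k.helix_id: k for k in spec.kinks}
    for hid in spec.straighten:
        k = kink_by_helix.get(hid)
        if k is None or k.kink_angle == 0.0:
            continue
        ks = layout.kink_specs[hid]
        # swing the m side onto the f axis: the fixed fragment keeps its
        # target pose, so the template differs from the target only by the
        # kink (plus noise), as in a homolog with a different kink pattern
        axis = _kink_axis(spec, layout, hid, k.swing)
        pivot_res = ks.bend_range[0] + 1
        pivot = tpl.coords[tpl.row(pivot_res), CA].copy()
        hlo, hhi = layout.helices[hid - 1]
        m_side = (hlo, pivot_res - 1) if ks.m_before_f \
            else (pivot_res + 1, hhi)
        R = rotation_about_axis(axis, -np.radians(k.kink_angle))
        rows = tpl.rows_in(*m_side)
        blk = tpl.coords[rows].reshape(-1, 3)
        tpl.coords[rows] = ((blk - pivot) @ R.T + pivot).reshape(-1, 5, 3)
        tpl = rebuild_region(tpl, RebuildWindow(*ks.bend_range), lib, rng,
                             steps_per_round=60, max_expansions=0,
                             bounds=ks.bend_range, ccd_cycles=400)
        if spec.remove_proline:
            tpl.aa[tpl.row(ks.ref_residue)] = "L"
        # straightening displaces the helix termini; re-close flanking loops
        hlo, hhi = layout.helices[hid - 1]
        for (lo, hi) in layout.loops:
            if hi == hlo - 1 or lo == hhi + 1:
                tpl = rebuild_region(tpl, RebuildWindow(lo, hi), lib, rng,
                                     max_expansions=2, bounds=(lo, hi),
                                     ccd_cycles=250)

    if spec.perturbation > 0.0:
        tpl = _perturb(tpl, spec.perturbation, rng)

    # loop deletions -> alignment gaps; capped so the shortened loop can
    # still span its (possibly straightening-displaced) anchors
    deleted: list[int] = []
    if spec.loop_delete > 0:
        for (lo, hi) in layout.loops:
            n_loop = hi - lo + 1
            k = min(spec.loop_delete, n_loop - 2)
            span = float(np.linalg.norm(tpl.coords[tpl.row(hi + 1), CA]
                                        - tpl.coords[tpl.row(lo - 1), CA]))
            while k > 0 and (n_loop - k) * 2.8 < span + 5.0:
                k -= 1
            if k == 0:
                continue
            mid = (lo + hi) // 2 - k // 2
            deleted.extend(range(mid, mid + k))
    keep = [r for r in target.index if r not in set(deleted)]
    rows = [tpl.row(r) for r in keep]
    tpl = Structure(np.arange(1, len(keep) + 1),
                    [tpl.aa[i] for i in rows], tpl.coords[rows].copy(),
                    tpl.chain_id, {}, tpl.cb_virtual[rows].copy())
    new_num = {r: i + 1 for i, r in enumerate(keep)}
    # re-close shortened loops: the template homolog has a continuous chain
    if deleted:
        for (lo, hi) in layout.loops:
            remaining = [new_num[r] for r in range(lo, hi + 1)
                         if r in new_num]
            if len(remaining) == hi - lo + 1 or not remaining:
                continue
            w = RebuildWindow(min(remaining), max(remaining))
            tpl = rebuild_region(tpl, w, lib, rng, max_expansions=0,
                                 steps_per_round=30,
                                 bounds=(w.first, w.last), ccd_cycles=250)

    # sequence mutation to the requested identity over mutual columns
    tgt_seq = list(target.sequence)
    tpl_cols = {r: tpl.aa[new_num[r] - 1] for r in keep}
    n_cols = len(keep)
    want_match = int(round(spec.seq_identity_target * n_cols))
    matches = sum(tpl_cols[r] == tgt_seq[r - 1] for r in keep)
    loop_set = set()
    for lo, hi in layout.loops:
        loop_set.update(range(lo, hi + 1))
    order = [r for r in keep if r in loop_set] + \
            [r for r in keep if r not in loop_set]
    order = [r for r in order if tpl_cols[r] == tgt_seq[r - 1]]
    perm = list(rng.permutation(len(order)))
    loop_count = sum(1 for r in order if r in loop_set)
    # shuffle within the loop-first / TMH-second blocks
    loops_first = [order[i] for i in sorted(range(len(order)),
                                            key=lambda i: (order[i] not in loop_set,
                                                           perm[i]))]
    for r in loops_first:
        if matches <= want_match:
            break
        new_aa = _mutate_away(tgt_seq[r - 1], rng)
        tpl.aa[new_num[r] - 1] = new_aa
        tpl_cols[r] = new_aa
        matches -= 1

    # alignment strings over target numbering (target has no gaps)
    target_row = target.sequence
    template_row = "".join(
        tpl_cols[r] if r in new_num else "-" for r in target.index)
    tmh_cols = []
    for lo, hi in layout.helices:
        tmh_cols.extend(range(lo - 1, hi))
    alignment = make_alignment(target_row, template_row,
                               modeled_columns=tmh_cols)

    profile = {i: (1.0 if a == "P" else 0.0)
               for i, a in enumerate(target_row)}

    annotations = []
    for h, (lo, hi) in enumerate(layout.helices):
        kept = [new_num[r] for r in range(lo, hi + 1) if r in new_num]
        annotations.append(SegmentAnnotation(f"H{h + 1}", min(kept),
                                             max(kept), "TMH"))
    tpl.validate()
    return TemplateFixture(tpl, alignment, profile, annotations, deleted)


# ---------------------------------------------------------------------------
# Stand-alone loop-closure problems
# ---------------------------------------------------------------------------

def make_loop_problem(rng: np.random.Generator, length: int,
                      flank: int = 10):
    """A guaranteed-feasible loop-closure problem.

    Builds a continuous chain helix-loop-helix with random loop torsions
    (so the anchors are reachable by construction), then scrambles the loop
    window's torsions to create the chain break to be closed.  Returns
    ``(broken structure, window, reference structure)``.
    """
    if length < 3:
        raise ValueError("loop length must be >= 3")
    n = flank + length + flank
    s = ideal_helix(flank, direction=(0, 0, 1))
    # grow loop + second helix as one continuous extension
    coords = np.full((n, 5, 3), np.nan)
    coords[:flank] = s.coords
    full = Structure(np.arange(1, n + 1), "A" * n, coords,
                     cb_virtual=np.ones(n, dtype=bool))
    X = full.coords
    X[flank, N] = place_atom(X[flank - 1, N], X[flank - 1, CA],
                             X[flank - 1, C], BOND_C_N, ANG_CA_C_N, -47.0)
    basins = [(-63.0, -43.0), (-120.0, 135.0), (60.0, 45.0)]
    tors = []
    for i in range(length):
        b = basins[rng.choice(3, p=[0.4, 0.4, 0.2])]
        tors.append((b[0] + rng.normal(0, 15), b[1] + rng.normal(0, 15),
                     180.0))
    tors += [(-57.8, -47.0, 180.0)] * flank
    full = rebuild_forward(full, flank + 1, n, np.array(tors))
    reference = full.copy()
    # scramble the loop window
    lo, hi = flank + 1, flank + length
    scram = np.column_stack([
        rng.uniform(-180.0, 180.0, length),
        rng.uniform(-180.0, 180.0, length),
        np.full(length, 180.0)])
    broken = rebuild_forward(full, lo, hi, scram)
    return broken, RebuildWindow(lo, hi), reference
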