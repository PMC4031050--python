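"""End-to-end rebuild-and-refine pipeline.

From a template structure, a target-template alignment and TMH annotations:
gate which TMHs need rebuilding, thread the target onto the template, sample
alternative kinked-helix conformations by constrained Monte Carlo, rebuild
bends and unaligned loops de novo, refine, and select final models by energy
and clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import N, CA, C, O, CB, Structure, SegmentAnnotation, ideal_cb
from .geometry import KinkSpec
from .alignment import (PairAlignment, gate_tmh, derive_constraints,
                        ConstraintSet, RebuildDecision)
from .sampler import MoveSet, EnergyWeights, CoarseEnergy, mc_run, _moving_range
from .loops import (FragmentLibrary, build_fragment_library, RebuildWindow,
                    rebuild_region, LoopClosureError)
from .refine import (RefineSchedule, refine, Model, ModelEnsemble,
                     rank_and_truncate, cluster_tm, select_final)
from .internal import place_atom, rebuild_forward, BOND_C_N, ANG_CA_C_N

BEND_LENGTH = 4


@dataclass
class PipelineConfig:
    """Tunable knobs of the modeling pipeline (desk-scale defaults)."""

    n_models: int = 200
    moves: MoveSet = field(default_factory=MoveSet)
    weights: EnergyWeights = field(default_factory=EnergyWeights)
    refine: RefineSchedule = field(default_factory=lambda: RefineSchedule(
        n_cycles=6, perturbation_magnitude=2.0))
    cluster_radius: float = 2.0
    constraint_cutoff: float = 8.0
    length_margin: int = 4
    fragment_source: str = "ideal"
    loop_steps: int = 12
    loop_max_expansions: int = 3
    do_refine: bool = True


def infer_kink(tmh: SegmentAnnotation, sequence_of) -> KinkSpec | None:
    """Kinked-helix decomposition of a TMH from its bend-inducing proline.

    The bend window is the 4 residues N-terminal to the proline; returns None
    when the TMH has no proline far enough from its ends to leave two >= 4
    residue helical fragments.
    """
    for r in range(tmh.first + BEND_LENGTH + 3, tmh.last - 2):
        if sequence_of(r) == "P":
            bend = (r - BEND_LENGTH, r - 1)
            m = (tmh.first, bend[0] - 1)
            f = (r, tmh.last)
            if m[1] - m[0] >= 3 and f[1] - f[0] >= 3:
                return KinkSpec(f_range=f, m_range=m, bend_range=bend,
                                ref_residue=r)
    return None


def thread_template(alignment: PairAlignment, template: Structure,
                    target_length: int | None = None):
    """Build the initial target model by copying aligned template coordinates.

    Returns ``(structure, missing_windows)`` where missing windows are
    contiguous target regions with no template counterpart (alignment gaps)
    whose coordinates are placeholders to be rebuilt de novo.
    """
    tgt_res = sorted(alignment.target_inverse)
    if target_length is not None and len(tgt_res) != target_length:
        raise ValueError("alignment does not cover the full target")
    n = len(tgt_res)
    coords = np.full((n, 5, 3), np.nan)
    aa = []
    missing = []
    inv = alignment.target_inverse
    for i, r in enumerate(tgt_res):
        c = inv[r]
        aa.append(alignment.target_seq[c])
        if c in alignment.template_map:
            p = alignment.template_map[c]
            if template.has_residue(p):
                coords[i] = template.coords[template.row(p)]
    s = Structure(np.array(tgt_res), aa, coords,
                  cb_virtual=np.ones(n, dtype=bool))
    # contiguous unassigned runs
    unassigned = np.any(np.isnan(coords[:, CA, :]), axis=1)
    i = 0
    while i < n:
        if unassigned[i]:
            j = i
            while j + 1 < n and unassigned[j + 1]:
                j += 1
            missing.append((tgt_res[i], tgt_res[j]))
            i = j + 1
        else:
            i += 1
    # placeholder geometry for missing runs: extended continuation
    for lo, hi in missing:
        i0 = s.row(lo)
        if i0 == 0 or not s.has_residue(hi + 1):
            raise ValueError(
                f"missing region [{lo}, {hi}] at a chain terminus")
        X = s.coords
        X[i0, N] = place_atom(X[i0 - 1, N], X[i0 - 1, CA], X[i0 - 1, C],
                              BOND_C_N, ANG_CA_C_N, -47.0)
        tors = np.tile([-120.0, 130.0, 180.0], (hi - lo + 1, 1))
        s = rebuild_forward(s, lo, hi, tors)
    return s, missing


@dataclass
class PipelineResult:
    ensemble: ModelEnsemble
    selected: list[Model]
    decisions: list[RebuildDecision]
    constraints: ConstraintSet
    start: Structure
    kinks: dict[str, KinkSpec]


def rebuild_and_refine(template: Structure, alignment: PairAlignment,
                       target_tmhs: list[SegmentAnnotation],
                       template_tmhs: list[SegmentAnnotation],
                       proline_profile: dict[int, float] | None = None,
                       config: PipelineConfig | None = None,
                       rng: np.random.Generator | None = None,
                       constraints: ConstraintSet | None = None,
                       ) -> PipelineResult:
    """Run the full rebuild-and-refine protocol; returns ranked, clustered,
    selected models.

    ``constraints`` overrides the alignment-derived constraint set (used by
    recovery experiments that constrain toward known target contacts).
    """
    cfg = config or PipelineConfig()
    rng = rng or np.random.default_rng(0)
    lib = build_fragment_library(cfg.fragment_source)

    decisions = gate_tmh(alignment, target_tmhs, template_tmhs,
                         proline_profile, cfg.length_margin)
    start, missing = thread_template(alignment, template)
    seq_of = lambda r: start.aa[start.row(r)]

    tmh_list = [t for t in target_tmhs if t.kind == "TMH"]
    kinks: dict[str, KinkSpec] = {}
    rebuilt_regions: list[tuple[int, int]] = list(missing)
    loop_windows: list[tuple[int, int]] = list(missing)
    first_res, last_res = int(start.index[0]), int(start.index[-1])
    for dec, tmh in zip(decisions, tmh_list):
        if not dec.rebuild:
            continue
        spec = infer_kink(tmh, seq_of)
        if spec is not None:
            kinks[dec.tmh_id] = spec
            rebuilt_regions.append(spec.bend_range)
            # a resampled TMH is stripped from its flanking loops, which are
            # rebuilt de novo after the rigid-body search
            neighbors_lo = [t.last for t in tmh_list if t.last < tmh.first]
            neighbors_hi = [t.first for t in tmh_list if t.first > tmh.last]
            lo = (max(neighbors_lo) + 1) if neighbors_lo else first_res
            hi = (min(neighbors_hi) - 1) if neighbors_hi else last_res
            if lo < tmh.first and tmh.first - 1 - lo >= 2 and lo > first_res:
                loop_windows.append((lo, tmh.first - 1))
            if hi > tmh.last and hi - (tmh.last + 1) >= 2 and hi < last_res:
                loop_windows.append((tmh.last + 1, hi))
    # merge overlapping loop windows
    loop_windows = sorted(set(loop_windows))
    merged: list[tuple[int, int]] = []
    for lo, hi in loop_windows:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    loop_windows = merged
    rebuilt_regions.extend(loop_windows)

    if constraints is None:
        constraints = derive_constraints(
            alignment, template, rebuilt_regions=rebuilt_regions,
            cutoff=cfg.constraint_cutoff)

    tm_regions = [(t.first, t.last) for t in target_tmhs if t.kind == "TMH"]
    rank_energy = CoarseEnergy(constraints, tmh_regions=tm_regions,
                               weights=cfg.weights)

    models = []
    for i in range(cfg.n_models):
        seed_i = int(rng.integers(2 ** 31))
        rng_i = np.random.default_rng(seed_i)
        st = start.copy()
        ok = True
        for tmh_id, spec in kinks.items():
            state = mc_run(st, spec, constraints, cfg.moves, rng_i)
            st = state.best_structure
            try:
                st = rebuild_region(st, RebuildWindow(*spec.bend_range), lib,
                                    rng_i, constraints=constraints,
                                    steps_per_round=cfg.loop_steps,
                                    max_expansions=cfg.loop_max_expansions)
            except LoopClosureError:
                ok = False
                break
        if ok:
            for lo, hi in loop_windows:
                try:
                    st = rebuild_region(st, RebuildWindow(lo, hi), lib, rng_i,
                                        constraints=constraints,
                                        steps_per_round=cfg.loop_steps,
                                        max_expansions=cfg.loop_max_expansions)
                except LoopClosureError:
                    ok = False
                    break
        if not ok:
            continue
        if cfg.do_refine:
            windows = [spec.bend_range for spec in kinks.values()] \
                + loop_windows
            try:
                st, _ = refine(st, constraints, cfg.refine, rng_i,
                               moveable=windows or None,
                               tmh_regions=tm_regions)
            except ValueError:
                continue
        models.append(Model(i, st, float(rank_energy(st)),
                            meta={"seed": seed_i}))

    ensemble = ModelEnsemble(models)
    if not models:
        raise LoopClosureError("no models survived the rebuild protocol")
    truncated = rank_and_truncate(ensemble)
    clustered = cluster_tm(truncated, tm_regions, cfg.cluster_radius)
    selected = select_final(clustered)
    return PipelineResult(clustered, selected, decisions, constraints,
                          start, kinks)
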