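"""Constrained refinement with repulsive ramping, and model selection.

Refinement cycles propose small backbone torsion perturbations inside a short
window, close the window back onto the unmoved downstream chain by CCD (so
perturbations stay local), re-derive CB positions, and accept by Metropolis
on a score whose repulsive (clash) weight ramps up across the schedule.
Model selection follows the comparative-modeling protocol: keep the 1000 or
up-to-10% lowest-energy models, leader-cluster their transmembrane region by
Cα RMSD, and return the lowest-energy member of each of the five largest
families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure import CA, Structure
from .internal import backbone_torsions, rebuild_forward
from .loops import RebuildWindow, ccd_close
from .sampler import metropolis_accept, CoarseEnergy, EnergyWeights
from .alignment import ConstraintSet, constraint_energy
from .metrics import kabsch_rmsd


@dataclass
class RefineSchedule:
    n_cycles: int = 12
    perturbation_magnitude: float = 3.0   # deg, torsion noise sd
    repulsive_ramp: tuple[float, ...] = (0.1, 0.5, 1.0)
    minimizer: bool = True
    constraint_weight: float = 1.0
    kT: float = 1.0
    window_length: int = 5

    def __post_init__(self):
        ramp = tuple(self.repulsive_ramp)
        if not ramp or ramp[-1] != 1.0:
            raise ValueError("repulsive_ramp must end at 1.0")
        if any(b <= a for a, b in zip(ramp, ramp[1:])):
            raise ValueError("repulsive_ramp must be strictly increasing")
        self.repulsive_ramp = ramp
        if self.perturbation_magnitude < 0:
            raise ValueError("perturbation_magnitude must be >= 0")

    def ramp_at(self, cycle: int) -> float:
        i = min(int(cycle * len(self.repulsive_ramp) / max(self.n_cycles, 1)),
                len(self.repulsive_ramp) - 1)
        return self.repulsive_ramp[i]


def refine(s: Structure, constraints: ConstraintSet | None,
           sched: RefineSchedule, rng: np.random.Generator,
           moveable=None, tmh_regions=(),
           log: list | None = None) -> tuple[Structure, float]:
    """Refine a closed-chain structure under constraints.

    ``moveable`` is a list of closed residue intervals allowed to move
    (default: everything except the two chain-end residues).  Returns the
    best structure and its energy at full repulsive weight.
    """
    breaks = s.chain_breaks()
    if breaks:
        raise ValueError(f"refine requires a closed chain; breaks at {breaks}")
    cset = constraints or ConstraintSet()
    if moveable is None:
        moveable = [(int(s.index[1]), int(s.index[-2]))] if len(s) > 3 else []
    windows = []
    for lo, hi in moveable:
        for first in range(lo, hi - sched.window_length + 2):
            last = first + sched.window_length - 1
            if s.row(first) >= 1 and s.has_residue(last + 1):
                windows.append((first, last))
    base = CoarseEnergy(cset, tmh_regions=tmh_regions,
                        weights=EnergyWeights(constraint=sched.constraint_weight,
                                              restraint=0.0))

    def score(st: Structure, rep: float) -> float:
        t = base.terms(st)
        return (rep * t["clash"] + sched.constraint_weight * t["constraint"]
                + base.weights.membrane * t["membrane"])

    current = s.copy()
    best = current.copy()
    best_full = score(current, 1.0)
    cur_score = None
    cur_rep = None
    for cycle in range(sched.n_cycles):
        rep = sched.ramp_at(cycle)
        if rep != cur_rep:
            cur_rep = rep
            cur_score = score(current, rep)
        if not windows or sched.perturbation_magnitude == 0.0:
            if log is not None:
                log.append((cycle, rep, cur_score, False))
            continue
        first, last = windows[rng.integers(len(windows))]
        cand, ok_gap = _window_perturbation(
            current, first, last, sched.perturbation_magnitude, rng)
        if not ok_gap and sched.minimizer:
            # step-halving retry with a gentler perturbation
            cand, ok_gap = _window_perturbation(
                current, first, last, sched.perturbation_magnitude / 2.0, rng)
        accepted = False
        if ok_gap:
            e_new = score(cand, rep)
            if metropolis_accept(e_new - cur_score, sched.kT, rng):
                current, cur_score = cand, e_new
                accepted = True
                full = score(current, 1.0)
                if full < best_full:
                    best, best_full = current.copy(), full
        if log is not None:
            log.append((cycle, rep, cur_score, accepted))
    return best, best_full


def _window_perturbation(s: Structure, first: int, last: int,
                         magnitude: float, rng: np.random.Generator):
    """Perturb phi/psi in [first, last], CCD-close back onto the chain."""
    tors = backbone_torsions(s)
    i0, i1 = s.row(first), s.row(last)
    seg = tors[i0:i1 + 1].copy()
    seg[np.isnan(seg)] = 180.0
    seg[:, :2] += rng.normal(0.0, magnitude, size=(len(seg), 2))
    cand = rebuild_forward(s, first, last, seg)
    w = RebuildWindow(first, last)
    cand, gap = ccd_close(cand, w, max_cycles=30, tolerance=0.03)
    return cand, gap <= 0.2


# ---------------------------------------------------------------------------
# Ensembles, ranking, clustering, selection
# ---------------------------------------------------------------------------

@dataclass
class Model:
    model_id: int
    structure: Structure
    energy: float
    meta: dict = field(default_factory=dict)


@dataclass
class ModelEnsemble:
    models: list[Model] = field(default_factory=list)
    cluster_labels: dict[int, int] = field(default_factory=dict)
    selected_ids: list[int] = field(default_factory=list)

    def __len__(self):
        return len(self.models)

    def by_id(self, model_id: int) -> Model:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)

    def manifest_tsv(self) -> str:
        lines = ["model_id\tenergy\tcluster\tselected"]
        for m in self.models:
            cl = self.cluster_labels.get(m.model_id, -1)
            sel = int(m.model_id in self.selected_ids)
            lines.append(f"{m.model_id}\t{m.energy:.4f}\t{cl}\t{sel}")
        return "\n".join(lines) + "\n"


def rank_and_truncate(e: ModelEnsemble) -> ModelEnsemble:
    """Keep the min(1000, ceil(10% of N)) lowest-energy models."""
    if len(e) == 0:
        raise ValueError("empty ensemble")
    keep = min(1000, math.ceil(0.10 * len(e)))
    ranked = sorted(e.models, key=lambda m: (m.energy, m.model_id))
    return ModelEnsemble(ranked[:keep])


def cluster_tm(e: ModelEnsemble, tm_region, radius: float = 2.0) -> ModelEnsemble:
    """Greedy leader clustering on TM-region Cα RMSD.

    Models are processed in ascending energy (ties by id); each joins the
    first cluster whose leader is within ``radius``, else founds a new one.
    ``tm_region`` is a list of closed residue intervals.
    """
    order = sorted(e.models, key=lambda m: (m.energy, m.model_id))
    resnums = []
    for lo, hi in tm_region:
        resnums.extend(range(lo, hi + 1))
    leaders: list[tuple[int, np.ndarray]] = []
    labels: dict[int, int] = {}
    for m in order:
        coords = m.structure.ca(resnums)
        assigned = None
        for ci, (lid, ref) in enumerate(leaders):
            rmsd, _, _ = kabsch_rmsd(ref, coords)
            if rmsd <= radius:
                assigned = ci
                break
        if assigned is None:
            leaders.append((m.model_id, coords))
            assigned = len(leaders) - 1
        labels[m.model_id] = assigned
    return ModelEnsemble(list(e.models), labels, list(e.selected_ids))


def select_final(e: ModelEnsemble, max_models: int = 5) -> list[Model]:
    """Lowest-energy member of each of the five largest cluster families.

    Cluster ties are broken by the lower best (minimum) energy, then by
    leader id; returns fewer models when fewer clusters exist.
    """
    if len(e) == 0:
        raise ValueError("empty ensemble")
    if not e.cluster_labels:
        raise ValueError("ensemble not clustered")
    clusters: dict[int, list[Model]] = {}
    for m in e.models:
        clusters.setdefault(e.cluster_labels[m.model_id], []).append(m)
    def cluster_key(item):
        label, members = item
        best_e = min(m.energy for m in members)
        return (-len(members), best_e, label)
    ordered = sorted(clusters.items(), key=cluster_key)
    out = []
    for label, members in ordered[:max_models]:
        best = min(members, key=lambda m: (m.energy, m.model_id))
        out.append(best)
    e.selected_ids = [m.model_id for m in out]
    return out
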