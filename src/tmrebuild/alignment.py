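"""Target-template alignment parsing, per-TMH rebuild gating, and harmonic
Cα-Cα constraint derivation.

A TMH is rebuilt when the alignment gives reason to distrust the template in
that region: gaps inside the helix, mismatched bend-inducing positions
(prolines in the target or frequent in homologs), or annotated helix lengths
differing by more than about one helical turn.  Constraints tie conserved,
spatially close residue pairs to their template distances with a flat-bottom
harmonic; the number retained scales with target-template sequence identity
so distant templates do not over-constrain the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO

import numpy as np

from .structure import Structure, SegmentAnnotation

# residue classes treated as "strictly conserved or similar"
SIMILARITY_CLASSES = ("ILVMF", "KR", "DE", "ST", "NQ", "FYW")
_CLASS_OF = {}
for _cls in SIMILARITY_CLASSES:
    for _a in _cls:
        _CLASS_OF.setdefault(_a, set()).add(_cls)

PROLINE_PROFILE_THRESHOLD = 0.10  # homolog proline fraction marking a bend


def residues_similar(a: str, b: str) -> bool:
    if a == b:
        return True
    return bool(_CLASS_OF.get(a, set()) & _CLASS_OF.get(b, set()))


class AlignmentError(ValueError):
    pass


@dataclass
class PairAlignment:
    """Gapped pairwise target/template alignment with residue maps."""

    target_seq: str
    template_seq: str
    target_map: dict[int, int]      # column -> target residue number
    template_map: dict[int, int]    # column -> template residue number
    identity_full: float = 0.0
    identity_modeled: float = 0.0

    def __post_init__(self):
        if len(self.target_seq) != len(self.template_seq):
            raise AlignmentError("gapped sequences differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.target_seq)

    @property
    def target_inverse(self) -> dict[int, int]:
        return {r: c for c, r in self.target_map.items()}

    @property
    def template_inverse(self) -> dict[int, int]:
        return {r: c for c, r in self.template_map.items()}

    def mutual_columns(self) -> list[int]:
        return [c for c in range(self.n_columns)
                if c in self.target_map and c in self.template_map]

    def to_fasta(self, target_name="target", template_name="template") -> str:
        return (f">{target_name}\n{self.target_seq}\n"
                f">{template_name}\n{self.template_seq}\n")


def _build_map(seq: str, start: int) -> dict[int, int]:
    out = {}
    r = start
    for c, a in enumerate(seq):
        if a != "-":
            out[c] = r
            r += 1
    return out


def _identity(a: PairAlignment, columns) -> float:
    cols = [c for c in columns
            if c in a.target_map and c in a.template_map]
    if not cols:
        return 0.0
    match = sum(a.target_seq[c] == a.template_seq[c] for c in cols)
    return match / len(cols)


def make_alignment(target_seq: str, template_seq: str,
                   target_start: int = 1, template_start: int = 1,
                   modeled_columns=None) -> PairAlignment:
    a = PairAlignment(target_seq.upper(), template_seq.upper(),
                      _build_map(target_seq.upper(), target_start),
                      _build_map(template_seq.upper(), template_start))
    a.identity_full = _identity(a, range(a.n_columns))
    a.identity_modeled = (_identity(a, modeled_columns)
                          if modeled_columns is not None else a.identity_full)
    return a


def parse_alignment(fasta_text: str, target_start: int = 1,
                    template_start: int = 1,
                    modeled_columns=None) -> PairAlignment:
    """Parse a 2-record aligned FASTA (target first, template second)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(StringIO(fasta_text), "fasta"))
    if len(records) != 2:
        raise AlignmentError(f"expected exactly 2 records, got {len(records)}")
    tgt, tpl = str(records[0].seq), str(records[1].seq)
    if len(tgt) != len(tpl):
        raise AlignmentError(
            f"gapped lengths differ: {len(tgt)} vs {len(tpl)}")
    return make_alignment(tgt, tpl, target_start, template_start,
                          modeled_columns)


# ---------------------------------------------------------------------------
# Rebuild gating
# ---------------------------------------------------------------------------

@dataclass
class RebuildDecision:
    tmh_id: str
    rebuild: bool
    reasons: frozenset[str]

    def __post_init__(self):
        self.reasons = frozenset(self.reasons)
        bad = self.reasons - {"gap_in_tmh", "bend_mismatch", "length_mismatch"}
        if bad:
            raise ValueError(f"unknown reasons {bad}")
        if self.rebuild != bool(self.reasons):
            raise ValueError("rebuild flag inconsistent with reasons")


def _tmh_columns(tmh: SegmentAnnotation, inverse: dict[int, int],
                 label: str) -> list[int]:
    cols = []
    for r in range(tmh.first, tmh.last + 1):
        if r not in inverse:
            raise AlignmentError(
                f"{label} TMH {tmh.segment_id}: residue {r} outside alignment")
        cols.append(inverse[r])
    return cols


def gate_tmh(a: PairAlignment, target_tmhs: list[SegmentAnnotation],
             template_tmhs: list[SegmentAnnotation],
             proline_profile: dict[int, float] | None = None,
             length_margin: int = 4) -> list[RebuildDecision]:
    """Decide per target TMH whether its structure must be rebuilt.

    Reasons: ``gap_in_tmh`` if any alignment gap falls inside the helix span;
    ``bend_mismatch`` if a bend-inducing position (proline in the target, or
    proline in >= 10% of homologs via ``proline_profile``) is unaligned or not
    matched by a template proline (and symmetrically for template prolines);
    ``length_mismatch`` if annotated helix lengths differ by more than
    ``length_margin`` residues.
    """
    profile = proline_profile or {}
    tgt_inv, tpl_inv = a.target_inverse, a.template_inverse
    tmh_only = [t for t in target_tmhs if t.kind == "TMH"]
    tpl_only = [t for t in template_tmhs if t.kind == "TMH"]
    decisions = []
    for tmh in tmh_only:
        cols_t = _tmh_columns(tmh, tgt_inv, "target")
        # pair with the template TMH overlapping most in alignment columns
        span = set(range(min(cols_t), max(cols_t) + 1))
        partner, best_overlap = None, 0
        for cand in tpl_only:
            cols_c = _tmh_columns(cand, tpl_inv, "template")
            ov = len(span & set(range(min(cols_c), max(cols_c) + 1)))
            if ov > best_overlap:
                partner, best_overlap = cand, ov
        reasons = set()
        if partner is not None:
            cols_p = _tmh_columns(partner, tpl_inv, "template")
            span |= set(range(min(cols_p), max(cols_p) + 1))
            if abs(tmh.length - partner.length) > length_margin:
                reasons.add("length_mismatch")
        else:
            reasons.add("length_mismatch")
        for c in sorted(span):
            if a.target_seq[c] == "-" or a.template_seq[c] == "-":
                reasons.add("gap_in_tmh")
                break
        # bend-inducing positions
        for c in sorted(span):
            tgt_bend = (a.target_seq[c] == "P"
                        or profile.get(c, 0.0) >= PROLINE_PROFILE_THRESHOLD)
            tpl_pro = a.template_seq[c] == "P"
            if tgt_bend and a.target_seq[c] != "-" and not tpl_pro:
                reasons.add("bend_mismatch")
            if tpl_pro and not tgt_bend:
                reasons.add("bend_mismatch")
        decisions.append(RebuildDecision(tmh.segment_id, bool(reasons),
                                         frozenset(reasons)))
    return decisions


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constraint:
    res_i: int   # target residue numbers, res_i < res_j
    res_j: int
    d0: float
    width: float
    weight: float = 1.0


@dataclass
class ConstraintSet:
    constraints: list[Constraint] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.constraints)

    def __iter__(self):
        return iter(self.constraints)

    def to_tsv(self) -> str:
        lines = ["res_i\tres_j\td0\twidth\tweight"]
        for c in self.constraints:
            lines.append(f"{c.res_i}\t{c.res_j}\t{c.d0:.3f}\t"
                         f"{c.width:.3f}\t{c.weight:.3f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "ConstraintSet":
        cons = []
        for ln, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("res_i"):
                continue
            p = line.split("\t")
            if len(p) < 4:
                raise ValueError(f"constraint line {ln}: expected >= 4 columns")
            w = float(p[4]) if len(p) > 4 else 1.0
            cons.append(Constraint(int(p[0]), int(p[1]), float(p[2]),
                                   float(p[3]), w))
        return cls(cons)


def write_proline_profile(profile: dict[int, float]) -> str:
    lines = ["column\tfraction"]
    for c in sorted(profile):
        lines.append(f"{c}\t{profile[c]:.4f}")
    return "\n".join(lines) + "\n"


def read_proline_profile(text: str) -> dict[int, float]:
    out = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("column"):
            continue
        p = line.split("\t")
        if len(p) != 2:
            raise ValueError(f"profile line {ln}: expected 2 columns")
        out[int(p[0])] = float(p[1])
    return out


def constraint_width(d0: float) -> float:
    """Width schedule: 0.2 A up to 5 A contacts, 0.5 A at 8 A, linear between."""
    if d0 <= 5.0:
        return 0.2
    if d0 >= 8.0:
        return 0.5
    return 0.2 + 0.3 * (d0 - 5.0) / 3.0


def constraint_budget_fraction(identity: float) -> float | None:
    """Fraction of modeled residues to constrain; None means unbudgeted."""
    if identity >= 0.25:
        return None
    if identity < 0.20:
        return 0.05
    return 0.05 + 0.05 * (identity - 0.20) / 0.05


def derive_constraints(a: PairAlignment, template: Structure,
                       identity_modeled: float | None = None,
                       rebuilt_regions=(), cutoff: float = 8.0,
                       min_separation: int = 4) -> ConstraintSet:
    """Build the harmonic Cα-Cα constraint set from conserved template contacts.

    Candidate pairs are aligned columns whose residues are identical or in the
    same similarity class in target and template, whose template Cα-Cα
    distance is within ``cutoff``, separated by at least ``min_separation`` in
    sequence, and not inside a region rebuilt de novo (``rebuilt_regions`` is
    a list of closed target residue intervals).  The retained count follows
    the identity-dependent budget; selection is by ascending template
    distance, ties broken by descending sequence separation.
    """
    identity = (a.identity_modeled if identity_modeled is None
                else identity_modeled)
    mutual = a.mutual_columns()

    def in_rebuilt(res):
        return any(lo <= res <= hi for lo, hi in rebuilt_regions)

    eligible = []
    for c in mutual:
        ta, pa = a.target_seq[c], a.template_seq[c]
        if not residues_similar(ta, pa):
            continue
        t_res, p_res = a.target_map[c], a.template_map[c]
        if in_rebuilt(t_res) or not template.has_residue(p_res):
            continue
        eligible.append((t_res, p_res))

    cands = []
    for x in range(len(eligible)):
        ti, pi = eligible[x]
        for y in range(x + 1, len(eligible)):
            tj, pj = eligible[y]
            if abs(tj - ti) < min_separation:
                continue
            d0 = float(np.linalg.norm(template.ca([pi])[0]
                                      - template.ca([pj])[0]))
            if d0 > cutoff:
                continue
            cands.append(Constraint(min(ti, tj), max(ti, tj), d0,
                                    constraint_width(d0)))

    n_modeled = len(mutual)
    frac = constraint_budget_fraction(identity)
    cands.sort(key=lambda c: (c.d0, -(c.res_j - c.res_i), c.res_i, c.res_j))
    if frac is not None:
        budget = int(round(frac * n_modeled))
        selected = cands[:budget]
    else:
        selected = cands
    if not selected:
        warnings.warn("no constraint candidates found; empty constraint set")
    return ConstraintSet(selected, meta={
        "n_candidates": len(cands), "n_selected": len(selected),
        "identity": identity, "budget_fraction": frac,
        "n_modeled": n_modeled,
    })


def constraint_energy(s: Structure, cset: ConstraintSet,
                      sigma: float = 1.0) -> float:
    """Flat-bottom harmonic: zero within ``width`` of d0, quadratic beyond."""
    if len(cset) == 0:
        return 0.0
    ri = [c.res_i for c in cset]
    rj = [c.res_j for c in cset]
    d = np.linalg.norm(s.ca(ri) - s.ca(rj), axis=1)
    d0 = np.array([c.d0 for c in cset])
    w = np.array([c.width for c in cset])
    wt = np.array([c.weight for c in cset])
    excess = np.maximum(np.abs(d - d0) - w, 0.0)
    return float(np.sum(wt * (excess / sigma) ** 2))
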