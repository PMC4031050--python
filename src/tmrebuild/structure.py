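"""Backbone structure container and PDB input/output.

Coordinates are stored in a dense ``(n_residues, 5, 3)`` array with atom slots
``N, CA, C, O, CB`` (missing O/CB are NaN).  Residue numbering follows PDB
author numbering: 1-based, strictly increasing within a chain, and all residue
intervals used throughout the package are closed on both ends.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

# atom slot indices
N, CA, C, O, CB = 0, 1, 2, 3, 4
ATOM_SLOTS = ("N", "CA", "C", "O", "CB")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AA1_TO_3["X"] = "UNK"

CANONICAL_AA = set(AA3_TO_1.values()) | {"X"}

# C(i)-N(i+1) peptide-bond distance window; outside it the junction is a break
BOND_MIN, BOND_MAX = 1.0, 2.0


class StructureError(ValueError):
    pass


def ideal_cb(n_xyz: np.ndarray, ca_xyz: np.ndarray, c_xyz: np.ndarray) -> np.ndarray:
    """Place CB at ideal tetrahedral geometry from backbone N, CA, C.

    Fixed internal coordinates (bond 1.527 A, angle C-CA-CB 110.1 deg,
    improper N-C-CA-CB -122.6 deg) keep the placement exact even on slightly
    distorted backbones.
    """
    ang = np.radians(110.113518)
    tor = np.radians(-122.586280)
    bond = 1.526797
    bc = ca_xyz - c_xyz
    nbc = np.linalg.norm(bc)
    bc = bc / nbc
    nrm = np.cross(c_xyz - n_xyz, bc)
    nn = np.linalg.norm(nrm)
    if nn < 1e-10:
        raise StructureError("collinear backbone atoms; cannot place CB")
    nrm = nrm / nn
    m = np.cross(nrm, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(tor),
                  -bond * np.sin(ang) * np.sin(tor)])
    return ca_xyz + d[0] * bc + d[1] * m + d[2] * nrm


@dataclass
class Residue:
    """One residue's backbone (view onto a Structure row)."""

    index: int
    aa: str
    n_xyz: np.ndarray
    ca_xyz: np.ndarray
    c_xyz: np.ndarray
    o_xyz: np.ndarray | None = None
    cb_xyz: np.ndarray | None = None
    cb_virtual: bool = False


class Structure:
    """Ordered backbone structure of a single chain."""

    def __init__(self, index, aa, coords, chain_id: str = "A",
                 segment_labels: dict[int, str] | None = None,
                 cb_virtual=None):
        self.index = np.asarray(index, dtype=int)
        self.aa = list(aa)
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.shape != (len(self.aa), 5, 3):
            raise StructureError(
                f"coords shape {self.coords.shape} != ({len(self.aa)}, 5, 3)")
        self.chain_id = chain_id
        self.segment_labels = dict(segment_labels or {})
        if cb_virtual is None:
            cb_virtual = np.zeros(len(self.aa), dtype=bool)
        self.cb_virtual = np.asarray(cb_virtual, dtype=bool)
        self._row = {int(r): i for i, r in enumerate(self.index)}

    # -- basics ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.aa)

    def copy(self) -> "Structure":
        new = object.__new__(Structure)
        new.index = self.index  # residue numbering is never mutated in place
        new.aa = list(self.aa)
        new.coords = self.coords.copy()
        new.chain_id = self.chain_id
        new.segment_labels = dict(self.segment_labels)
        new.cb_virtual = self.cb_virtual.copy()
        new._row = self._row
        return new

    def row(self, resnum: int) -> int:
        try:
            return self._row[int(resnum)]
        except KeyError:
            raise StructureError(f"residue {resnum} not in structure") from None

    def has_residue(self, resnum: int) -> bool:
        return int(resnum) in self._row

    def ca(self, resnums=None) -> np.ndarray:
        if resnums is None:
            return self.coords[:, CA, :]
        rows = [self.row(r) for r in resnums]
        return self.coords[rows, CA, :]

    def rows_in(self, first: int, last: int) -> np.ndarray:
        mask = (self.index >= first) & (self.index <= last)
        return np.nonzero(mask)[0]

    @property
    def residues(self) -> list[Residue]:
        out = []
        for i, (r, a) in enumerate(zip(self.index, self.aa)):
            o = self.coords[i, O]
            cb = self.coords[i, CB]
            out.append(Residue(
                int(r), a,
                self.coords[i, N].copy(), self.coords[i, CA].copy(),
                self.coords[i, C].copy(),
                None if np.any(np.isnan(o)) else o.copy(),
                None if np.any(np.isnan(cb)) else cb.copy(),
                bool(self.cb_virtual[i]),
            ))
        return out

    @property
    def sequence(self) -> str:
        return "".join(self.aa)

    # -- validation --------------------------------------------------------
    def chain_breaks(self) -> list[int]:
        """Residue numbers i where the C(i)-N(i+1) junction is broken."""
        if len(self) < 2:
            return []
        d = np.linalg.norm(self.coords[1:, N] - self.coords[:-1, C], axis=1)
        bad = np.nonzero(~((d > BOND_MIN) & (d < BOND_MAX)))[0]
        return [int(self.index[i]) for i in bad]

    def validate(self, allow_breaks: bool = True) -> None:
        if len(self) == 0:
            return
        if np.any(np.diff(self.index) <= 0):
            raise StructureError("residue numbering not strictly increasing")
        core = self.coords[:, (N, CA, C), :]
        if not np.all(np.isfinite(core)):
            raise StructureError("non-finite backbone coordinates")
        for a in self.aa:
            if a not in CANONICAL_AA:
                raise StructureError(f"unknown amino acid {a!r}")
        cb = self.coords[:, CB, :]
        have = ~np.any(np.isnan(cb), axis=1)
        if np.any(have):
            d = np.linalg.norm(cb[have] - self.coords[have, CA, :], axis=1)
            if np.any((d <= 1.2) | (d >= 1.8)):
                raise StructureError("CA-CB distance outside (1.2, 1.8) A")
        if not allow_breaks and self.chain_breaks():
            raise StructureError(f"chain breaks at {self.chain_breaks()}")


# ---------------------------------------------------------------------------
# PDB reading (via biotite) and writing
# ---------------------------------------------------------------------------

def read_backbone(pdb_text: str, chain: str = "A") -> Structure:
    """Parse ATOM records of one chain into a backbone Structure.

    altLoc conflicts are resolved to the highest occupancy (ties
    alphabetically); a missing CB is rebuilt at ideal tetrahedral geometry and
    flagged virtual; a missing CA is a hard error naming the residue.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(io.StringIO(pdb_text))
    arr = pdb.get_structure(model=1, altloc="occupancy")
    chains = sorted(set(arr.chain_id))
    if chain not in chains:
        raise StructureError(f"chain {chain!r} not found; available: {chains}")
    arr = arr[arr.chain_id == chain]
    arr = arr[struc.filter_amino_acids(arr)]
    if arr.array_length() == 0:
        raise StructureError(f"chain {chain!r} has no amino-acid residues")

    starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
    index, aa, coords, cb_virtual = [], [], [], []
    for s, e in zip(starts[:-1], starts[1:]):
        res = arr[s:e]
        resnum = int(res.res_id[0])
        name3 = res.res_name[0]
        one = AA3_TO_1.get(name3, "X")
        row = np.full((5, 3), np.nan)
        for k, atom_name in enumerate(ATOM_SLOTS):
            sel = res.atom_name == atom_name
            if np.any(sel):
                row[k] = res.coord[sel][0]
        if np.any(np.isnan(row[CA])):
            raise StructureError(f"residue {name3} {resnum}: missing CA atom")
        if np.any(np.isnan(row[N])) or np.any(np.isnan(row[C])):
            raise StructureError(f"residue {name3} {resnum}: incomplete backbone")
        virt = False
        if np.any(np.isnan(row[CB])):
            row[CB] = ideal_cb(row[N], row[CA], row[C])
            virt = True
        index.append(resnum)
        aa.append(one)
        coords.append(row)
        cb_virtual.append(virt)

    s = Structure(index, aa, np.array(coords), chain_id=chain,
                  cb_virtual=cb_virtual)
    s.validate()
    return s


def write_pdb(s: Structure) -> str:
    """Serialize to standard fixed-width PDB ATOM records with a final TER."""
    lines = []
    serial = 1
    for i, (resnum, a) in enumerate(zip(s.index, s.aa)):
        res3 = AA1_TO_3.get(a, "UNK")
        for k, atom_name in enumerate(ATOM_SLOTS):
            xyz = s.coords[i, k]
            if np.any(np.isnan(xyz)):
                continue
            if atom_name == "CB" and s.cb_virtual[i] and a == "G":
                continue  # glycine virtual CB is an internal construct
            name_fmt = f" {atom_name:<3s}"
            element = atom_name[0]
            lines.append(
                f"ATOM  {serial:5d} {name_fmt}{'':1s}{res3:>3s} {s.chain_id:1s}"
                f"{int(resnum):4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
            )
            serial += 1
    if len(s) > 0:
        resnum = int(s.index[-1])
        res3 = AA1_TO_3.get(s.aa[-1], "UNK")
        lines.append(f"TER   {serial:5d}      {res3:>3s} {s.chain_id:1s}{resnum:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def extract_segment(s: Structure, first: int, last: int) -> Structure:
    """Closed-interval [first, last] sub-structure (1-based residue numbers)."""
    if first > last:
        raise StructureError(f"invalid interval [{first}, {last}]")
    i0, i1 = s.row(first), s.row(last)
    sl = slice(i0, i1 + 1)
    labels = {r: lab for r, lab in s.segment_labels.items()
              if first <= r <= last}
    return Structure(s.index[sl].copy(), s.aa[i0:i1 + 1], s.coords[sl].copy(),
                     s.chain_id, labels, s.cb_virtual[sl].copy())


# ---------------------------------------------------------------------------
# Segment annotation TSV (segment_id, first_res, last_res, kind)
# ---------------------------------------------------------------------------

@dataclass
class SegmentAnnotation:
    segment_id: str
    first: int
    last: int
    kind: str  # "TMH" or "loop"

    def __post_init__(self):
        if self.kind not in ("TMH", "loop"):
            raise ValueError(f"kind must be TMH or loop, got {self.kind!r}")
        if self.first > self.last:
            raise ValueError("first > last")

    @property
    def length(self) -> int:
        return self.last - self.first + 1


def write_annotations(segments: list[SegmentAnnotation]) -> str:
    lines = ["segment_id\tfirst_res\tlast_res\tkind"]
    for seg in segments:
        lines.append(f"{seg.segment_id}\t{seg.first}\t{seg.last}\t{seg.kind}")
    return "\n".join(lines) + "\n"


def read_annotations(text: str) -> list[SegmentAnnotation]:
    out = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("segment_id"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"annotation line {ln}: expected 4 columns")
        out.append(SegmentAnnotation(parts[0], int(parts[1]), int(parts[2]),
                                     parts[3]))
    return out
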