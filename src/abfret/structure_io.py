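"""Conformer container, PDB multi-model I/O, atom selections and backbone dihedrals.

A :class:`Conformer` is a flat, array-backed record of one structure (atom
names, elements, residue indices/names, coordinates in Angstrom).  Multi-MODEL
PDB files are read as conformer ensembles, one :class:`Conformer` per MODEL.
Backbone torsions follow the IUPAC convention: phi = C(i-1)-N-CA-C,
psi = N-CA-C-N(i+1), reported in degrees on (-180, 180].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

from .geometry import dihedral

__all__ = [
    "Conformer",
    "DihedralRecord",
    "AtomSelection",
    "MissingBackboneWarning",
    "read_pdb",
    "write_pdb",
    "compute_dihedrals",
    "resolve_selection",
]

BACKBONE_NAMES = ("N", "CA", "C")


class MissingBackboneWarning(UserWarning):
    """Raised (as a warning) when incomplete backbone atoms force dihedral exclusion."""


@dataclass
class Conformer:
    """One structure: parallel per-atom arrays plus a free-text label."""

    atom_names: list
    elements: list
    res_indices: np.ndarray  # int, per atom
    res_names: list
    coords: np.ndarray  # (n_atoms, 3) float, Angstrom
    label: str = ""

    def __post_init__(self):
        self.res_indices = np.asarray(self.res_indices, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atom_names), 3):
            raise ValueError("coords shape does not match atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residue_ids(self) -> np.ndarray:
        """Distinct residue indices in chain order."""
        seen = dict.fromkeys(self.res_indices.tolist())
        return np.array(list(seen), dtype=int)

    def atom_index(self, res_index: int, atom_name: str):
        """Index of a uniquely named atom in a residue, or None if absent."""
        hits = [
            i
            for i in range(self.n_atoms)
            if self.res_indices[i] == res_index and self.atom_names[i] == atom_name
        ]
        if not hits:
            return None
        if len(hits) > 1:
            raise ValueError(
                f"atom {atom_name!r} not unique in residue {res_index}"
            )
        return hits[0]

    def validate(self) -> None:
        """Check container invariants: finite coordinates, ordered residues, unique backbone."""
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        rid = self.res_indices.tolist()
        block_ids = [rid[0]] if rid else []
        for r in rid[1:]:
            if r != block_ids[-1]:
                block_ids.append(r)
        if any(b <= a for a, b in zip(block_ids, block_ids[1:])):
            raise ValueError("residue indices not strictly increasing along the chain")
        for r in block_ids:
            names = [n for n, ri in zip(self.atom_names, rid) if ri == r]
            for bb in BACKBONE_NAMES:
                if names.count(bb) != 1:
                    raise ValueError(
                        f"residue {r}: backbone atom {bb} present {names.count(bb)} times"
                    )

    def transformed(self, R: np.ndarray, t=(0.0, 0.0, 0.0)) -> "Conformer":
        """Rigidly transformed copy (x -> x R^T + t)."""
        return Conformer(
            list(self.atom_names),
            list(self.elements),
            self.res_indices.copy(),
            list(self.res_names),
            self.coords @ np.asarray(R).T + np.asarray(t, dtype=float),
            self.label,
        )


@dataclass(frozen=True)
class DihedralRecord:
    res_index: int
    phi: float  # degrees, (-180, 180]
    psi: float


@dataclass
class AtomSelection:
    """Atom selection by a small predicate grammar.

    Grammar: clauses joined by ``and``; each clause is one of
    ``res A-B[,C-D...]``, ``resname X[,Y...]``, ``name N1[,N2...]``,
    optionally prefixed by ``not``.  Example:
    ``"res 17-21 and name CA"``, ``"resname CYS and not name N,C,O"``.
    """

    expression: str
    resolved_indices: list = field(default_factory=list)


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "SE"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def read_pdb(path) -> list:
    """Read a PDB file into a list of Conformers, one per MODEL block.

    A file without MODEL records yields a single Conformer.  Elements missing
    from the element column are inferred from the atom name.  The first
    alternate location is kept; insertion codes are rejected.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    conformers = []
    for model in structure:
        names, elements, res_idx, res_names, xyz = [], [], [], [], []
        for chain in model:
            for residue in chain:
                het, resseq, icode = residue.id
                if icode.strip():
                    raise ValueError(
                        f"insertion code {icode!r} at residue {resseq}: not supported"
                    )
                for atom in residue:
                    if atom.is_disordered():
                        atom = atom.disordered_get_list()[0]
                    names.append(atom.get_name())
                    el = (atom.element or "").strip()
                    elements.append(el if el else _infer_element(atom.get_name()))
                    res_idx.append(resseq)
                    res_names.append(residue.get_resname())
                    xyz.append(atom.get_coord())
        conformers.append(
            Conformer(
                names,
                elements,
                np.array(res_idx, dtype=int),
                res_names,
                np.array(xyz, dtype=float),
                label=f"model_{model.id + 1}",
            )
        )
    if not conformers:
        raise ValueError(f"no ATOM records found in {path}")
    return conformers


def write_pdb(conformers, path) -> None:
    """Write one or more Conformers as a (multi-)MODEL PDB file."""
    if isinstance(conformers, Conformer):
        conformers = [conformers]
    multi = len(conformers) > 1
    with open(path, "w") as fh:
        for m, conf in enumerate(conformers, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for i in range(conf.n_atoms):
                name = conf.atom_names[i]
                pad_name = f" {name}" if len(name) < 4 else name
                x, y, z = conf.coords[i]
                fh.write(
                    f"ATOM  {i + 1:5d} {pad_name:<4s} {conf.res_names[i]:<3.3s}"
                    f" A{conf.res_indices[i]:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {conf.elements[i]:>2.2s}\n"
                )
            fh.write("ENDMDL\n" if multi else "TER\n")
        fh.write("END\n")


def compute_dihedrals(conf: Conformer, res_range=None) -> list:
    """Backbone (phi, psi) records for residues in ``res_range`` (inclusive interval).

    A residue contributes a record only when all of C(i-1), N, CA, C, N(i+1)
    exist; residues with missing backbone neighbours are omitted with a
    :class:`MissingBackboneWarning` rather than returned as NaN.
    """
    rids = conf.residue_ids
    if res_range is None:
        wanted = rids.tolist()
    else:
        lo, hi = res_range
        wanted = [r for r in rids if lo <= r <= hi]
    pos = {int(r): k for k, r in enumerate(rids)}
    records = []
    for r in wanted:
        k = pos[int(r)]
        if k == 0 or k == len(rids) - 1:
            continue  # chain termini: phi or psi undefined
        prev_r, next_r = int(rids[k - 1]), int(rids[k + 1])
        if prev_r != r - 1 or next_r != r + 1:
            continue  # non-contiguous neighbours
        idx = {}
        ok = True
        for rr, nm in ((prev_r, "C"), (r, "N"), (r, "CA"), (r, "C"), (next_r, "N")):
            i = conf.atom_index(rr, nm)
            if i is None:
                ok = False
                break
            idx[(rr, nm)] = i
        if not ok:
            warnings.warn(
                f"residue {r}: incomplete backbone, dihedral omitted",
                MissingBackboneWarning,
                stacklevel=2,
            )
            continue
        c_prev = conf.coords[idx[(prev_r, "C")]]
        n = conf.coords[idx[(r, "N")]]
        ca = conf.coords[idx[(r, "CA")]]
        c = conf.coords[idx[(r, "C")]]
        n_next = conf.coords[idx[(next_r, "N")]]
        records.append(
            DihedralRecord(int(r), dihedral(c_prev, n, ca, c), dihedral(n, ca, c, n_next))
        )
    return records


def _parse_ranges(token: str):
    spans = []
    for part in token.split(","):
        part = part.strip()
        if "-" in part[1:]:
            a, b = part.rsplit("-", 1)
            spans.append((int(a), int(b)))
        else:
            spans.append((int(part), int(part)))
    return spans


def _clause_mask(conf: Conformer, clause: str) -> np.ndarray:
    clause = clause.strip()
    negate = False
    if clause.startswith("not "):
        negate = True
        clause = clause[4:].strip()
    if clause.startswith("res "):
        spans = _parse_ranges(clause[4:])
        mask = np.zeros(conf.n_atoms, dtype=bool)
        for lo, hi in spans:
            mask |= (conf.res_indices >= lo) & (conf.res_indices <= hi)
    elif clause.startswith("resname "):
        wanted = {w.strip().upper() for w in clause[8:].split(",")}
        mask = np.array([rn.upper() in wanted for rn in conf.res_names])
    elif clause.startswith("name "):
        wanted = {w.strip().upper() for w in clause[5:].split(",")}
        mask = np.array([an.upper() in wanted for an in conf.atom_names])
    else:
        raise ValueError(f"unrecognized selection clause: {clause!r}")
    return ~mask if negate else mask


def resolve_selection(conf: Conformer, sel) -> list:
    """Resolve an AtomSelection (or expression string) to sorted unique atom indices."""
    expr = sel.expression if isinstance(sel, AtomSelection) else str(sel)
    mask = np.ones(conf.n_atoms, dtype=bool)
    for clause in expr.split(" and "):
        mask &= _clause_mask(conf, clause)
    indices = sorted(int(i) for i in np.nonzero(mask)[0])
    if not indices:
        raise ValueError(f"selection {expr!r} resolved to no atoms")
    if isinstance(sel, AtomSelection):
        sel.resolved_indices = indices
    return indices
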