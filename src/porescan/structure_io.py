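"""Macromolecular structure I/O and the uniform in-memory atomic model.

Parsing of PDB and mmCIF files is delegated to gemmi; this module converts
the parsed hierarchy into a flat, deterministic model used by every
downstream stage:

* one model per :class:`Structure` (model 1 by default — each deposited
  entry is treated as a single conformation),
* alternate locations resolved to the highest-occupancy conformer
  (ties broken by file order),
* HETATM records kept and flagged,
* hydrogens kept if present (downstream geometry and energy stages ignore
  them).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .geometry import RigidTransform

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureFormatError",
    "read_structure",
    "write_structure",
    "chain_sequence",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Elements accepted as monatomic ions by the pore-geometry stage.
ION_ELEMENTS = {"K", "NA", "CA", "MG", "ZN", "CD", "CS", "RB", "BA", "TL", "CL", "BR"}


class StructureFormatError(ValueError):
    """Raised when a file cannot be parsed or serialized in the named dialect."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    het: bool = False

    def copy(self) -> "Atom":
        return dataclasses.replace(self, xyz=self.xyz.copy())


@dataclass
class Residue:
    chain: str
    seqid: int
    icode: str
    name: str
    het: bool
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seqid, self.icode)

    @property
    def is_polymer(self) -> bool:
        # Waters and monatomic ions come in as HETATM; polymer residues do not.
        return not self.het

    @property
    def is_amino_acid(self) -> bool:
        return self.name in THREE_TO_ONE

    def atom(self, name: str) -> Atom:
        try:
            return self.atoms[name]
        except KeyError:
            raise KeyError(
                f"atom {name!r} not in {self.chain}/{self.name}{self.seqid}{self.icode}; "
                f"available: {sorted(self.atoms)}"
            ) from None

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms.values()])

    def copy(self) -> "Residue":
        return Residue(
            self.chain, self.seqid, self.icode, self.name, self.het,
            {k: a.copy() for k, a in self.atoms.items()},
        )


@dataclass
class Structure:
    """Flat residue list with metadata; order follows the source file."""

    residues: list[Residue] = field(default_factory=list)
    accession: str = ""
    title: str = ""

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, int, str], Residue] = {}
        for r in self.residues:
            if r.key in self._index:
                raise ValueError(f"duplicate residue key {r.key}")
            self._index[r.key] = r

    def add_residue(self, r: Residue) -> None:
        if r.key in self._index:
            raise ValueError(f"duplicate residue key {r.key}")
        self.residues.append(r)
        self._index[r.key] = r

    def get_residue(self, chain: str, seqid: int, icode: str = "") -> Residue:
        try:
            return self._index[(chain, seqid, icode)]
        except KeyError:
            raise KeyError(f"no residue ({chain}, {seqid}, {icode!r})") from None

    def has_residue(self, chain: str, seqid: int, icode: str = "") -> bool:
        return (chain, seqid, icode) in self._index

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def chain_residues(self, chain: str, polymer_only: bool = True) -> list[Residue]:
        rs = [r for r in self.residues if r.chain == chain]
        if polymer_only:
            rs = [r for r in rs if r.is_polymer]
        return rs

    def het_residues(self, name: str | None = None) -> list[Residue]:
        rs = [r for r in self.residues if r.het]
        if name is not None:
            rs = [r for r in rs if r.name == name]
        return rs

    def ion_residues(self) -> list[Residue]:
        """Monatomic HETATM residues whose single atom is a known ion element."""
        out = []
        for r in self.residues:
            if r.het and len(r.atoms) == 1:
                atom = next(iter(r.atoms.values()))
                if atom.element.upper() in ION_ELEMENTS:
                    out.append(r)
        return out

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def all_atoms(self) -> list[tuple[Residue, Atom]]:
        return [(r, a) for r in self.residues for a in r.atoms.values()]

    def transform(self, t: RigidTransform) -> None:
        """Apply a rigid transform to every atom, in place."""
        for r in self.residues:
            for a in r.atoms.values():
                a.xyz = t.apply(a.xyz)

    def copy(self) -> "Structure":
        return Structure([r.copy() for r in self.residues], self.accession, self.title)


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.strip()
    if el and el != "X":
        return el
    # deduce from the atom name: first alphabetic character
    for ch in atom.name:
        if ch.isalpha():
            return ch.upper()
    raise StructureFormatError(f"cannot deduce element for atom {atom.name!r}")


def read_structure(path: str | Path, format: str = "auto", model: int = 1) -> Structure:
    """Read a PDB or mmCIF file into the uniform atomic model.

    Parameters
    ----------
    path : file path
    format : ``"pdb"``, ``"mmcif"`` or ``"auto"`` (by extension/content)
    model : 1-based model index for multi-model files (default: first)
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif format == "auto":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureFormatError(f"{path}: file contains no models")
    if model < 1 or model > len(st):
        raise StructureFormatError(
            f"{path}: model {model} requested but file has {len(st)} model(s)"
        )
    gmodel = st[model - 1]

    info = getattr(st, "info", {})
    title = info["_struct.title"] if "_struct.title" in info else ""
    out = Structure(accession=(st.name or path.stem), title=title)
    n_atoms = 0
    for chain in gmodel:
        for res in chain:
            het = res.het_flag == "H"
            residue = Residue(
                chain=chain.name,
                seqid=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                name=res.name,
                het=het,
            )
            # altloc resolution: highest occupancy, ties by file order
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ + 1e-9:
                    best[atom.name] = atom
            for name, atom in best.items():
                xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if not np.all(np.isfinite(xyz)):
                    raise StructureFormatError(f"non-finite coordinates for atom {name}")
                residue.atoms[name] = Atom(
                    name=name,
                    element=_element_of(atom),
                    xyz=xyz,
                    occupancy=atom.occ,
                    b_factor=atom.b_iso,
                    het=het,
                )
                n_atoms += 1
            out.add_residue(residue)
    if n_atoms == 0:
        raise StructureFormatError(f"{path}: selected model is empty")
    return out


_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999


def write_structure(s: Structure, path: str | Path, format: str = "pdb") -> Path:
    """Write a structure as fixed-column PDB (v3.3 coordinate records).

    Coordinates outside the fixed-column range raise instead of being
    silently truncated.
    """
    if format != "pdb":
        raise ValueError("only PDB output is supported")
    path = Path(path)
    lines = []
    if s.title:
        lines.append(f"TITLE     {s.title[:70]}")
    serial = 0
    last_chain = None
    for r in s.residues:
        if len(r.name) > 3:
            raise StructureFormatError(f"residue name {r.name!r} exceeds PDB columns")
        if last_chain is not None and r.chain != last_chain and not r.het:
            lines.append("TER")
        last_chain = r.chain
        for a in r.atoms.values():
            if len(a.name) > 4:
                raise StructureFormatError(f"atom name {a.name!r} exceeds PDB columns")
            x, y, z = a.xyz
            for v in (x, y, z):
                if not (_PDB_COORD_MIN <= v <= _PDB_COORD_MAX):
                    raise StructureFormatError(
                        f"coordinate {v:.3f} overflows PDB fixed columns"
                    )
            serial += 1
            record = "HETATM" if a.het else "ATOM  "
            # column-29 rule: short names start at col 14 unless 4 chars
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"{record}{serial:5d} {name:<4s}{'':1s}{r.name:>3s} {r.chain[:1]:1s}"
                f"{r.seqid:4d}{r.icode[:1] or '':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                f"          {a.element[:2].upper():>2s}"
            )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def chain_sequence(
    s: Structure, chain: str, selenomet_as_met: bool = False
) -> tuple[str, list[int]]:
    """One-letter sequence of a chain's polymer residues, with residue numbers.

    Non-standard residues become ``'X'`` (``MSE`` maps to ``'M'`` when
    ``selenomet_as_met`` is enabled).  Returns ``(sequence, residue_numbers)``.
    """
    if chain not in s.chain_ids:
        raise KeyError(f"chain {chain!r} not present; available: {s.chain_ids}")
    seq = []
    nums = []
    for r in s.chain_residues(chain, polymer_only=True):
        one = THREE_TO_ONE.get(r.name)
        if one is None:
            one = "M" if (r.name == "MSE" and selenomet_as_met) else "X"
        seq.append(one)
        nums.append(r.seqid)
    return "".join(seq), nums
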