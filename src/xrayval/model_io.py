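"""Coordinate-file I/O and the domain model for structures under validation.

The in-memory model is a thin hierarchy (Structure -> Chain -> Residue ->
Atom) carrying exactly what the validators need: orthogonal coordinates,
occupancies, isotropic B values, alternate-location labels, the unit cell
and the nominal resolution.  Parsing and writing of the fixed-column PDB
format is delegated to gemmi; a light pre-check supplies line-numbered
errors for malformed records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import gemmi
import numpy as np

__all__ = [
    "Atom", "Residue", "Chain", "Cell", "Structure",
    "parse_pdb", "write_pdb", "classify_residue",
    "vdw_radius", "electron_count",
    "PdbParseError", "FormatOverflowError",
    "AMINO_ACIDS", "NUCLEOTIDES", "WATERS",
    "select_primary_conformer",
]

AMINO_ACIDS = frozenset([
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
])
NUCLEOTIDES = frozenset([
    "A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI",
])
WATERS = frozenset(["HOH", "WAT"])


class PdbParseError(ValueError):
    """Malformed or empty PDB content; carries the offending line number."""


class FormatOverflowError(ValueError):
    """A value does not fit the fixed-column PDB field width."""


def _load_element_table() -> dict[str, tuple[int, float]]:
    table = {}
    text = resources.files("xrayval.data").joinpath("elements.txt").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, electrons, radius = line.split()
        table[sym.upper()] = (int(electrons), float(radius))
    return table


_ELEMENTS = _load_element_table()


def vdw_radius(element: str) -> float:
    """Van der Waals radius (A) of *element* from the shipped table."""
    try:
        return _ELEMENTS[element.upper()][1]
    except KeyError:
        raise KeyError(
            f"unknown element {element!r}; known: {sorted(_ELEMENTS)}"
        ) from None


def electron_count(element: str) -> int:
    """Electron count (atomic number) used as the flat scattering weight."""
    try:
        return _ELEMENTS[element.upper()][0]
    except KeyError:
        raise KeyError(
            f"unknown element {element!r}; known: {sorted(_ELEMENTS)}"
        ) from None


def classify_residue(name: str) -> str:
    """Classify a 3-letter residue code.

    Returns one of ``amino_acid``, ``nucleotide``, ``water`` or ``ligand``;
    any name outside the shipped tables is a ligand.  Total function.
    """
    name = name.strip().upper()
    if name in AMINO_ACIDS:
        return "amino_acid"
    if name in NUCLEOTIDES:
        return "nucleotide"
    if name in WATERS:
        return "water"
    return "ligand"


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray          # orthogonal A, shape (3,)
    occupancy: float = 1.0
    b_factor: float = 20.0
    altloc: str = ""

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    name: str
    seq: int
    icode: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def category(self) -> str:
        return classify_residue(self.name)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq, self.icode)

    def atom(self, name: str) -> Atom | None:
        """First atom with this label (any altloc), or None."""
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.seq}{self.icode} {self.name}"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Cell:
    """Unit cell; fractionalisation uses a along x, b in the xy-plane."""
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")

    @property
    def orth_matrix(self) -> np.ndarray:
        """Fractional -> orthogonal transform (columns are a, b, c)."""
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    @property
    def frac_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orth_matrix)

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.frac_matrix.T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.orth_matrix.T


@dataclass
class Structure:
    entry_id: str = "xxxx"
    chains: list[Chain] = field(default_factory=list)
    cell: Cell | None = None
    resolution: float | None = None

    def residues(self):
        for ch in self.chains:
            yield from ch.residues

    def atoms(self):
        for res in self.residues():
            yield from res.atoms

    @property
    def atom_count(self) -> int:
        """Number of non-hydrogen atoms."""
        return sum(1 for a in self.atoms() if not a.is_hydrogen)

    def validate(self) -> None:
        seen = set()
        for res in self.residues():
            if not res.atoms:
                raise ValueError(f"residue {res.label} has no atoms")
            if res.key in seen:
                raise ValueError(f"duplicate residue identifier {res.key}")
            seen.add(res.key)


def _precheck_lines(text: str) -> int:
    """Check fixed-column sanity of ATOM/HETATM records; return their count."""
    n = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        n += 1
        if len(line.rstrip("\n")) < 54:
            raise PdbParseError(
                f"line {lineno}: record shorter than the coordinate columns")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z"),
                             (54, 60, "occupancy"), (60, 66, "B factor")):
            fieldtxt = line[lo:hi].strip()
            if not fieldtxt and lo >= 54:
                continue  # occupancy/B may be absent; gemmi defaults them
            try:
                float(fieldtxt)
            except ValueError:
                raise PdbParseError(
                    f"line {lineno}: bad {what} field {fieldtxt!r}") from None
    return n


def parse_pdb(text: str, entry_id: str = "xxxx") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Atoms are grouped into residues by (chain, seq, icode); CRYST1
    populates the cell, ``REMARK 2`` the resolution.  Alternate-location
    records are all retained.  Malformed ATOM/HETATM records raise
    :class:`PdbParseError` naming the line; content with no atoms raises
    as well.
    """
    if _precheck_lines(text) == 0:
        raise PdbParseError("no ATOM or HETATM records in input")
    st = gemmi.read_pdb_string(text)
    cell = None
    if st.cell.is_crystal():
        cell = Cell(st.cell.a, st.cell.b, st.cell.c,
                    st.cell.alpha, st.cell.beta, st.cell.gamma)
    resolution = st.resolution if st.resolution > 0 else None
    chains: list[Chain] = []
    model = st[0]
    for gch in model:
        chain = Chain(gch.name)
        for gres in gch:
            res = Residue(
                name=gres.name,
                seq=gres.seqid.num,
                icode=gres.seqid.icode.strip(),
                chain_id=gch.name,
            )
            for ga in gres:
                res.atoms.append(Atom(
                    name=ga.name,
                    element=ga.element.name,
                    pos=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    b_factor=ga.b_iso,
                    altloc=ga.altloc if ga.altloc != "\0" else "",
                ))
            chain.residues.append(res)
        chains.append(chain)
    # gemmi may split a PDB chain into segments (e.g. waters); merge same ids
    merged: dict[str, Chain] = {}
    ordered: list[Chain] = []
    for ch in chains:
        if ch.chain_id in merged:
            merged[ch.chain_id].residues.extend(ch.residues)
        else:
            merged[ch.chain_id] = ch
            ordered.append(ch)
    s = Structure(entry_id=entry_id, chains=ordered,
                  cell=cell, resolution=resolution)
    s.validate()
    return s


def write_pdb(s: Structure) -> str:
    """Serialize a structure to PDB fixed-column text.

    Coordinates are kept to 3 decimals, occupancy and B to 2; a TER record
    separates chains.  Coordinates with magnitude >= 10000 A cannot be
    represented and raise :class:`FormatOverflowError`.
    """
    for a in s.atoms():
        if np.any(np.abs(a.pos) >= 10000.0):
            raise FormatOverflowError(
                f"coordinate magnitude >= 10000 A in atom {a.name}")
    st = gemmi.Structure()
    st.name = s.entry_id
    if s.cell is not None:
        st.cell = gemmi.UnitCell(s.cell.a, s.cell.b, s.cell.c,
                                 s.cell.alpha, s.cell.beta, s.cell.gamma)
    st.spacegroup_hm = "P 1"
    if s.resolution is not None:
        st.resolution = s.resolution
    model = gemmi.Model("1")
    for ch in s.chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq, res.icode or " ")
            gres.het_flag = "A" if res.category in ("amino_acid", "nucleotide") else "H"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                ga.altloc = a.altloc or "\0"
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def select_primary_conformer(s: Structure) -> Structure:
    """Reduce alternate conformations to a single conformer per residue.

    For every atom label with several altlocs, the highest-occupancy record
    is kept (ties broken by alphabetically first altloc label).  All
    downstream scoring operates on the reduced model.
    """
    chains = []
    for ch in s.chains:
        new_ch = Chain(ch.chain_id)
        for res in ch.residues:
            best: dict[str, Atom] = {}
            for a in res.atoms:
                prev = best.get(a.name)
                if prev is None:
                    best[a.name] = a
                    continue
                if (a.occupancy, _alt_rank(a.altloc)) > (
                        prev.occupancy, _alt_rank(prev.altloc)):
                    best[a.name] = a
            new_res = replace(res, atoms=[replace(a, altloc="")
                                          for a in best.values()])
            new_ch.residues.append(new_res)
        chains.append(new_ch)
    return Structure(entry_id=s.entry_id, chains=chains,
                     cell=s.cell, resolution=s.resolution)


def _alt_rank(altloc: str) -> float:
    # higher is preferred; alphabetically first label wins ties
    return -ord(altloc) if altloc else 0.0
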