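"""Model-only validation: covalent geometry, torsion analysis, clashes.

Covalent bonds and angles are compared against a shipped restraint
dictionary as z-scores.  Backbone (phi, psi) pairs are classified on a
shipped Ramachandran region grid; side-chain chi vectors against a
rotamer-mode library.  Steric validation places idealized backbone amide
hydrogens and searches for van der Waals overlaps with a KD-tree, so the
cost is near-linear in the atom count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .model_io import (
    Atom, Residue, Structure, select_primary_conformer, vdw_radius,
)

__all__ = [
    "GeometryDictionary", "RamachandranRegions", "RotamerLibrary",
    "GeometryFeature", "Clash",
    "covalent_zscores", "dihedral", "backbone_torsions",
    "classify_ramachandran", "ramachandran_report",
    "sidechain_chis", "classify_rotamer", "rotamer_report",
    "place_riding_hydrogens", "find_clashes", "clashscore",
]

#: peptide-bond length gate for treating consecutive residues as linked (A)
PEPTIDE_BOND_MAX = 2.5


# --------------------------------------------------------------------------
# shipped tables

class GeometryDictionary:
    """Bond/angle restraint dictionary (mean, sd) keyed by residue and atoms.

    The special residue name ``PEPTIDE`` keys the inter-residue link;
    its atom labels are suffixed ``-`` (preceding residue) or ``+``
    (following residue).
    """

    def __init__(self, bonds, angles, peptide_bonds, peptide_angles):
        self.bonds = bonds          # (res, (a1, a2)) -> (mean, sd)
        self.angles = angles        # (res, (a1, a2, a3)) -> (mean, sd)
        self.peptide_bonds = peptide_bonds    # (a1, a2) -> (mean, sd)
        self.peptide_angles = peptide_angles  # (a1, a2, a3) -> (mean, sd)

    @classmethod
    def load(cls, path=None) -> "GeometryDictionary":
        if path is None:
            text = resources.files("xrayval.data").joinpath(
                "geometry_dict.txt").read_text()
        else:
            text = open(path).read()
        bonds, angles, pbonds, pangles = {}, {}, {}, {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, res, *rest = line.split()
            mean, sd = float(rest[-2]), float(rest[-1])
            if sd <= 0:
                raise ValueError(f"non-positive sd in entry: {line}")
            atoms = tuple(rest[:-2])
            if res == "PEPTIDE":
                (pbonds if kind == "bond" else pangles)[atoms] = (mean, sd)
            else:
                (bonds if kind == "bond" else angles)[(res, atoms)] = (mean, sd)
        return cls(bonds, angles, pbonds, pangles)

    def bond(self, res: str, a1: str, a2: str):
        return self.bonds.get((res, (a1, a2))) or self.bonds.get((res, (a2, a1)))

    def angle(self, res: str, a1: str, a2: str, a3: str):
        return (self.angles.get((res, (a1, a2, a3)))
                or self.angles.get((res, (a3, a2, a1))))


class RamachandranRegions:
    """Favored/allowed/outlier label grid over the (phi, psi) torus.

    10-degree bins for four residue categories (general, GLY, PRO, prePRO);
    every cell of the torus carries a label, so classification is total.
    """

    BIN = 10

    def __init__(self, grid: dict[str, np.ndarray]):
        self.grid = grid  # category -> (36, 36) array of 'F'/'A'/'O'

    @classmethod
    def load(cls, path=None) -> "RamachandranRegions":
        if path is None:
            text = resources.files("xrayval.data").joinpath(
                "rama_grid.txt").read_text()
        else:
            text = open(path).read()
        rows: dict[str, dict[int, str]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cat, lo, labels = line.split()
            rows.setdefault(cat, {})[int(lo)] = labels
        grid = {}
        for cat, by_lo in rows.items():
            arr = np.empty((36, 36), dtype="U1")
            for lo, labels in by_lo.items():
                arr[(lo + 180) // cls.BIN, :] = list(labels)
            grid[cat] = arr
        return cls(grid)

    def label(self, category: str, phi: float, psi: float) -> str:
        i = int(((phi + 180.0) % 360.0) // self.BIN) % 36
        j = int(((psi + 180.0) % 360.0) // self.BIN) % 36
        return self.grid[category][i, j]


class RotamerLibrary:
    """Chi-angle definitions and canonical rotamer modes per residue type."""

    def __init__(self, chi_atoms, modes):
        self.chi_atoms = chi_atoms  # res -> [ (a1,a2,a3,a4), ... ] per chi
        self.modes = modes          # res -> [ (name, np.ndarray of chis) ]

    @classmethod
    def load(cls, path=None) -> "RotamerLibrary":
        if path is None:
            text = resources.files("xrayval.data").joinpath(
                "rotamers.txt").read_text()
        else:
            text = open(path).read()
        chi_atoms: dict[str, list] = {}
        modes: dict[str, list] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "chidef":
                res, chi = parts[1], parts[2]
                idx = int(chi[3:]) - 1
                chi_atoms.setdefault(res, [])
                while len(chi_atoms[res]) <= idx:
                    chi_atoms[res].append(None)
                chi_atoms[res][idx] = tuple(parts[3:7])
            elif parts[0] == "rotamer":
                res, name = parts[1], parts[2]
                modes.setdefault(res, []).append(
                    (name, np.array([float(x) for x in parts[3:]])))
        return cls(chi_atoms, modes)


# --------------------------------------------------------------------------
# covalent geometry

@dataclass
class GeometryFeature:
    kind: str          # 'bond' | 'angle'
    residue: Residue   # owning residue (first residue for peptide links)
    feature_id: str
    observed: float
    mean: float
    sd: float

    @property
    def z(self) -> float:
        return (self.observed - self.mean) / self.sd


def _dist(a: Atom, b: Atom) -> float:
    return float(np.linalg.norm(a.pos - b.pos))


def _angle(a: Atom, b: Atom, c: Atom) -> float:
    u = a.pos - b.pos
    v = c.pos - b.pos
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosv, -1.0, 1.0)))


def _linked(prev: Residue, res: Residue) -> bool:
    c, n = prev.atom("C"), res.atom("N")
    return c is not None and n is not None and _dist(c, n) < PEPTIDE_BOND_MAX


def covalent_zscores(s: Structure, gdict: GeometryDictionary | None = None,
                     z_cutoff: float = 4.0):
    """Compare every covered bond and angle to the restraint dictionary.

    Returns ``(features, outliers)`` where features are
    :class:`GeometryFeature` records (z = (obs - mean)/sd) and outliers is
    the subset with ``|z| > z_cutoff``.  Residue types or atoms absent from
    the dictionary simply contribute no features.
    """
    if gdict is None:
        gdict = GeometryDictionary.load()
    s = select_primary_conformer(s)
    feats: list[GeometryFeature] = []

    def emit(kind, res, names, observed, stat):
        feats.append(GeometryFeature(
            kind, res, f"{res.label} {'-'.join(names)}",
            observed, stat[0], stat[1]))

    for ch in s.chains:
        for i, res in enumerate(ch.residues):
            for (rname, anames), stat in list(gdict.bonds.items()):
                if rname != res.name:
                    continue
                a, b = res.atom(anames[0]), res.atom(anames[1])
                if a is not None and b is not None:
                    emit("bond", res, anames, _dist(a, b), stat)
            for (rname, anames), stat in list(gdict.angles.items()):
                if rname != res.name:
                    continue
                abc = [res.atom(nm) for nm in anames]
                if all(x is not None for x in abc):
                    emit("angle", res, anames, _angle(*abc), stat)
            # inter-residue link features
            nxt = ch.residues[i + 1] if i + 1 < len(ch.residues) else None
            linked = (nxt is not None and res.category == "amino_acid"
                      and nxt.category == "amino_acid" and _linked(res, nxt))

            def resolve(label):
                if label.endswith("-"):
                    return res.atom(label[:-1])
                if label.endswith("+"):
                    return nxt.atom(label[:-1]) if nxt is not None else None
                return None

            for anames, stat in gdict.peptide_bonds.items():
                needs_next = any(nm.endswith("+") for nm in anames)
                if needs_next and not linked:
                    continue
                ab = [resolve(nm) for nm in anames]
                if all(x is not None for x in ab):
                    emit("bond", res, anames, _dist(*ab), stat)
            for anames, stat in gdict.peptide_angles.items():
                needs_next = any(nm.endswith("+") for nm in anames)
                if needs_next and not linked:
                    continue
                abc = [resolve(nm) for nm in anames]
                if all(x is not None for x in abc):
                    emit("angle", res, anames, _angle(*abc), stat)
    outliers = [f for f in feats if abs(f.z) > z_cutoff]
    return feats, outliers


# --------------------------------------------------------------------------
# torsions

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) of four points."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def backbone_torsions(s: Structure):
    """Per-residue (phi, psi), IUPAC convention, None where undefined.

    phi = C(i-1)-N-CA-C, psi = N-CA-C-N(i+1); chain termini and chain
    breaks (peptide bond longer than 2.5 A) leave the respective torsion
    undefined.  Returns a list of (residue, phi, psi).
    """
    s = select_primary_conformer(s)
    out = []
    for ch in s.chains:
        aa = [r for r in ch.residues if r.category == "amino_acid"]
        for i, res in enumerate(aa):
            prev = aa[i - 1] if i > 0 else None
            nxt = aa[i + 1] if i + 1 < len(aa) else None
            n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
            phi = psi = None
            if (prev is not None and _linked(prev, res)
                    and all(x is not None for x in (n, ca, c))):
                pc = prev.atom("C")
                if pc is not None:
                    phi = dihedral(pc.pos, n.pos, ca.pos, c.pos)
            if (nxt is not None and _linked(res, nxt)
                    and all(x is not None for x in (n, ca, c))):
                nn = nxt.atom("N")
                if nn is not None:
                    psi = dihedral(n.pos, ca.pos, c.pos, nn.pos)
            out.append((res, phi, psi))
    return out


def rama_category(res: Residue, nxt: Residue | None) -> str:
    if res.name == "GLY":
        return "GLY"
    if res.name == "PRO":
        return "PRO"
    if nxt is not None and nxt.name == "PRO":
        return "prePRO"
    return "general"


def classify_ramachandran(phi, psi, category: str,
                          regions: RamachandranRegions) -> str:
    """Label a (phi, psi) pair: favored / allowed / outlier / undefined."""
    if phi is None or psi is None:
        return "undefined"
    lab = regions.label(category, phi, psi)
    return {"F": "favored", "A": "allowed", "O": "outlier"}[lab]


def ramachandran_report(s: Structure,
                        regions: RamachandranRegions | None = None):
    """Classify every amino-acid residue; returns (residue, phi, psi, label)."""
    if regions is None:
        regions = RamachandranRegions.load()
    torsions = backbone_torsions(s)
    # successor lookup for the pre-proline category
    succ = {}
    for ch in s.chains:
        aa = [r for r in ch.residues if r.category == "amino_acid"]
        for i, r in enumerate(aa[:-1]):
            succ[r.key] = aa[i + 1]
    out = []
    for res, phi, psi in torsions:
        cat = rama_category(res, succ.get(res.key))
        out.append((res, phi, psi, classify_ramachandran(phi, psi, cat, regions)))
    return out


def sidechain_chis(s: Structure, lib: RotamerLibrary | None = None):
    """Per-residue chi vectors; missing atoms leave the chi undefined (None)."""
    if lib is None:
        lib = RotamerLibrary.load()
    s = select_primary_conformer(s)
    out = []
    for res in s.residues():
        if res.category != "amino_acid":
            continue
        defs = lib.chi_atoms.get(res.name, [])
        chis = []
        for quad in defs:
            atoms = [res.atom(nm) for nm in quad]
            if any(a is None for a in atoms):
                chis.append(None)
            else:
                chis.append(dihedral(*(a.pos for a in atoms)))
        out.append((res, chis))
    return out


def circular_delta(a: float, b: float) -> float:
    """Shortest angular distance |a - b| on the circle, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def classify_rotamer(chis, name: str, lib: RotamerLibrary | None = None,
                     cutoff: float = 40.0):
    """Nearest rotamer mode by max-over-chis circular distance.

    Returns ``(rotamer name, deviation, outlier)`` or ``None`` when the
    residue type has no library entry or a needed chi is undefined.
    Ties go to the first library entry; deviation > *cutoff* flags an
    outlier.
    """
    if lib is None:
        lib = RotamerLibrary.load()
    modes = lib.modes.get(name)
    if not modes:
        return None
    if chis is None or any(c is None for c in chis) or not chis:
        return None
    chis = np.asarray(chis, dtype=float)
    best_name, best_dev = None, math.inf
    for mname, mode in modes:
        if len(mode) != len(chis):
            continue
        dev = max(circular_delta(c, m) for c, m in zip(chis, mode))
        if dev < best_dev:  # strict: ties keep the first entry
            best_name, best_dev = mname, dev
    if best_name is None:
        return None
    return (best_name, best_dev, best_dev > cutoff)


def rotamer_report(s: Structure, lib: RotamerLibrary | None = None,
                   cutoff: float = 40.0):
    """Rotamer classification per residue: (residue, result-or-None)."""
    if lib is None:
        lib = RotamerLibrary.load()
    return [(res, classify_rotamer(chis, res.name, lib, cutoff))
            for res, chis in sidechain_chis(s, lib)]


# --------------------------------------------------------------------------
# riding hydrogens and clashes

def place_riding_hydrogens(s: Structure) -> Structure:
    """Add idealized backbone amide hydrogens (riding positions).

    H sits in the C(i-1)-N-CA plane, 1.0 A from N, opposite the bisector
    of the C-N and CA-N directions.  Prolines and chain-start residues are
    skipped; an existing atom named H is replaced.  Returns a new
    structure (single-conformer).
    """
    s = select_primary_conformer(s)
    for ch in s.chains:
        aa = [r for r in ch.residues if r.category == "amino_acid"]
        for i in range(1, len(aa)):
            prev, res = aa[i - 1], aa[i]
            if res.name == "PRO" or not _linked(prev, res):
                continue
            c, n, ca = prev.atom("C"), res.atom("N"), res.atom("CA")
            if c is None or n is None or ca is None:
                continue
            u = c.pos - n.pos
            v = ca.pos - n.pos
            bis = u / np.linalg.norm(u) + v / np.linalg.norm(v)
            h_pos = n.pos - bis / np.linalg.norm(bis)
            res.atoms = [a for a in res.atoms if a.name != "H"]
            res.atoms.append(Atom("H", "H", h_pos, occupancy=1.0,
                                  b_factor=n.b_factor))
    return s


@dataclass
class Clash:
    atom1: Atom
    atom2: Atom
    res1: Residue
    res2: Residue
    distance: float
    overlap: float


def _bond_graph(s: Structure, connectivity=None) -> dict[int, set[int]]:
    """Covalent bonds as an adjacency map over flat atom indices.

    Standard residues use the shipped connectivity table plus the
    inter-residue peptide bond; all residues additionally get the
    distance heuristic d < 0.6 (r1 + r2).
    """
    if connectivity is None:
        connectivity = _load_connectivity()
    atoms, owners = [], []
    for res in s.residues():
        for a in res.atoms:
            atoms.append(a)
            owners.append(res)
    adj: dict[int, set[int]] = {i: set() for i in range(len(atoms))}

    def link(i, j):
        adj[i].add(j)
        adj[j].add(i)

    index_of = {}
    for i, (a, res) in enumerate(zip(atoms, owners)):
        index_of[(id(res), a.name)] = i
    # table bonds
    for res in s.residues():
        for a1, a2 in connectivity.get(res.name, ()):
            i = index_of.get((id(res), a1))
            j = index_of.get((id(res), a2))
            if i is not None and j is not None:
                link(i, j)
    # peptide bonds between consecutive amino acids
    for ch in s.chains:
        aa = [r for r in ch.residues if r.category == "amino_acid"]
        for p, r in zip(aa, aa[1:]):
            if _linked(p, r):
                i = index_of.get((id(p), "C"))
                j = index_of.get((id(r), "N"))
                if i is not None and j is not None:
                    link(i, j)
    # distance heuristic (covers ligands and non-tabled names)
    pos = np.array([a.pos for a in atoms])
    radii = np.array([vdw_radius(a.element) for a in atoms])
    tree = cKDTree(pos)
    for i, j in tree.query_pairs(r=float(0.6 * 2 * radii.max())):
        d = np.linalg.norm(pos[i] - pos[j])
        if d < 0.6 * (radii[i] + radii[j]):
            link(i, j)
    return adj, atoms, owners


def _load_connectivity(path=None) -> dict[str, list[tuple[str, str]]]:
    if path is None:
        text = resources.files("xrayval.data").joinpath(
            "connectivity.txt").read_text()
    else:
        text = open(path).read()
    table: dict[str, list[tuple[str, str]]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, a1, a2 = line.split()
        table.setdefault(res, []).append((a1, a2))
    return table


def _is_hbond_pair(i: int, j: int, atoms, adj) -> bool:
    """Polar hydrogen against an N/O acceptor: scored as an H bond, not
    a clash (backbone amide H is a donor by construction)."""
    for a, b in ((i, j), (j, i)):
        if atoms[a].element.upper() != "H":
            continue
        if atoms[b].element.upper() not in ("N", "O"):
            continue
        parent_polar = any(atoms[k].element.upper() in ("N", "O")
                           for k in adj[a])
        if parent_polar:
            return True
    return False


def find_clashes(s: Structure, cutoff: float = 0.4) -> list[Clash]:
    """All atom pairs whose van der Waals overlap is at least *cutoff* (A).

    overlap = r1 + r2 - d.  Pairs up to three bonds apart (1-2, 1-3 and
    1-4) are excluded, as are hydrogen-bond pairs (a polar hydrogen
    against an N/O acceptor); bonding combines the shipped connectivity
    table with a distance heuristic.  Pairs are unordered and
    duplicate-free.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    adj, atoms, owners = _bond_graph(s)
    if not atoms:
        return []
    pos = np.array([a.pos for a in atoms])
    radii = np.array([vdw_radius(a.element) for a in atoms])
    tree = cKDTree(pos)
    out = []
    for i, j in sorted(tree.query_pairs(r=float(2 * radii.max() - cutoff))):
        if j in adj[i]:
            continue
        if adj[i] & adj[j]:  # 1-3
            continue
        if any(adj[k] & adj[j] for k in adj[i]):  # 1-4
            continue
        if _is_hbond_pair(i, j, atoms, adj):
            continue
        d = float(np.linalg.norm(pos[i] - pos[j]))
        overlap = radii[i] + radii[j] - d
        if overlap >= cutoff:
            out.append(Clash(atoms[i], atoms[j], owners[i], owners[j],
                             d, float(overlap)))
    return out


def clashscore(clashes, n_atoms: int) -> float:
    """Clashes per 1000 atoms (atom count includes placed hydrogens)."""
    if n_atoms <= 0:
        raise ValueError("n_atoms must be positive")
    return 1000.0 * len(clashes) / n_atoms
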