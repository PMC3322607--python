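"""Model-versus-density validation: RSR and RSR-Z scoring.

A calculated density map is synthesised as a sum of isotropic atomic
Gaussians; the grid is partitioned into per-residue regions (points owned
by their nearest non-H atom within a capture radius); the real-space R
value compares observed and calculated density over each region after a
per-region least-squares scale.  RSR values are standardised into RSR-Z
scores against a reference table of mean/sd per (residue class,
resolution shell), where ligands are pooled into groups by non-H atom
count and by the presence of elements outside the common organic set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model_io import Residue, Structure, electron_count, select_primary_conformer

__all__ = [
    "MapGrid", "RsrReferenceTable", "LigandGroupKey", "ResidueFitScore",
    "calc_density_map", "partition_grid", "rsr",
    "ligand_group_key", "residue_class", "shell_index", "shell_of_resolution",
    "build_rsr_reference", "rsrz", "score_residue_fit",
    "write_map", "read_map", "RSR_UNDEFINED",
]

#: sentinel for regions where RSR cannot be formed (zero denominators)
RSR_UNDEFINED = None

#: resolution-shell edges (A): 0.2 A bins over [0.8, 4.0], open-ended ends
SHELL_EDGES = np.round(np.arange(0.8, 4.01, 0.2), 10)

#: elements regarded as ordinary pharmaceutical-organic chemistry
ORGANIC_ELEMENTS = frozenset({"H", "C", "N", "O", "S", "P",
                              "F", "CL", "BR", "I"})

#: upper edges (inclusive) of the ligand-size bins over non-H atom counts
LIGAND_SIZE_EDGES = (5, 10, 20, 40)


@dataclass
class MapGrid:
    """Regular 3-D density grid in orthogonal coordinates."""
    origin: np.ndarray     # A, position of grid point (0,0,0)
    spacing: np.ndarray    # A per axis, shape (3,)
    values: np.ndarray     # shape = dims

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=float))
        if self.spacing.size == 1:
            self.spacing = np.repeat(self.spacing, 3)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("grid must be 3-D with at least 2 points per axis")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def congruent(self, other: "MapGrid") -> bool:
        return (self.dims == other.dims
                and np.allclose(self.origin, other.origin)
                and np.allclose(self.spacing, other.spacing))

    def point_coords(self, flat_idx: np.ndarray) -> np.ndarray:
        """Orthogonal coordinates of grid points given flat indices."""
        ijk = np.stack(np.unravel_index(np.asarray(flat_idx), self.dims), axis=-1)
        return self.origin + ijk * self.spacing

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def calc_density_map(s: Structure, spacing: float = 0.5, padding: float = 3.0,
                     b_soften: float = 10.0,
                     like: MapGrid | None = None) -> MapGrid:
    """Synthesise a calculated density map as a sum of atomic Gaussians.

    Each atom contributes occ * w * (2 pi sigma^2)^(-3/2) *
    exp(-|r - r_a|^2 / (2 sigma^2)) with sigma^2 = (B + b_soften)/(8 pi^2)
    and w its electron count; contributions are truncated beyond 5 sigma.
    The grid spans the model bounding box plus *padding* on each side;
    alternatively *like* forces the exact raster of an existing grid
    (needed to score against an observed map).
    """
    if not 0.1 < spacing <= 2.0:
        raise ValueError("spacing must lie in (0.1, 2.0]")
    atoms = list(select_primary_conformer(s).atoms())
    if not atoms:
        raise ValueError("cannot build a density map for an empty structure")
    if like is not None:
        grid = MapGrid(like.origin.copy(), like.spacing.copy(),
                       np.zeros(like.dims))
    else:
        pos = np.array([a.pos for a in atoms])
        lo = pos.min(axis=0) - padding
        hi = pos.max(axis=0) + padding
        dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
        grid = MapGrid(lo, np.repeat(spacing, 3), np.zeros(tuple(dims)))
    lo = grid.origin
    dims = grid.dims
    spacing_vec = grid.spacing
    axes = [lo[k] + spacing_vec[k] * np.arange(dims[k]) for k in range(3)]
    for a in atoms:
        sigma2 = (a.b_factor + b_soften) / (8.0 * math.pi ** 2)
        sigma = math.sqrt(sigma2)
        amp = a.occupancy * electron_count(a.element) \
            * (2.0 * math.pi * sigma2) ** -1.5
        cut = 5.0 * sigma
        sl, axvals = [], []
        for k in range(3):
            i0 = int(np.searchsorted(axes[k], a.pos[k] - cut, side="left"))
            i1 = int(np.searchsorted(axes[k], a.pos[k] + cut, side="right"))
            sl.append(slice(i0, i1))
            axvals.append(axes[k][i0:i1] - a.pos[k])
        if any(v.size == 0 for v in axvals):
            continue
        gx = np.exp(-axvals[0] ** 2 / (2 * sigma2))
        gy = np.exp(-axvals[1] ** 2 / (2 * sigma2))
        gz = np.exp(-axvals[2] ** 2 / (2 * sigma2))
        grid.values[sl[0], sl[1], sl[2]] += amp * (
            gx[:, None, None] * gy[None, :, None] * gz[None, None, :])
    return grid


def partition_grid(s: Structure, g: MapGrid, radius: float = 2.0
                   ) -> dict[tuple, np.ndarray]:
    """Assign grid points to residues: nearest non-H atom within *radius*.

    Returns residue key -> sorted array of flat grid indices.  A point
    equidistant to atoms of two residues goes to the residue earlier in
    file order; each point belongs to at most one region.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    s = select_primary_conformer(s)
    atoms, res_order, res_keys = [], {}, []
    for ridx, res in enumerate(s.residues()):
        res_order[res.key] = ridx
        res_keys.append(res.key)
        for a in res.heavy_atoms():
            atoms.append((a.pos, ridx))
    if not atoms:
        return {}
    pos = np.array([p for p, _ in atoms])
    owner = np.array([r for _, r in atoms])
    tree = cKDTree(pos)
    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in g.dims], indexing="ij")
    pts = g.origin + np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * g.spacing
    dist, nearest = tree.query(pts, k=1)
    inside = dist <= radius
    regions: dict[tuple, list] = {}
    idx_inside = np.nonzero(inside)[0]
    # resolve near-ties deterministically: earliest residue in file order wins
    ties = tree.query_ball_point(pts[idx_inside], dist[idx_inside] + 1e-9)
    for flat, cands in zip(idx_inside, ties):
        ridx = min(owner[c] for c in cands)
        regions.setdefault(res_keys[ridx], []).append(int(flat))
    return {k: np.array(sorted(v), dtype=int) for k, v in regions.items()}


def rsr(obs: MapGrid, calc: MapGrid, points: np.ndarray):
    """Real-space R over a grid-point region, with per-region scaling.

    The observed density is matched to the calculated by the
    least-squares factor k = sum(rho_o rho_c) / sum(rho_c^2); then
    RSR = sum|rho_o - k rho_c| / sum|rho_o + k rho_c|.  Returns
    :data:`RSR_UNDEFINED` when the denominators vanish.
    """
    if not obs.congruent(calc):
        raise ValueError("observed and calculated grids are not congruent")
    points = np.asarray(points)
    if points.size == 0:
        raise ValueError("empty grid-point region")
    ro = obs.values.ravel()[points]
    rc = calc.values.ravel()[points]
    denom_k = float(np.sum(rc * rc))
    if denom_k == 0.0:
        return RSR_UNDEFINED
    k = float(np.sum(ro * rc)) / denom_k
    denom = float(np.sum(np.abs(ro + k * rc)))
    if denom == 0.0:
        return RSR_UNDEFINED
    return float(np.sum(np.abs(ro - k * rc)) / denom)


@dataclass(frozen=True)
class LigandGroupKey:
    size_bin: int        # index into the non-H atom-count bins
    has_nonpharma: bool  # any element outside the organic whitelist

    def __str__(self):
        return f"LIG{self.size_bin}{'X' if self.has_nonpharma else ''}"


def ligand_group_key(res: Residue) -> LigandGroupKey:
    """Pooling key for a ligand: non-H atom-count bin and element class.

    Bins over the non-H atom count: 1-5, 6-10, 11-20, 21-40, >40.
    ``has_nonpharma`` is true when any element falls outside the common
    organic set (H C N O S P F Cl Br I).
    """
    if res.category != "ligand":
        raise ValueError(f"{res.label} is not a ligand")
    n_heavy = len(res.heavy_atoms())
    size_bin = sum(n_heavy > e for e in LIGAND_SIZE_EDGES)
    nonpharma = any(a.element.upper() not in ORGANIC_ELEMENTS
                    for a in res.atoms)
    return LigandGroupKey(size_bin, nonpharma)


def residue_class(res: Residue) -> str | None:
    """Reference-table class: amino-acid name, NUC, or a ligand group.

    Waters are not scored and return None.
    """
    cat = res.category
    if cat == "amino_acid":
        return res.name
    if cat == "nucleotide":
        return "NUC"
    if cat == "water":
        return None
    return str(ligand_group_key(res))


def shell_index(d: float) -> int:
    """Resolution shell of d (A): 0.2 A bins on [0.8, 4.0), open-ended ends.

    Shell 0 is d < 0.8; the last shell is d >= 4.0.  Interior shells are
    half-open [lo, hi), so a boundary value belongs to the shell it starts.
    """
    if d < SHELL_EDGES[0]:
        return 0
    i = int(np.searchsorted(SHELL_EDGES, d, side="right"))  # 1..len(edges)
    return i


N_SHELLS = len(SHELL_EDGES) + 1

shell_of_resolution = shell_index


class RsrReferenceTable:
    """Mean/sd of RSR per (residue class, resolution shell)."""

    def __init__(self, cells: dict[tuple[str, int], tuple[float, float, int]]):
        self.cells = cells

    def lookup(self, cls: str, shell: int):
        return self.cells.get((cls, shell))

    def to_text(self) -> str:
        lines = ["# RSR reference table", "# class shell mean sd count"]
        for (cls, shell), (m, sd, n) in sorted(self.cells.items()):
            lines.append(f"{cls} {shell} {m:.6f} {sd:.6f} {n}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RsrReferenceTable":
        cells = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            c, shell, m, sd, n = line.split()
            cells[(c, int(shell))] = (float(m), float(sd), int(n))
        return cls(cells)


def build_rsr_reference(scored, min_count: int = 20) -> RsrReferenceTable:
    """Pool (class, resolution, rsr) observations into a reference table.

    Sample mean and sd (n-1 denominator) are computed per class and
    resolution shell; cells with fewer than *min_count* observations are
    omitted.  *min_count* must be at least 2 so the sd is defined.
    """
    if min_count < 2:
        raise ValueError("min_count must be >= 2")
    rows = [(cls, shell_index(res), val) for cls, res, val in scored]
    if not rows:
        return RsrReferenceTable({})
    df = pd.DataFrame(rows, columns=["cls", "shell", "rsr"])
    agg = df.groupby(["cls", "shell"])["rsr"].agg(["mean", "std", "count"])
    cells = {}
    for (c, sh), row in agg.iterrows():
        if row["count"] >= min_count:
            cells[(c, int(sh))] = (float(row["mean"]), float(row["std"]),
                                   int(row["count"]))
    return RsrReferenceTable(cells)


def rsrz(rsr_value: float, cls: str, resolution: float,
         table: RsrReferenceTable, threshold: float = 2.0):
    """Standardise an RSR value against the reference table.

    Returns ``(z, outlier)`` or ``None`` when no reference cell exists.
    The flag is one-sided: only z >= threshold (poor fit) is an outlier.
    """
    cell = table.lookup(cls, shell_index(resolution))
    if cell is None:
        return None
    mean, sd, _ = cell
    z = (rsr_value - mean) / sd
    return (float(z), z >= threshold)


@dataclass
class ResidueFitScore:
    residue: Residue
    rsr: float | None
    rsrz: float | None
    rsrz_outlier: bool | None
    shell: int
    n_grid_points: int


def score_residue_fit(s: Structure, obs: MapGrid, calc: MapGrid,
                      radius: float = 2.0,
                      table: RsrReferenceTable | None = None,
                      rsrz_threshold: float = 2.0) -> list[ResidueFitScore]:
    """Per-residue RSR (and RSR-Z when a reference table is supplied).

    Waters are skipped; residues with no grid region get no score entry.
    """
    regions = partition_grid(s, obs, radius)
    resolution = s.resolution if s.resolution is not None else 0.0
    shell = shell_index(resolution)
    out = []
    for res in select_primary_conformer(s).residues():
        if res.category == "water":
            continue
        pts = regions.get(res.key)
        if pts is None or pts.size == 0:
            continue
        val = rsr(obs, calc, pts)
        z = flag = None
        if val is not None and table is not None:
            cls = residue_class(res)
            if cls is not None:
                zres = rsrz(val, cls, resolution, table, rsrz_threshold)
                if zres is not None:
                    z, flag = zres
        out.append(ResidueFitScore(res, val, z, flag, shell, int(pts.size)))
    return out


# --------------------------------------------------------------------------
# map text format: versioned header, then whitespace-separated values

_MAP_MAGIC = "xrayval-map 1"


def write_map(g: MapGrid) -> str:
    """Serialise a grid in the toolkit's versioned text map format."""
    head = [
        f"# {_MAP_MAGIC}",
        "# origin_x origin_y origin_z / spacing_x y z / nx ny nz",
        " ".join(f"{v:.6f}" for v in g.origin),
        " ".join(f"{v:.6f}" for v in g.spacing),
        " ".join(str(d) for d in g.dims),
    ]
    body = "\n".join(" ".join(f"{v:.6e}" for v in row)
                     for row in g.values.reshape(g.dims[0] * g.dims[1],
                                                 g.dims[2]))
    return "\n".join(head) + "\n" + body + "\n"


def read_map(text: str) -> MapGrid:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].lstrip("# ").strip() != _MAP_MAGIC:
        raise ValueError("not an xrayval map file (bad or missing magic line)")
    data = [ln for ln in lines if not ln.lstrip().startswith("#")]
    origin = np.array([float(x) for x in data[0].split()])
    spacing = np.array([float(x) for x in data[1].split()])
    dims = tuple(int(x) for x in data[2].split())
    vals = np.array([float(x) for ln in data[3:] for x in ln.split()])
    if vals.size != int(np.prod(dims)):
        raise ValueError("map body length does not match declared dims")
    return MapGrid(origin, spacing, vals.reshape(dims))
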