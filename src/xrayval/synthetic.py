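"""Synthetic fixtures: idealized models, noisy maps, Wilson-type data.

These generators stand in for depositions, density maps, diffraction
experiments and the archive itself, so the whole pipeline is exercised
without any external data.  All generators are deterministic for a fixed
seed.  The helix builder extends the chain atom-by-atom from internal
coordinates (bond, angle, torsion) taken from the shipped restraint
dictionary, so an unperturbed helix scores clean on every model check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .data_checks import ReflectionSet, half_sphere_indices, resolutions_of
from .density_fit import MapGrid, calc_density_map
from .geometry import GeometryDictionary
from .model_io import Atom, Cell, Chain, Residue, Structure
from .ranking import ArchiveStatistics, DEFAULT_METRICS, build_archive_statistics

__all__ = [
    "SimulationConfig", "make_helix", "perturb_structure",
    "simulate_observed_map", "simulate_wilson_set", "sample_archive",
    "place_atom",
]

HELIX_PHI = -57.0
HELIX_PSI = -47.0
HELIX_OMEGA = 180.0


@dataclass
class SimulationConfig:
    """Default study conditions for the synthetic fixtures."""
    seed: int = 0
    n_residues: int = 10
    coord_sd: float = 0.0          # A
    b_sd: float = 0.0              # A^2
    map_noise_sd: float = 0.0      # relative to map value sd
    wilson_b: float = 40.0         # A^2
    twin_alpha: float = 0.0
    archive_size: int = 5000
    resolution_range: tuple[float, float] = (1.0, 3.5)


def place_atom(a, b, c, bond: float, angle: float, torsion: float
               ) -> np.ndarray:
    """Position a new atom D from internal coordinates.

    Given positions of A, B, C, returns D with |C-D| = bond,
    angle(B,C,D) = *angle* and dihedral(A,B,C,D) = *torsion*
    (degrees, same sign convention as :func:`xrayval.geometry.dihedral`).
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = math.radians(angle)
    tau = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(tau),
        -bond * math.sin(theta) * math.sin(tau),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _place_cb(n_pos, ca_pos, c_pos, bond, ang_n, ang_c) -> np.ndarray:
    """CB position satisfying both N-CA-CB and C-CA-CB angles (L branch)."""
    u = n_pos - ca_pos
    u /= np.linalg.norm(u)
    v = c_pos - ca_pos
    v /= np.linalg.norm(v)
    cu = math.cos(math.radians(ang_n))
    cv = math.cos(math.radians(ang_c))
    dot = float(np.dot(u, v))
    det = 1.0 - dot * dot
    alpha = (cu - cv * dot) / det
    beta = (cv - cu * dot) / det
    gamma2 = 1.0 - (alpha * alpha + beta * beta + 2 * alpha * beta * dot)
    gamma = math.sqrt(max(gamma2, 0.0))   # +branch gives the L-configuration
    nrm = np.cross(u, v)
    nrm /= np.linalg.norm(nrm)
    w = alpha * u + beta * v + gamma * nrm
    return ca_pos + bond * w


def make_helix(n_residues: int, seed: int = 0, entry_id: str = "helx",
               b_factor: float = 20.0) -> Structure:
    """Ideal poly-alanine alpha helix (phi -57, psi -47, omega 180).

    Bond lengths and angles come from the shipped restraint dictionary,
    so the construction scores zero covalent and Ramachandran outliers.
    All B factors are *b_factor*, all occupancies 1.  The structure gets
    a P1 cubic cell enclosing the model and a nominal 2.0 A resolution.
    """
    if n_residues < 2:
        raise ValueError("a helix needs at least 2 residues")
    gd = GeometryDictionary.load()
    b_nca = gd.bond("ALA", "N", "CA")[0]
    b_cac = gd.bond("ALA", "CA", "C")[0]
    b_co = gd.bond("ALA", "C", "O")[0]
    b_cacb = gd.bond("ALA", "CA", "CB")[0]
    b_cn = gd.peptide_bonds[("C-", "N+")][0]
    a_ncac = gd.angle("ALA", "N", "CA", "C")[0]
    a_ncacb = gd.angle("ALA", "N", "CA", "CB")[0]
    a_cbcac = gd.angle("ALA", "CB", "CA", "C")[0]
    a_cacn = gd.peptide_angles[("CA-", "C-", "N+")][0]
    a_caco = gd.peptide_angles[("CA-", "C-", "O-")][0]
    a_cnca = gd.peptide_angles[("C-", "N+", "CA+")][0]

    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([b_nca, 0.0, 0.0])
    th = math.radians(180.0 - a_ncac)
    c = ca + b_cac * np.array([math.cos(th), math.sin(th), 0.0])
    backbone = [(n, ca, c)]
    for _ in range(n_residues - 1):
        n_next = place_atom(n, ca, c, b_cn, a_cacn, HELIX_PSI)
        ca_next = place_atom(ca, c, n_next, b_nca, a_cnca, HELIX_OMEGA)
        c_next = place_atom(c, n_next, ca_next, b_cac, a_ncac, HELIX_PHI)
        backbone.append((n_next, ca_next, c_next))
        n, ca, c = n_next, ca_next, c_next

    chain = Chain("A")
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        res = Residue("ALA", i + 1, "", "A")
        # carbonyl O anti to the next amide N (torsion psi + 180)
        o_i = place_atom(n_i, ca_i, c_i, b_co, a_caco, HELIX_PSI + 180.0)
        cb_i = _place_cb(n_i, ca_i, c_i, b_cacb, a_ncacb, a_cbcac)
        for name, el, pos in (("N", "N", n_i), ("CA", "C", ca_i),
                              ("C", "C", c_i), ("O", "O", o_i),
                              ("CB", "C", cb_i)):
            res.atoms.append(Atom(name, el, pos, 1.0, b_factor))
        chain.residues.append(res)

    s = Structure(entry_id=entry_id, chains=[chain], resolution=2.0)
    pos = np.array([a.pos for a in s.atoms()])
    # recentre into a generous cubic P1 cell
    extent = float((pos.max(axis=0) - pos.min(axis=0)).max()) + 10.0
    shift = -pos.min(axis=0) + 5.0
    for a in s.atoms():
        a.pos = a.pos + shift
    s.cell = Cell(extent, extent, extent)
    return s


def perturb_structure(s: Structure, coord_sd: float, seed: int = 0,
                      b_sd: float = 0.0) -> Structure:
    """Add i.i.d. Gaussian noise to atom positions (and optionally B).

    ``coord_sd = 0`` returns an identical copy; the perturbation is
    deterministic per seed.
    """
    if coord_sd < 0 or b_sd < 0:
        raise ValueError("noise sigmas must be non-negative")
    rng = np.random.default_rng(seed)
    chains = []
    for ch in s.chains:
        new_ch = Chain(ch.chain_id)
        for res in ch.residues:
            new_res = replace(res, atoms=[])
            for a in res.atoms:
                pos = a.pos + (rng.normal(0.0, coord_sd, 3)
                               if coord_sd > 0 else 0.0)
                b = a.b_factor + (rng.normal(0.0, b_sd) if b_sd > 0 else 0.0)
                new_res.atoms.append(replace(a, pos=pos,
                                             b_factor=max(b, 1.0)))
            new_ch.residues.append(new_res)
        chains.append(new_ch)
    return Structure(entry_id=s.entry_id, chains=chains, cell=s.cell,
                     resolution=s.resolution)


def simulate_observed_map(s: Structure, spacing: float = 0.5,
                          noise_sd: float = 0.0, seed: int = 0,
                          padding: float = 3.0) -> MapGrid:
    """Observed map: calculated density plus relative Gaussian noise.

    The noise sd is *noise_sd* times the standard deviation of the
    noise-free map values, so noise levels are comparable across models.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    g = calc_density_map(s, spacing=spacing, padding=padding)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g.values = g.values + rng.normal(
            0.0, noise_sd * g.values.std(), g.values.shape)
    return g


def simulate_wilson_set(cell: Cell, d_min: float, b: float = 40.0,
                        alpha: float = 0.0, seed: int = 0,
                        free_fraction: float = 0.05) -> ReflectionSet:
    """Wilson-distributed intensity set with an optional twin fraction.

    All P1 half-sphere reflections to *d_min* get I = exp(-2 B s^2) E
    with E ~ Exp(1) and s = sin(theta)/lambda.  For alpha > 0, disjoint
    twin-mate pairs (h,k,l)/(-h,-k,l) are mixed as
    I' = (1-alpha) I1 + alpha I2 and symmetrically, emulating a
    (pseudo)merohedral twin; alpha = 0.5 is a perfect twin.
    """
    if b < 0:
        raise ValueError("B must be non-negative")
    if not 0.0 <= alpha <= 0.5:
        raise ValueError("twin fraction must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    hkl = half_sphere_indices(cell, d_min)
    d = resolutions_of(hkl, cell)
    s2 = 1.0 / (4.0 * d ** 2)
    intensities = np.exp(-2.0 * b * s2) * rng.exponential(1.0, len(hkl))
    if alpha > 0.0:
        index = {tuple(x): i for i, x in enumerate(hkl)}
        done = np.zeros(len(hkl), dtype=bool)
        for i, (h, k, l) in enumerate(hkl):
            if done[i] or l == 0:
                # l = 0 mates coincide with Friedel equivalents: unchanged
                continue
            j = index.get((-h, -k, l))
            if j is None or done[j] or j == i:
                continue
            i1, i2 = intensities[i], intensities[j]
            intensities[i] = (1.0 - alpha) * i1 + alpha * i2
            intensities[j] = alpha * i1 + (1.0 - alpha) * i2
            done[i] = done[j] = True
    sigmas = np.sqrt(np.maximum(intensities, 0.0)) * 0.05
    free = rng.random(len(hkl)) < free_fraction
    return ReflectionSet(kind="intensity", cell=cell, hkl=hkl,
                         values=intensities, sigmas=sigmas, free=free)


#: archive metric models: metric -> (median at 1 A, slope per A, log-sd)
_ARCHIVE_TRENDS = {
    "r_free": (0.17, 0.035, 0.12),
    "clashscore": (2.0, 6.0, 0.5),
    "rama_outlier_pct": (0.15, 0.9, 0.6),
    "rotamer_outlier_pct": (0.6, 1.4, 0.5),
    "rsrz_outlier_pct": (1.0, 2.2, 0.5),
}


def sample_archive(n_entries: int = 5000,
                   resolution_range: tuple[float, float] = (1.0, 3.5),
                   seed: int = 0, version: str = "synthetic-1"
                   ) -> ArchiveStatistics:
    """Synthetic archive with resolution-dependent quality trends.

    Resolutions are uniform over the range; each slider metric is drawn
    from a log-normal whose median worsens linearly with resolution, so
    percentile cohorts behave like the real archive (structures at poor
    resolution score worse in absolute terms).
    """
    if n_entries < 1:
        raise ValueError("need at least one entry")
    rng = np.random.default_rng(seed)
    lo, hi = resolution_range
    resolutions = rng.uniform(lo, hi, n_entries)
    entries = []
    for i in range(n_entries):
        d = resolutions[i]
        metrics = {}
        for mid, (m0, slope, sd) in _ARCHIVE_TRENDS.items():
            median = m0 + slope * (d - 1.0)
            metrics[mid] = float(median * math.exp(rng.normal(0.0, sd)))
        entries.append((f"S{i:05d}", float(d), metrics))
    return build_archive_statistics(entries, DEFAULT_METRICS, version)
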