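"""Diffraction-data validation and global model-vs-data agreement.

Checks on an intensity set: the Wilson plot (overall B from the slope of
ln<I> against (sin theta / lambda)^2), the second-moment ratio
<I^2>/<I>^2 after shell normalisation (amplitude/intensity mislabelling),
the L-test on local intensity pairs (twinning), and outlier reflections.
Model-vs-data agreement uses direct-summation structure factors in P1 and
the standard R / Rfree with a working-set scale.

All reciprocal-space work assumes P1; reflections are stored on a
Friedel half-sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_io import Cell, Structure, electron_count, select_primary_conformer

__all__ = [
    "Reflection", "ReflectionSet", "WilsonResult", "MomentResult",
    "LTestResult", "DataCheckResult",
    "parse_reflections", "write_reflections", "resolution_of",
    "wilson_b", "second_moments", "l_test", "flag_outlier_reflections",
    "calc_structure_factors", "r_factors", "run_data_checks",
]


@dataclass
class Reflection:
    h: int
    k: int
    l: int
    value: float
    sigma: float = 0.0
    is_free: bool = False


@dataclass
class ReflectionSet:
    """Columnar reflection data (unique hkl on a half-sphere, P1)."""
    kind: str                      # 'intensity' | 'amplitude'
    cell: Cell
    hkl: np.ndarray                # (n, 3) int
    values: np.ndarray             # I or |F|
    sigmas: np.ndarray
    free: np.ndarray               # bool
    phases: np.ndarray | None = None   # radians, for calculated sets

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.free = np.asarray(self.free, dtype=bool)
        if self.kind not in ("intensity", "amplitude"):
            raise ValueError("kind must be 'intensity' or 'amplitude'")
        keys = {tuple(x) for x in self.hkl}
        if len(keys) != len(self.hkl):
            raise ValueError("duplicate hkl in reflection set")
        if (0, 0, 0) in keys:
            raise ValueError("(0,0,0) is not a valid reflection")

    def __len__(self):
        return len(self.hkl)

    @property
    def d_spacings(self) -> np.ndarray:
        return resolutions_of(self.hkl, self.cell)

    @property
    def d_min(self) -> float:
        return float(self.d_spacings.min())


def resolution_of(h: int, k: int, l: int, cell: Cell) -> float:
    """d-spacing (A) of reflection (h,k,l): 1/|S| in the standard frame."""
    if (h, k, l) == (0, 0, 0):
        raise ValueError("(0,0,0) has no resolution")
    return float(resolutions_of(np.array([[h, k, l]]), cell)[0])


def resolutions_of(hkl: np.ndarray, cell: Cell) -> np.ndarray:
    # reciprocal vectors: rows of inv(orth_matrix); S = B^T h
    recip = cell.frac_matrix            # frac = recip @ xyz
    svec = np.asarray(hkl, dtype=float) @ recip
    return 1.0 / np.linalg.norm(svec, axis=1)


# --------------------------------------------------------------------------
# text format: "# kind=I|F a b c alpha beta gamma", then h k l value sigma free

def parse_reflections(text: str) -> ReflectionSet:
    """Parse the toolkit's columnar reflection format.

    Header: ``# kind=I|F a b c alpha beta gamma``; one reflection per
    line: ``h k l value sigma free``.  Duplicate indices or non-integer
    indices raise with the line number.
    """
    lines = text.splitlines()
    header = None
    rows = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if "kind=" in stripped and header is None:
                header = stripped
            continue
        parts = stripped.split()
        if len(parts) != 6:
            raise ValueError(f"line {lineno}: expected 6 columns")
        try:
            h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
        except ValueError:
            raise ValueError(
                f"line {lineno}: non-integer Miller index") from None
        rows.append((lineno, h, k, l, float(parts[3]), float(parts[4]),
                     bool(int(parts[5]))))
    if header is None:
        raise ValueError("missing header line '# kind=I|F a b c al be ga'")
    toks = header.lstrip("# ").split()
    kind = {"kind=I": "intensity", "kind=F": "amplitude"}[toks[0]]
    cell = Cell(*[float(x) for x in toks[1:7]])
    seen = {}
    for lineno, h, k, l, *_ in rows:
        if (h, k, l) in seen:
            raise ValueError(f"line {lineno}: duplicate reflection "
                             f"({h},{k},{l}) first seen on line {seen[(h, k, l)]}")
        seen[(h, k, l)] = lineno
    hkl = np.array([[r[1], r[2], r[3]] for r in rows], dtype=int)
    return ReflectionSet(
        kind=kind, cell=cell, hkl=hkl,
        values=np.array([r[4] for r in rows]),
        sigmas=np.array([r[5] for r in rows]),
        free=np.array([r[6] for r in rows], dtype=bool),
    )


def write_reflections(rs: ReflectionSet) -> str:
    c = rs.cell
    head = (f"# kind={'I' if rs.kind == 'intensity' else 'F'} "
            f"{c.a:.4f} {c.b:.4f} {c.c:.4f} {c.alpha:.3f} {c.beta:.3f} "
            f"{c.gamma:.3f}")
    body = "\n".join(
        f"{h} {k} {l} {v:.6e} {s:.6e} {int(f)}"
        for (h, k, l), v, s, f in zip(rs.hkl, rs.values, rs.sigmas, rs.free))
    return head + "\n" + body + "\n"


# --------------------------------------------------------------------------
# intensity statistics

def _equal_count_shells(order_stat: np.ndarray, n_shells: int):
    """Indices of equal-count shells after sorting by *order_stat*."""
    return np.array_split(np.argsort(order_stat, kind="stable"), n_shells)


def _shell_normalised(rs: "ReflectionSet", per_shell: int = 200) -> np.ndarray:
    """Intensities divided by their resolution-shell mean.

    Shells are equal-count in s^2 with about *per_shell* reflections
    each, narrow enough that the Wilson falloff is flat within a shell.
    """
    s2 = 1.0 / (4.0 * rs.d_spacings ** 2)
    n_shells = max(1, len(rs) // per_shell)
    out = np.empty(len(rs))
    for idx in _equal_count_shells(s2, n_shells):
        m = rs.values[idx].mean()
        out[idx] = rs.values[idx] / m if m != 0 else 0.0
    return out


@dataclass
class WilsonResult:
    b: float
    shells: list = field(default_factory=list)  # (mean s^2, ln mean I)


def wilson_b(rs: ReflectionSet, n_shells: int = 10,
             min_reflections: int = 500) -> WilsonResult | None:
    """Estimate the overall B from the Wilson plot.

    Reflections with d < 4.5 A are binned into equal-count shells in
    s^2 = 1/(4 d^2); a least-squares line of ln<I> on <s^2> gives slope
    -2B under the flat-scattering-factor convention, so B = -slope/2.
    Returns None (not evaluated) when fewer than *min_reflections*
    usable reflections exist.
    """
    if rs.kind != "intensity":
        raise ValueError("Wilson plot needs intensities")
    if n_shells < 3:
        raise ValueError("need at least 3 shells")
    d = rs.d_spacings
    sel = d < 4.5
    vals = rs.values[sel]
    s2 = 1.0 / (4.0 * d[sel] ** 2)
    if vals.size < min_reflections:
        return None
    pts = []
    for idx in _equal_count_shells(s2, n_shells):
        mean_i = vals[idx].mean()
        if mean_i <= 0:
            continue
        pts.append((s2[idx].mean(), math.log(mean_i)))
    if len(pts) < 3:
        return None
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    slope = np.polyfit(x, y, 1)[0]
    return WilsonResult(b=float(-slope / 2.0), shells=pts)


@dataclass
class MomentResult:
    ratio: float
    verdict: str   # consistent_I | suspect_F_as_I | inconclusive


def second_moments(rs: ReflectionSet, n_shells: int = 20,
                   min_reflections: int = 500) -> MomentResult | None:
    """Shell-normalised second-moment ratio <I^2>/<I>^2 and its verdict.

    Values are divided by their shell mean to remove the Wilson falloff;
    the pooled ratio is ~2 for acentric intensities and ~4/pi (= 1.27)
    when amplitudes were mislabelled as intensities.
    """
    if len(rs) < min_reflections:
        return None
    d = rs.d_spacings
    s2 = 1.0 / (4.0 * d ** 2)
    normed = np.empty(len(rs))
    for idx in _equal_count_shells(s2, n_shells):
        m = rs.values[idx].mean()
        normed[idx] = rs.values[idx] / m if m != 0 else 0.0
    mean = normed.mean()
    if mean == 0:
        return MomentResult(float("nan"), "inconclusive")
    ratio = float(np.mean(normed ** 2) / mean ** 2)
    if 1.8 <= ratio <= 2.3:
        verdict = "consistent_I"
    elif 1.1 <= ratio <= 1.45:
        verdict = "suspect_F_as_I"
    else:
        verdict = "inconclusive"
    return MomentResult(ratio, verdict)


@dataclass
class LTestResult:
    l_mean: float    # <|L|>
    l_second: float  # <L^2>
    n_pairs: int
    verdict: str     # untwinned | partial | near_perfect


def l_test(rs: ReflectionSet, n_pairs: int = 5000, seed: int = 0,
           min_reflections: int = 1000) -> LTestResult | None:
    """Local-intensity-difference L statistic for twinning detection.

    Pairs (h, h + delta) with delta components in {0, +-1, +-2} give
    L = (I1 - I2)/(I1 + I2); for untwinned acentric data <|L|> = 1/2,
    for a perfect twin 3/8.  Intensities are first normalised by
    resolution-shell means so the Wilson falloff does not bias the local
    differences.  Verdict: untwinned when <|L|> >= 0.46, near_perfect
    when <= 0.40, else partial.  Deterministic per seed.
    """
    if rs.kind != "intensity":
        raise ValueError("L test needs intensities")
    if len(rs) < min_reflections:
        return None
    rng = np.random.default_rng(seed)
    index = {tuple(x): i for i, x in enumerate(rs.hkl)}
    values = _shell_normalised(rs)
    ls = []
    attempts = 0
    max_attempts = 200 * n_pairs
    n = len(rs)
    while len(ls) < n_pairs and attempts < max_attempts:
        attempts += 1
        i = int(rng.integers(n))
        delta = rng.integers(-2, 3, size=3)
        if not delta.any():
            continue
        j = index.get(tuple(rs.hkl[i] + delta))
        if j is None or j == i:
            continue
        i1, i2 = values[i], values[j]
        tot = i1 + i2
        if tot == 0:
            ls.append(0.0)
        else:
            ls.append((i1 - i2) / tot)
    if len(ls) < max(100, n_pairs // 10):
        return None
    ls = np.abs(np.array(ls))
    l_mean = float(ls.mean())
    l_second = float((ls ** 2).mean())
    if l_mean >= 0.46:
        verdict = "untwinned"
    elif l_mean <= 0.40:
        verdict = "near_perfect"
    else:
        verdict = "partial"
    return LTestResult(l_mean, l_second, len(ls), verdict)


def flag_outlier_reflections(rs: ReflectionSet, t: float = 10.0):
    """Reflections with I greater than t times their shell mean.

    Shell means use narrow equal-count resolution shells (as in the
    other intensity statistics).  Returns (h, k, l, ratio) tuples sorted
    by descending ratio.
    """
    if rs.kind != "intensity":
        raise ValueError("outlier detection needs intensities")
    if t <= 0:
        raise ValueError("t must be positive")
    ratios = _shell_normalised(rs)
    flagged = [(tuple(int(x) for x in rs.hkl[i]), float(r))
               for i, r in enumerate(ratios) if r > t]
    flagged.sort(key=lambda item: -item[1])
    return [(h, k, l, r) for (h, k, l), r in flagged]


# --------------------------------------------------------------------------
# structure factors and R factors (P1, direct summation)

def half_sphere_indices(cell: Cell, d_min: float) -> np.ndarray:
    """Unique-reflection indices (Friedel half-sphere) to d_min in P1.

    The half-sphere keeps l > 0, or l = 0 and k > 0, or l = k = 0 and
    h > 0.
    """
    hmax = int(math.ceil(cell.a / d_min))
    kmax = int(math.ceil(cell.b / d_min))
    lmax = int(math.ceil(cell.c / d_min))
    hs, ks, ls = np.meshgrid(np.arange(-hmax, hmax + 1),
                             np.arange(-kmax, kmax + 1),
                             np.arange(0, lmax + 1), indexing="ij")
    hkl = np.stack([hs.ravel(), ks.ravel(), ls.ravel()], axis=1)
    half = (hkl[:, 2] > 0) | ((hkl[:, 2] == 0) & (hkl[:, 1] > 0)) \
        | ((hkl[:, 2] == 0) & (hkl[:, 1] == 0) & (hkl[:, 0] > 0))
    hkl = hkl[half]
    d = resolutions_of(hkl, cell)
    return hkl[d >= d_min]


def calc_structure_factors(s: Structure, cell: Cell | None = None,
                           d_min: float = 2.0,
                           free_fraction: float = 0.05,
                           free_seed: int = 0) -> ReflectionSet:
    """Direct-summation structure-factor amplitudes in P1.

    F(h) = sum_j occ_j w_j exp(-B_j s^2/4) exp(2 pi i h . x_j) with w_j
    the electron count and x_j fractional coordinates.  Friedel mates are
    implied; phases are retained on the returned set.  A random
    *free_fraction* of reflections is flagged free (deterministic per
    *free_seed*) for cross-validation bookkeeping.
    """
    if cell is None:
        cell = s.cell
    if cell is None:
        raise ValueError("a unit cell is required for structure factors")
    atoms = list(select_primary_conformer(s).atoms())
    if len(atoms) > 10_000:
        raise ValueError("direct summation limited to 10000 atoms")
    hkl = half_sphere_indices(cell, d_min)
    d = resolutions_of(hkl, cell)
    s2 = 1.0 / (4.0 * d ** 2)                      # (sin theta / lambda)^2
    pos = np.array([a.pos for a in atoms])
    frac = cell.fractionalize(pos)                 # (n_atoms, 3)
    w = np.array([a.occupancy * electron_count(a.element) for a in atoms])
    b = np.array([a.b_factor for a in atoms])
    phase = np.exp(2j * np.pi * (hkl @ frac.T))    # (n_hkl, n_atoms)
    damp = np.exp(-np.outer(s2, b))                # exp(-B s^2 / 4) per atom
    # note: s2 here is (sin th/lambda)^2 = 1/(4 d^2); Debye-Waller uses
    # exp(-B (sin th / lambda)^2) = exp(-B s2)
    f = (phase * damp * w).sum(axis=1)
    rng = np.random.default_rng(free_seed)
    free = rng.random(len(hkl)) < free_fraction
    return ReflectionSet(kind="amplitude", cell=cell, hkl=hkl,
                         values=np.abs(f), sigmas=np.zeros(len(hkl)),
                         free=free, phases=np.angle(f))


def r_factors(obs: ReflectionSet, calc: ReflectionSet):
    """R and Rfree between observed and calculated amplitudes.

    The scale k = sum|Fo||Fc| / sum|Fc|^2 is fitted on the working set
    and applied to both sets; Rfree uses the free flags carried by *obs*.
    Returns (r, r_free, k); r_free is None when the free set is empty.
    """
    if obs.kind != "amplitude" or calc.kind != "amplitude":
        raise ValueError("R factors need amplitude sets")
    key_to_idx = {tuple(x): i for i, x in enumerate(calc.hkl)}
    try:
        order = np.array([key_to_idx[tuple(x)] for x in obs.hkl])
    except KeyError as e:
        raise ValueError(f"hkl sets differ: {e} missing from calc") from None
    if len(obs) != len(calc):
        raise ValueError("hkl sets differ in size")
    fo = obs.values
    fc = calc.values[order]
    work = ~obs.free
    denom = float(np.sum(fc[work] ** 2))
    if denom == 0:
        raise ValueError("calculated amplitudes vanish on the working set")
    k = float(np.sum(fo[work] * fc[work])) / denom

    def _r(mask):
        s_obs = np.sum(fo[mask])
        if s_obs == 0:
            return None
        return float(np.sum(np.abs(fo[mask] - k * fc[mask])) / s_obs)

    r = _r(work)
    r_free = _r(obs.free) if obs.free.any() else None
    return r, r_free, k


@dataclass
class DataCheckResult:
    wilson: WilsonResult | None = None
    moments: MomentResult | None = None
    ltest: LTestResult | None = None
    outlier_hkls: list = field(default_factory=list)
    r: float | None = None
    r_free: float | None = None
    scale_k: float | None = None


def run_data_checks(rs: ReflectionSet, structure: Structure | None = None,
                    seed: int = 0, outlier_t: float = 10.0,
                    d_min: float | None = None) -> DataCheckResult:
    """Run the applicable diffraction-data checks on a reflection set.

    Intensity sets get the Wilson plot, moment, L-test and outlier
    checks; amplitude sets (with a structure) get R / Rfree against
    direct-summation structure factors.
    """
    out = DataCheckResult()
    if rs.kind == "intensity":
        out.wilson = wilson_b(rs)
        out.moments = second_moments(rs)
        out.ltest = l_test(rs, seed=seed)
        out.outlier_hkls = flag_outlier_reflections(rs, t=outlier_t)
    elif structure is not None:
        calc = calc_structure_factors(
            structure, rs.cell, d_min=d_min or rs.d_min)
        # score only the hkls present in the observed set
        key_to_idx = {tuple(x): i for i, x in enumerate(calc.hkl)}
        keep = [i for i, x in enumerate(rs.hkl) if tuple(x) in key_to_idx]
        if len(keep) != len(rs.hkl):
            obs = ReflectionSet(kind="amplitude", cell=rs.cell,
                                hkl=rs.hkl[keep], values=rs.values[keep],
                                sigmas=rs.sigmas[keep], free=rs.free[keep])
        else:
            obs = rs
        order = [key_to_idx[tuple(x)] for x in obs.hkl]
        calc_matched = ReflectionSet(
            kind="amplitude", cell=calc.cell, hkl=calc.hkl[order],
            values=calc.values[order], sigmas=calc.sigmas[order],
            free=calc.free[order])
        out.r, out.r_free, out.scale_k = r_factors(obs, calc_matched)
    return out
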