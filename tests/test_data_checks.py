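import math

import gemmi
import numpy as np
import pytest

from xrayval.data_checks import (
    ReflectionSet, calc_structure_factors, flag_outlier_reflections, l_test,
    parse_reflections, r_factors, resolution_of, second_moments, wilson_b,
    write_reflections, half_sphere_indices,
)
from xrayval.model_io import Atom, Cell, Chain, Residue, Structure
from xrayval.synthetic import make_helix, perturb_structure, simulate_wilson_set

CELL = Cell(30.0, 30.0, 30.0)

FIXTURE = """# kind=I 10.0 10.0 10.0 90.0 90.0 90.0
1 0 0 5.0 0.5 0
0 1 0 4.0 0.4 1
0 0 2 3.0 0.3 0
"""


class TestReflectionIO:
    def test_three_line_fixture(self):
        rs = parse_reflections(FIXTURE)
        assert len(rs) == 3
        assert rs.kind == "intensity"
        assert rs.d_min == pytest.approx(5.0)   # (0,0,2) at a=10
        assert rs.free.sum() == 1

    def test_duplicate_hkl_rejected(self):
        bad = FIXTURE + "1 0 0 9.0 0.1 0\n"
        with pytest.raises(ValueError, match="duplicate"):
            parse_reflections(bad)

    def test_non_integer_index_names_line(self):
        bad = FIXTURE.replace("0 0 2", "0 0 2.5")
        with pytest.raises(ValueError, match="line 4"):
            parse_reflections(bad)

    def test_round_trip(self):
        rs = parse_reflections(FIXTURE)
        again = parse_reflections(write_reflections(rs))
        assert np.array_equal(again.hkl, rs.hkl)
        assert np.allclose(again.values, rs.values)
        assert np.array_equal(again.free, rs.free)


class TestResolution:
    def test_cubic_closed_forms(self):
        c = Cell(10, 10, 10)
        assert resolution_of(1, 0, 0, c) == pytest.approx(10.0)
        assert resolution_of(2, 0, 0, c) == pytest.approx(5.0)

    def test_zero_index_error(self):
        with pytest.raises(ValueError):
            resolution_of(0, 0, 0, CELL)

    def test_triclinic_matches_gemmi_metric_tensor(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c = rng.uniform(10, 40, 3)
            al, be, ga = rng.uniform(75, 105, 3)
            cell = Cell(a, b, c, al, be, ga)
            gcell = gemmi.UnitCell(a, b, c, al, be, ga)
            h, k, l = (int(x) for x in rng.integers(-8, 9, 3))
            if (h, k, l) == (0, 0, 0):
                continue
            assert resolution_of(h, k, l, cell) == pytest.approx(
                gcell.calculate_d((h, k, l)), abs=1e-8)


class TestWilson:
    def test_recovers_generator_b(self):
        for seed in (1, 2, 3):
            rs = simulate_wilson_set(CELL, 1.4, b=40.0, seed=seed)
            est = wilson_b(rs)
            assert est.b == pytest.approx(40.0, rel=0.05)

    def test_flat_intensities_give_zero_b(self):
        hkl = half_sphere_indices(CELL, 2.0)
        rs = ReflectionSet("intensity", CELL, hkl, np.ones(len(hkl)),
                           np.zeros(len(hkl)), np.zeros(len(hkl), bool))
        assert wilson_b(rs).b == pytest.approx(0.0, abs=1e-9)

    def test_b_zero_simulation(self):
        rs = simulate_wilson_set(CELL, 1.4, b=0.0, seed=4)
        assert abs(wilson_b(rs).b) < 2.0

    def test_too_few_reflections_not_evaluated(self):
        rs = parse_reflections(FIXTURE)
        assert wilson_b(rs) is None


class TestSecondMoments:
    def test_exponential_intensities_consistent(self):
        rs = simulate_wilson_set(CELL, 1.4, b=0.0, seed=6)
        res = second_moments(rs)
        assert res.ratio == pytest.approx(2.0, abs=0.06)
        assert res.verdict == "consistent_I"

    def test_amplitudes_as_intensities_flagged(self):
        rs = simulate_wilson_set(CELL, 1.4, b=0.0, seed=7)
        sq = ReflectionSet("intensity", CELL, rs.hkl, np.sqrt(rs.values),
                           rs.sigmas, rs.free)
        res = second_moments(sq)
        assert res.ratio == pytest.approx(4.0 / math.pi, abs=0.06)
        assert res.verdict == "suspect_F_as_I"

    def test_constant_values_inconclusive(self):
        hkl = half_sphere_indices(CELL, 2.0)
        rs = ReflectionSet("intensity", CELL, hkl, np.ones(len(hkl)),
                           np.zeros(len(hkl)), np.zeros(len(hkl), bool))
        res = second_moments(rs)
        assert res.ratio == pytest.approx(1.0)
        assert res.verdict == "inconclusive"


class TestLTest:
    def test_untwinned_theory_value(self):
        rs = simulate_wilson_set(CELL, 1.4, b=40.0, alpha=0.0, seed=8)
        res = l_test(rs, n_pairs=5000, seed=9)
        assert res.l_mean == pytest.approx(0.5, abs=0.02)
        assert res.verdict == "untwinned"

    def test_perfect_twin_theory_value(self):
        rs = simulate_wilson_set(CELL, 1.4, b=40.0, alpha=0.5, seed=10)
        res = l_test(rs, n_pairs=5000, seed=11)
        assert res.l_mean == pytest.approx(0.375, abs=0.02)
        assert res.verdict == "near_perfect"

    def test_equal_intensities_give_zero_l(self):
        hkl = half_sphere_indices(CELL, 2.5)
        rs = ReflectionSet("intensity", CELL, hkl, np.ones(len(hkl)),
                           np.zeros(len(hkl)), np.zeros(len(hkl), bool))
        res = l_test(rs, n_pairs=500, seed=1)
        assert res.l_mean == 0.0

    def test_deterministic_per_seed(self):
        rs = simulate_wilson_set(CELL, 1.6, b=20.0, seed=12)
        a = l_test(rs, n_pairs=1000, seed=5)
        b = l_test(rs, n_pairs=1000, seed=5)
        assert a.l_mean == b.l_mean and a.n_pairs == b.n_pairs


class TestOutlierReflections:
    def test_injected_outlier_flagged(self):
        rs = simulate_wilson_set(CELL, 1.6, b=0.0, seed=13)
        values = rs.values.copy()
        values[100] = 50.0 * values.mean()
        spiked = ReflectionSet("intensity", CELL, rs.hkl, values,
                               rs.sigmas, rs.free)
        flagged = flag_outlier_reflections(spiked, t=10.0)
        assert tuple(rs.hkl[100]) in {(h, k, l) for h, k, l, _ in flagged}
        assert flagged[0][:3] == tuple(rs.hkl[100])

    def test_clean_data_few_false_positives(self):
        rs = simulate_wilson_set(CELL, 1.4, b=40.0, seed=14)
        assert len(flag_outlier_reflections(rs, t=10.0)) <= 5

    def test_sorted_by_descending_ratio(self):
        rs = simulate_wilson_set(CELL, 1.6, b=0.0, seed=15)
        flagged = flag_outlier_reflections(rs, t=2.0)
        ratios = [r for *_, r in flagged]
        assert ratios == sorted(ratios, reverse=True)


def brute_force_sf(atoms, cell, hkl):
    """Independent direct summation, atom by atom, reflection by reflection."""
    from xrayval.model_io import electron_count
    out = []
    for h, k, l in hkl:
        f = 0j
        d = resolution_of(h, k, l, cell)
        s2 = 1.0 / (4.0 * d * d)
        for a in atoms:
            x, y, z = cell.fractionalize(a.pos)
            f += (a.occupancy * electron_count(a.element)
                  * math.exp(-a.b_factor * s2)
                  * complex(math.cos(2 * math.pi * (h * x + k * y + l * z)),
                            math.sin(2 * math.pi * (h * x + k * y + l * z))))
        out.append(abs(f))
    return np.array(out)


class TestStructureFactors:
    def test_single_atom_amplitude_depends_only_on_s(self):
        s = Structure(chains=[Chain("A", [Residue(
            "UNX", 1, "", "A", [Atom("C", "C", [0.0, 0.0, 0.0])])])],
            cell=Cell(20, 20, 20))
        fc = calc_structure_factors(s, d_min=5.0)
        idx = {tuple(x): i for i, x in enumerate(fc.hkl)}
        trio = [fc.values[idx[k]] for k in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]]
        assert np.allclose(trio, trio[0])

    def test_centrosymmetric_pair_is_cosine(self):
        cell = Cell(20, 20, 20)
        x = np.array([2.0, 1.0, 3.0])
        atoms = [Atom("C", "C", x, b_factor=10.0),
                 Atom("C", "C", -x, b_factor=10.0)]
        ch = Chain("A", [Residue("UNX", 1, "", "A", [atoms[0]]),
                         Residue("UNX", 2, "", "A", [atoms[1]])])
        s = Structure(chains=[ch], cell=cell)
        fc = calc_structure_factors(s, d_min=5.0)
        idx = {tuple(k): i for i, k in enumerate(fc.hkl)}
        h = (1, 0, 1)
        d = resolution_of(*h, cell)
        s2 = 1.0 / (4 * d * d)
        frac = cell.fractionalize(x)
        expected = abs(2 * 6 * math.exp(-10.0 * s2)
                       * math.cos(2 * math.pi * np.dot(h, frac)))
        assert fc.values[idx[h]] == pytest.approx(expected, abs=1e-8)

    def test_matches_brute_force_on_small_fixture(self):
        rng = np.random.default_rng(21)
        cell = Cell(15, 18, 12, 85, 95, 100)
        atoms = [Atom(f"C{i}", "C", rng.uniform(0, 10, 3),
                      occupancy=float(rng.uniform(0.5, 1.0)),
                      b_factor=float(rng.uniform(10, 50))) for i in range(5)]
        ch = Chain("A", [Residue("UNX", i + 1, "", "A", [a])
                         for i, a in enumerate(atoms)])
        s = Structure(chains=[ch], cell=cell)
        fc = calc_structure_factors(s, d_min=3.0)
        want = brute_force_sf(atoms, cell, fc.hkl)
        assert np.allclose(fc.values, want, atol=1e-8)

    def test_missing_cell_error(self, helix10):
        s = Structure(chains=helix10.chains, cell=None)
        with pytest.raises(ValueError):
            calc_structure_factors(s)


class TestRFactors:
    def test_identity_gives_zero(self, helix10):
        fc = calc_structure_factors(helix10, d_min=3.0, free_seed=3)
        r, r_free, k = r_factors(fc, fc)
        assert r == 0.0 and r_free == 0.0 and k == pytest.approx(1.0)

    def test_global_scale_absorbed(self, helix10):
        fc = calc_structure_factors(helix10, d_min=3.0, free_seed=3)
        obs = ReflectionSet("amplitude", fc.cell, fc.hkl, 3.0 * fc.values,
                            fc.sigmas, fc.free)
        r, r_free, k = r_factors(obs, fc)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert k == pytest.approx(3.0)

    def test_perturbation_increases_r(self):
        s = make_helix(4)
        fc = calc_structure_factors(s, d_min=2.5, free_seed=3)
        moved = perturb_structure(s, coord_sd=0.3, seed=9)
        fc2 = calc_structure_factors(moved, d_min=2.5, free_seed=3)
        r_perturbed, _, _ = r_factors(fc, fc2)
        assert r_perturbed > 0.02

    def test_empty_free_set_not_evaluated(self, helix10):
        fc = calc_structure_factors(helix10, d_min=3.0, free_fraction=0.0)
        r, r_free, _ = r_factors(fc, fc)
        assert r == 0.0 and r_free is None
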