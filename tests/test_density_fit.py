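import numpy as np
import pytest

from xrayval.density_fit import (
    LigandGroupKey, MapGrid, RSR_UNDEFINED, RsrReferenceTable,
    build_rsr_reference, calc_density_map, ligand_group_key, partition_grid,
    read_map, residue_class, rsr, rsrz, score_residue_fit, shell_index,
    write_map, SHELL_EDGES, N_SHELLS,
)
from xrayval.model_io import Atom, Chain, Residue, Structure, electron_count
from xrayval.synthetic import make_helix, simulate_observed_map
from tests.conftest import random_structure


def single_atom_structure(element="C", b=20.0, pos=(5.0, 5.0, 5.0)):
    return Structure(chains=[Chain("A", [Residue(
        "UNX", 1, "", "A", [Atom(element, element, np.array(pos),
                                 b_factor=b)])])])


class TestDensityMap:
    def test_maximum_at_atom_position(self):
        g = calc_density_map(single_atom_structure(), spacing=0.5)
        flat = int(np.argmax(g.values))
        peak = g.point_coords(np.array([flat]))[0]
        assert np.all(np.abs(peak - 5.0) <= 0.26)

    def test_linearity_in_occupancy(self):
        s1 = single_atom_structure()
        s2 = single_atom_structure()
        next(s2.atoms()).occupancy = 0.5
        g1 = calc_density_map(s1, spacing=0.5)
        g2 = calc_density_map(s2, spacing=0.5)
        assert np.allclose(g1.values, 2.0 * g2.values)

    def test_integral_matches_electron_count(self, helix10):
        g = calc_density_map(helix10, spacing=0.3)
        total = g.values.sum() * g.voxel_volume
        expected = sum(a.occupancy * electron_count(a.element)
                       for a in helix10.atoms())
        assert total == pytest.approx(expected, rel=0.02)

    def test_empty_structure_error(self):
        with pytest.raises(ValueError):
            calc_density_map(Structure(chains=[]))

    def test_like_raster(self, helix10):
        obs = calc_density_map(helix10, spacing=0.5)
        again = calc_density_map(helix10, like=obs)
        assert obs.congruent(again)
        assert np.allclose(obs.values, again.values)


class TestPartitionGrid:
    def test_distant_residues_get_disjoint_regions(self):
        ch = Chain("A", [
            Residue("UNX", 1, "", "A", [Atom("C1", "C", [0.0, 0, 0])]),
            Residue("UNX", 2, "", "A", [Atom("C1", "C", [20.0, 0, 0])])])
        s = Structure(chains=[ch])
        g = calc_density_map(s, spacing=0.5)
        regions = partition_grid(s, g, radius=2.0)
        r1 = set(regions[("A", 1, "")])
        r2 = set(regions[("A", 2, "")])
        assert r1 and r2 and not (r1 & r2)
        c1 = g.point_coords(np.array(sorted(r1))).mean(axis=0)
        assert np.linalg.norm(c1 - [0, 0, 0]) < 0.5

    def test_equidistant_point_goes_to_earlier_residue(self):
        ch = Chain("A", [
            Residue("UNX", 1, "", "A", [Atom("C1", "C", [0.0, 0, 0])]),
            Residue("UNX", 2, "", "A", [Atom("C1", "C", [1.0, 0, 0])])])
        s = Structure(chains=[ch])
        g = MapGrid(origin=[0.5, 0, 0], spacing=[1.0, 1.0, 1.0],
                    values=np.zeros((2, 2, 2)))
        regions = partition_grid(s, g, radius=2.0)
        # grid point (0.5,0,0) is exactly between both atoms
        assert 0 in regions[("A", 1, "")]
        assert 0 not in regions.get(("A", 2, ""), [])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_nearest_atom_scan(self, seed):
        s = random_structure(30, seed, box=8.0)
        g = calc_density_map(s, spacing=0.7)
        regions = partition_grid(s, g, radius=2.0)
        atoms = [(a.pos, res.key) for res in s.residues()
                 for a in res.heavy_atoms()]
        ii, jj, kk = np.meshgrid(*[np.arange(d) for d in g.dims],
                                 indexing="ij")
        pts = g.origin + np.stack(
            [ii, jj, kk], -1).reshape(-1, 3) * g.spacing
        want: dict = {}
        for flat, p in enumerate(pts):
            dists = [(float(np.linalg.norm(p - pos)), i)
                     for i, (pos, _) in enumerate(atoms)]
            dmin, imin = min(dists)
            if dmin <= 2.0:
                want.setdefault(atoms[imin][1], set()).add(flat)
        got = {k: set(v) for k, v in regions.items()}
        assert got == want

    def test_regions_are_disjoint(self, helix10):
        g = calc_density_map(helix10, spacing=0.6)
        regions = partition_grid(helix10, g, radius=2.0)
        seen = set()
        for pts in regions.values():
            as_set = set(pts)
            assert not (seen & as_set)
            seen |= as_set


class TestRsr:
    def _grids(self):
        vals = np.arange(27, dtype=float).reshape(3, 3, 3) + 1.0
        obs = MapGrid([0, 0, 0], [1, 1, 1], vals)
        calc = MapGrid([0, 0, 0], [1, 1, 1], vals.copy())
        return obs, calc

    def test_perfect_fit_zero(self):
        obs, calc = self._grids()
        assert rsr(obs, calc, np.arange(27)) == pytest.approx(0.0)

    def test_scale_invariance(self):
        obs, calc = self._grids()
        obs.values *= 2.0
        assert rsr(obs, calc, np.arange(27)) == pytest.approx(0.0)

    def test_degenerate_obs_returns_sentinel(self):
        obs, calc = self._grids()
        obs.values[:] = 0.0
        assert rsr(obs, calc, np.arange(27)) is RSR_UNDEFINED

    def test_incongruent_grids_error(self):
        obs, calc = self._grids()
        calc.origin = calc.origin + 0.5
        with pytest.raises(ValueError):
            rsr(obs, calc, np.arange(27))

    def test_noise_monotonicity(self):
        """Mean residue RSR grows with observed-map noise."""
        s = make_helix(4)
        means = []
        for noise in (0.1, 0.3, 0.5):
            reps = []
            for rep in range(20):
                obs = simulate_observed_map(s, spacing=0.7, noise_sd=noise,
                                            seed=1000 * rep + int(noise * 10))
                calc = calc_density_map(s, spacing=0.7)
                scores = score_residue_fit(s, obs, calc)
                reps.append(np.mean([f.rsr for f in scores]))
            means.append(np.mean(reps))
        assert means[0] < means[1] < means[2]


class TestLigandGrouping:
    def _ligand(self, n_heavy, elements):
        atoms = [Atom(f"X{i}", elements[i % len(elements)],
                      [float(i), 0, 0]) for i in range(n_heavy)]
        return Residue("LIG", 1, "", "A", atoms)

    def test_small_organic(self):
        key = ligand_group_key(self._ligand(7, ["C", "N", "O"]))
        assert key == LigandGroupKey(1, False)

    def test_heme_like(self):
        res = self._ligand(43, ["C", "N"])
        res.atoms[0] = Atom("FE", "FE", [0, 0, 0])
        assert ligand_group_key(res) == LigandGroupKey(4, True)

    def test_water_rejected(self):
        res = Residue("HOH", 1, "", "A", [Atom("O", "O", [0, 0, 0])])
        with pytest.raises(ValueError):
            ligand_group_key(res)

    def test_residue_class_mapping(self):
        aa = Residue("ALA", 1, "", "A", [Atom("CA", "C", [0, 0, 0])])
        assert residue_class(aa) == "ALA"
        wat = Residue("HOH", 1, "", "A", [Atom("O", "O", [0, 0, 0])])
        assert residue_class(wat) is None
        assert residue_class(self._ligand(3, ["C"])) == "LIG0"


class TestShells:
    def test_boundaries_belong_to_their_lower_edge_shell(self):
        i_below = shell_index(0.99)
        i_at = shell_index(1.0)
        i_above = shell_index(1.01)
        assert i_at == i_above
        assert i_at == i_below + 1

    def test_open_ended_bins(self):
        assert shell_index(0.1) == 0
        assert shell_index(0.79) == 0
        assert shell_index(4.0) == N_SHELLS - 1
        assert shell_index(9.9) == N_SHELLS - 1

    def test_every_resolution_maps_to_exactly_one_shell(self):
        rng = np.random.default_rng(0)
        for d in rng.uniform(0.3, 5.0, 500):
            i = shell_index(float(d))
            assert 0 <= i < N_SHELLS


class TestReferenceTable:
    def test_mean_and_sd(self):
        table = build_rsr_reference(
            [("ALA", 2.0, 0.1), ("ALA", 2.0, 0.2), ("ALA", 2.0, 0.3)],
            min_count=2)
        m, sd, n = table.lookup("ALA", shell_index(2.0))
        assert m == pytest.approx(0.2)
        assert sd == pytest.approx(0.1)
        assert n == 3

    def test_underpopulated_cell_omitted(self):
        table = build_rsr_reference([("ALA", 2.0, 0.1)], min_count=20)
        assert table.lookup("ALA", shell_index(2.0)) is None

    def test_sampling_recovery(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0.15, 0.03, 10_000)
        table = build_rsr_reference([("GLY", 1.5, v) for v in vals])
        m, sd, n = table.lookup("GLY", shell_index(1.5))
        assert m == pytest.approx(0.15, rel=0.02)
        assert sd == pytest.approx(0.03, rel=0.02)

    def test_text_round_trip(self):
        table = build_rsr_reference(
            [("ALA", 2.0, v) for v in (0.1, 0.2, 0.3)], min_count=2)
        again = RsrReferenceTable.from_text(table.to_text())
        assert again.lookup("ALA", shell_index(2.0)) \
            == pytest.approx(table.lookup("ALA", shell_index(2.0)))


class TestRsrz:
    def _table(self):
        return RsrReferenceTable({("ALA", shell_index(2.0)): (0.1, 0.05, 50)})

    def test_mean_value_scores_zero(self):
        z, flag = rsrz(0.1, "ALA", 2.0, self._table())
        assert z == 0.0 and not flag

    def test_boundary_counts_as_outlier(self):
        z, flag = rsrz(0.2, "ALA", 2.0, self._table())
        assert z == pytest.approx(2.0)
        assert flag

    def test_low_rsr_never_outlier(self):
        z, flag = rsrz(0.0, "ALA", 2.0, self._table())
        assert z < 0 and not flag

    def test_missing_cell_not_evaluated(self):
        assert rsrz(0.1, "VAL", 2.0, self._table()) is None

    def test_standardisation_property(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(0.15, 0.03, 10_000)
        table = build_rsr_reference([("ALA", 2.0, v) for v in vals])
        zs = np.array([rsrz(v, "ALA", 2.0, table)[0] for v in vals])
        assert abs(zs.mean()) < 0.05
        assert abs(zs.std(ddof=1) - 1.0) < 0.05


class TestMapFormat:
    def test_round_trip(self, helix10):
        g = calc_density_map(helix10, spacing=0.8)
        again = read_map(write_map(g))
        assert again.congruent(g)
        assert np.allclose(again.values, g.values, rtol=1e-5)

    def test_bad_magic_rejected(self):
        with pytest.raises(ValueError):
            read_map("not a map\n1 2 3\n")
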