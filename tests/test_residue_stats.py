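"""Bound-water counts, ASA, hydration correlations and the desolvation trend."""

import numpy as np
import pytest

from hydroshell.core import AtomRecord, ModelError, StructureModel
from hydroshell.residue_stats import (HOPP_WOODS, VDW_RADII,
                                      accessible_surface_area,
                                      count_bound_waters, desolvation_trend,
                                      hydration_correlation, total_bound_waters,
                                      water_protein_distance_distribution)
from hydroshell.synth import generate_condition_ensemble, toy_protein


def _with_waters(scaffold, water_positions, occupancies=None):
    atoms = [a for a in scaffold.atoms]
    occupancies = occupancies or [1.0] * len(water_positions)
    for i, (p, occ) in enumerate(zip(water_positions, occupancies)):
        atoms.append(AtomRecord("O", "O", "HOH", 1000 + i, "W", p,
                                occupancy=occ))
    return StructureModel(atoms)


class TestCountBoundWaters:
    def test_no_waters_all_zero(self, scaffold):
        table = count_bound_waters(scaffold, cutoff=3.6)
        assert table.per_residue["n_waters"].sum() == 0
        assert table.per_type.sum() == 0

    def test_single_contact_counts_once(self, scaffold):
        glu = next(a for a in scaffold.atoms
                   if a.residue_name == "GLU" and a.atom_name == "CB")
        outward = np.array([*glu.position[:2], 0.0])
        outward /= np.linalg.norm(outward)
        m = _with_waters(scaffold, [glu.position + 3.0 * outward])
        table = count_bound_waters(m, cutoff=3.6)
        row = table.per_residue[table.per_residue.residue_id == glu.residue_id]
        assert int(row.n_waters.iloc[0]) == 1
        assert int(table.per_type["GLU"]) >= 1

    def test_multi_assignment_vs_nearest_mode(self, scaffold):
        """A water wedged between two residues counts for both in 'multi'
        mode and once in 'nearest' mode."""
        a1 = scaffold.atoms[1]   # CA of residue 1
        a2 = scaffold.atoms[6]   # CA of residue 2
        midpoint = (a1.position + a2.position) / 2 + np.array([0, 0, 2.0])
        m = _with_waters(scaffold, [midpoint])
        multi = count_bound_waters(m, cutoff=3.6, mode="multi")
        nearest = count_bound_waters(m, cutoff=3.6, mode="nearest")
        assert multi.per_residue["n_waters"].sum() >= 2
        assert nearest.per_residue["n_waters"].sum() == 1

    def test_cutoff_monotonicity(self, clean_ensemble):
        models, _ = clean_ensemble
        m = list(models.values())[0]
        sums = [count_bound_waters(m, cutoff=c).per_residue["n_waters"].sum()
                for c in (2.8, 3.6, 5.0)]
        assert sums[0] <= sums[1] <= sums[2]


class TestTotalBoundWaters:
    def test_empty_is_zero(self, scaffold):
        assert total_bound_waters(scaffold) == (0, 0.0)

    def test_generator_plant_and_occupancy_weighting(self, scaffold):
        rng = np.random.default_rng(2)
        pos = [scaffold.coords[0] + [0, 0, 3.0 + i] for i in range(4)]
        m = _with_waters(scaffold, pos, occupancies=[1.0, 0.5, 0.33, 0.25])
        total = total_bound_waters(m)
        assert total.count == 4
        assert total.occupancy_weighted == pytest.approx(2.08)

    def test_monotone_planted_series(self):
        models, truth = generate_condition_ensemble(
            None, desolvation_slope=100.0, total_noise_sigma=0.0, seed=13)
        counts = [total_bound_waters(m).count for m in models.values()]
        assert counts == sorted(counts)
        assert counts == [truth.payload["totals"][lab] for lab in models]


class TestAccessibleSurfaceArea:
    def test_isolated_carbon_closed_form(self):
        """4π(1.70 + 1.40)² ≈ 120.76 Å² for a lone carbon."""
        atom = AtomRecord("C", "CA", "ALA", 1, "A", np.zeros(3))
        m = StructureModel([atom])
        table = accessible_surface_area(m, probe=1.4, n_points=960)
        assert table.per_residue.asa.iloc[0] == pytest.approx(
            4 * np.pi * 3.10 ** 2, rel=1e-9)

    def test_fully_enclosed_atom_zero(self):
        center = AtomRecord("C", "CA", "ALA", 1, "A", np.zeros(3))
        shell = []
        # cage of 26 atoms on a 2.4 Å lattice blocks every probe position
        k = 0
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    k += 1
                    shell.append(AtomRecord("C", "CA", "GLY", 2, "A",
                                            2.4 * np.array([dx, dy, dz])))
        m = StructureModel([center] + shell)
        table = accessible_surface_area(m, probe=1.4, n_points=960)
        ala = table.per_residue[table.per_residue.residue_name == "ALA"]
        assert ala.asa.iloc[0] == 0.0

    def test_two_atom_pair_analytic_caps(self):
        """Two overlapping spheres: ASA equals the closed-form spherical-cap
        solution within 2% at several separations."""
        for d in (2.0, 3.0, 4.0, 5.5):
            a = AtomRecord("C", "CA", "ALA", 1, "A", np.zeros(3))
            b = AtomRecord("O", "O", "GLY", 2, "A", np.array([d, 0.0, 0.0]))
            m = StructureModel([a, b])
            table = accessible_surface_area(m, probe=1.4, n_points=4000)
            r1 = VDW_RADII["C"] + 1.4
            r2 = VDW_RADII["O"] + 1.4
            exp = []
            for ra, rb in ((r1, r2), (r2, r1)):
                if d >= ra + rb:
                    exp.append(4 * np.pi * ra ** 2)
                else:
                    h = ra - (d ** 2 + ra ** 2 - rb ** 2) / (2 * d)
                    exp.append(4 * np.pi * ra ** 2 - 2 * np.pi * ra * h)
            got = table.per_residue.asa.to_numpy()
            assert got[0] == pytest.approx(exp[0], rel=0.02)
            assert got[1] == pytest.approx(exp[1], rel=0.02)

    def test_residue_asa_bounded_by_isolated_spheres(self, scaffold):
        table = accessible_surface_area(scaffold, n_points=240)
        for _, row in table.per_residue.iterrows():
            atoms = [a for a in scaffold.atoms
                     if a.residue_id == row.residue_id and a.is_protein]
            bound = sum(4 * np.pi * (VDW_RADII[a.element] + 1.4) ** 2
                        for a in atoms)
            assert row.asa <= bound + 1e-9

    def test_unknown_element_rejected(self):
        atom = AtomRecord("XX", "XX", "UNK", 1, "A", np.zeros(3))
        with pytest.raises(ModelError, match="XX"):
            accessible_surface_area(StructureModel([atom]))


class TestHydrationCorrelation:
    def test_exact_linear_relation(self):
        cov = {aa: float(i + 1) for i, aa in enumerate(sorted(HOPP_WOODS))}
        counts = {aa: 3.0 * v + 2.0 for aa, v in cov.items()}
        fit = hydration_correlation(counts, cov)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(3.0)

    def test_planted_noise_r_squared(self):
        """R² of a planted linear relation matches its analytic expectation
        R² ≈ var(signal)/(var(signal)+σ²) within simulation tolerance."""
        rng = np.random.default_rng(41)
        types = sorted(HOPP_WOODS)
        x = np.linspace(0, 10, len(types))
        sigma = 2.0
        r2s = []
        for _ in range(40):
            y = 2.0 * x + rng.normal(0, sigma, len(x))
            fit = hydration_correlation(dict(zip(types, y)),
                                        dict(zip(types, x)))
            r2s.append(fit.r_squared)
        signal_var = np.var(2.0 * x)
        expected = signal_var / (signal_var + sigma ** 2)
        assert np.mean(r2s) == pytest.approx(expected, abs=0.05)

    def test_independent_covariate_near_zero(self):
        rng = np.random.default_rng(43)
        types = sorted(HOPP_WOODS)
        x = np.linspace(0, 10, len(types))
        r2s = [hydration_correlation(
            dict(zip(types, rng.normal(5, 1, len(types)))),
            dict(zip(types, x))).r_squared for _ in range(60)]
        assert np.median(r2s) < 0.05

    def test_zero_variance_covariate_rejected(self):
        types = sorted(HOPP_WOODS)[:5]
        with pytest.raises(ValueError, match="variance"):
            hydration_correlation({t: 1.0 for t in types},
                                  {t: 2.0 for t in types})

    def test_sign_recovery_with_hydrophilicity(self):
        rng = np.random.default_rng(47)
        counts = {aa: 10.0 + 3.0 * v + rng.normal(0, 1)
                  for aa, v in HOPP_WOODS.items()}
        assert hydration_correlation(counts, HOPP_WOODS).pearson_r > 0.5


class TestDesolvationTrend:
    def test_exact_slope_100(self):
        ph = [3.5, 4.0, 5.0, 7.0, 9.0]
        totals = [100.0 * p + 37.0 for p in ph]
        fit = desolvation_trend(totals, ph)
        assert fit.slope == pytest.approx(100.0)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_planted_slope_with_noise(self):
        """Slope 100 waters/pH with σ = 30 noise recovered within ±3 slope-SEs
        over the five-condition grid."""
        rng = np.random.default_rng(53)
        ph = np.array([3.5, 4.0, 5.0, 7.0, 9.0])
        sigma = 30.0
        se_slope = sigma / np.sqrt(np.sum((ph - ph.mean()) ** 2))
        for _ in range(10):
            totals = 600 + 100.0 * (ph - ph.mean()) + rng.normal(0, sigma, 5)
            fit = desolvation_trend(totals, ph)
            assert abs(fit.slope - 100.0) <= 3 * se_slope

    def test_shift_and_scale_invariances(self):
        ph = np.array([3.5, 4.0, 5.0, 7.0, 9.0])
        totals = np.array([380.0, 410.0, 550.0, 740.0, 930.0])
        base = desolvation_trend(totals, ph)
        shifted = desolvation_trend(totals, ph + 2.0)
        assert shifted.slope == pytest.approx(base.slope)
        assert shifted.pearson_r == pytest.approx(base.pearson_r)
        assert shifted.intercept == pytest.approx(
            base.intercept - 2.0 * base.slope)
        scaled = desolvation_trend(totals, ph * 2.0)
        assert scaled.slope == pytest.approx(base.slope / 2.0)
        assert scaled.pearson_r == pytest.approx(base.pearson_r)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            desolvation_trend([1.0, 2.0], [3.0, 4.0])


class TestWaterProteinDistances:
    def test_single_water_single_bin(self, scaffold):
        a = scaffold.atoms[0]
        m = _with_waters(scaffold, [a.position + np.array([0, 0, 2.8])])
        hist = water_protein_distance_distribution(m)
        assert len(hist.distances) == 1
        assert hist.distances[0] <= 2.8 + 1e-9

    def test_iqr_orders_tight_vs_broad(self, scaffold):
        rng = np.random.default_rng(59)
        base = scaffold.coords[::5]
        tight = _with_waters(scaffold, list(
            base + np.array([0, 0, 3.0]) + rng.normal(0, 0.1, base.shape)))
        broad = _with_waters(scaffold, list(
            base + np.array([0, 0, 3.0]) + rng.normal(0, 0.6, base.shape)))
        assert (water_protein_distance_distribution(tight).iqr
                < water_protein_distance_distribution(broad).iqr)

    def test_distances_match_exhaustive_scan(self, scaffold):
        rng = np.random.default_rng(61)
        pos = [rng.uniform(-25, 25, 3) for _ in range(100)]
        m = _with_waters(scaffold, pos)
        hist = water_protein_distance_distribution(m)
        heavy = np.array([a.position for a in scaffold.protein_atoms(True)])
        expected = sorted(
            min(np.linalg.norm(p - h) for h in heavy) for p in pos)
        assert np.allclose(hist.distances, expected)
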