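"""Scenario seeding, outcome metrics, and the competition runners."""

import dataclasses

import numpy as np
import pytest

from t6sim import experiments as E
from t6sim.mechanics import Arena, segment_min_distance


def slow_lethal():
    """The faster strain re-parameterised to the slow activation rate."""
    base = E.simulated_es401()
    return dataclasses.replace(
        base,
        name="slow-lethal",
        kinetics=dataclasses.replace(base.kinetics, lambda_plus=0.25, p0=0.05),
    )


# ---------------------------------------------------------------------------
# Seeding


class TestSeedCoincubation:
    def config(self, primed=False, n_init=None, strains=None, size=40.0):
        return E.ScenarioConfig(
            arena=Arena(Lx=size, Ly=size),
            strains=strains or (E.simulated_es401(), E.simulated_fqa002()),
            primed=primed,
            t_end=1.0,
            n_init=n_init,
            seed=0,
        )

    def test_primed_population_fully_activated(self, rng):
        cells = E.seed_coincubation(self.config(primed=True), rng)
        assert all(c.G for c in cells)
        assert any(c.N > 0 for c in cells)  # stationary arsenals on board

    def test_unprimed_zero_p0_all_inactive(self, rng):
        base = E.simulated_es401()
        cold = dataclasses.replace(
            base, kinetics=dataclasses.replace(base.kinetics, p0=0.0)
        )
        cells = E.seed_coincubation(self.config(strains=(cold, cold)), rng)
        assert not any(c.G for c in cells)
        assert all(c.N == 0 for c in cells)

    def test_unprimed_activation_fraction_binomial(self, rng):
        strain = E.simulated_es401()  # p0 = 0.10
        cells = E.seed_coincubation(
            self.config(strains=(strain, strain), n_init=4000, size=120.0), rng
        )
        frac = np.mean([c.G for c in cells])
        se = np.sqrt(0.1 * 0.9 / 4000)
        assert abs(frac - 0.10) < 3 * se

    def test_equal_mix_and_no_overlap(self, rng):
        cfg = self.config(n_init=300)
        cells = E.seed_coincubation(cfg, rng)
        counts = np.bincount([c.strain_id for c in cells])
        assert counts[0] == counts[1] == 150
        for i, a in enumerate(cells):
            for b in cells[i + 1 :]:
                d, _, _ = segment_min_distance(
                    *a.endpoints(), *b.endpoints(), cfg.arena
                )
                assert d >= 2 * a.radius - 1e-9

    def test_impossible_density_raises(self, rng):
        with pytest.raises(E.PlacementError):
            E.seed_coincubation(self.config(n_init=400, size=10.0), rng)

    def test_nonfiring_strain_seeds_without_sheaths(self, rng):
        cells = E.seed_coincubation(
            self.config(
                primed=True,
                strains=(E.simulated_es401(vasa=True), E.simulated_fqa002(vasa=True)),
            ),
            rng,
        )
        assert all(c.N == 0 for c in cells)


# ---------------------------------------------------------------------------
# Metrics


class TestCompetitionOutcome:
    @pytest.mark.parametrize(
        "res, comp, expected", [(500, 0, 1.0), (7, 7, 0.0), (0, 500, -1.0), (300, 100, 0.5)]
    )
    def test_values(self, res, comp, expected):
        assert E.competition_outcome(res, comp) == pytest.approx(expected)

    def test_antisymmetric_under_label_swap(self, rng):
        for _ in range(100):
            a, b = rng.integers(0, 1000, 2)
            if a + b == 0:
                continue
            assert E.competition_outcome(a, b) == -E.competition_outcome(b, a)

    def test_undefined_for_empty_population(self):
        with pytest.raises(ValueError):
            E.competition_outcome(0, 0)


class TestLethalityBeta:
    @pytest.mark.parametrize(
        "comp, res, expected", [(20.0, 20.0, 0.5), (0.0, 20.0, 0.0), (10.0, 20.0, 1 / 3)]
    )
    def test_values(self, comp, res, expected):
        assert E.lethality_beta(comp, res) == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            E.lethality_beta(0.0, 0.0)


class TestAreaOccupancy:
    def test_single_strain_owns_everything(self, small_arena, rng):
        from t6sim.fixtures import make_toy_population

        cells = make_toy_population(10, small_arena, 0, rng)
        occ = E.area_occupancy(cells, (0.0, 0.0, 40.0, 40.0))
        assert occ == {0: pytest.approx(1.0)}

    def test_two_congruent_cells_split_evenly(self, small_arena, rng):
        from t6sim.fixtures import make_toy_population

        cells = make_toy_population(2, small_arena, [0, 1], rng)
        occ = E.area_occupancy(cells, (0.0, 0.0, 40.0, 40.0))
        assert occ[0] == pytest.approx(0.5) and occ[1] == pytest.approx(0.5)

    def test_empty_window_is_undefined(self, small_arena, rng):
        from t6sim.fixtures import make_toy_population

        cells = make_toy_population(5, small_arena, 0, rng)
        with pytest.raises(E.NoLiveCellsError):
            E.area_occupancy(cells, (39.9, 39.9, 40.0, 40.0))

    def test_matches_rasterization_oracle(self, rng):
        """Strain shares from the footprint formula vs 0.05 µm pixel counting."""
        arena = Arena(Lx=30.0, Ly=30.0)
        from t6sim.fixtures import make_toy_population

        cells = make_toy_population(36, arena, [0, 1] * 18, rng)
        inside = [c for c in cells if np.all(c.center > 4.0) and np.all(c.center < 26.0)]
        window = (4.0, 4.0, 26.0, 26.0)
        occ = E.area_occupancy(inside, window)

        grid = np.arange(0.0, 30.0, 0.05) + 0.025
        gx, gy = np.meshgrid(grid, grid)
        pix = {0: 0, 1: 0}
        covered_by = np.full(gx.shape, -1)
        for c in inside:
            a1, a2 = c.endpoints()
            t = ((gx - a1[0]) * (a2[0] - a1[0]) + (gy - a1[1]) * (a2[1] - a1[1])) / (
                (a2 - a1) @ (a2 - a1)
            )
            tc = np.clip(t, 0.0, 1.0)
            px = a1[0] + tc * (a2[0] - a1[0])
            py = a1[1] + tc * (a2[1] - a1[1])
            dist = np.sqrt((gx - px) ** 2 + (gy - py) ** 2)
            mask = dist <= c.radius
            covered_by[mask] = c.strain_id
        for s in (0, 1):
            pix[s] = int((covered_by == s).sum())
        total = pix[0] + pix[1]
        for s in (0, 1):
            assert occ[s] == pytest.approx(pix[s] / total, abs=0.01)


# ---------------------------------------------------------------------------
# Runners


class TestRunCompetition:
    def test_symmetry_null_identical_strains(self):
        """Identical strains: phi fluctuates around zero over replicates."""
        strain_a = E.simulated_es401()
        strain_b = dataclasses.replace(strain_a, name="mirror")
        cfg = E.ScenarioConfig(
            arena=Arena(Lx=30.0, Ly=30.0),
            strains=(strain_a, strain_b),
            primed=True,
            t_end=1.5,
            n_replicates=50,
            seed=42,
        )
        phis = np.array([r.phi for r in E.run_replicates(cfg)])
        se = phis.std(ddof=1) / np.sqrt(phis.size)
        assert abs(phis.mean()) < 3 * se

    def test_statistical_antisymmetry_under_strain_swap(self):
        """Swapping the strain order negates the mean outcome."""
        kw = dict(
            arena=Arena(Lx=36.0, Ly=36.0), primed=False, t_end=2.5,
            n_replicates=8, seed=7,
        )
        fwd = E.ScenarioConfig(
            strains=(E.simulated_es401(), E.simulated_fqa002()), **kw
        )
        rev = E.ScenarioConfig(
            strains=(E.simulated_fqa002(), E.simulated_es401()), **kw
        )
        pf = np.array([r.phi for r in E.run_replicates(fwd)])
        pr = np.array([r.phi for r in E.run_replicates(rev)])
        pooled_se = np.sqrt(pf.var(ddof=1) / pf.size + pr.var(ddof=1) / pr.size)
        assert pf.mean() > 0  # the faster activator wins either way
        assert pr.mean() < 0
        assert abs(pf.mean() + pr.mean()) < 3 * pooled_se

    def test_area_fractions_sum_to_one(self):
        cfg = E.duel_config(arena_size=40.0, t_end=2.0, n_replicates=1, seed=5)
        r = E.run_competition(cfg)
        sums = r.area_frac.sum(axis=1)
        assert np.allclose(sums[~np.isnan(sums)], 1.0)
        assert np.all((r.area_frac[~np.isnan(r.area_frac)] >= 0))

    def test_phi_within_bounds(self):
        cfg = E.duel_config(arena_size=40.0, t_end=1.0, n_replicates=3, seed=6)
        for r in E.run_replicates(cfg):
            assert -1.0 <= r.phi <= 1.0


class TestTargetElimination:
    def test_requires_exactly_one_firing_strain(self):
        cfg = E.duel_config(arena_size=40.0, t_end=1.0, n_replicates=1)
        with pytest.raises(ValueError):
            E.run_target_elimination(cfg)

    def test_slower_activator_lets_target_peak_higher(self):
        """The central lethal-vs-target contrast: activation speed rules."""
        results = {}
        for name, lethal in (("fast", E.simulated_es401()), ("slow", slow_lethal())):
            cfg = E.ScenarioConfig(
                arena=Arena(Lx=70.0, Ly=70.0),
                strains=(lethal, E.simulated_fqa002(vasa=True)),
                t_end=8.0,
                n_replicates=5,
                seed=21,
                init_area_fraction=0.04,
            )
            results[name] = E.run_target_elimination(cfg)
        assert results["slow"].target_mean.max() > results["fast"].target_mean.max()
        assert results["slow"].target_mean[-1] > results["fast"].target_mean[-1]

    def test_unarmed_lethal_cannot_suppress_target(self):
        """With lambda_s = 0 the 'lethal' strain never fires a shot."""
        base = E.simulated_es401()
        harmless = dataclasses.replace(
            base,
            kinetics=dataclasses.replace(base.kinetics, lambda_s=0.0),
        )
        cfg = E.ScenarioConfig(
            arena=Arena(Lx=50.0, Ly=50.0),
            strains=(harmless, E.simulated_fqa002(vasa=True)),
            t_end=4.0,
            n_replicates=2,
            seed=9,
            init_area_fraction=0.04,
        )
        res = E.run_target_elimination(cfg)
        assert np.all(np.diff(res.target_mean) >= 0)  # never declines


class TestRangeExpansion:
    def expansion_config(self, strains, t_end=10.0, size=300.0, seed=3):
        return E.ScenarioConfig(
            arena=Arena(Lx=size, Ly=size, boundary="open"),
            strains=strains,
            primed=False,
            t_end=t_end,
            n_replicates=1,
            seed=seed,
        )

    def test_needs_open_arena(self):
        cfg = E.duel_config(arena_size=100.0, t_end=1.0, n_replicates=1)
        with pytest.raises(ValueError):
            E.run_range_expansion(cfg, 10.0)

    def test_lethal_only_census_is_whole_population(self):
        cfg = self.expansion_config((E.simulated_es401(),), t_end=3.0, size=120.0)
        res = E.run_range_expansion(cfg, inoculum_radius=8.0)
        assert res.target_index is None
        assert res.survivor_count == res.competition.live[-1].sum()

    def test_target_survivors_cluster_at_the_edge(self):
        """Survivors sit outside the colony's half-radius (edge survival)."""
        cfg = self.expansion_config(
            (slow_lethal(), E.simulated_fqa002(vasa=True)), t_end=12.0, size=400.0
        )
        res = E.run_range_expansion(cfg, inoculum_radius=20.0)
        assert res.survivor_count > 0
        assert res.survivor_radii.mean() > res.colony_radius / 2.0
        assert res.colony_radius > 20.0  # the colony actually expanded

    def test_deterministic(self):
        cfg = self.expansion_config(
            (slow_lethal(), E.simulated_fqa002(vasa=True)), t_end=3.0, size=150.0
        )
        a = E.run_range_expansion(cfg, 10.0)
        b = E.run_range_expansion(cfg, 10.0)
        assert a.survivor_count == b.survivor_count
        assert np.array_equal(a.survivor_radii, b.survivor_radii)


class TestPhaseSweep:
    def test_rejects_beta_out_of_range(self):
        cfg = E.duel_config(arena_size=40.0, t_end=1.0, n_replicates=1)
        with pytest.raises(ValueError):
            E.phase_sweep(cfg, [0.7], [0.5], n_replicates=1)

    def test_sweep_point_validation(self):
        with pytest.raises(ValueError):
            E.SweepPoint(beta=0.6, c_hat=0.5, phi_mean=0.0, phi_sd=0.0, n_rep=1)

    def test_symmetric_point_is_near_coexistence(self):
        cfg = E.ScenarioConfig(
            arena=Arena(Lx=50.0, Ly=50.0),
            strains=(E.simulated_es401(), E.simulated_fqa002()),
            t_end=6.0,
            n_replicates=4,
            seed=13,
        )
        (pt,) = E.phase_sweep(cfg, [0.5], [0.2], n_replicates=4)
        assert abs(pt.phi_mean) < 0.3
        assert pt.n_rep == 4
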