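"""Generators: landscapes, virtual species, and scenario sets."""

import numpy as np
import pytest

from consensus_sdm.grids import PERIODS
from consensus_sdm.synthetic import (LayerSpec, PrevalenceError, ScenarioDelta,
                                     VirtualSpeciesSpec, default_scenario_deltas,
                                     gen_landscape, gen_scenarios,
                                     gen_virtual_species)


def lag1_autocorr(field):
    a, b = field[:, :-1].ravel(), field[:, 1:].ravel()
    return np.corrcoef(a, b)[0, 1]


class TestGenLandscape:
    def test_requested_marginal_moments(self):
        env = gen_landscape(50, 50, {"t": LayerSpec(mean=10, sd=3,
                                                    autocorr_range=0)}, seed=1)
        layer = env.layer("t")
        # mean over 2500 cells; restandardization makes the moments exact
        assert abs(layer.mean() - 10) < 3 * (3 / 50)
        assert layer.std() == pytest.approx(3, rel=1e-9)

    def test_zero_range_is_white_noise(self):
        env = gen_landscape(50, 50, {"t": LayerSpec(autocorr_range=0)}, seed=2)
        assert abs(lag1_autocorr(env.layer("t"))) < 0.1

    def test_positive_range_induces_spatial_correlation(self):
        env = gen_landscape(50, 50, {"t": LayerSpec(autocorr_range=4)}, seed=2)
        assert lag1_autocorr(env.layer("t")) > 0.5

    def test_deterministic_given_seed(self):
        specs = {"t": LayerSpec(autocorr_range=2), "p": LayerSpec(mean=5)}
        a = gen_landscape(30, 30, specs, seed=9)
        b = gen_landscape(30, 30, specs, seed=9)
        assert np.array_equal(a.values, b.values)
        c = gen_landscape(30, 30, specs, seed=10)
        assert not np.array_equal(a.values, c.values)

    def test_rejects_tiny_grids(self):
        with pytest.raises(ValueError):
            gen_landscape(5, 50, {"t": LayerSpec()}, seed=0)

    def test_latitude_decreases_with_row(self):
        env = gen_landscape(20, 20, {"t": LayerSpec()}, seed=0)
        lats = env.latitudes()
        assert np.all(np.diff(lats) < 0)


class TestVirtualSpecies:
    def test_flat_niche_gives_uniformish_presences(self, env2):
        a = env2.layer("A")[env2.mask]
        spec = VirtualSpeciesSpec(
            optimum={"A": float(a.mean())}, breadth={"A": 1e9},
            prevalence_target=0.3, seed=1, sampling_mode="bernoulli")
        species, suit = gen_virtual_species(env2, spec)
        assert suit[env2.mask].min() > 0.999
        pres_mean = env2.layer("A")[species.presence].mean()
        assert abs(pres_mean - a.mean()) < 3 * a.std() / np.sqrt(species.n_presences)

    def test_shifted_optimum_shifts_presence_mean(self, env2):
        a = env2.layer("A")[env2.mask]
        spec = VirtualSpeciesSpec(
            optimum={"A": float(a.mean() + 2 * a.std())},
            breadth={"A": float(a.std())}, prevalence_target=0.1, seed=1)
        species, _ = gen_virtual_species(env2, spec)
        assert env2.layer("A")[species.presence].mean() > a.mean()

    def test_narrower_breadth_concentrates_presences(self, env2):
        # bernoulli mode: absolute suitability drives the draw, so shrinking
        # breadth 4x at fixed prevalence shrinks the environmental variance
        a = env2.layer("A")[env2.mask]
        out = []
        for b in (2.0, 0.5):
            spec = VirtualSpeciesSpec(
                optimum={"A": float(a.mean())}, breadth={"A": b * float(a.std())},
                prevalence_target=0.15, sampling_mode="bernoulli", seed=5)
            species, _ = gen_virtual_species(env2, spec)
            out.append(env2.layer("A")[species.presence].var())
        assert out[1] < out[0]

    @pytest.mark.parametrize("target", np.linspace(0.05, 0.5, 10))
    def test_prevalence_hits_target(self, env2, target):
        spec = VirtualSpeciesSpec(
            optimum={"A": 10.0}, breadth={"A": 3.0},
            prevalence_target=float(target), seed=3)
        species, _ = gen_virtual_species(env2, spec)
        assert abs(species.prevalence - target) <= 0.1 * target

    def test_monotone_niche_control(self, env2):
        """Presence-mean departure from the landscape mean is nondecreasing
        in the optimum offset."""
        a = env2.layer("A")[env2.mask]
        dists = []
        for off in np.linspace(0, 2.5, 6):
            spec = VirtualSpeciesSpec(
                optimum={"A": float(a.mean() + off * a.std())},
                breadth={"A": 0.5 * float(a.std())},
                prevalence_target=0.1, seed=11)
            species, _ = gen_virtual_species(env2, spec)
            dists.append(abs(env2.layer("A")[species.presence].mean() - a.mean()))
        assert all(d2 >= d1 - 1e-9 for d1, d2 in zip(dists, dists[1:]))

    def test_determinism(self, env2):
        spec = VirtualSpeciesSpec(optimum={"A": 12.0}, breadth={"A": 2.0},
                                  prevalence_target=0.2, seed=21)
        s1, _ = gen_virtual_species(env2, spec)
        s2, _ = gen_virtual_species(env2, spec)
        assert np.array_equal(s1.presence, s2.presence)

    def test_unattainable_prevalence_fails_explicitly(self, env2):
        spec = VirtualSpeciesSpec(
            optimum={"A": 1e4}, breadth={"A": 0.1},
            prevalence_target=0.99, sampling_mode="bernoulli", seed=1)
        with pytest.raises(PrevalenceError):
            gen_virtual_species(env2, spec)

    def test_validates_spec(self):
        with pytest.raises(ValueError):
            VirtualSpeciesSpec(optimum={"A": 0}, breadth={"A": -1},
                               prevalence_target=0.1)
        with pytest.raises(ValueError):
            VirtualSpeciesSpec(optimum={"A": 0}, breadth={"A": 1},
                               prevalence_target=1.0)


class TestScenarios:
    def test_zero_deltas_identity(self, env2):
        deltas = {(g, s, "2050s"): ScenarioDelta()
                  for g in (1, 2, 3) for s in (1, 2, 3)}
        sset = gen_scenarios(env2, deltas)
        for grid in sset.scenario_grids.values():
            assert np.array_equal(grid.values, env2.values)

    def test_uniform_offset_additivity(self, env2):
        deltas = {(g, s, "2050s"): ScenarioDelta(offsets={"A": 2.0})
                  for g in (1, 2, 3) for s in (1, 2, 3)}
        sset = gen_scenarios(env2, deltas)
        grid = sset.scenario_grids[(1, 1, "2050s")]
        assert grid.layer("A").mean() == pytest.approx(env2.layer("A").mean() + 2.0)
        assert np.array_equal(grid.layer("B"), env2.layer("B"))

    def test_nine_grids_per_period(self, full_env):
        sset = gen_scenarios(full_env, default_scenario_deltas(("2020s",)))
        assert len(sset.for_period("2020s")) == 9
        assert sset.periods == ["2020s"]

    def test_incomplete_combinations_rejected(self, env2):
        deltas = {(1, 1, "2050s"): ScenarioDelta()}
        with pytest.raises(ValueError, match="need all 9"):
            gen_scenarios(env2, deltas)

    def test_default_deltas_cover_all_periods(self):
        deltas = default_scenario_deltas()
        assert len(deltas) == 27
        assert {p for (_, _, p) in deltas} == set(PERIODS)
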