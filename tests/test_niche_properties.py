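"""Niche traits: prevalence, 10%-extreme ranges, thermal PCA range, ENFA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from consensus_sdm.grids import SpeciesDistribution
from consensus_sdm.niche_properties import (enfa, extreme_range, prevalence,
                                            species_traits, thermal_range)
from consensus_sdm.synthetic import (LayerSpec, VirtualSpeciesSpec,
                                     gen_landscape, gen_virtual_species)
from .conftest import make_species


class TestPrevalence:
    def test_arithmetic(self):
        cal = pd.DataFrame({"label": ["presence"] * 70 + ["absence"] * 70})
        assert prevalence(cal) == 0.5

    def test_all_presences_degenerate_but_computable(self):
        cal = pd.DataFrame({"label": ["presence"] * 10})
        assert prevalence(cal) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prevalence(pd.DataFrame({"label": []}))

    def test_equal_across_stratified_bouts(self, env2, species2):
        from consensus_sdm.pseudoabsence import fit_sre, make_subsets
        species, _ = species2
        bouts = make_subsets(env2, species, fit_sre(env2, species), seed=0)
        values = {round(prevalence(b.calibration), 6) for b in bouts}
        assert len(values) == 1


class TestExtremeRange:
    def test_constant_values_zero(self):
        assert extreme_range([5.0] * 20) == 0.0

    def test_closed_form_1_to_100(self):
        assert extreme_range(np.arange(1, 101), 0.1) == pytest.approx(90.0)

    def test_homogeneous_of_degree_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=50)
        assert extreme_range(2 * v) == pytest.approx(2 * extreme_range(v))

    def test_sort_and_average_oracle(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=37)
        k = int(np.ceil(0.1 * 37))
        s = np.sort(v)
        assert extreme_range(v) == s[-k:].mean() - s[:k].mean()

    def test_too_few_values_fails(self):
        with pytest.raises(ValueError):
            extreme_range([1.0] * 9)


class TestThermalRange:
    def test_uniform_thermal_landscape_gives_zero(self, full_env):
        # flatten the five thermal layers
        values = full_env.values.copy()
        for name in ("MAT", "MWMT", "MCMT", "TD", "DD"):
            values[full_env.layer_names.index(name)] = 1.0
        env = full_env.with_values(values)
        sp = make_species(env, 0.2, seed=1)
        r, _ = thermal_range(env, sp)
        assert r == 0.0

    def test_wider_occupied_thermal_band_increases_range(self, full_env):
        # hold the other four thermal layers spatially constant so the
        # first thermal axis is exactly the MAT gradient
        values = full_env.values.copy()
        for name in ("MWMT", "MCMT", "TD", "DD"):
            values[full_env.layer_names.index(name)] = 1.0
        env = full_env.with_values(values)
        mat = env.layer("MAT")[env.mask]
        ranges = []
        for b in (0.3, 1.2):
            spec = VirtualSpeciesSpec(
                optimum={"MAT": float(mat.mean())},
                breadth={"MAT": b * float(mat.std())},
                prevalence_target=0.15, sampling_mode="bernoulli", seed=2)
            species, _ = gen_virtual_species(env, spec)
            ranges.append(thermal_range(env, species)[0])
        assert ranges[1] > ranges[0]

    def test_two_axis_variance_fraction_bounded(self, full_env):
        sp = make_species(full_env, 0.2, seed=3)
        _, var2 = thermal_range(full_env, sp)
        assert 0.0 < var2 <= 1.0

    def test_missing_thermal_layer_named(self, env2):
        sp = make_species(env2, 0.2, seed=4)
        with pytest.raises(KeyError, match="MAT"):
            thermal_range(env2, sp)


@pytest.fixture(scope="module")
def big_env():
    specs = {"A": LayerSpec(mean=10, sd=3, autocorr_range=2),
             "B": LayerSpec(mean=0, sd=2, autocorr_range=2)}
    return gen_landscape(150, 150, specs, seed=7)


class TestEnfa:
    def test_null_species_limits(self, big_env):
        """Uniform random presence: marginality ~ 0, specialization ~ 1."""
        sp = make_species(big_env, presence_fraction=0.03, seed=5)
        M, S = enfa(big_env, sp)
        assert M < 0.1
        assert 0.8 < S < 1.2

    def test_diagonal_closed_form(self, big_env):
        """Optimum +2 global SD on one layer -> M ~ 2/1.96, n >= 500."""
        a = big_env.layer("A")[big_env.mask]
        spec = VirtualSpeciesSpec(
            optimum={"A": float(a.mean() + 2 * a.std()), "B": 0.0},
            breadth={"A": 0.3 * float(a.std()), "B": 1e6},
            prevalence_target=0.025, seed=3)
        species, _ = gen_virtual_species(big_env, spec)
        assert species.n_presences >= 500
        M, _ = enfa(big_env, species)
        assert M == pytest.approx(2 / 1.96, abs=0.12)

    def test_marginality_monotone_recovery(self, big_env):
        a = big_env.layer("A")[big_env.mask]
        offsets = [0.0, 0.4, 0.8, 1.2, 1.6, 2.0]
        Ms = []
        for off in offsets:
            spec = VirtualSpeciesSpec(
                optimum={"A": float(a.mean() + off * a.std()), "B": 0.0},
                breadth={"A": 0.5 * float(a.std()), "B": 1e6},
                prevalence_target=0.05, seed=11)
            species, _ = gen_virtual_species(big_env, spec)
            Ms.append(enfa(big_env, species)[0])
        assert spearmanr(offsets, Ms).statistic >= 0.9

    def test_specialization_monotone_recovery(self, big_env):
        a = big_env.layer("A")[big_env.mask]
        b = big_env.layer("B")[big_env.mask]
        breadths = [0.25, 0.4, 0.6, 0.9, 1.3, 2.0]
        Ss = []
        for br in breadths:
            spec = VirtualSpeciesSpec(
                optimum={"A": float(a.mean()), "B": float(b.mean())},
                breadth={"A": br * float(a.std()), "B": br * float(b.std())},
                prevalence_target=0.10, sampling_mode="bernoulli", seed=13)
            species, _ = gen_virtual_species(big_env, spec)
            Ss.append(enfa(big_env, species)[1])
        assert spearmanr([1 / b for b in breadths], Ss).statistic >= 0.9
        # halving breadth at fixed optimum strictly increases S
        assert Ss[0] > Ss[2] > Ss[4]

    def test_too_few_presences_fails(self, env2):
        presence = np.zeros(env2.shape, bool)
        presence[0, :2] = True
        sp = SpeciesDistribution(presence=presence, env=env2)
        with pytest.raises(ValueError):
            enfa(env2, sp)


class TestSpeciesTraits:
    def test_all_traits_finite_and_signed(self, full_env):
        mat = full_env.layer("MAT")[full_env.mask]
        spec = VirtualSpeciesSpec(
            optimum={"MAT": float(mat.mean() + mat.std())},
            breadth={"MAT": float(mat.std())},
            prevalence_target=0.15, seed=9)
        species, _ = gen_virtual_species(full_env, spec)
        cal = pd.DataFrame({"label": ["presence"] * 30 + ["absence"] * 70})
        t = species_traits(full_env, species, cal)
        d = t.as_dict()
        assert all(np.isfinite(v) for v in d.values())
        assert d["lat_range"] >= 0 and d["elev_range"] >= 0
        assert d["thermal_range"] >= 0
        assert d["marginality"] >= 0 and d["specialization"] >= 0
        assert d["prevalence"] == pytest.approx(0.3)
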