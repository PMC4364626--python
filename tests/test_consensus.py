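"""Consensus combiners: average, frequency, and median (PCA)."""

import numpy as np
import pytest

from consensus_sdm.consensus import (consensus_average, consensus_frequency,
                                     consensus_median_pca, pca_select)
from consensus_sdm.models import ModelProjection, ProjectionEnsemble


def mk_proj(probs, mc="glm", bout=1, scenario="baseline", period="baseline"):
    return ModelProjection(probs=np.asarray(probs, dtype=float),
                           model_class=mc, bout=bout, scenario=scenario,
                           period=period)


def random_stack(k=5, shape=(6, 6), seed=0):
    rng = np.random.default_rng(seed)
    return [mk_proj(rng.uniform(size=shape), mc=f"m{i}") for i in range(k)]


class TestAverage:
    def test_idempotent_on_identical_stack(self):
        p = np.full((4, 4), 0.3)
        out = consensus_average([mk_proj(p, mc=f"m{i}") for i in range(5)])
        assert np.allclose(out.probs, 0.3)

    def test_two_value_arithmetic(self):
        out = consensus_average([mk_proj([[0.2]], "a"), mk_proj([[0.8]], "b")])
        assert out.probs[0, 0] == pytest.approx(0.5)

    def test_matches_loop_oracle(self):
        stack = random_stack(5)
        out = consensus_average(stack)
        for r in range(6):
            for c in range(6):
                expect = sum(p.probs[r, c] for p in stack) / 5
                assert out.probs[r, c] == pytest.approx(expect, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_average([])


class TestFrequency:
    def test_unanimous_presence(self):
        out = consensus_frequency([mk_proj([[0.9]], f"m{i}") for i in range(4)])
        assert out.probs[0, 0] == 1.0

    def test_three_of_four(self):
        maps = [mk_proj([[p]], f"m{i}") for i, p in enumerate([0.9, 0.8, 0.7, 0.2])]
        assert consensus_frequency(maps).probs[0, 0] == pytest.approx(0.75)

    def test_values_on_k_lattice(self):
        stack = random_stack(10)
        out = consensus_frequency(stack)
        lattice = np.arange(11) / 10
        assert np.all(np.isin(np.round(out.probs, 12), np.round(lattice, 12)))

    def test_threshold_is_strict(self):
        out = consensus_frequency([mk_proj([[0.5]], "a")])
        assert out.probs[0, 0] == 0.0


class TestPcaSelect:
    def test_single_projection_returned(self):
        p = mk_proj(np.random.default_rng(0).uniform(size=(5, 5)))
        sel, corr = pca_select([p])
        assert sel is p and corr == 1.0

    def test_outlier_not_selected(self):
        """Four intercorrelated signal columns plus one anti-signal outlier:
        PC1 follows the majority, so a signal column is chosen."""
        rng = np.random.default_rng(1)
        base = rng.uniform(0.2, 0.8, size=(8, 8))
        projs = [mk_proj(np.clip(base + rng.normal(0, 0.02, base.shape), 0, 1),
                         mc=f"sig{i}") for i in range(4)]
        projs.append(mk_proj(np.clip(1 - base, 0, 1), mc="outlier"))
        sel, corr = pca_select(projs)
        assert sel.model_class.startswith("sig")
        assert abs(corr) > 0.99

    def test_selection_against_eigen_oracle(self):
        rng = np.random.default_rng(3)
        projs = random_stack(4, seed=3)
        sel, _ = pca_select(projs)
        # oracle: eigen-decomposition of the covariance of centred columns
        X = np.column_stack([p.probs.ravel() for p in sorted(
            projs, key=lambda p: p.model_class)])
        Xc = X - X.mean(axis=0)
        w, v = np.linalg.eigh(Xc.T @ Xc)
        pc1 = Xc @ v[:, -1]
        corrs = [abs(np.corrcoef(Xc[:, j], pc1)[0, 1]) for j in range(4)]
        expect = sorted(projs, key=lambda p: p.model_class)[int(np.argmax(corrs))]
        assert sel is expect

    def test_duplicate_column_tie_breaks_by_class_order(self):
        projs = random_stack(4, seed=5)
        sel, _ = pca_select(projs, class_order=[p.model_class for p in projs])
        dup = mk_proj(sel.probs.copy(), mc="zzz_dup")
        sel2, _ = pca_select(projs + [dup],
                             class_order=[p.model_class for p in projs] + ["zzz_dup"])
        assert sel2 is sel

    def test_constant_block_falls_back_with_warning(self):
        projs = [mk_proj(np.full((4, 4), 0.4), mc=f"m{i}") for i in range(3)]
        with pytest.warns(UserWarning, match="constant"):
            sel, corr = pca_select(projs)
        assert sel.model_class == "m0" and corr == 0.0


class TestMedianPca:
    def build_ensemble(self, n_classes=3, bouts=range(1, 10),
                       scenarios=None, period="2050s", seed=0):
        rng = np.random.default_rng(seed)
        ens = ProjectionEnsemble()
        scenarios = scenarios or [(g, s) for g in (1, 2, 3) for s in (1, 2, 3)]
        for b in bouts:
            for sc in scenarios:
                for i in range(n_classes):
                    ens.add(mk_proj(rng.uniform(size=(5, 5)), mc=f"m{i}",
                                    bout=b, scenario=sc, period=period))
        return ens

    def test_future_median_over_81_selections(self):
        ens = self.build_ensemble()
        out = consensus_median_pca(ens, "2050s")
        assert out.provenance["n_selected"] == 81

    def test_baseline_median_over_9_selections(self):
        ens = self.build_ensemble(scenarios=["baseline"], period="baseline")
        out = consensus_median_pca(ens, "baseline")
        assert out.provenance["n_selected"] == 9

    def test_identical_projections_idempotent(self):
        ens = ProjectionEnsemble()
        p = np.random.default_rng(1).uniform(size=(4, 4))
        for b in (1, 2, 3):
            for i in range(3):
                ens.add(mk_proj(p.copy(), mc=f"m{i}", bout=b,
                                scenario="baseline", period="baseline"))
        out = consensus_median_pca(ens, "baseline")
        assert np.allclose(out.probs, p)

    def test_no_projections_fails(self):
        with pytest.raises(RuntimeError):
            consensus_median_pca(ProjectionEnsemble(), "2080s")


class TestStackInvariants:
    def test_average_and_median_within_envelope(self):
        stack = random_stack(7, seed=9)
        arr = np.stack([p.probs for p in stack])
        lo, hi = arr.min(axis=0), arr.max(axis=0)
        avg = consensus_average(stack).probs
        med = np.median(arr, axis=0)
        assert np.all(avg >= lo - 1e-12) and np.all(avg <= hi + 1e-12)
        assert np.all(med >= lo) and np.all(med <= hi)

    def test_permutation_invariance(self):
        stack = random_stack(6, seed=11)
        rng = np.random.default_rng(2)
        shuffled = [stack[i] for i in rng.permutation(6)]
        assert np.array_equal(consensus_average(stack).probs,
                              consensus_average(shuffled).probs)
        assert np.array_equal(consensus_frequency(stack).probs,
                              consensus_frequency(shuffled).probs)
        assert pca_select(stack)[0] is pca_select(shuffled)[0]

    def test_median_more_robust_to_outlier_than_mean(self):
        """Replacing one of 9 maps by a constant adversarial map moves the
        median strictly less than the mean on average over cells (the mean
        shifts by |1 - x|/9 everywhere; the median only moves between
        adjacent order statistics, and only where the replaced value was on
        the low side)."""
        rng = np.random.default_rng(4)
        for trial in range(5):
            arr = rng.uniform(0.3, 0.7, size=(9, 6, 6))
            corrupted = arr.copy()
            corrupted[0] = 1.0
            d_mean = np.abs(corrupted.mean(0) - arr.mean(0)).mean()
            d_med = np.abs(np.median(corrupted, 0) - np.median(arr, 0)).mean()
            assert d_med < d_mean
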