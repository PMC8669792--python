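"""Variograms, surrogate ensembles, correspondence tests, p adjustment."""

import numpy as np
import pytest
from scipy.stats import rankdata

import lesioncov as lc
from lesioncov.nulls import _PairWorkspace, correlate_values

from conftest import line_map


class TestVariogram:
    def test_constant_map_zero_semivariance(self, truth):
        m = lc.BrainMap(truth.grid, "cortex",
                        np.full(truth.grid.n_voxels("cortex"), 2.5))
        vg = lc.empirical_variogram(m, seed=0)
        assert np.allclose(vg.gamma, 0.0)

    def test_two_voxel_hand_computation(self):
        shape = (16, 16, 16)
        mask = np.zeros(shape, bool)
        mask[0, 0, 0] = mask[1, 0, 0] = True
        g = lc.VoxelGrid(shape, (1, 1, 1), masks={"m": mask})
        vg = lc.empirical_variogram(lc.BrainMap(g, "m", [0.0, 2.0]), seed=0)
        assert vg.gamma.size == 1
        assert vg.gamma[0] == pytest.approx(2.0)  # half of (2-0)^2

    def test_smooth_field_monotone_at_small_lags(self, smooth_cortex_map):
        from scipy.stats import spearmanr

        vg = lc.empirical_variogram(smooth_cortex_map, seed=0)
        rho = spearmanr(vg.bin_centers_mm, vg.gamma).statistic
        assert rho > 0.8


class TestSurrogates:
    def test_rank_resampling_preserves_value_multiset(self, smooth_cortex_map):
        ens = lc.make_surrogates(smooth_cortex_map, 3, seed=1)
        src_sorted = np.sort(smooth_cortex_map.values)
        for s in range(ens.n):
            assert np.array_equal(np.sort(ens.values[s]), src_sorted)

    def test_resampling_preserves_moments_exactly(self, smooth_cortex_map):
        ens = lc.make_surrogates(smooth_cortex_map, 2, seed=2)
        v = smooth_cortex_map.values
        assert ens.values[0].mean() == pytest.approx(v.mean(), rel=1e-12)
        assert ens.values[0].var() == pytest.approx(v.var(), rel=1e-12)

    def test_white_noise_selects_smallest_smoothing(self, truth):
        g = truth.grid
        rng = np.random.default_rng(5)
        wn = lc.BrainMap(g, "cortex", rng.standard_normal(g.n_voxels("cortex")))
        ens = lc.make_surrogates(wn, 20, seed=6)
        # flat variogram: coefficient of variation across bins is tiny
        ws = _PairWorkspace(g.coords_mm("cortex"), 25, None, 1500,
                            np.random.default_rng(0))
        gam = np.array([ws.gamma_of(v) for v in ens.values]).mean(axis=0)
        assert gam.std() / gam.mean() < 0.05

    def test_smooth_map_variogram_matched(self, smooth_cortex_map, truth):
        """Mean surrogate variogram tracks the target per bin and beats
        permutation surrogates in SSE almost always."""
        ens = lc.make_surrogates(smooth_cortex_map, 199, seed=3)
        ws = _PairWorkspace(truth.grid.coords_mm("cortex"), 25, None, 3000,
                            np.random.default_rng(9))
        target = ws.gamma_of(smooth_cortex_map.values)
        gam = np.array([ws.gamma_of(v) for v in ens.values])
        rel = np.abs(gam.mean(axis=0) - target) / target
        assert rel.max() <= 0.15
        rng = np.random.default_rng(11)
        sse_surr = ((gam - target) ** 2).sum(axis=1)
        sse_perm = np.array([
            ((ws.gamma_of(rng.permutation(smooth_cortex_map.values)) - target) ** 2).sum()
            for _ in range(199)])
        assert (sse_surr < sse_perm).mean() >= 0.95


class TestCorrelateMaps:
    def test_identity(self):
        a = line_map(np.random.default_rng(0).standard_normal(50))
        assert lc.correlate_maps(a, a) == pytest.approx(1.0)

    def test_spearman_invariant_to_monotone_transform(self):
        v = np.random.default_rng(1).standard_normal(80)
        a, b = line_map(v), line_map(np.exp(v))
        assert lc.correlate_maps(a, b, "spearman") == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x, y = rng.standard_normal((2, 30))
            r = correlate_values(x, y, "pearson")
            xc, yc = x - x.mean(), y - y.mean()
            brute = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert r == pytest.approx(brute, abs=1e-12)
            rs = correlate_values(x, y, "spearman")
            rx, ry = rankdata(x), rankdata(y)
            rxc, ryc = rx - rx.mean(), ry - ry.mean()
            brute_s = (rxc @ ryc) / np.sqrt((rxc @ rxc) * (ryc @ ryc))
            assert rs == pytest.approx(brute_s, abs=1e-12)

    def test_pearson_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 60))
        r0 = correlate_values(x, y)
        assert correlate_values(3.2 * x + 1.0, y) == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(lc.ValidationError):
            lc.correlate_maps(line_map(np.ones(10)), line_map(np.arange(10.0)))


def _fake_ensemble(values):
    return lc.SurrogateEnsemble("src", np.asarray(values, float),
                                np.zeros(len(values)), np.zeros(len(values)), 0)


class TestSurrogateTest:
    def test_rank_formula(self):
        rng = np.random.default_rng(4)
        a = line_map(rng.standard_normal(40))
        b = line_map(a.values + 0.1 * rng.standard_normal(40))
        # 99 null maps, none reaching the observed correlation
        ens = _fake_ensemble(rng.standard_normal((99, 40)))
        t = lc.surrogate_test(a, b, ens)
        assert t.p_uncorrected == pytest.approx(1 / 100)

    def test_self_comparison_minimum_p(self):
        rng = np.random.default_rng(5)
        a = line_map(rng.standard_normal(40))
        ens = _fake_ensemble(rng.standard_normal((49, 40)))
        t = lc.surrogate_test(a, a, ens)
        assert t.p_uncorrected == pytest.approx(1 / 50)

    def test_null_calibration(self, smooth_cortex_map, truth):
        """Independent targets with matched smoothness are rejected at about
        the nominal rate."""
        g = truth.grid
        ens = lc.make_surrogates(smooth_cortex_map, 199, seed=7)
        rej = 0
        for rep in range(200):
            rng = np.random.default_rng(3000 + rep)
            tgt = lc.smooth(lc.BrainMap(g, "cortex",
                                        rng.standard_normal(g.n_voxels("cortex"))), 8.0)
            t = lc.surrogate_test(smooth_cortex_map, tgt, ens)
            rej += t.p_uncorrected < 0.05
        assert 0.02 <= rej / 200 <= 0.09


try:
    from hypothesis import given, settings, strategies as st

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0001, 1.0), min_size=1, max_size=30),
           st.sampled_from(["bonferroni", "fdr_bh"]))
    def test_adjustment_dominates_raw_p_and_stays_in_unit_interval(p, method):
        adj = lc.adjust(p, method)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all((adj > 0) & (adj <= 1))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_rank_resampling_never_invents_values(seed):
        rng = np.random.default_rng(seed)
        from lesioncov.nulls import _rank_resample

        x = rng.standard_normal(37)
        out = _rank_resample(rng.standard_normal(37), np.sort(x), rng)
        assert np.array_equal(np.sort(out), np.sort(x))
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


class TestAdjust:
    def test_bonferroni_examples(self):
        assert lc.adjust([0.01] * 6, "bonferroni")[0] == pytest.approx(0.06)
        assert lc.adjust([0.0001] * 63, "bonferroni")[0] == pytest.approx(0.0063)

    def test_bh_equal_ps_unchanged(self):
        p = [0.04] * 10
        assert np.allclose(lc.adjust(p, "fdr_bh"), p)

    def test_invalid_p_rejected(self):
        with pytest.raises(lc.ValidationError):
            lc.adjust([0.0, 0.5])
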