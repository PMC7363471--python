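"""Functional-connectivity observables against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from epileptornet import (
    FitSummary,
    coarse_grain,
    coherence_metastability,
    compare_spcc,
    global_similarity,
    instantaneous_phase,
    ks_distance,
    kuramoto_order,
    mse_profile,
    rmsd,
    sample_entropy,
    sliding_window_fcd,
    static_pcc,
)
from epileptornet.hemo import BoldSeries
from epileptornet.metrics import window_samples


def _bold(data, TR=3.6):
    data = np.atleast_2d(data)
    return BoldSeries(labels=[f"r{i}" for i in range(data.shape[0])],
                      data=data, TR=TR)


class TestStaticPcc:
    def test_diagonal_and_anticorrelation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        r = static_pcc(_bold(np.vstack([x, -x])))
        assert r[0, 0] == 1.0 and r[1, 1] == 1.0
        assert r[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_five_point_pair_matches_hand_expanded_formula(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        # direct covariance/SD expansion of the correlation definition
        xm, ym = x - x.mean(), y - y.mean()
        expected = (xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
        r = static_pcc(_bold(np.vstack([x, y])))
        assert r[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_region_flagged(self):
        data = np.vstack([np.ones(30), np.random.default_rng(1).standard_normal(30)])
        with pytest.warns(UserWarning, match="zero-variance"):
            r = static_pcc(_bold(data))
        assert np.isnan(r[0, 1])

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 80))
        scaled = data * np.array([[2.0], [0.5], [7.0], [1.0]]) + \
            np.array([[1.0], [-3.0], [0.0], [10.0]])
        np.testing.assert_allclose(static_pcc(_bold(data)),
                                   static_pcc(_bold(scaled)), atol=1e-10)


class TestCompareSpcc:
    def test_identical_and_negated(self):
        rng = np.random.default_rng(3)
        m = np.corrcoef(rng.standard_normal((4, 60)))
        assert compare_spcc(m, m) == pytest.approx(1.0)
        assert compare_spcc(m, -m) == pytest.approx(-1.0)

    def test_four_by_four_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal((2, 4, 4))
        va = [a[i, j] for i in range(4) for j in range(i + 1, 4)]
        vb = [b[i, j] for i in range(4) for j in range(i + 1, 4)]
        assert compare_spcc(a, b) == pytest.approx(np.corrcoef(va, vb)[0, 1])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_spcc(np.eye(3), np.eye(4))


class TestFcd:
    def test_printed_window_arithmetic(self):
        # 344 samples at TR 3.6 s, 60 s windows advancing 1 TR -> 328 windows
        assert window_samples(60.0, 3.6) == 17
        rng = np.random.default_rng(5)
        bold = _bold(rng.standard_normal((5, 344)))
        fcd = sliding_window_fcd(bold)
        assert fcd.shape == (328, 328)
        np.testing.assert_allclose(np.diag(fcd), 1.0)
        np.testing.assert_allclose(fcd, fcd.T, atol=1e-12)

    def test_iid_noise_has_unstructured_fcd(self):
        rng = np.random.default_rng(6)
        fcd = sliding_window_fcd(_bold(rng.standard_normal((8, 200))))
        off = fcd[np.triu_indices_from(fcd, k=17)]  # non-overlapping windows
        assert abs(off.mean()) < 0.1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            sliding_window_fcd(_bold(np.zeros((3, 10))))


class TestKsDistance:
    def test_identical_and_disjoint(self):
        x = np.array([0.1, 0.5, 0.9])
        assert ks_distance(x, x) == 0.0
        assert ks_distance([0, 1, 2], [10, 11, 12]) == 1.0

    def test_small_shifted_sample_by_hand(self):
        # ECDFs of {1,2,3} and {2,3,4} differ maximally by 1/3
        assert ks_distance([1, 2, 3], [2, 3, 4]) == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_distance([], [1.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=40),
           st.lists(st.floats(-5, 5), min_size=1, max_size=40))
    def test_matches_scipy_two_sample_statistic(self, a, b):
        assert ks_distance(a, b) == pytest.approx(
            ks_2samp(a, b, method="asymp").statistic, abs=1e-12)


class TestPhasesAndSynchrony:
    def test_cosine_phase_slope_recovers_frequency(self):
        TR = 3.6
        t = np.arange(400) * TR
        w = 2 * np.pi * 0.03
        ph = instantaneous_phase(_bold(np.cos(w * t)), trim=0.1)[0]
        slopes = np.diff(np.unwrap(ph)) / TR
        assert np.median(slopes) == pytest.approx(w, rel=0.01)

    def test_quadrature_and_sign_flip_offsets(self):
        t = np.arange(600) * 1.0
        w = 2 * np.pi * 0.02
        s = np.vstack([np.cos(w * t), np.sin(w * t), -np.cos(w * t)])
        ph = instantaneous_phase(_bold(s, TR=1.0), trim=0.1)
        d_quad = np.angle(np.exp(1j * (ph[0] - ph[1])))
        d_flip = np.angle(np.exp(1j * (ph[0] - ph[2])))
        assert np.median(d_quad) == pytest.approx(np.pi / 2, abs=0.02)
        assert np.median(np.abs(d_flip)) == pytest.approx(np.pi, abs=0.02)

    def test_constant_region_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            instantaneous_phase(_bold(np.ones(100)))

    def test_kuramoto_limits(self):
        assert kuramoto_order(np.zeros((5, 10))) == pytest.approx(1.0)
        uniform = np.linspace(0, 2 * np.pi, 8, endpoint=False)[:, None]
        assert kuramoto_order(uniform)[0] == pytest.approx(0.0, abs=1e-12)
        antiphase = np.array([[0.0], [np.pi]])
        assert kuramoto_order(antiphase)[0] == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            kuramoto_order(np.zeros((1, 10)))

    def test_coherence_metastability_definitions(self):
        coh, meta = coherence_metastability(np.full(50, 0.7))
        assert (coh, meta) == (pytest.approx(0.7), pytest.approx(0.0))
        coh, _ = coherence_metastability(np.tile([0.0, 1.0], 25))
        assert coh == pytest.approx(0.5)
        with pytest.raises(ValueError):
            coherence_metastability([])


class TestCoarseGrain:
    def test_scale_one_is_identity(self):
        x = np.arange(7.0)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_floor_length_and_block_means(self):
        assert len(coarse_grain(np.arange(10.0), 3)) == 3
        x = np.array([1.0, 3.0, 2.0, 4.0, 10.0, 0.0])
        np.testing.assert_allclose(coarse_grain(x, 2), [2.0, 3.0, 5.0])
        np.testing.assert_allclose(coarse_grain(x, 3), [2.0, 14.0 / 3])

    def test_scale_beyond_length_rejected(self):
        with pytest.raises(ValueError):
            coarse_grain(np.arange(5.0), 6)


def sampen_bruteforce(x, m, r):
    """Independent O(N^2) template counter (Chebyshev norm, no self-matches)."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    counts = []
    for mm in (m, m + 1):
        n_templates = N - m
        c = 0
        for i in range(n_templates):
            for j in range(n_templates):
                if i == j:
                    continue
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
        counts.append(c)
    B, A = counts
    if B == 0 or A == 0:
        return float("inf")
    return -np.log(A / B)


class TestSampleEntropy:
    @pytest.mark.parametrize("n,seed", [(20, 0), (50, 1), (120, 2), (200, 3)])
    def test_matches_bruteforce_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        r = 0.35 * x.std()
        assert sample_entropy(x, m=1, r=r) == pytest.approx(
            sampen_bruteforce(x, 1, r), abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(15, 80))
    def test_oracle_property_random_series(self, seed, n):
        x = np.random.default_rng(seed).standard_normal(n)
        r = 0.35 * x.std()
        ours, ref = sample_entropy(x, m=1, r=r), sampen_bruteforce(x, 1, r)
        if np.isinf(ref):
            assert np.isinf(ours)
        else:
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_white_noise_more_entropic_than_sinusoid(self):
        rng = np.random.default_rng(7)
        noise = rng.standard_normal(300)
        tone = np.sin(2 * np.pi * 0.05 * np.arange(300))
        assert sample_entropy(noise) > sample_entropy(tone)

    def test_constant_series_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(sample_entropy(np.ones(50)))


class TestMseProfile:
    def test_default_scales_span_printed_range(self):
        # 13 scales at TR 3.6 s: coarsest block covers 46.8 s
        scales = tuple(range(1, 14))
        assert scales[-1] * 3.6 == pytest.approx(46.8)
        rng = np.random.default_rng(8)
        prof = mse_profile(_bold(rng.standard_normal((2, 150))), scales=scales)
        assert prof.shape == (2, 13)

    def test_white_noise_entropy_falls_faster_than_correlated_signal(self):
        rng = np.random.default_rng(9)
        white = rng.standard_normal(600)
        ar = np.zeros(600)  # AR(1), long-range correlated surrogate
        e = rng.standard_normal(600)
        for i in range(1, 600):
            ar[i] = 0.95 * ar[i - 1] + e[i]
        scales = (1, 2, 4, 8)
        pw = mse_profile(white[None, :], scales=scales)[0]
        pa = mse_profile(ar[None, :], scales=scales)[0]
        assert (pw[0] - pw[-1]) > (pa[0] - pa[-1])

    def test_short_series_names_offending_scale(self):
        # 50 samples: the first scale leaving < 10 points is 6
        with pytest.raises(ValueError, match="scale 6"):
            mse_profile(_bold(np.random.default_rng(10).standard_normal((1, 50))))


class TestRmsd:
    def test_identities_and_hand_example(self):
        p = np.random.default_rng(11).standard_normal((2, 3))
        assert rmsd(p, p) == 0.0
        assert rmsd(p, p + 0.7) == pytest.approx(0.7)
        a = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        b = np.array([[2.0, 2.0, 1.0], [4.0, 8.0, 6.0]])
        assert rmsd(a, b) == pytest.approx(np.sqrt((1 + 0 + 4 + 0 + 9 + 0) / 6))
        with pytest.raises(ValueError):
            rmsd(np.zeros((2, 3)), np.zeros((3, 2)))


class TestGlobalSimilarity:
    def _summary(self, corr=0.5, ks=0.2, dcoh=0.1, dmeta=0.1, rmsd_=0.3):
        return FitSummary(corr=corr, ks=ks, dcoh=dcoh, dmeta=dmeta, rmsd=rmsd_)

    def test_perfect_fit_attains_gs_one(self):
        batch = [self._summary(), FitSummary(1.0, 0.0, 0.0, 0.0, 0.0)]
        out = global_similarity(batch)
        assert out[1].gs == pytest.approx(1.0)
        assert out[0].gs == pytest.approx(2.0)

    def test_normalized_range_and_argmin_preserved(self):
        rng = np.random.default_rng(12)
        batch = [self._summary(corr=c, rmsd_=r)
                 for c, r in rng.random((10, 2))]
        out = global_similarity(batch)
        gs = np.array([s.gs for s in out])
        raw = np.array([s.raw_score() for s in batch])
        assert gs.min() >= 1.0 and gs.max() <= 2.0
        assert np.argmin(gs) == np.argmin(raw)

    def test_raw_score_is_quadratic_in_rmsd_linear_elsewhere(self):
        s = self._summary()
        bumped = self._summary(rmsd_=0.6)
        assert bumped.raw_score() - s.raw_score() == pytest.approx(
            0.6 ** 2 - 0.3 ** 2)
        assert self._summary(ks=0.4).raw_score() - s.raw_score() == \
            pytest.approx(0.2)

    def test_degenerate_sweep_warns_and_yields_ones(self):
        batch = [self._summary(), self._summary()]
        with pytest.warns(UserWarning, match="degenerate"):
            out = global_similarity(batch)
        assert all(s.gs == 1.0 for s in out)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            global_similarity([self._summary()])
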