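"""Entropy features against independent brute-force oracles, closed forms
and the documented matrix-assembly dimensions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from entrofuse.entropy import (
    FEATURES,
    EntropyParams,
    approximate_entropy,
    coarse_grain,
    differential_entropy,
    extract_features,
    fuzzy_entropy,
    multiscale_entropy,
    renyi_entropy,
    sample_entropy,
)
from entrofuse import _kernels
from entrofuse.errors import (
    DegenerateToleranceError,
    EmptyOutputError,
    InsufficientDataError,
    InvalidIndexError,
)

# ---------------------------------------------------------------------------
# naive double-loop oracles (independent of the numba kernels)


def naive_sampen_counts(x, m, r):
    L = len(x) - m
    a = b = 0
    for i in range(L):
        for j in range(i + 1, L):
            d = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d <= r:
                b += 1
                if max(d, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    return a, b


def naive_apen(x, m, r):
    phis = []
    for mm in (m, m + 1):
        L = len(x) - mm + 1
        total = 0.0
        for i in range(L):
            count = 0
            for j in range(L):
                d = max(abs(x[i + k] - x[j + k]) for k in range(mm))
                if d <= r:
                    count += 1
            total += np.log(count / L)
        phis.append(total / L)
    return phis[0] - phis[1]


def naive_fuzzyen(x, m, n, r):
    L = len(x) - m
    omegas = []
    for mm in (m, m + 1):
        sims = []
        for i in range(L):
            ti = x[i:i + mm] - np.mean(x[i:i + mm])
            for j in range(i + 1, L):
                tj = x[j:j + mm] - np.mean(x[j:j + mm])
                d = np.max(np.abs(ti - tj))
                sims.append(np.exp(-((d / r) ** n)))
        omegas.append(np.mean(sims))
    return np.log(omegas[0] / omegas[1])


# ---------------------------------------------------------------------------


class TestCoarseGrain:
    def test_block_means(self):
        assert np.array_equal(coarse_grain(np.array([1, 2, 3, 4, 5, 6.0]), 2),
                              [1.5, 3.5, 5.5])

    def test_scale_one_is_identity(self, rng):
        x = rng.standard_normal(50)
        assert np.array_equal(coarse_grain(x, 1), x)

    def test_remainder_dropped(self):
        assert np.array_equal(coarse_grain(np.array([1, 2, 3, 4, 5.0]), 2),
                              [1.5, 3.5])

    def test_scale_beyond_length_rejected(self):
        with pytest.raises(EmptyOutputError):
            coarse_grain(np.arange(4.0), 5)


class TestSampleEntropy:
    def test_periodic_series_has_zero_entropy(self):
        x = np.array([1.0, 2.0] * 64)
        assert sample_entropy(x, m=2, r=0.2 * np.std(x)) == 0.0

    def test_counts_match_naive_oracle_bitwise(self, rng):
        for _ in range(20):
            x = rng.standard_normal(120)
            r = 0.2 * np.std(x)
            assert _kernels.sampen_counts(x, 2, r) == naive_sampen_counts(x, 2, r)

    def test_value_matches_oracle(self, rng):
        x = rng.standard_normal(300)
        r = 0.2 * np.std(x)
        a, b = naive_sampen_counts(x, 2, r)
        assert sample_entropy(x, 2, r) == pytest.approx(-np.log(a / b), abs=1e-14)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            sample_entropy(np.arange(3.0), m=2)

    def test_degenerate_tolerance_rejected(self):
        with pytest.raises(DegenerateToleranceError):
            sample_entropy(np.full(64, 2.0), m=2)  # constant -> r = 0


class TestApproximateEntropy:
    def test_constant_series_is_zero(self):
        assert approximate_entropy(np.full(64, 5.0), m=2, r=0.0) == 0.0

    def test_affine_invariance_with_proportional_r(self, rng):
        x = rng.standard_normal(128)
        y = 3.5 * x - 2.0
        ae_x = approximate_entropy(x, 2, 0.2 * np.std(x))
        ae_y = approximate_entropy(y, 2, 0.2 * np.std(y))
        assert ae_x == pytest.approx(ae_y, abs=1e-10)

    def test_matches_naive_oracle(self, rng):
        for _ in range(10):
            x = rng.standard_normal(100)
            r = 0.2 * np.std(x)
            assert approximate_entropy(x, 2, r) == pytest.approx(
                naive_apen(x, 2, r), abs=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            approximate_entropy(np.arange(3.0), m=2, r=0.1)


class TestFuzzyEntropy:
    def test_constant_series_is_zero(self):
        assert fuzzy_entropy(np.full(64, 1.0), m=2, n=2, r=0.5) == 0.0

    def test_nonnegative_on_random_series(self, rng):
        for _ in range(30):
            x = rng.standard_normal(rng.integers(30, 200))
            assert fuzzy_entropy(x) >= 0.0

    def test_matches_naive_oracle(self, rng):
        for _ in range(10):
            x = rng.standard_normal(80)
            r = 0.2 * np.std(x)
            assert fuzzy_entropy(x, 2, 2, r) == pytest.approx(
                naive_fuzzyen(x, 2, 2, r), abs=1e-12)

    def test_degenerate_tolerance_rejected(self, rng):
        with pytest.raises(DegenerateToleranceError):
            fuzzy_entropy(rng.standard_normal(64), r=0.0)


class TestRenyiEntropy:
    def test_uniform_over_k_bins_gives_log_k(self):
        # 10 equal-width bins each holding exactly 4 samples
        edges = np.linspace(0.0, 10.0, 11)
        centers = (edges[:-1] + edges[1:]) / 2
        x = np.repeat(centers, 4)
        assert renyi_entropy(x, q=2, histogram_bins=10) == pytest.approx(
            np.log(10), abs=1e-12)

    def test_single_bin_gives_zero(self):
        assert renyi_entropy(np.full(32, 7.0), q=2) == 0.0

    def test_matches_direct_formula(self, rng):
        x = rng.standard_normal(256)
        counts, _ = np.histogram(x, bins=10)
        p = counts / x.size
        expected = np.log(np.sum(p[p > 0] ** 2)) / (1 - 2)
        assert renyi_entropy(x, q=2, histogram_bins=10) == pytest.approx(
            expected, abs=1e-12)

    @pytest.mark.parametrize("q", [1.0, -0.5])
    def test_invalid_index_rejected(self, q, rng):
        with pytest.raises(InvalidIndexError):
            renyi_entropy(rng.standard_normal(64), q=q)


class TestDifferentialEntropy:
    def test_unit_variance_closed_form(self):
        x = np.array([-1.0, 1.0]) / np.sqrt(2)  # sample variance exactly 1
        assert differential_entropy(x) == pytest.approx(
            0.5 * np.log(2 * np.pi * np.e), abs=1e-9)

    def test_quadrupling_variance_adds_ln2(self, rng):
        x = rng.standard_normal(256)
        assert differential_entropy(2 * x) - differential_entropy(x) == \
            pytest.approx(np.log(2), abs=1e-10)

    def test_large_sample_consistency(self, rng):
        x = rng.standard_normal(200_000)
        assert differential_entropy(x) == pytest.approx(1.4189, abs=0.05)

    def test_zero_variance_flagged(self):
        assert differential_entropy(np.full(16, 3.0)) == -np.inf


class TestMultiscaleEntropy:
    def test_scale_one_equals_sample_entropy(self, rng):
        x = rng.standard_normal(256)
        params = EntropyParams()
        mse = multiscale_entropy(x, params)
        assert mse[0] == sample_entropy(x, params.m, params.r_factor * np.std(x))

    def test_five_scales_from_one_window(self, rng):
        mse = multiscale_entropy(rng.standard_normal(256), EntropyParams())
        assert mse.shape == (5,)
        assert coarse_grain(np.arange(256.0), 5).size == 51

    def test_white_noise_mse_decreases_with_scale(self, rng):
        acc = np.zeros(5)
        n = 60
        for _ in range(n):
            acc += multiscale_entropy(rng.standard_normal(256), EntropyParams())
        mean = acc / n
        assert np.all(np.diff(mean) < 0)

    def test_pink_noise_flatter_than_white(self, rng):
        """1/f noise loses less entropy under coarse-graining than white."""
        from entrofuse.synth import _pink_noise

        drop_w, drop_p = 0.0, 0.0
        for _ in range(40):
            w = multiscale_entropy(rng.standard_normal(256), EntropyParams())
            p = multiscale_entropy(_pink_noise(rng, 256, 256.0, 0.5, 128.0),
                                   EntropyParams())
            drop_w += w[0] - w[4]
            drop_p += p[0] - p[4]
        assert drop_p < drop_w

    def test_short_window_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            multiscale_entropy(rng.standard_normal(10), EntropyParams())


@settings(deadline=None, derandomize=True, max_examples=20)
@given(scale=st.floats(0.5, 20.0), offset=st.floats(-10.0, 10.0),
       seed=st.integers(0, 2 ** 16))
def test_entropy_scaling_laws(scale, offset, seed):
    """SE/FE are affine-invariant with r proportional to the window std;
    DE shifts by ln|a| under amplitude scaling."""
    x = np.random.default_rng(seed).standard_normal(128)
    y = scale * x + offset
    rx, ry = 0.2 * np.std(x), 0.2 * np.std(y)
    assert sample_entropy(x, 2, rx) == pytest.approx(
        sample_entropy(y, 2, ry), abs=1e-9)
    assert fuzzy_entropy(x, 2, 2, rx) == pytest.approx(
        fuzzy_entropy(y, 2, 2, ry), abs=1e-9)
    assert differential_entropy(y) - differential_entropy(x) == pytest.approx(
        np.log(scale), abs=1e-9)


class TestExtractFeatures:
    def test_row_counts_per_feature(self, small_banded):
        # 3 channels x 5 bands: 15 rows per single entropy, 75 for 5-scale MSE
        mse = extract_features(small_banded, EntropyParams(), ("mse",))
        assert mse.n_rows == 3 * 5 * 5
        for feat in ("ae", "fe", "re", "de"):
            fm = extract_features(small_banded, EntropyParams(), (feat,))
            assert fm.n_rows == 3 * 5

    def test_window_columns_and_clip_alignment(self, small_banded):
        fm = extract_features(small_banded, EntropyParams(), ("de",))
        # 6 clips x 4 s of clip-only signal -> 24 one-second windows
        assert fm.n_windows == 24
        assert np.array_equal(np.bincount(fm.clip_index), np.full(6, 4))
        assert np.all(np.isfinite(fm.values))

    def test_combined_call_matches_fused_dimension(self, small_banded):
        fm = extract_features(small_banded, EntropyParams(), FEATURES)
        assert fm.n_rows == 75 + 4 * 15
        assert list(fm.row_meta["feature"].unique()) == list(FEATURES)

    def test_row_meta_scales_only_for_mse(self, small_banded):
        fm = extract_features(small_banded, EntropyParams(), ("mse", "de"))
        mse_rows = fm.row_meta[fm.row_meta.feature == "mse"]
        assert sorted(mse_rows["scale"].unique()) == [1, 2, 3, 4, 5]
        de_rows = fm.row_meta[fm.row_meta.feature == "de"]
        assert de_rows["scale"].isna().all()
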