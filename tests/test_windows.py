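"""Window aggregation, smoothing, density summaries and correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pmeth
from pmeth.io import as_cpg_track
from tests.conftest import random_cpg_track


def brute_window_means(calls, window_size, min_cpgs):
    """Independent per-window recomputation by explicit site enumeration."""
    out = {}
    for chrom, grp in calls.groupby("chrom", sort=False):
        informative = grp[grp["fraction"].notna()]
        n_win = int(grp["pos"].max() // window_size) + 1
        for w in range(n_win):
            lo, hi = w * window_size, (w + 1) * window_size
            sites = informative[(informative["pos"] >= lo) & (informative["pos"] < hi)]
            mean = sites["fraction"].mean() if len(sites) >= min_cpgs else np.nan
            out[(chrom, lo)] = (mean, len(sites))
    return out


def brute_running_median(values, width):
    """Naive O(n*w) centered median with truncated end neighborhoods."""
    x = np.asarray(values, dtype=float)
    half = width // 2
    out = np.full(len(x), np.nan)
    for i in range(len(x)):
        nb = x[max(0, i - half): i + half + 1]
        nb = nb[~np.isnan(nb)]
        if len(nb):
            out[i] = np.median(nb)
    return out


class TestWindowMethylation:
    def test_min_cpgs_filter(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(20_000, size=19, replace=False))
        calls = as_cpg_track(
            pd.DataFrame({"chrom": "chr1", "pos": pos, "meth_reads": 1.0, "total_reads": 1.0})
        )
        track = pmeth.window_methylation(calls, 20_000, min_cpgs=20)
        assert np.isnan(track.loc[0, "mean_meth"])
        assert track.loc[0, "n_cpgs"] == 19
        track = pmeth.window_methylation(calls, 20_000, min_cpgs=19)
        assert track.loc[0, "mean_meth"] == 1.0

    def test_known_mean(self):
        calls = as_cpg_track(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "pos": [10, 20, 30, 40, 50],
                    "fraction": [0.2, 0.4, 0.6, 0.8, 1.0],
                }
            )
        )
        track = pmeth.window_methylation(calls, 100, min_cpgs=5)
        assert track.loc[0, "mean_meth"] == pytest.approx(0.6)

    def test_empty_input(self):
        empty = as_cpg_track(pd.DataFrame(columns=["chrom", "pos"]).astype({"pos": int}))
        assert pmeth.window_methylation(empty, 1000, 1).empty

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        calls = random_cpg_track(rng, n=400)
        track = pmeth.window_methylation(calls, 50_000, min_cpgs=3)
        expected = brute_window_means(calls, 50_000, 3)
        for _, row in track.iterrows():
            exp_mean, exp_n = expected[(row["chrom"], row["start"])]
            assert row["n_cpgs"] == exp_n
            if np.isnan(exp_mean):
                assert np.isnan(row["mean_meth"])
            else:
                assert row["mean_meth"] == pytest.approx(exp_mean, abs=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        calls = random_cpg_track(rng, n=300)
        shuffled = as_cpg_track(calls.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(
            pmeth.window_methylation(calls, 10_000, 2),
            pmeth.window_methylation(shuffled, 10_000, 2),
        )


class TestGlobalMethylation:
    def test_pooled_counts(self):
        calls = as_cpg_track(
            pd.DataFrame(
                {"chrom": "chr1", "pos": [1, 2], "meth_reads": [3.0, 1.0], "total_reads": [4.0, 4.0]}
            )
        )
        assert pmeth.global_methylation(calls) == 0.5

    def test_zero_site(self):
        calls = as_cpg_track(
            pd.DataFrame({"chrom": "chr1", "pos": [1], "meth_reads": [0.0], "total_reads": [10.0]})
        )
        assert pmeth.global_methylation(calls) == 0.0

    def test_matches_pooled_ratio_and_bounds(self):
        rng = np.random.default_rng(11)
        calls = random_cpg_track(rng, n=1000)
        expected = calls["meth_reads"].sum() / calls["total_reads"].sum()
        g = pmeth.global_methylation(calls)
        assert g == pytest.approx(expected, abs=1e-15)
        assert calls["fraction"].min() <= g <= calls["fraction"].max()

    def test_fraction_dialect_falls_back_with_warning(self):
        rng = np.random.default_rng(12)
        calls = random_cpg_track(rng, n=50, with_counts=False)
        with pytest.warns(UserWarning, match="unweighted"):
            g = pmeth.global_methylation(calls)
        assert g == pytest.approx(calls["fraction"].mean())


class TestRunningMedian:
    def test_constant_series(self):
        np.testing.assert_array_equal(pmeth.running_median([3.0] * 10, 5), [3.0] * 10)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            pmeth.running_median([1.0, 2.0], 4)

    def test_toy_series_against_oracle(self):
        x = [1.0, 9.0, 1.0, 9.0, 1.0]
        np.testing.assert_array_equal(
            pmeth.running_median(x, 3), brute_running_median(x, 3)
        )
        np.testing.assert_array_equal(pmeth.running_median(x, 3), [5.0, 1.0, 9.0, 1.0, 5.0])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        width=st.sampled_from([1, 3, 5, 15]),
        n=st.integers(5, 60),
    )
    def test_matches_oracle_with_missing(self, seed, width, n):
        rng = np.random.default_rng(seed)
        x = rng.random(n)
        x[rng.random(n) < 0.25] = np.nan
        got = pmeth.running_median(x, width)
        exp = brute_running_median(x, width)
        np.testing.assert_allclose(got, exp, equal_nan=True)

    def test_idempotent_on_monotone(self):
        # interior windows only: truncated end neighborhoods shift a ramp's
        # first/last values on the first pass, so idempotency holds inside
        x = np.linspace(0, 1, 40)
        once = pmeth.running_median(x, 5)
        twice = pmeth.running_median(once, 5)
        np.testing.assert_allclose(twice[2:-2], once[2:-2])


class TestKernelSmooth:
    @staticmethod
    def _track(vals, size=1000):
        n = len(vals)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * size,
                "end": (np.arange(n) + 1) * size,
                "mean_meth": vals,
                "n_cpgs": 10,
            }
        )

    def test_constant_track(self):
        t = self._track([0.5] * 20)
        out = pmeth.kernel_smooth(t, bandwidth=3000)
        np.testing.assert_allclose(out["mean_meth"], 0.5)

    def test_tiny_bandwidth_reproduces_input(self):
        rng = np.random.default_rng(3)
        t = self._track(rng.random(15))
        out = pmeth.kernel_smooth(t, bandwidth=1.0)
        np.testing.assert_allclose(out["mean_meth"], t["mean_meth"], atol=1e-12)

    def test_against_double_loop(self):
        rng = np.random.default_rng(4)
        vals = rng.random(5)
        t = self._track(vals)
        bw = 1500.0
        out = pmeth.kernel_smooth(t, bandwidth=bw)
        centers = (t["start"] + t["end"]).to_numpy() / 2
        for i in range(5):
            num = den = 0.0
            for j in range(5):
                w = np.exp(-0.5 * ((centers[i] - centers[j]) / bw) ** 2)
                num += w * vals[j]
                den += w
            assert out.loc[i, "mean_meth"] == pytest.approx(num / den, abs=1e-10)

    def test_never_invents_values_across_gaps(self):
        vals = [0.5] * 5 + [np.nan] * 20 + [0.8] * 5
        t = self._track(vals)
        out = pmeth.kernel_smooth(t, bandwidth=3000)
        # gap interior (further than one bandwidth from any data) stays missing
        assert out["mean_meth"].iloc[10:20].isna().all()


class TestDensity:
    @staticmethod
    def _track_from_values(vals):
        n = len(vals)
        return pd.DataFrame(
            {
                "chrom": "chr1", "start": np.arange(n) * 20_000,
                "end": (np.arange(n) + 1) * 20_000, "mean_meth": vals, "n_cpgs": 30,
            }
        )

    def test_point_mass(self):
        d = pmeth.methylation_density(self._track_from_values([0.75] * 50))
        assert d.point_mass and not d.bimodal
        assert d.median == 75.0 and d.iqr == 0.0

    def test_planted_mixture_is_bimodal(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate(
            [rng.normal(0.35, 0.03, 2500), rng.normal(0.75, 0.03, 2500)]
        ).clip(0, 1)
        d = pmeth.methylation_density(self._track_from_values(vals))
        assert d.bimodal

    def test_single_gaussian_not_bimodal(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(0.6, 0.05, 3000).clip(0, 1)
        d = pmeth.methylation_density(self._track_from_values(vals))
        assert not d.bimodal

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(10)
        d = pmeth.methylation_density(self._track_from_values(rng.random(500)))
        assert np.trapezoid(d.density, d.grid) == pytest.approx(1.0, abs=1e-6)


class TestCorrelate:
    def test_identical_and_inverted(self):
        rng = np.random.default_rng(6)
        vals = rng.random(50)
        a = TestKernelSmooth._track(vals)
        b = TestKernelSmooth._track(1 - vals)
        r, n = pmeth.correlate_tracks(a, a)
        assert r == pytest.approx(1.0)
        r, _ = pmeth.correlate_tracks(a, b)
        assert r == pytest.approx(-1.0)

    def test_too_few_shared_windows(self):
        a = TestKernelSmooth._track([0.1, np.nan, 0.3, np.nan])
        with pytest.raises(ValueError):
            pmeth.correlate_tracks(a, a)

    def test_formula_and_replicate_correlation(self, demo_bundle, demo_methylome):
        """Two binomial resamplings of one methylome correlate strongly at 20 kb."""
        # an unrearranged, offset-free species pair is a technical replicate:
        # same per-site truth, fresh noise and fresh binomial sampling
        rep2 = pmeth.simulate_species_pair(demo_bundle, demo_methylome, seed=999)
        ta = pmeth.window_methylation(demo_methylome.calls, 20_000, 20,
                                      chrom_sizes=demo_bundle.chrom_sizes)
        tb = pmeth.window_methylation(rep2.calls, 20_000, 20,
                                      chrom_sizes=demo_bundle.chrom_sizes)
        r, n = pmeth.correlate_tracks(ta, tb)
        merged = ta.merge(tb, on=["chrom", "start"], suffixes=("_a", "_b")).dropna(
            subset=["mean_meth_a", "mean_meth_b"]
        )
        x, y = merged["mean_meth_a"], merged["mean_meth_b"]
        direct = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(direct, abs=1e-12)
        assert r > 0.8 and n > 900
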