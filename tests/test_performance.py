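"""Removal arithmetic, smoothing, Spearman screening and Kruskal-Wallis."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adlink.datamodel import Feed, PerformanceSeries, Stage
from adlink.performance import (
    DegenerateInputError,
    correlate_taxa_performance,
    kruskal_wallis,
    moving_average,
    removal_percent,
    smooth_performance,
    spearman,
)
from adlink.qpcr import estimated_absolute_abundance, relative_abundance
from adlink.simulate import GeneratorConfig, generate_experiment
from adlink import pipeline


class TestRemoval:
    def test_ninety_percent(self):
        assert removal_percent(8000, 800) == pytest.approx(90.0)

    def test_no_removal(self):
        assert removal_percent(5000, 5000) == 0.0

    def test_complete_removal(self):
        assert removal_percent(5000, 0) == 100.0

    def test_negative_removal_reported_not_clipped(self):
        assert removal_percent(1000, 1500) == pytest.approx(-50.0)

    def test_nonpositive_influent_rejected(self):
        with pytest.raises(ValueError):
            removal_percent(0, 10)


class TestMovingAverage:
    def test_trailing_window_membership(self):
        got = moving_average([(1, 10.0), (4, 20.0), (8, 30.0)], window_days=5)
        assert got == [(1, 10.0), (4, 15.0), (8, 25.0)]

    def test_constant_series_unchanged(self):
        series = [(d, 7.0) for d in range(0, 30, 3)]
        assert moving_average(series) == series

    def test_single_point_is_itself(self):
        assert moving_average([(10, 42.0)]) == [(10, 42.0)]

    def test_empty_series(self):
        assert moving_average([]) == []

    def test_bounded_by_windowed_extremes(self):
        rng = np.random.default_rng(30)
        days = np.cumsum(rng.integers(1, 5, size=25))
        vals = rng.normal(50, 10, size=25)
        series = list(zip(days.tolist(), vals.tolist()))
        for d, sm in moving_average(series, window_days=5):
            window = [v for dd, v in series if d - 5 <= dd <= d]
            assert min(window) - 1e-9 <= sm <= max(window) + 1e-9

    def test_smooth_performance_attaches_series(self):
        ps = PerformanceSeries("p", [(1, 8000.0, 800.0), (3, 8000.0, 400.0)])
        smooth_performance(ps, 5)
        assert ps.smoothed[0] == (1, pytest.approx(90.0))
        assert ps.smoothed[1] == (3, pytest.approx(92.5))


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.tuples(st.integers(0, 400), st.floats(-100, 200)),
        min_size=1, max_size=25, unique_by=lambda t: t[0],
    )
)
def test_moving_average_stays_within_observed_range(points):
    series = sorted(points)
    smoothed = moving_average(series, window_days=5)
    lo = min(v for _, v in series)
    hi = max(v for _, v in series)
    assert all(lo - 1e-9 <= v <= hi + 1e-9 for _, v in smoothed)
    assert [d for d, _ in smoothed] == [d for d, _ in series]


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.lists(st.integers(-50, 50), min_size=10, max_size=20),
    st.integers(0, 2**31 - 1),
)
def test_spearman_invariant_under_strictly_monotone_transform(x, seed):
    x = np.asarray(x, dtype=float)
    y = np.random.default_rng(seed).normal(size=x.size)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    rho, _ = spearman(x, y)
    rho2, _ = spearman(3.0 * x + 7.0, y)      # affine, order-preserving
    rho3, _ = spearman(x, np.exp(y / 10.0))   # nonlinear, order-preserving
    assert rho2 == pytest.approx(rho, abs=1e-12)
    assert rho3 == pytest.approx(rho, abs=1e-12)


def brute_force_spearman_rho(x, y):
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def brute_force_exact_p(x, y):
    """Direct two-sided enumeration over all pairings (small n only)."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    count = 0
    for perm in itertools.permutations(range(n)):
        r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return count / math.factorial(n)


class TestSpearman:
    def test_monotone_increasing(self):
        rho, _ = spearman([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        rho, _ = spearman([1, 2, 3], [30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_tied_ranks_hand_case(self):
        rho, _ = spearman([1, 2, 2, 3], [1, 3, 2, 4])
        assert rho == pytest.approx(brute_force_spearman_rho([1, 2, 2, 3], [1, 3, 2, 4]))
        assert rho == pytest.approx(3 / math.sqrt(10), abs=1e-12)

    def test_rho_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(4, 25))
            x = rng.integers(0, 8, n).astype(float)
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_permutation_p_equals_enumeration(self, n):
        rng = np.random.default_rng(32 + n)
        x = rng.normal(size=n)
        y = rng.integers(0, 3, size=n).astype(float)
        if np.ptp(y) == 0:
            y[0] += 1
        _, p = spearman(x, y)
        assert p == pytest.approx(brute_force_exact_p(x, y), abs=1e-15)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(33)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = spearman(x, y)
        t = rho * math.sqrt(28 / (1 - rho**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 28), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(34)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        rho, p = spearman(x, y)
        rho2, p2 = spearman(np.exp(x), y)  # strictly monotone transform
        assert rho2 == pytest.approx(rho, abs=1e-12)
        assert p2 == pytest.approx(p, abs=1e-12)

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman([1, 2], [3, 4])


def brute_force_kruskal_h(groups):
    """Tie-corrected rank-sum formula evaluated directly."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx: idx + len(g)]
        idx += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_hand_case_h_7_2(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.h == pytest.approx(7.2, abs=1e-12)
        assert res.h == pytest.approx(
            brute_force_kruskal_h([[1, 2, 3], [4, 5, 6], [7, 8, 9]]), abs=1e-12
        )

    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[2, 2, 2], [2, 2, 2]])
        assert res.h == 0.0 and res.p_value == 1.0

    def test_matches_formula_with_ties_on_random_groups(self):
        rng = np.random.default_rng(35)
        for _ in range(50):
            groups = [
                rng.integers(0, 6, size=int(rng.integers(3, 9))).astype(float)
                for _ in range(int(rng.integers(2, 5)))
            ]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            res = kruskal_wallis(groups)
            assert res.h == pytest.approx(brute_force_kruskal_h(groups), abs=1e-10)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestScreening:
    def test_zero_noise_perfect_correlate_recovered_exactly(self):
        bundle = generate_experiment(
            GeneratorConfig(seed=7, target_rho=1.0, day_end=120)
        )
        n = pipeline.total_copies_per_ml(bundle.qpcr, bundle.metadata)
        ra, _ = relative_abundance(bundle.counts)
        eaa = estimated_absolute_abundance(n, ra)
        records = correlate_taxa_performance(eaa, bundle.scod, bundle.metadata)
        by = {(r.genus, r.stage, r.feed): r for r in records}
        for genus, stage, feed, _ in bundle.truth.planted_correlates:
            rec = by[(genus, stage, feed)]
            assert rec.rho == 1.0
            assert rec.passed_filter

    def test_constant_abundance_genus_emits_no_record(self, toy):
        bundle, _ = toy
        n = pipeline.total_copies_per_ml(bundle.qpcr, bundle.metadata)
        ra, _ = relative_abundance(bundle.counts)
        eaa = estimated_absolute_abundance(n, ra)
        eaa.eaa.loc["g_ubiquitous"] = 5.0  # flat abundance: degenerate screen
        records = correlate_taxa_performance(
            eaa, bundle.scod, bundle.metadata, min_n=3
        )
        assert records  # others are screened
        assert all(r.genus != "g_ubiquitous" for r in records)

    def test_records_sorted_by_stage_feed_abs_rho(self, default_bundle):
        bundle = default_bundle
        n = pipeline.total_copies_per_ml(bundle.qpcr, bundle.metadata)
        ra, _ = relative_abundance(bundle.counts)
        eaa = estimated_absolute_abundance(n, ra)
        records = correlate_taxa_performance(eaa, bundle.scod, bundle.metadata)
        keys = [(r.stage.value, r.feed.value) for r in records]
        assert keys == sorted(keys)
        for (s, f), grp in itertools.groupby(
            records, key=lambda r: (r.stage, r.feed)
        ):
            rhos = [abs(r.rho) for r in grp]
            assert rhos == sorted(rhos, reverse=True)

    def test_total_biomass_not_correlated_with_removal(self):
        """Total 16S copies are generated independently of removal, so the
        biomass-removal Spearman should rarely be significant."""
        hits, seeds = 0, 20
        for seed in range(seeds):
            bundle = generate_experiment(
                GeneratorConfig(seed=400 + seed, day_end=120, n_background_taxa=10,
                                n_core=4, n_unique_per_feed=2)
            )
            n = pipeline.total_copies_per_ml(bundle.qpcr, bundle.metadata)
            by_feed = {s.pair_id: dict(s.smoothed) for s in bundle.scod}
            xs, ys = [], []
            for rec in bundle.metadata:
                if rec.stage is not Stage.first:
                    continue
                xs.append(n[rec.sample_id])
                ys.append(by_feed[rec.feed.value][rec.day])
            _, p = spearman(xs, ys)
            hits += p <= 0.05
        assert hits / seeds <= 0.10
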