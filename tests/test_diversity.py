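"""Bray-Curtis, Shannon, NMDS and the Mantel permutation test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skbio.stats.distance import DistanceMatrix

from adlink.datamodel import AlignmentError, CountTable, Feed, SampleRecord, Stage
from adlink.diversity import (
    bray_curtis,
    factor_distance,
    mantel,
    nmds,
    shannon,
    shannon_per_sample,
)
from conftest import random_count_table


def _table(arr, samples=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountTable(
        pd.DataFrame(arr, index=[f"t{i}" for i in range(arr.shape[0])], columns=samples)
    )


def brute_force_bray_curtis(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return np.abs(x - y).sum() / (x + y).sum()


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        d = bray_curtis(_table([[3, 3], [1, 1]]))
        assert d["s0", "s1"] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(_table([[4, 0], [0, 9]]))
        assert d["s0", "s1"] == 1.0

    def test_hand_example(self):
        d = bray_curtis(_table([[1, 0], [1, 2]]))
        assert d["s0", "s1"] == pytest.approx(0.5)

    def test_zero_sum_column_rejected_with_name(self):
        with pytest.raises(ValueError, match="s1"):
            bray_curtis(_table([[1, 0], [2, 0]]))

    def test_matches_formula_and_invariances_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            table = random_count_table(rng)
            d = bray_curtis(table)
            arr = d.data
            assert np.allclose(arr, arr.T)
            assert np.allclose(np.diag(arr), 0.0)
            assert (arr >= -1e-12).all() and (arr <= 1 + 1e-12).all()
            i, j = table.samples[0], table.samples[-1]
            assert d[i, j] == pytest.approx(
                brute_force_bray_curtis(table.column(i), table.column(j)), abs=1e-12
            )
            # common scaling of all columns leaves the dissimilarity unchanged
            scaled = CountTable(table.data * 3)
            assert np.allclose(bray_curtis(scaled).data, arr, atol=1e-12)


class TestShannon:
    def test_uniform_over_four(self):
        assert shannon([10, 10, 10, 10]) == pytest.approx(math.log(4), abs=1e-12)

    def test_single_taxon_zero(self):
        assert shannon([5, 0, 0]) == 0.0

    def test_hand_example(self):
        # -sum p ln p for p = (1/2, 1/4, 1/4)
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert shannon([2, 1, 1]) == pytest.approx(expected, abs=1e-12)
        assert shannon([2, 1, 1]) == pytest.approx(1.0397, abs=1e-4)

    def test_scale_invariance_and_richness_bound(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.integers(1, 50, size=int(rng.integers(2, 10)))
            assert shannon(x) == pytest.approx(shannon(100 * x), abs=1e-12)
            assert 0.0 <= shannon(x) <= math.log(len(x)) + 1e-12

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_per_sample_records(self):
        recs = shannon_per_sample(_table([[2, 5], [2, 0]]))
        assert [r.sample_id for r in recs] == ["s0", "s1"]
        assert recs[0].shannon_h == pytest.approx(math.log(2))
        assert recs[1].shannon_h == 0.0


def euclidean_dm(points):
    pts = np.asarray(points, float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(d, ids=[f"p{i}" for i in range(len(pts))])


class TestNMDS:
    def test_colinear_points_embed_in_one_dimension(self):
        d = euclidean_dm([[0.0], [1.0], [2.5], [4.0], [7.0]])
        res = nmds(d, k=1, trymax=20, seed=0)
        assert res.stress < 0.01

    def test_exactly_embeddable_stress_near_zero(self):
        rng = np.random.default_rng(13)
        d = euclidean_dm(rng.normal(size=(9, 3)))
        res = nmds(d, k=3, trymax=20, seed=1)
        assert res.stress <= 1e-3

    def test_stress_non_increasing_in_k(self):
        rng = np.random.default_rng(14)
        table = random_count_table(rng, n_taxa=10, n_samples=14)
        d = bray_curtis(table)
        s2 = nmds(d, k=2, trymax=10, seed=2).stress
        s4 = nmds(d, k=4, trymax=10, seed=2).stress
        assert s4 <= s2 + 1e-9

    def test_same_seed_identical(self):
        rng = np.random.default_rng(15)
        table = random_count_table(rng, n_taxa=8, n_samples=10)
        d = bray_curtis(table)
        r1 = nmds(d, k=2, trymax=5, seed=3)
        r2 = nmds(d, k=2, trymax=5, seed=3)
        assert r1.stress == r2.stress
        assert np.array_equal(r1.coordinates, r2.coordinates)

    def test_too_few_samples_rejected(self):
        d = euclidean_dm([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError):
            nmds(d, k=4, seed=0)

    def test_configuration_is_centred(self):
        d = euclidean_dm(np.random.default_rng(16).normal(size=(8, 2)))
        res = nmds(d, k=2, trymax=5, seed=4)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)


def brute_force_mantel_p(d1, d2, method="pearson"):
    """Exhaustive enumeration over all label permutations of d2."""
    from adlink.diversity import _corr, _triangle

    t1 = _triangle(d1)
    r_obs = _corr(t1, _triangle(d2), method)
    n = d1.shape[0]
    count = 0
    for perm in itertools.permutations(range(n)):
        idx = np.asarray(perm)
        if _corr(t1, _triangle(d2[np.ix_(idx, idx)]), method) >= r_obs - 1e-12:
            count += 1
    return r_obs, count / math.factorial(n)


class TestMantel:
    def _pair(self, rng, n=4):
        a = rng.normal(size=(n, 2))
        b = rng.normal(size=(n, 2))
        return euclidean_dm(a), euclidean_dm(b)

    def test_identical_matrices_r_one_minimal_p(self):
        rng = np.random.default_rng(17)
        d = euclidean_dm(rng.normal(size=(20, 3)))
        res = mantel(d, d, n_permutations=999, seed=5)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_constant_off_diagonal_degenerate(self):
        d1 = euclidean_dm(np.random.default_rng(18).normal(size=(5, 2)))
        d2 = DistanceMatrix(1 - np.eye(5), ids=d1.ids)
        res = mantel(d1, d2, seed=6)
        assert res.degenerate and math.isnan(res.r)

    @pytest.mark.parametrize("trial", range(10))
    def test_exhaustive_small_case_matches_enumeration(self, trial):
        rng = np.random.default_rng(300 + trial)
        d1, d2 = self._pair(rng, n=4)
        res = mantel(d1, d2, n_permutations=999, seed=7)
        r_oracle, p_oracle = brute_force_mantel_p(
            np.asarray(d1.data), np.asarray(d2.data)
        )
        assert res.n_permutations == 24
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-15)

    def test_statistic_agrees_with_reference_implementation(self):
        """Cross-check r against the independent scikit-bio Mantel."""
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(19)
        d1, d2 = self._pair(rng, n=12)
        res = mantel(d1, d2, n_permutations=99, seed=8)
        r_ref, _, _ = skbio_mantel(d1, d2, permutations=0)
        assert res.r == pytest.approx(float(r_ref), abs=1e-12)

    def test_spearman_method(self):
        rng = np.random.default_rng(20)
        d1, d2 = self._pair(rng, n=10)
        res = mantel(d1, d2, n_permutations=99, method="spearman", seed=9)
        from scipy.stats import spearmanr
        from adlink.diversity import _triangle

        r_ref = spearmanr(
            _triangle(np.asarray(d1.data)), _triangle(np.asarray(d2.data))
        ).statistic
        assert res.r == pytest.approx(float(r_ref), abs=1e-12)

    def test_label_mismatch_rejected(self):
        d1 = euclidean_dm(np.random.default_rng(21).normal(size=(5, 2)))
        d2 = DistanceMatrix(np.asarray(d1.data), ids=[f"q{i}" for i in range(5)])
        with pytest.raises(AlignmentError):
            mantel(d1, d2)


class TestFactorDistance:
    def _meta(self):
        return [
            SampleRecord("a", "R1", Stage.first, Feed.starch, 55, 1.5, 100.0),
            SampleRecord("b", "R1", Stage.first, Feed.starch, 120, 1.5, 100.0),
            SampleRecord("c", "R2", Stage.second, Feed.dairy, 185, 1.5, 100.0),
        ]

    def test_categorical_mismatch_encoding(self):
        d = factor_distance(self._meta(), "feed")
        assert d["a", "b"] == 0.0 and d["a", "c"] == 1.0

    def test_stage_encoding(self):
        d = factor_distance(self._meta(), "stage")
        assert d["a", "c"] == 1.0 and d["a", "b"] == 0.0

    def test_day_rescaled_to_unit_range(self):
        d = factor_distance(self._meta(), "day")
        assert d["a", "c"] == pytest.approx(1.0)
        assert d["a", "b"] == pytest.approx(65 / 130)

    def test_missing_sample_rejected(self):
        with pytest.raises(ValueError):
            factor_distance(self._meta(), "feed", ids=["a", "zzz"])
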