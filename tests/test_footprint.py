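import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from deltadnase.core_io import CutProfile, GenomicInterval
from deltadnase.footprint import (
    FootprintMatrix,
    aggregate_profile,
    compare_stability,
    footprint_matrix,
    kmeans_stability,
    matched_correlations,
    select_k,
    _pearson_matrix,
)
from deltadnase.synthetic_data import default_templates


def template_rows(rng, n_per=200, rate=1.0):
    """Poisson footprint vectors: ~30 expected cuts/site at rate 1/bp."""
    rows, labels = [], []
    for name, tpl in sorted(default_templates().items()):
        mean = rate * tpl.values
        rows.append(rng.poisson(np.tile(mean, (n_per, 1))))
        labels += [name] * n_per
    return np.vstack(rows), labels


@pytest.fixture()
def planted_matrix(rng):
    values, labels = template_rows(rng)
    order = rng.permutation(len(labels))
    mat = FootprintMatrix(values[order], [labels[i] for i in order])
    return mat, [labels[i] for i in order]


class TestFootprintMatrix:
    def _matches(self, centers, strand="+"):
        return [
            GenomicInterval("c", c - 7, c + 8, strand) for c in centers
        ]

    def test_zero_profile_zero_matrix(self):
        prof = CutProfile({"c": np.zeros(1000, dtype=np.int64)})
        mat = footprint_matrix(prof, self._matches([500]))
        assert mat.values.shape == (1, 31)
        assert mat.values.sum() == 0

    def test_single_cut_at_center_lands_in_middle_column(self):
        vec = np.zeros(1000, dtype=np.int64)
        vec[500] = 1
        mat = footprint_matrix(CutProfile({"c": vec}), self._matches([500]))
        assert mat.values[0, 15] == 1
        assert mat.values.sum() == 1

    def test_minus_strand_row_is_reversed_plus_row(self, rng):
        vec = rng.poisson(1.0, 1000)
        prof = CutProfile({"c": vec})
        plus = footprint_matrix(prof, self._matches([500], "+"))
        minus = footprint_matrix(prof, self._matches([500], "-"))
        assert np.array_equal(minus.values[0], plus.values[0][::-1])

    def test_edge_sites_skipped_with_count(self, rng):
        prof = CutProfile({"c": rng.poisson(1.0, 100)})
        mat = footprint_matrix(prof, self._matches([10, 50, 95]))
        assert len(mat) == 1
        assert mat.n_skipped == 2


class TestAggregateProfile:
    def test_single_site_equals_its_row(self, rng):
        vec = rng.poisson(1.0, 2000)
        prof = CutProfile({"c": vec})
        m = GenomicInterval("c", 993, 1008)
        agg = aggregate_profile(prof, [m], flank=100)
        assert agg.size == 15 + 200
        assert np.array_equal(agg, vec[893:1108])

    def test_total_conservation(self, rng):
        vec = rng.poisson(1.0, 5000)
        prof = CutProfile({"c": vec})
        matches = [GenomicInterval("c", c, c + 15) for c in (1000, 2000, 3000)]
        agg = aggregate_profile(prof, matches, flank=50)
        expected = sum(vec[c - 50 : c + 65].sum() for c in (1000, 2000, 3000))
        assert agg.sum() == expected

    def test_symmetric_template_gives_symmetric_aggregate(self, rng):
        """Full-dimer protection is mirror symmetric, so the aggregate over
        many sites is symmetric up to sampling noise."""
        tpl = default_templates()["full_dimer"]
        n = 400
        rate = np.ones(215)
        rate[92:123] = tpl.values
        vec = rng.poisson(np.tile(rate, n)).astype(np.int64)
        prof = CutProfile({"c": vec})
        matches = [
            GenomicInterval("c", i * 215 + 100, i * 215 + 115)
            for i in range(n)
        ]
        agg = aggregate_profile(prof, matches, flank=100).astype(float)
        asym = np.abs(agg - agg[::-1]) / agg.mean()
        assert asym.max() < 0.25


class TestMatchedCorrelations:
    def test_equals_brute_force_permutation_search(self, rng):
        """Optimal assignment equals exhaustive search over all k!
        center permutations for k <= 4."""
        for k in (2, 3, 4):
            for _ in range(20):
                a = rng.normal(size=(k, 31))
                b = rng.normal(size=(k, 31))
                got = np.sort(matched_correlations(a, b))
                corr = _pearson_matrix(a, b)
                best = max(
                    sum(corr[i, p[i]] for i in range(k))
                    for p in itertools.permutations(range(k))
                )
                assert got.sum() == pytest.approx(best, abs=1e-12)

    def test_identical_centers_all_ones(self, rng):
        a = rng.normal(size=(3, 31))
        assert np.allclose(matched_correlations(a, a), 1.0)

    def test_constant_center_correlation_zero(self, rng):
        a = np.vstack([np.full(31, 5.0), rng.normal(size=(1, 31))])
        b = rng.normal(size=(2, 31))
        corr = _pearson_matrix(a, b)
        assert np.allclose(corr[0], 0.0)


class TestKmeansStability:
    def test_planted_templates_are_stable(self, rng):
        """Well-separated planted templates (deep coverage, small relative
        noise) give near-perfect cross-run center correlations."""
        values, labels = template_rows(rng, n_per=200, rate=10.0)
        mat = FootprintMatrix(values, labels)
        res = kmeans_stability(mat, k=3, runs=20, seed=0)
        assert res.correlations.size == 3 * 20 * 19 // 2
        assert res.median > 0.99

    def test_recovered_centers_match_templates(self, planted_matrix):
        mat, _ = planted_matrix
        res = kmeans_stability(mat, k=3, runs=5, seed=0)
        templates = default_templates()
        for tpl in templates.values():
            best = max(
                np.corrcoef(tpl.values, c)[0, 1] for c in res.centers[0]
            )
            assert best > 0.9

    def test_noise_rows_are_unstable(self, rng):
        mat = FootprintMatrix(
            rng.poisson(1.0, (600, 31)), [f"s{i}" for i in range(600)]
        )
        res = kmeans_stability(mat, k=3, runs=20, seed=0)
        assert res.median < 0.8

    def test_deterministic_given_seed(self, planted_matrix):
        mat, _ = planted_matrix
        a = kmeans_stability(mat, k=3, runs=5, seed=3)
        b = kmeans_stability(mat, k=3, runs=5, seed=3)
        assert np.array_equal(a.correlations, b.correlations)

    def test_two_runs_identical_convergence(self, rng):
        """On well-separated clusters both runs converge to the same
        centers, so every matched correlation is ~1."""
        values, labels = template_rows(rng, n_per=200, rate=10.0)
        res = kmeans_stability(FootprintMatrix(values, labels), k=3, runs=2,
                               seed=1)
        assert np.all(res.correlations > 0.999)

    def test_k_exceeding_rows_rejected(self, rng):
        mat = FootprintMatrix(rng.poisson(1.0, (4, 31)), list("abcd"))
        with pytest.raises(ValueError):
            kmeans_stability(mat, k=5, runs=2, seed=0)


class TestCompareStability:
    def test_identical_distributions_p_near_one(self, planted_matrix):
        mat, _ = planted_matrix
        res = kmeans_stability(mat, k=3, runs=10, seed=0)
        comp = compare_stability(res, res)
        assert comp.pvalue > 0.9
        assert comp.higher == "tie"

    def test_argument_order_flips_label_not_p(self, planted_matrix, rng):
        mat, _ = planted_matrix
        noise = FootprintMatrix(
            rng.poisson(1.0, (600, 31)), [f"s{i}" for i in range(600)]
        )
        a = kmeans_stability(mat, k=3, runs=15, seed=0)
        b = kmeans_stability(noise, k=3, runs=15, seed=0)
        ab = compare_stability(a, b)
        ba = compare_stability(b, a)
        assert ab.pvalue == pytest.approx(ba.pvalue)
        assert ab.higher == "a" and ba.higher == "b"
        assert ab.pvalue < 1e-10


class TestSelectK:
    def test_three_planted_templates_recommend_three(self, planted_matrix):
        mat, _ = planted_matrix
        sel = select_k(mat, [2, 3, 4, 5], runs=20, seed=4)
        assert sel["recommended"] == 3

    def test_single_template_saturates_stability(self, rng):
        """With one planted pattern every center inherits its shape, so the
        matched-correlation medians stay high for every candidate k and the
        statistic cannot discriminate pattern count (reported as such)."""
        tpl = default_templates()["full_dimer"]
        values = rng.poisson(np.tile(tpl.values, (300, 1)))
        mat = FootprintMatrix(values, [f"s{i}" for i in range(300)])
        sel = select_k(mat, [2, 3], runs=8, seed=0)
        assert set(sel["medians"]) == {2, 3}
        assert all(m > 0.9 for m in sel["medians"].values())

    def test_noise_gives_no_recommendation(self, rng):
        mat = FootprintMatrix(rng.poisson(1.0, (300, 31)),
                              [f"s{i}" for i in range(300)])
        sel = select_k(mat, [2, 3], runs=8, seed=0)
        assert sel["recommended"] is None

    def test_deterministic(self, planted_matrix):
        mat, _ = planted_matrix
        a = select_k(mat, [2, 3], runs=5, seed=9)
        b = select_k(mat, [2, 3], runs=5, seed=9)
        assert a["medians"] == b["medians"]
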