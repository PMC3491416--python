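import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

from deltadnase.core_io import CutProfile, GenomicInterval
from deltadnase.delta_dnase import (
    CountMatrix,
    DiffResult,
    Window,
    classify_and_merge,
    count_and_filter,
    estimate_common_dispersion,
    exact_nb_pvalue,
    nb_exact_test,
    normalized_differential_score,
    tile_region,
    tmm_factors,
    union_regions,
)
from deltadnase.peaks import overlap_fraction
from deltadnase.synthetic_data import UNTREATED


def brute_force_tiling(length, width=300, step=150, edge_frac=0.10):
    """Independent statement of the tiling rule for cross-checking."""
    if length <= width:
        return 1, True
    n = (length - width) // step + 1
    uncovered = length - ((n - 1) * step + width)
    if uncovered < edge_frac * length:
        return n, uncovered == 0
    return n + 1, True


class TestTiling:
    def test_small_region_centered_expansion(self):
        w = tile_region(GenomicInterval("c", 1000, 1200))
        assert [(w[0].interval.start, w[0].interval.end)] == [(950, 1250)]

    def test_exact_width_region_is_itself(self):
        w = tile_region(GenomicInterval("c", 0, 300))
        assert [(x.interval.start, x.interval.end) for x in w] == [(0, 300)]

    def test_default_stride_accepted_at_750(self):
        w = tile_region(GenomicInterval("c", 0, 750))
        assert [x.interval.start for x in w] == [0, 150, 300, 450]
        assert w[-1].interval.end == 750

    def test_oracle_on_random_lengths(self, rng):
        """Window count, exact width, coverage and edge-loss bounds match a
        brute-force restatement on 1,000 random lengths."""
        for _ in range(1000):
            length = int(rng.integers(50, 5001))
            wins = tile_region(GenomicInterval("c", 10_000, 10_000 + length))
            n_expected, full = brute_force_tiling(length)
            assert len(wins) == n_expected
            assert all(len(x.interval) == 300 for x in wins)
            cov = np.zeros(length, bool)
            for x in wins:
                lo = max(x.interval.start - 10_000, 0)
                hi = min(x.interval.end - 10_000, length)
                cov[lo:hi] = True
            if length > 300:
                uncovered = int((~cov).sum())
                if full:
                    assert uncovered == 0
                else:
                    assert uncovered < 0.10 * length

    def test_window_wider_than_chromosome_rejected(self):
        with pytest.raises(ValueError):
            tile_region(GenomicInterval("c", 0, 100), chrom_size=200)


class TestUnionRegions:
    def test_overlap_merged(self):
        u = union_regions(
            [GenomicInterval("c", 0, 100)], [GenomicInterval("c", 50, 150)]
        )
        assert [(r.start, r.end) for r in u] == [(0, 150)]

    def test_disjoint_sorted(self):
        u = union_regions(
            [GenomicInterval("c", 500, 600)], [GenomicInterval("c", 0, 100)]
        )
        assert [(r.start, r.end) for r in u] == [(0, 100), (500, 600)]


class TestCounting:
    def _profiles(self, vecs):
        return [
            CutProfile({"c": np.asarray(v, dtype=np.int64)},
                       replicate=f"r{i}",
                       condition="untreated" if i < len(vecs) // 2 else "induced")
            for i, v in enumerate(vecs)
        ]

    def test_min_sum_filter_is_strict(self):
        wins = [Window(GenomicInterval("c", 0, 4), 0),
                Window(GenomicInterval("c", 4, 8), 0)]
        vecs = np.zeros((2, 10), dtype=int)
        vecs[0, :4] = 1  # first window sums to 4 -> dropped
        vecs[0, 4:8] = 1
        vecs[1, 4] = 1  # second window sums to 5 -> kept
        mat = count_and_filter(wins, self._profiles(vecs), min_sum=5)
        assert len(mat.windows) == 1
        assert mat.windows[0].interval.start == 4

    def test_counts_match_brute_force(self, rng):
        vecs = rng.poisson(0.5, (4, 3000))
        profiles = self._profiles(vecs)
        wins = []
        for _ in range(1000):
            s = int(rng.integers(0, 2700))
            w = int(rng.integers(1, 300))
            wins.append(Window(GenomicInterval("c", s, s + w), 0))
        mat = count_and_filter(wins, profiles, min_sum=0)
        for wi, w in enumerate(wins):
            expected = vecs[:, w.interval.start : w.interval.end].sum(axis=1)
            assert np.array_equal(mat.counts[wi], expected)

    def test_window_outside_profile_rejected(self):
        wins = [Window(GenomicInterval("c", 90, 120), 0)]
        with pytest.raises(ValueError, match="outside"):
            count_and_filter(wins, self._profiles(np.ones((2, 100), int)))


class TestExactTest:
    def test_symmetric_counts_give_p_one(self):
        assert exact_nb_pvalue(30, 3, 30, 3, 0.1) == 1.0
        assert exact_nb_pvalue(0, 3, 0, 3, 0.1) == 1.0

    def test_poisson_limit_matches_binomial(self):
        for z1, z2 in ((30, 50), (5, 20), (61, 40)):
            p_nb = exact_nb_pvalue(z1, 3, z2, 3, 0.0)
            p_binom = stats.binomtest(z1, z1 + z2, 0.5).pvalue
            assert p_nb == pytest.approx(p_binom, rel=1e-9)

    def test_unbalanced_groups_use_group_sizes(self):
        # 3 vs 2 replicates: the null split probability is 3/5
        p = exact_nb_pvalue(60, 3, 40, 2, 0.0)
        assert p == pytest.approx(stats.binomtest(60, 100, 0.6).pvalue, rel=1e-9)

    def _null_matrix(self, rng, n=4000, phi=0.1, mu=20.0):
        counts = rng.poisson(rng.gamma(1 / phi, mu * phi, (n, 6)))
        wins = [Window(GenomicInterval("c", i * 400, i * 400 + 300), i)
                for i in range(n)]
        lib = np.full(6, counts.sum() / 6)
        return CountMatrix(counts, wins, ["untreated"] * 3 + ["induced"] * 3,
                           lib)

    def test_null_type_one_error_and_validity(self, rng):
        """Type-I error near nominal and p-values never anti-conservative
        by more than discreteness allows."""
        res = nb_exact_test(self._null_matrix(rng))
        p = res.pvalue
        assert 0.03 < (p < 0.05).mean() < 0.06
        grid = np.linspace(0.01, 0.99, 50)
        emp = np.searchsorted(np.sort(p), grid) / p.size
        assert np.all(emp <= grid + 0.02)

    def test_dispersion_recovered_from_null_data(self, rng):
        mat = self._null_matrix(rng, n=6000, phi=0.08)
        phi_hat = estimate_common_dispersion(mat)
        assert phi_hat == pytest.approx(0.08, rel=0.25)

    def test_all_zero_condition_rejected(self):
        counts = np.zeros((10, 6), dtype=int)
        counts[:, 3:] = 5
        wins = [Window(GenomicInterval("c", i * 400, i * 400 + 300), i)
                for i in range(10)]
        mat = CountMatrix(counts, wins, ["untreated"] * 3 + ["induced"] * 3,
                          np.full(6, 100.0))
        with pytest.raises(ValueError):
            nb_exact_test(mat)


class TestAgainstReferenceImplementation:
    def test_pvalues_match_edgeR(self, rng, tmp_path):
        """Cross-check the whole normalization + dispersion + exact-test
        chain against the Bioconductor reference on one small matrix."""
        n = 300
        mu = rng.gamma(2, 15, n)
        fold = np.ones(n)
        fold[:30] = 3.0
        counts = np.empty((n, 6), dtype=np.int64)
        for j in range(6):
            m = mu * (fold if j >= 3 else 1.0)
            counts[:, j] = rng.poisson(rng.gamma(1 / 0.08, m * 0.08))
        cm = tmp_path / "cm.tsv"
        np.savetxt(cm, counts, fmt="%d", delimiter="\t")
        out = tmp_path / "edger.tsv"
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.table("{cm}"))
            group <- factor(c("u","u","u","i","i","i"), levels=c("u","i"))
            y <- DGEList(counts=x, group=group)
            y <- calcNormFactors(y)
            y <- estimateCommonDisp(y)
            et <- exactTest(y)
            write.table(data.frame(p=et$table$PValue, disp=y$common.dispersion),
                        "{out}", sep="\\t", row.names=FALSE, quote=FALSE)
        """)
        r = tmp_path / "cmp.R"
        r.write_text(script)
        subprocess.run(["Rscript", str(r)], check=True, capture_output=True)
        ref = np.loadtxt(out, skiprows=1, delimiter="\t")
        wins = [Window(GenomicInterval("c", i * 400, i * 400 + 300), i)
                for i in range(n)]
        mat = CountMatrix(counts, wins, ["untreated"] * 3 + ["induced"] * 3,
                          counts.sum(axis=0).astype(float))
        res = nb_exact_test(mat)
        phi_ref = ref[0, 1]
        assert estimate_common_dispersion(mat) == pytest.approx(phi_ref,
                                                                rel=0.2)
        corr = np.corrcoef(np.log10(res.pvalue), np.log10(ref[:, 0]))[0, 1]
        assert corr > 0.99
        assert ((res.pvalue < 0.05) == (ref[:, 0] < 0.05)).mean() > 0.95


def _diff_from_pvalues(windows, pvalues, log2fc):
    from statsmodels.stats.multitest import multipletests

    fdr = multipletests(pvalues, method="fdr_bh")[1]
    return DiffResult(windows, np.asarray(log2fc), np.asarray(pvalues), fdr,
                      "untreated", "induced")


class TestClassifyAndMerge:
    def test_overlapping_significant_windows_merge(self):
        wins = [Window(GenomicInterval("c", 0, 300), 0),
                Window(GenomicInterval("c", 150, 450), 0)]
        sets = classify_and_merge(
            _diff_from_pvalues(wins, [1e-5, 1e-5], [1.0, 1.2])
        )
        assert [(r.start, r.end) for r in sets.strict_increase] == [(0, 450)]

    def test_opposite_directions_not_merged(self):
        wins = [Window(GenomicInterval("c", 0, 300), 0),
                Window(GenomicInterval("c", 300, 600), 0)]
        sets = classify_and_merge(
            _diff_from_pvalues(wins, [1e-5, 1e-5], [1.0, -1.0])
        )
        assert len(sets.loose_increase) == 1
        assert len(sets.loose_decrease) == 1

    def test_region_p_is_min_window_p(self):
        wins = [Window(GenomicInterval("c", 0, 300), 0),
                Window(GenomicInterval("c", 150, 450), 0)]
        sets = classify_and_merge(
            _diff_from_pvalues(wins, [1e-3, 1e-6], [1.0, 1.2])
        )
        assert sets.loose_increase[0].score == pytest.approx(1e-6)

    def test_strict_subset_of_loose_on_random_inputs(self, rng):
        """BH-adjusted thresholds can only drop windows, so every strict
        region must be contained in a loose region (100 random datasets)."""
        for _ in range(100):
            n = int(rng.integers(5, 60))
            wins = [
                Window(GenomicInterval("c", i * 200, i * 200 + 300), 0)
                for i in range(n)
            ]
            pv = rng.uniform(1e-6, 1, n)
            fc = rng.normal(0, 1, n)
            sets = classify_and_merge(_diff_from_pvalues(wins, pv, fc))
            for strict, loose in (
                (sets.strict_increase, sets.loose_increase),
                (sets.strict_decrease, sets.loose_decrease),
            ):
                for r in strict:
                    assert any(
                        l.start <= r.start and r.end <= l.end for l in loose
                    )


class TestNormalizedDifferentialScore:
    def test_identical_profiles_zero(self, rng):
        vec = rng.poisson(1.0, 2000)
        prof = CutProfile({"c": vec})
        regions = [GenomicInterval("c", i * 400, i * 400 + 300)
                   for i in range(5)]
        scores = normalized_differential_score(regions, [prof], [prof])
        assert np.allclose(scores, 0.0)

    def test_scores_average_to_zero(self, rng):
        a = CutProfile({"c": rng.poisson(1.0, 2000)})
        b = CutProfile({"c": rng.poisson(2.0, 2000)})
        regions = [GenomicInterval("c", i * 400, i * 400 + 300)
                   for i in range(5)]
        scores = normalized_differential_score(regions, [a], [b])
        assert scores.mean() == pytest.approx(0.0, abs=1e-12)

    def test_planted_regions_rank_in_top_decile(self, scenario, profiles,
                                                delta_results):
        from deltadnase.synthetic_data import INDUCED

        union = delta_results["union"]
        scores = normalized_differential_score(
            union, profiles[UNTREATED], profiles[INDUCED]
        )
        truth = scenario.planted_regions
        planted_idx = [
            i for i, r in enumerate(union)
            if any(r.overlaps(t) for t in truth)
        ]
        ranks = stats.rankdata(-scores)[planted_idx] / len(union)
        assert np.all(ranks <= 0.10)


class TestTmm:
    def test_depth_only_factors_near_one(self, rng):
        mu = rng.gamma(2, 15, 1500)
        depth = np.array([0.7, 1.0, 1.4, 0.9, 1.2, 1.0])
        counts = np.column_stack([rng.poisson(mu * d) for d in depth])
        lib = counts.sum(axis=0).astype(float)
        f = tmm_factors(counts, lib)
        assert np.allclose(f, 1.0, atol=0.03)
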