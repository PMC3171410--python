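"""The eight evaluation measures, the efficient AUC and the AUC bound."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazeframe import (ClassificationSample, DensityMap, DisplayGeometry,
                       SalienceMap, auc, chance_adjusted_salience,
                       kl_divergence, map_correlation,
                       naive_bayes_percent_correct, nss, percentile_measure,
                       ratio_of_medians, roc_curve, sample_scores,
                       symmetric_kl, theoretical_max_auc)
from gazeframe.measures import _disc_max
from gazeframe.exceptions import ConfigError, EmptyDatasetError

from conftest import pairwise_auc

GEOM22 = DisplayGeometry(2, 2, 1.0, 1.0)


class TestSampleScores:
    def test_all_pixels(self, make_fixations):
        m = SalienceMap([[1.0, 2.0], [3.0, 4.0]], GEOM22)
        s = sample_scores(m, make_fixations([(0.5, 0.5)], GEOM22),
                          "all_pixels")
        assert s.positives.tolist() == [1.0]
        assert sorted(s.negatives.tolist()) == [1.0, 2.0, 3.0, 4.0]

    def test_nonfixated_pixels(self, make_fixations):
        m = SalienceMap([[1.0, 2.0], [3.0, 4.0]], GEOM22)
        s = sample_scores(m, make_fixations([(0.5, 0.5)], GEOM22),
                          "nonfixated_pixels")
        assert sorted(s.negatives.tolist()) == [2.0, 3.0, 4.0]

    def test_other_image_fixations(self, make_fixations):
        geom = DisplayGeometry(10, 10, 1.0, 1.0)
        m = SalienceMap(np.arange(100.0).reshape(10, 10), geom)
        rng = np.random.default_rng(0)
        donors = make_fixations(rng.uniform(0, 10, (10, 2)), geom,
                                image="other")
        s = sample_scores(m, make_fixations([(0.0, 0.0)], geom),
                          "other_image_fixations", donor_fixations=donors)
        assert s.negatives.size == 10
        expected = m.value_at(donors.xy()[:, 0], donors.xy()[:, 1])
        np.testing.assert_array_equal(np.sort(s.negatives),
                                      np.sort(expected))

    def test_unknown_strategy(self, make_fixations):
        m = SalienceMap([[1.0, 2.0], [3.0, 4.0]], GEOM22)
        with pytest.raises(ConfigError):
            sample_scores(m, make_fixations([(0.5, 0.5)], GEOM22), "bogus")


class TestAuc:
    def test_perfect_separation(self):
        s = ClassificationSample([0.9, 0.8], [0.1, 0.2, 0.3])
        assert auc(s).value == 1.0

    def test_all_ties_is_chance(self):
        s = ClassificationSample([1.0] * 5, [1.0] * 100)
        assert auc(s).value == 0.5

    def test_worked_example(self):
        # wins: 0.9 beats all 3; 0.7 beats 2 -> 5 of 6 pairs
        s = ClassificationSample([0.9, 0.7], [0.8, 0.2, 0.1])
        assert auc(s).value == pytest.approx(5 / 6, abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(EmptyDatasetError):
            auc(ClassificationSample([], [1.0]))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pairwise_and_trapezoid_oracles(self, seed):
        rng = np.random.default_rng(seed)
        # mix continuous and heavily tied integer scores
        if seed % 2:
            pos = rng.integers(0, 5, rng.integers(1, 50)).astype(float)
            neg = rng.integers(0, 5, rng.integers(1, 80)).astype(float)
        else:
            pos = rng.normal(0.3, 1, rng.integers(1, 50))
            neg = rng.normal(0, 1, rng.integers(1, 80))
        s = ClassificationSample(pos, neg)
        expected = pairwise_auc(pos, neg)
        assert auc(s).value == pytest.approx(expected, abs=1e-12)
        assert roc_curve(s).area == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=30)
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        s = ClassificationSample(rng.normal(size=5), rng.normal(size=7))
        assert 0.0 <= auc(s).value <= 1.0

    def test_linearity_over_positive_subsets(self):
        # pooled AUC equals the size-weighted mean of subset AUCs
        rng = np.random.default_rng(42)
        neg = rng.normal(size=60)
        parts = [rng.normal(0.5, 1, n) for n in (3, 10, 27)]
        pooled = auc(ClassificationSample(np.concatenate(parts), neg)).value
        weighted = sum(len(p) * auc(ClassificationSample(p, neg)).value
                       for p in parts) / sum(len(p) for p in parts)
        assert pooled == pytest.approx(weighted, abs=1e-12)


class TestRocCurve:
    def test_perfect_curve_passes_through_corner(self):
        c = roc_curve(ClassificationSample([2.0, 3.0], [0.0, 1.0]))
        pts = set(zip(c.fpr.tolist(), c.tpr.tolist()))
        assert (0.0, 1.0) in pts
        assert c.fpr[-1] == 1.0 and c.tpr[-1] == 1.0

    def test_single_pair(self):
        c = roc_curve(ClassificationSample([1.0], [0.0]))
        assert list(zip(c.fpr, c.tpr)) == [(0.0, 0.0), (0.0, 1.0),
                                           (1.0, 1.0)]


class TestNss:
    def test_worked_example(self, make_fixations):
        m = SalienceMap([[1.0, 2.0], [3.0, 6.0]], GEOM22)
        ds = make_fixations([(1.5, 1.5)], GEOM22)  # the 6-valued cell
        assert nss(m, ds).value == pytest.approx(3 / np.sqrt(3.5), abs=1e-12)

    def test_fixating_the_mean_gives_zero(self, make_fixations):
        m = SalienceMap([[1.0, 3.0], [3.0, 5.0]], GEOM22)  # mean 3
        ds = make_fixations([(1.5, 0.5)], GEOM22)
        assert nss(m, ds).value == pytest.approx(0.0, abs=1e-12)

    def test_duplication_invariance(self, make_fixations):
        m = SalienceMap([[1.0, 2.0], [3.0, 6.0]], GEOM22)
        once = nss(m, make_fixations([(0.5, 0.5), (1.5, 1.5)], GEOM22)).value
        twice = nss(m, make_fixations([(0.5, 0.5), (1.5, 1.5)] * 2,
                                      GEOM22)).value
        assert once == pytest.approx(twice, abs=1e-12)

    def test_constant_map_rejected(self, make_fixations):
        with pytest.raises(ZeroDivisionError):
            nss(SalienceMap(np.ones((2, 2)), GEOM22),
                make_fixations([(0.5, 0.5)], GEOM22))

    def test_linearity_over_positive_subsets(self, make_fixations):
        geom = DisplayGeometry(10, 10, 1.0, 1.0)
        m = SalienceMap(np.random.default_rng(0).random((10, 10)), geom)
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 10, (30, 2))
        pooled = nss(m, make_fixations(xy, geom)).value
        weighted = (10 * nss(m, make_fixations(xy[:10], geom)).value
                    + 20 * nss(m, make_fixations(xy[10:], geom)).value) / 30
        assert pooled == pytest.approx(weighted, abs=1e-12)


class TestChanceAdjustedSalience:
    def test_uniform_coverage_gives_zero(self, make_fixations):
        m = SalienceMap([[1.0, 2.0], [3.0, 4.0]], GEOM22)
        ds = make_fixations([(0.5, 0.5), (1.5, 0.5), (0.5, 1.5), (1.5, 1.5)],
                            GEOM22)
        assert chance_adjusted_salience(m, ds).value == pytest.approx(0.0)

    def test_worked_example(self, make_fixations):
        m = SalienceMap([[0.0, 10.0], [0.0, 10.0]], GEOM22)
        ds = make_fixations([(1.5, 0.5), (1.5, 1.5)], GEOM22)
        assert chance_adjusted_salience(m, ds).value == pytest.approx(5.0)


class TestRatioOfMedians:
    def test_constant_map_gives_one(self, make_fixations):
        geom = DisplayGeometry(10, 10, 1.0, 1.0)
        m = SalienceMap(np.full((10, 10), 3.0), geom)
        ds = make_fixations([(2.0, 2.0), (7.0, 7.0)], geom)
        assert ratio_of_medians(m, ds, rng_seed=0).value == 1.0

    def test_whole_image_radius_saturates(self, make_fixations):
        geom = DisplayGeometry(10, 10, 1.0, 1.0)
        m = SalienceMap(np.random.default_rng(0).random((10, 10)), geom)
        ds = make_fixations([(1.0, 1.0)], geom)
        # radius 10 deg = 100 px covers any 10x10 map entirely
        assert ratio_of_medians(m, ds, radius_deg=10, rng_seed=1).value == 1.0

    def test_disc_max_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        values = rng.random((10, 10))
        ry, rx = 2.3, 3.1
        rows = np.repeat(np.arange(10), 10)
        cols = np.tile(np.arange(10), 10)
        got = _disc_max(values, rows, cols, ry, rx)
        for k, (r, c) in enumerate(zip(rows, cols)):
            best = max(values[i, j] for i in range(10) for j in range(10)
                       if ((i - r) / ry) ** 2 + ((j - c) / rx) ** 2 <= 1)
            assert got[k] == best


class TestPercentileMeasure:
    def test_fixations_on_global_max(self, make_fixations):
        geom = DisplayGeometry(10, 1, 1.0, 0.1)
        m = SalienceMap(np.arange(1.0, 11.0).reshape(1, 10), geom)
        ds = make_fixations([(9.5, 0.5)] * 4, geom)
        assert percentile_measure(m, ds).value == 1.0

    def test_worked_example(self, make_fixations):
        # values 1..10; 80th percentile threshold 8.2; hits: 9 yes, 3 no
        geom = DisplayGeometry(10, 1, 1.0, 0.1)
        m = SalienceMap(np.arange(1.0, 11.0).reshape(1, 10), geom)
        ds = make_fixations([(8.5, 0.5), (2.5, 0.5)], geom)
        assert percentile_measure(m, ds, percentile=80).value == 0.5


class TestNaiveBayes:
    def test_perfect_separation(self):
        s = ClassificationSample(np.linspace(10, 11, 40),
                                 np.linspace(0, 1, 40))
        r = naive_bayes_percent_correct(s, rng_seed=0)
        assert r.value == 1.0

    def test_identical_distributions_near_chance(self):
        rng = np.random.default_rng(0)
        s = ClassificationSample(rng.normal(size=1000),
                                 rng.normal(size=1000))
        r = naive_bayes_percent_correct(s, rng_seed=1)
        assert r.value == pytest.approx(0.5, abs=0.05)

    def test_matches_hand_unrolled_folds(self):
        # tiny instance: replay the stratified folds and recompute the
        # Laplace-smoothed histogram classifier independently
        from sklearn.model_selection import StratifiedKFold

        pos = np.array([1.0, 2.0, 8.0, 9.0])
        neg = np.array([0.0, 3.0, 4.0, 5.0])
        s = ClassificationSample(pos, neg)
        got = naive_bayes_percent_correct(s, n_bins=2, k_folds=2,
                                          rng_seed=7).value

        scores = np.concatenate([pos, neg])
        labels = np.array([1] * 4 + [0] * 4)
        edges = np.linspace(scores.min(), scores.max(), 3)
        bins = np.clip(np.digitize(scores, edges[1:-1]), 0, 1)
        correct = 0
        skf = StratifiedKFold(2, shuffle=True, random_state=7)
        for train, test in skf.split(scores.reshape(-1, 1), labels):
            cf = np.array([np.sum(bins[train][labels[train] == 1] == b)
                           for b in (0, 1)]) + 1.0
            cn = np.array([np.sum(bins[train][labels[train] == 0] == b)
                           for b in (0, 1)]) + 1.0
            for t in test:
                pred = 1 if cf[bins[t]] / cf.sum() > cn[bins[t]] / cn.sum() \
                    else 0
                correct += pred == labels[t]
        assert got == pytest.approx(correct / 8)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            naive_bayes_percent_correct(
                ClassificationSample([1.0] * 3, [0.0] * 30), k_folds=10)


def _density(values, width=None):
    values = np.atleast_2d(np.asarray(values, float))
    geom = DisplayGeometry(values.shape[1], values.shape[0],
                           float(values.shape[1]), float(values.shape[0]))
    return DensityMap(values / values.sum() if values.sum() != 1 else values,
                      geom)


class TestKlDivergence:
    def test_self_divergence_is_zero(self):
        p = _density(np.random.default_rng(0).random((4, 4)) + 0.1)
        assert kl_divergence(p, p).value == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_worked_example(self):
        p = _density([0.5, 0.5])
        q = _density([0.25, 0.75])
        expected = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert kl_divergence(p, q).value == pytest.approx(expected, abs=1e-12)
        assert kl_divergence(p, q, log_base=2).value == pytest.approx(
            expected / np.log(2), abs=1e-12)

    def test_zero_p_terms_drop(self):
        p = _density([1.0, 0.0])
        q = _density([0.5, 0.5])
        assert kl_divergence(p, q).value == pytest.approx(np.log(2),
                                                          abs=1e-12)

    def test_symmetric_extension(self):
        p = _density([0.5, 0.5])
        q = _density([0.25, 0.75])
        fwd = kl_divergence(p, q).value + kl_divergence(q, p).value
        assert symmetric_kl(p, q).value == pytest.approx(fwd, abs=1e-12)
        assert symmetric_kl(p, q).value == symmetric_kl(q, p).value


class TestMapCorrelation:
    def test_affine_invariance(self):
        p = _density(np.random.default_rng(0).random((4, 4)))
        q = SalienceMap(2 * p.values + 1, p.geometry)
        assert map_correlation(p, q).value == pytest.approx(1.0)

    def test_anti_correlation(self):
        p = _density(np.random.default_rng(1).random((4, 4)))
        q = SalienceMap(-p.values, p.geometry)
        assert map_correlation(p, q).value == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        p = _density(rng.random((5, 5)))
        q = SalienceMap(rng.random((5, 5)), p.geometry)
        a, b = p.values.ravel(), q.values.ravel()
        expected = (np.sum((a - a.mean()) * (b - b.mean()))
                    / np.sqrt(np.sum((a - a.mean()) ** 2)
                              * np.sum((b - b.mean()) ** 2)))
        assert map_correlation(p, q).value == pytest.approx(expected,
                                                            abs=1e-12)


class TestTheoreticalMaxAuc:
    def test_uniform_density_is_chance(self):
        assert theoretical_max_auc(_density(np.ones((5, 5)))).value == 0.5

    def test_delta_density_closed_form(self):
        for n in (4, 25, 100):
            v = np.zeros(n)
            v[0] = 1.0
            got = theoretical_max_auc(_density(v.reshape(1, -1))).value
            assert got == pytest.approx(1 - 1 / (2 * n), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_weighted_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = _density(rng.random((rng.integers(2, 10), rng.integers(2, 10))))
        pv = p.values.ravel()
        n = pv.size
        oracle = sum(pv[i] / n * (float(pv[i] > pv[j])
                                  + 0.5 * float(pv[i] == pv[j]))
                     for i in range(n) for j in range(n))
        assert theoretical_max_auc(p).value == pytest.approx(oracle,
                                                             abs=1e-12)
        assert theoretical_max_auc(p).value < 1.0


class TestMonotoneTransformInvariance:
    """AUC and the percentile measure only see the ranking of salience
    values; NSS and correlation see the values themselves."""

    def _setup(self):
        geom = DisplayGeometry(10, 10, 1.0, 1.0)
        rng = np.random.default_rng(9)
        m = SalienceMap(rng.random((10, 10)), geom)
        warped = SalienceMap(np.exp(3 * m.values), geom)
        xy = rng.uniform(0, 10, (20, 2))
        return geom, m, warped, xy

    def test_rank_measures_invariant(self, make_fixations):
        geom, m, warped, xy = self._setup()
        ds = make_fixations(xy, geom)
        for fn in (lambda mm: auc(sample_scores(mm, ds)).value,
                   lambda mm: percentile_measure(mm, ds).value):
            assert fn(m) == pytest.approx(fn(warped), abs=1e-12)

    def test_value_measures_not_invariant(self, make_fixations):
        geom, m, warped, xy = self._setup()
        ds = make_fixations(xy, geom)
        assert nss(m, ds).value != pytest.approx(nss(warped, ds).value,
                                                 abs=1e-6)
        p = DensityMap.from_values(m.values, geom)
        q1 = DensityMap.from_values(m.values + 1e-3, geom)
        q2 = DensityMap.from_values(np.exp(3 * (m.values + 1e-3)), geom)
        assert kl_divergence(p, q1).value != pytest.approx(
            kl_divergence(p, q2).value, abs=1e-6)
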