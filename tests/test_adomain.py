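"""Applicability-domain verdicts against hand computations and brute force.

The KDEOS, INFLO and Sahigara checks re-derive every quantity with plain
nested loops on small fixtures, independently of the vectorised
implementations.
"""

import math

import numpy as np
import pandas as pd
import pytest

from qsarstack import adomain
from qsarstack.adomain import (
    EPS,
    RoyStandardizationAD,
    SahigaraKNNAD,
    inflo_scores,
    kdeos_scores,
)


def _unit_train(n_cols=3):
    """Two-row training set with exact column mean 0 and SD (ddof=1) 1."""
    a = 1.0 / math.sqrt(2.0)
    return pd.DataFrame({f"d{i}": [a, -a] for i in range(n_cols)})


class TestRoy:
    def test_row_at_training_means_is_inside(self):
        ad = RoyStandardizationAD().fit(_unit_train())
        assert ad.predict(pd.DataFrame([[0.0, 0.0, 0.0]], columns=ad.columns_))[0]

    def test_all_values_beyond_three_sd_is_outside(self):
        ad = RoyStandardizationAD().fit(_unit_train())
        probe = pd.DataFrame([[3.5, 3.5, 3.5]], columns=ad.columns_)
        assert not ad.predict(probe)[0]

    def test_hand_computed_mixed_profile(self):
        # |s| = {0.1, 0.2, 3.4}: mean 1.233 + 1.28*SD 1.877 = 3.64 > 3 -> out
        ad = RoyStandardizationAD().fit(_unit_train())
        probe = pd.DataFrame([[0.1, 0.2, 3.4]], columns=ad.columns_)
        s = np.array([0.1, 0.2, 3.4])
        assert s.mean() + 1.28 * s.std(ddof=1) == pytest.approx(3.636, abs=0.01)
        assert not ad.predict(probe)[0]

    def test_mixed_profile_with_small_spread_is_inside(self):
        # one mild excursion, low spread: 90th-percentile score stays <= 3
        ad = RoyStandardizationAD().fit(_unit_train(10))
        values = [2.9] * 9 + [3.05]
        probe = pd.DataFrame([values], columns=ad.columns_)
        s = np.array(values)
        assert s.mean() + 1.28 * s.std(ddof=1) < 3
        assert ad.predict(probe)[0]

    def test_shrinking_toward_means_never_flips_inside_to_outside(self, rng):
        train = pd.DataFrame(rng.standard_normal((40, 4)))
        ad = RoyStandardizationAD().fit(train)
        test = pd.DataFrame(rng.standard_normal((25, 4)) * 3.0)
        inside_before = ad.predict(test)
        shrunk = (test - train.mean()) * 0.5 + train.mean()
        inside_after = ad.predict(shrunk)
        assert (inside_after | ~inside_before).all()

    def test_zero_variance_column_excluded_with_warning(self, rng):
        train = pd.DataFrame(
            {"a": rng.standard_normal(20), "b": np.ones(20)}
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            ad = RoyStandardizationAD().fit(train)
        assert ad.columns_ == ["a"]


def _sahigara_oracle(train, test, k):
    """Published kNN-AD rules re-derived with explicit loops."""
    train = np.asarray(train, float)
    test = np.asarray(test, float)
    n = len(train)
    dist = lambda a, b: math.dist(list(a), list(b))
    mean_knn = []
    for i in range(n):
        ds = sorted(dist(train[i], train[j]) for j in range(n) if j != i)
        mean_knn.append(sum(ds[:k]) / k)
    q1, q3 = np.percentile(mean_knn, [25, 75])
    ref = q3 + 1.5 * (q3 - q1)
    thresholds = []
    for i in range(n):
        ds = sorted(dist(train[i], train[j]) for j in range(n) if j != i)
        ki = sum(1 for d in ds if d <= ref)
        thresholds.append(sum(ds[:ki]) / ki if ki else 0.0)
    verdicts = []
    for t in test:
        verdicts.append(
            any(dist(t, train[i]) <= thresholds[i] for i in range(n))
        )
    return np.array(verdicts)


class TestSahigara:
    def test_duplicated_training_point_is_inside(self, rng):
        train = rng.standard_normal((25, 3))
        ad = SahigaraKNNAD(k=4).fit(train)
        assert ad.predict(train[:5]).all()

    def test_point_beyond_every_pairwise_distance_is_outside(self, rng):
        train = rng.standard_normal((20, 2))
        far = np.array([[1000.0, 1000.0]])
        ad = SahigaraKNNAD(k=3).fit(train)
        assert not ad.predict(far)[0]

    def test_two_cluster_midgap_verdicts_match_brute_force(self, rng):
        cluster_a = rng.normal(0, 0.5, size=(15, 2))
        cluster_b = rng.normal(8, 0.5, size=(15, 2))
        train = np.vstack([cluster_a, cluster_b])
        test = np.array(
            [[4.0, 4.0], [0.1, 0.0], [8.0, 8.2], [2.5, 2.5], [50.0, 50.0]]
        )
        ad = SahigaraKNNAD(k=5).fit(train)
        np.testing.assert_array_equal(
            ad.predict(test), _sahigara_oracle(train, test, k=5)
        )

    def test_verdicts_invariant_to_training_row_order(self, rng):
        train = rng.standard_normal((30, 3))
        test = rng.standard_normal((10, 3)) * 2
        base = SahigaraKNNAD(k=4).fit(train).predict(test)
        perm = SahigaraKNNAD(k=4).fit(train[rng.permutation(30)]).predict(test)
        np.testing.assert_array_equal(base, perm)

    def test_k_validation(self, rng):
        train = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            SahigaraKNNAD(k=0).fit(train)
        with pytest.raises(ValueError):
            SahigaraKNNAD(k=10).fit(train)


def _kdeos_oracle(train, test, k_min, k_max):
    """Documented KDEOS contract recomputed with explicit loops."""
    train = np.asarray(train, float)
    test = np.asarray(test, float)
    n = len(train)

    def density(point, exclude=None, k=3):
        ds = sorted(
            (math.dist(list(point), list(train[j])), j)
            for j in range(n)
            if j != exclude
        )[:k]
        h = max(ds[-1][0], EPS)
        vals = [
            math.exp(-0.5 * (d / h) ** 2) / (h * math.sqrt(2 * math.pi))
            for d, _ in ds
        ]
        return sum(vals) / k, [j for _, j in ds]

    scores = []
    for p in test:
        zs = []
        for k in range(k_min, k_max + 1):
            dens_p, nb = density(p, k=k)
            nb_dens = [density(train[j], exclude=j, k=k)[0] for j in nb]
            mu = np.mean(nb_dens)
            sd = max(np.std(nb_dens, ddof=1), EPS)
            zs.append((mu - dens_p) / sd)
        scores.append(np.mean(zs))
    return np.array(scores)


class TestKDEOS:
    def test_matches_brute_force_oracle_on_small_fixture(self, rng):
        train = rng.standard_normal((20, 2))
        test = np.vstack([rng.standard_normal((4, 2)), [[6.0, 6.0]]])
        got = kdeos_scores(train, test, k_min=3, k_max=6)
        want = _kdeos_oracle(train, test, 3, 6)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_isolated_point_scores_above_cluster_member(self, rng):
        train = rng.normal(0, 1, size=(25, 2))
        test = np.array([[0.0, 0.0], [15.0, 15.0]])
        s = kdeos_scores(train, test)
        assert s[1] > s[0]

    def test_duplicated_central_point_scores_at_or_below_median(self, rng):
        # 19 clustered points plus one isolated: a duplicate of the most
        # central training point must not look more outlying than typical
        cluster = rng.normal(0, 1, size=(19, 2))
        train = np.vstack([cluster, [[12.0, 12.0]]])
        central = cluster[np.argmin(((cluster - cluster.mean(0)) ** 2).sum(1))]
        all_scores = kdeos_scores(train, train)
        dup = kdeos_scores(train, central[None, :])
        assert dup[0] <= np.median(all_scores) + 1e-12

    def test_translation_invariance(self, rng):
        train = rng.standard_normal((20, 3))
        test = rng.standard_normal((5, 3))
        a = kdeos_scores(train, test)
        b = kdeos_scores(train + 100.0, test + 100.0)
        np.testing.assert_allclose(a, b, rtol=1e-8)

    def test_degenerate_training_set_rejected(self):
        train = np.zeros((15, 2))
        with pytest.raises(ValueError, match="degenerate"):
            kdeos_scores(train, np.array([[1.0, 1.0]]))

    def test_k_range_validation(self, rng):
        train = rng.standard_normal((8, 2))
        with pytest.raises(ValueError):
            kdeos_scores(train, train[:1], k_min=5, k_max=3)
        with pytest.raises(ValueError):
            kdeos_scores(train, train[:1], k_min=3, k_max=8)


def _inflo_oracle(train, test, k):
    """Influence-space density ratio recomputed with explicit loops."""
    train = np.asarray(train, float)
    test = np.asarray(test, float)
    n = len(train)

    def kdist_train(i):
        ds = sorted(math.dist(list(train[i]), list(train[j]))
                    for j in range(n) if j != i)
        return max(ds[k - 1], EPS)

    dens = [1.0 / kdist_train(i) for i in range(n)]
    out = []
    for p in test:
        d = [math.dist(list(p), list(train[j])) for j in range(n)]
        order = np.argsort(d, kind="stable")[:k]
        members = set(order.tolist())
        for j in range(n):
            if d[j] <= kdist_train(j):
                members.add(j)
        own = 1.0 / max(sorted(d)[k - 1], EPS)
        out.append(np.mean([dens[j] for j in members]) / own)
    return np.array(out)


class TestINFLO:
    def test_matches_brute_force_oracle_on_small_fixture(self, rng):
        train = rng.standard_normal((25, 2))
        test = np.vstack([rng.standard_normal((5, 2)), [[8.0, 8.0]]])
        np.testing.assert_allclose(
            inflo_scores(train, test, k=5), _inflo_oracle(train, test, 5),
            rtol=1e-10,
        )

    def test_uniform_grid_interior_point_near_one(self):
        xx, yy = np.meshgrid(np.arange(7.0), np.arange(7.0))
        train = np.column_stack([xx.ravel(), yy.ravel()])
        center = np.array([[3.0, 3.0]])
        score = inflo_scores(np.delete(train, 24, axis=0), center, k=4)
        assert score[0] == pytest.approx(1.0, abs=0.3)

    def test_outlier_scores_much_larger_than_one(self, rng):
        train = rng.normal(0, 0.5, size=(30, 2))
        outlier = np.array([[10.0, 10.0]])
        assert inflo_scores(train, outlier, k=5)[0] > 2.0

    def test_invariant_to_uniform_coordinate_scaling(self, rng):
        train = rng.standard_normal((20, 3))
        test = rng.standard_normal((5, 3)) * 2
        a = inflo_scores(train, test, k=4)
        b = inflo_scores(train * 7.0, test * 7.0, k=4)
        np.testing.assert_allclose(a, b, rtol=1e-8)


def test_ad_report_covers_four_methods(rng):
    train = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
    test = pd.DataFrame(rng.standard_normal((6, 3)), columns=list("abc"))
    rep = adomain.ad_report(train, test)
    assert set(rep.method) == {"roy", "sahigara_knn", "kdeos", "inflo"}
    assert len(rep) == 4 * len(test)
    assert rep.inside.isin([True, False]).all()


def test_sahigara_mask_uses_each_models_feature_space(rng):
    train = pd.DataFrame(rng.standard_normal((40, 4)), columns=list("abcd"))
    test = pd.DataFrame(rng.standard_normal((10, 4)), columns=list("abcd"))
    test.loc[test.index[0], ["a", "b"]] = 50.0  # outlier only in ab-space
    mask = adomain.sahigara_mask(
        {"m_ab": ["a", "b"], "m_cd": ["c", "d"]}, train, test, k=5
    )
    assert not mask.iloc[0]["m_ab"]
    assert mask.iloc[0]["m_cd"]
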