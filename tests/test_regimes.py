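import numpy as np
import pandas as pd
import pytest

from lagoonconnect.regimes import (
    RawWindow, StressParams, WindRegimeClassifier, WindSequence,
    ZeroVarianceError, circular_mean_sd, cluster_regimes, extract_sequences,
    occurrence_statistics, pam_kmedoids, pca_scores, season_assignment,
    select_reference, summarize_subsequences, wind_stress_components,
)
from lagoonconnect.wind import RegimeSpec, WindSeries, generate_wind_series


def _series_of(u, v, start="2000-01-01"):
    dates = pd.date_range(start, periods=len(u), freq="D")
    return WindSeries(dates=dates, u=np.asarray(u, float), v=np.asarray(v, float))


class TestWindStress:
    def test_zero_wind_zero_stress(self):
        assert wind_stress_components(0.0, 0.0) == (0.0, 0.0)

    def test_hand_evaluated_values(self):
        tx, ty = wind_stress_components(10.0, 0.0, StressParams(rho_a=1.2, cd=0.0016))
        assert tx == pytest.approx(0.192)
        assert ty == 0.0
        tx, ty = wind_stress_components(3.0, 4.0)
        assert tx == pytest.approx(0.00192 * 5 * 3)
        assert ty == pytest.approx(0.00192 * 5 * 4)

    def test_constant_cd_scaling_is_homothetic(self):
        u, v = np.array([3.0, -2.0]), np.array([4.0, 1.0])
        t1 = wind_stress_components(u, v, StressParams(rho_a=1.2, cd=0.0016))
        t2 = wind_stress_components(u, v, StressParams(rho_a=1.2, cd=0.0032))
        assert np.allclose(np.asarray(t2), 2.0 * np.asarray(t1))


class TestWindowing:
    def test_33_year_series_gives_1203_sequences(self):
        n = (pd.Timestamp("2011-12-31") - pd.Timestamp("1979-01-01")).days + 1
        s = _series_of(np.ones(n), np.zeros(n), start="1979-01-01")
        assert len(extract_sequences(s, 30, 20)) == 1203

    def test_exactly_30_days_one_window(self):
        s = _series_of(np.ones(30), np.zeros(30))
        assert len(extract_sequences(s)) == 1

    def test_49_day_series_two_windows(self):
        s = _series_of(np.ones(49), np.zeros(49))
        seqs = extract_sequences(s)
        assert len(seqs) == 2
        assert seqs[0].start_index == 0 and seqs[1].start_index == 10

    def test_short_series_empty(self):
        s = _series_of(np.ones(10), np.zeros(10))
        assert extract_sequences(s) == []

    def test_overlap_must_be_smaller_than_window(self):
        s = _series_of(np.ones(60), np.zeros(60))
        with pytest.raises(ValueError):
            extract_sequences(s, 30, 30)


class TestSubsequences:
    def test_constant_window(self):
        w = RawWindow(pd.Timestamp("2000-01-01"), 0, np.full(30, 2.0), np.full(30, -1.0))
        seq = summarize_subsequences(w)
        assert np.allclose(seq.sub_means[:, 0], 2.0)
        assert np.allclose(seq.sub_means[:, 1], -1.0)

    def test_alternating_days_cancel(self):
        tx = np.tile([1.0, -1.0], 15)
        w = RawWindow(pd.Timestamp("2000-01-01"), 0, tx, tx.copy())
        assert np.allclose(summarize_subsequences(w).sub_means, 0.0)

    def test_mean_preserved(self):
        rng = np.random.default_rng(0)
        tx, ty = rng.normal(size=30), rng.normal(size=30)
        seq = summarize_subsequences(RawWindow(pd.Timestamp("2000-01-01"), 0, tx, ty))
        assert seq.sub_means[:, 0].mean() == pytest.approx(tx.mean())
        assert seq.sub_means[:, 1].mean() == pytest.approx(ty.mean())

    def test_wrong_length_rejected(self):
        w = RawWindow(pd.Timestamp("2000-01-01"), 0, np.ones(29), np.ones(29))
        with pytest.raises(ValueError):
            summarize_subsequences(w)


def _seq(vec, start="2000-01-01", idx=0):
    v = np.asarray(vec, float).reshape(15, 2)
    return WindSequence(pd.Timestamp(start), v, idx)


class TestPca:
    def test_collinear_sequences_one_component(self):
        base = np.arange(30.0)
        seqs = [_seq(t * base) for t in (0.0, 1.0, 2.0, 3.0)]
        scores, loadings, expl = pca_scores(seqs, variance_kept=0.95)
        assert scores.shape[1] == 1
        assert expl[0] == pytest.approx(1.0)

    def test_full_space_preserves_distances(self):
        rng = np.random.default_rng(1)
        seqs = [_seq(rng.normal(size=30)) for _ in range(8)]
        X = np.array([s.flatten() for s in seqs])
        scores, _, _ = pca_scores(seqs, variance_kept=1.0)
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(scores), pdist(X - X.mean(axis=0)), atol=1e-9)

    def test_antipodal_pair_symmetric_scores(self):
        v = np.arange(30.0)
        scores, _, _ = pca_scores([_seq(v), _seq(-v)], variance_kept=1.0)
        d = np.linalg.norm(2 * v)
        assert np.allclose(np.abs(scores[:, 0]), d / 2)
        assert scores[0, 0] == pytest.approx(-scores[1, 0])

    def test_identical_sequences_rejected(self):
        with pytest.raises(ZeroVarianceError):
            pca_scores([_seq(np.ones(30)), _seq(np.ones(30))])

    def test_not_variance_scaled(self):
        # one high-variance coordinate must dominate the first component
        seqs = [_seq(np.r_[t * 100.0, np.zeros(28), t * 0.01]) for t in (-1, 0, 1.0)]
        _, loadings, _ = pca_scores(seqs, variance_kept=0.95)
        assert abs(loadings[0][0]) > 0.99


class TestClustering:
    def test_three_planted_blobs_recovered(self):
        rng = np.random.default_rng(2)
        centers = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
        truth = np.repeat([0, 1, 2], 30)
        pts = centers[truth] + rng.normal(scale=1.0, size=(90, 2))
        assign, medoids = cluster_regimes(pts, k=3, seed=0)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, assign) == 1.0
        assert len(medoids) == 3

    def test_k_equals_n_zero_cost(self):
        pts = np.arange(10.0).reshape(5, 2)
        assign, medoids = cluster_regimes(pts, k=5, seed=0)
        assert sorted(medoids) == list(range(5))
        assert len(set(assign)) == 5

    def test_k_one_brute_force_medoid(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 4))
        from scipy.spatial.distance import squareform, pdist
        D = squareform(pdist(pts))
        medoids, assign = pam_kmedoids(D, 1)
        assert medoids[0] == np.argmin(D.sum(axis=1))
        assert np.all(assign == 0)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            cluster_regimes(np.zeros((3, 2)), k=5)

    def test_scale_invariance_of_clustering(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(8, 1, (20, 3))])
        a1, m1 = cluster_regimes(pts, k=2)
        a2, m2 = cluster_regimes(pts * 37.5, k=2)
        assert np.array_equal(a1, a2) and np.array_equal(m1, m2)


class TestReference:
    def test_singleton_cluster(self):
        scores = np.array([[1.0, 2.0], [5.0, 5.0]])
        assert select_reference(np.array([1]), scores) == 1

    def test_tie_broken_by_earliest_date(self):
        scores = np.array([[1.0], [-1.0]])
        dates = [pd.Timestamp("2001-05-05"), pd.Timestamp("2000-01-01")]
        assert select_reference(np.array([0, 1]), scores, dates) == 1

    def test_reference_minimizes_distance(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(12, 3))
        members = np.arange(12)
        ref = select_reference(members, scores)
        bary = scores.mean(axis=0)
        d = np.linalg.norm(scores - bary, axis=1)
        assert d[ref] == pytest.approx(d.min())


class TestOccurrence:
    def test_published_member_counts_reproduce_percentages(self):
        # 160/1203 -> 13.3 %, 59/1203 -> 4.9 %
        counts = [135, 98, 87, 83, 94, 83, 88, 160, 108, 86, 122, 59]
        assign = np.repeat(np.arange(12), counts)
        occ = occurrence_statistics(assign, total=1203)
        assert round(occ.loc[7, "probability_pct"], 1) == 13.3
        assert round(occ.loc[11, "probability_pct"], 1) == 4.9
        assert occ["probability_pct"].sum() == pytest.approx(100.0)

    def test_single_cluster_is_100(self):
        occ = occurrence_statistics(np.zeros(10, int))
        assert occ.loc[0, "probability_pct"] == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            occurrence_statistics(np.array([], dtype=int))


class TestSeasons:
    def test_july_only_regime_is_winter(self):
        mass = np.zeros(12)
        mass[6] = 1.0  # July
        assert season_assignment(mass) == "winter"

    def test_uniform_regime_is_transition(self):
        assert season_assignment(np.full(12, 1 / 12)) == "transition"

    def test_november_to_may_regime_is_summer(self):
        mass = np.zeros(12)
        for m in (11, 12, 1, 2, 3):
            mass[m - 1] = 0.2
        assert season_assignment(mass) == "summer"

    def test_overlapping_month_sets_rejected(self):
        with pytest.raises(ValueError):
            season_assignment(np.full(12, 1 / 12), winter_months=(6,), summer_months=(6,))


class TestClassifierEndToEnd:
    def test_planted_regime_recovery_with_seasons(self):
        winter = RegimeSpec(4.0, 60.0, 0.3, 3.0, tuple(
            1.0 if m in (6, 7, 8, 9, 10) else 0.0 for m in range(1, 13)))
        summer = RegimeSpec(9.0, 120.0, 0.3, 3.0, tuple(
            0.0 if m in (6, 7, 8, 9, 10) else 1.0 for m in range(1, 13)))
        series = generate_wind_series("2000-01-01", "2009-12-31",
                                      [winter, summer], persistence_days=45,
                                      seed=8)
        res = WindRegimeClassifier(series, k=2, seed=0).fit()
        assert res.occurrence_probs.sum() == pytest.approx(100.0)
        seasons = {r.season for r in res.regimes}
        assert seasons == {"winter", "summer"}
        # the faster regime is the summer one
        fast = max(res.regimes, key=lambda r: r.mean_speed)
        assert fast.season == "summer"

    def test_reference_is_member_of_its_cluster(self):
        series = generate_wind_series("2000-01-01", "2004-12-31",
                                      [RegimeSpec(5.0, 90.0, 1.5, 30.0)],
                                      seed=9)
        res = WindRegimeClassifier(series, k=3, seed=0).fit()
        for r in res.regimes:
            assert r.reference_index in r.members

    def test_occurrence_probabilities_sum_to_100(self):
        series = generate_wind_series("2000-01-01", "2005-12-31",
                                      [RegimeSpec(5.0, 90.0, 2.0, 40.0)],
                                      seed=10)
        res = WindRegimeClassifier(series, k=5, seed=0).fit()
        assert res.occurrence_probs.sum() == pytest.approx(100.0, abs=1e-9)

    def test_summary_table_shape(self):
        series = generate_wind_series("2000-01-01", "2002-12-31",
                                      [RegimeSpec(5.0, 90.0, 1.0, 20.0)], seed=1)
        res = WindRegimeClassifier(series, k=4, seed=0).fit()
        tab = res.summary()
        assert list(tab.columns) == ["start_date", "n_sequences", "probability_pct",
                                     "speed_mean", "speed_sd", "direction_mean",
                                     "direction_sd", "season"]
        assert len(tab) == 4


def test_circular_mean_handles_north_wrap():
    mean, sd = circular_mean_sd(np.array([350.0, 10.0]))
    assert mean == pytest.approx(0.0, abs=1e-9) or mean == pytest.approx(360.0)
    assert sd == pytest.approx(10.0, rel=0.05)
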