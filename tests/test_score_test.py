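"""Score vector, information matrix, 3-df statistic and logrank comparator."""

import math

import numpy as np
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from curescore import (
    CureScoreModel,
    DegenerateDesignError,
    SurvivalDataset,
    information_matrix,
    logrank_test,
    nelson_aalen,
    score_statistic,
    score_vector,
    score_weights,
)
from conftest import random_dataset


def brute_force_score_and_information(data):
    """Independent O(n^2) evaluation of the printed sums, subject by subject."""
    n = len(data)
    X, delta, G = data.time, data.event, data.group
    ev_times = np.sort(np.unique(X[delta == 1]))
    # left-continuous Nelson-Aalen by direct summation
    def na_left(t):
        tot = 0.0
        for s in ev_times:
            if s < t:
                tot += np.sum((X == s) & (delta == 1)) / np.sum(X >= s)
        return tot

    w_hat = na_left(ev_times[-1]) + np.sum((X == ev_times[-1]) & (delta == 1)) / np.sum(
        X >= ev_times[-1]
    )
    V = np.zeros(3)
    I = np.zeros((3, 3))
    for j in range(n):
        if delta[j] == 0:
            continue
        t = X[j]
        ratio = na_left(t) / w_hat
        w = np.array([1.0 + math.log(1.0 - ratio), 1.0 - ratio, 1.0])
        at_risk = X >= t
        s0 = at_risk.mean()
        s1 = (at_risk & (G == 1)).mean()
        e_bar = s1 / s0
        V += w * (G[j] - e_bar)
        I += np.outer(w, w) * (s1 / s0 - (s1 / s0) ** 2)
    return V, I, w_hat


class TestScoreWeights:
    def test_first_event_weights_are_unit(self):
        data = SurvivalDataset([1.0, 2.0, 3.0], [1, 1, 1], [0, 1, 0])
        est = nelson_aalen(data)
        a, b, c = score_weights(est, 1.0)
        assert (a, b, c) == (1.0, 1.0, 1.0)

    def test_hand_computed_weights(self):
        data = SurvivalDataset([1.0, 2.0, 3.0], [1, 1, 1], [0, 1, 0])
        est = nelson_aalen(data)
        a, b, _ = score_weights(est, 2.0)
        assert b == pytest.approx(9 / 11, rel=1e-12)
        assert a == pytest.approx(1 + math.log(9 / 11), rel=1e-12)

    def test_zero_crossing_of_log_weight(self):
        class Fake:
            omega0_hat = 1.0

            def cumhaz_left(self, t):
                return 1 - math.exp(-1)

        a, b, _ = score_weights(Fake(), 0.0)
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(math.exp(-1), rel=1e-12)


class TestScoreVector:
    def test_zero_when_one_group_absent_is_error(self):
        data = SurvivalDataset([1.0, 2.0], [1, 1], [0, 0])
        with pytest.raises(ValueError):
            score_vector(data)

    def test_matches_brute_force_on_small_instance(self):
        data = SurvivalDataset([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [1, 0, 1, 0])
        V, _, _ = brute_force_score_and_information(data)
        np.testing.assert_allclose(score_vector(data), V, atol=1e-12)

    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(5):
            data = random_dataset(rng, n=25)
            V, I, _ = brute_force_score_and_information(data)
            np.testing.assert_allclose(score_vector(data), V, atol=1e-10)
            np.testing.assert_allclose(information_matrix(data), I, atol=1e-10)

    def test_gamma_component_is_logrank_numerator(self, rng):
        # V_gamma and I_gg agree with an independent logrank implementation
        data = random_dataset(rng, n=20, censor_frac=0.25)
        res = ll_logrank(
            data.time[data.group == 0],
            data.time[data.group == 1],
            event_observed_A=data.event[data.group == 0],
            event_observed_B=data.event[data.group == 1],
        )
        v_gamma = score_vector(data)[2]
        i_gg = information_matrix(data)[2, 2]
        assert v_gamma**2 / i_gg == pytest.approx(res.test_statistic, abs=1e-8)


class TestInformationMatrix:
    def test_psd_on_random_datasets(self, rng):
        for _ in range(50):
            data = random_dataset(rng, n=18)
            I = information_matrix(data)
            np.testing.assert_allclose(I, I.T, atol=1e-14)
            assert np.linalg.eigvalsh(I).min() >= -1e-10


class TestScoreStatistic:
    def test_single_group_errors(self):
        data = SurvivalDataset([1.0, 2.0, 3.0], [1, 1, 1], [1, 1, 1])
        with pytest.raises(ValueError):
            score_statistic(data)

    def test_degenerate_design_refused(self):
        # two distinct event times cannot support a rank-3 information
        data = SurvivalDataset([1.0, 1.0, 2.0, 2.0], [1, 1, 1, 1], [0, 1, 0, 1])
        with pytest.raises(DegenerateDesignError):
            score_statistic(data)

    def test_statistic_is_quadratic_form(self, dataset_factory):
        data = dataset_factory(n=40)
        res = score_statistic(data)
        V, I = score_vector(data), information_matrix(data)
        expected = float(V @ np.linalg.solve(I, V))
        assert res.statistic == pytest.approx(expected, rel=1e-10)
        assert res.df == 3
        assert res.statistic >= 0

    def test_group_label_symmetry(self, dataset_factory):
        data = dataset_factory(n=40)
        flipped = SurvivalDataset(data.time, data.event, 1 - data.group)
        a, b = score_statistic(data), score_statistic(flipped)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)
        lr_a, lr_b = logrank_test(data), logrank_test(flipped)
        assert lr_a.statistic == pytest.approx(lr_b.statistic, abs=1e-10)

    def test_rank_invariance_under_monotone_transform(self, dataset_factory):
        data = dataset_factory(n=40)
        warped = SurvivalDataset(data.time**1.7 + np.sqrt(data.time), data.event, data.group)
        assert score_statistic(warped).statistic == pytest.approx(
            score_statistic(data).statistic, abs=1e-10
        )
        assert logrank_test(warped).statistic == pytest.approx(
            logrank_test(data).statistic, abs=1e-10
        )


class TestLogrank:
    def test_matches_lifelines(self, rng):
        for _ in range(5):
            data = random_dataset(rng, n=30)
            res = logrank_test(data)
            ref = ll_logrank(
                data.time[data.group == 0],
                data.time[data.group == 1],
                event_observed_A=data.event[data.group == 0],
                event_observed_B=data.event[data.group == 1],
            )
            assert res.statistic == pytest.approx(ref.test_statistic, abs=1e-8)
            assert res.p_value == pytest.approx(ref.p_value, abs=1e-8)

    def test_perfectly_balanced_sample_gives_zero(self):
        t = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        data = SurvivalDataset(t, np.ones(6, dtype=int), [0, 1, 0, 1, 0, 1])
        assert logrank_test(data).statistic == pytest.approx(0.0, abs=1e-12)


class TestModelResultsApi:
    def test_fit_exposes_both_tests_and_summary(self, dataset_factory):
        data = dataset_factory(n=60)
        model = CureScoreModel(data.time, data.event, data.group)
        res = model.fit()
        assert res.statistic == pytest.approx(score_statistic(data).statistic)
        assert res.logrank.statistic == pytest.approx(logrank_test(data).statistic)
        assert list(res.score.index) == ["alpha", "theta", "gamma"]
        assert res.information.shape == (3, 3)
        text = res.summary()
        assert "score (3 df)" in text and "logrank" in text
        doc = res.to_dict()
        assert doc["score_test"]["df"] == 3 and doc["logrank"]["df"] == 1

    def test_from_dataframe_constructor(self, dataset_factory):
        df = dataset_factory(n=30).to_dataframe()
        res = CureScoreModel.from_dataframe(df).fit()
        assert 0 < res.p_value <= 1
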