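"""Calibration/discrimination metrics against hand computations and oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_c_index, random_survival_fixture
from equialloc import metrics as mx
from equialloc import survival as sv
from equialloc import synthetic as syn
from equialloc.errors import DataError, UndefinedMetricError


class TestIPCW:
    def test_no_censoring_all_weights_one(self):
        time = np.array([10.0, 50.0, 120.0, 300.0])
        event = np.array([1, 1, 1, 1])
        np.testing.assert_allclose(mx.ipcw_weights(time, event, 100.0),
                                   [1.0, 1.0, 1.0, 1.0])

    def test_censored_before_t_weight_zero(self):
        time = np.array([50.0, 200.0])
        event = np.array([0, 1])
        w = mx.ipcw_weights(time, event, 100.0)
        assert w[0] == 0.0

    def test_half_censored_hand_km(self):
        # two censored at 50, two failing later: Ĝ(50⁺) = 1/2, so records at
        # risk past t=100 carry weight 2
        time = np.array([50.0, 50.0, 150.0, 200.0])
        event = np.array([0, 0, 1, 1])
        w = mx.ipcw_weights(time, event, 100.0)
        np.testing.assert_allclose(w, [0.0, 0.0, 2.0, 2.0])

    def test_positive_weights_at_least_one(self):
        rng = np.random.default_rng(0)
        time = rng.exponential(100, 200)
        event = (rng.random(200) > 0.4).astype(int)
        w = mx.ipcw_weights(time, event, 80.0)
        assert (w[w > 0] >= 1.0 - 1e-12).all()


class TestBrier:
    def test_perfect_foresight_zero(self):
        time = np.array([10.0, 3000.0, 20.0, 4000.0])
        event = np.array([1, 1, 1, 1])
        pred = np.array([0.0, 1.0, 0.0, 1.0])
        cfg = mx.MetricConfig(eval_time_days=1826.0)
        assert mx.brier_score(pred, time, event, cfg) == 0.0

    def test_coin_flip_quarter(self):
        rng = np.random.default_rng(1)
        time = rng.exponential(2000, 500)
        event = np.ones(500, dtype=int)
        pred = np.full(500, 0.5)
        assert mx.brier_score(pred, time, event) == pytest.approx(0.25)

    def test_hand_weighted_fixture(self):
        # record censored at 900 < t drops out; Ĝ(t)=3/4 weights the others 4/3
        time = np.array([900.0, 2000.0, 2200.0, 1000.0])
        event = np.array([0, 1, 1, 1])
        pred = np.array([0.8, 0.6, 0.4, 0.2])
        cfg = mx.MetricConfig(eval_time_days=1826.0)
        w = 4.0 / 3.0
        expected = (w * (1 - 0.6) ** 2 + w * (1 - 0.4) ** 2 + w * (0 - 0.2) ** 2) / 4
        assert mx.brier_score(pred, time, event, cfg) == pytest.approx(expected)

    def test_prediction_outside_unit_interval(self):
        with pytest.raises(DataError):
            mx.brier_score([1.2], [100.0], [1], mx.MetricConfig(eval_time_days=50))


class TestMeanSignedError:
    def test_calibrated_is_zero(self):
        time = np.array([100.0, 100.0, 3000.0, 3000.0])
        event = np.array([1, 1, 1, 1])
        pred = np.full(4, 0.5)
        assert mx.mean_signed_error(pred, time, event) == pytest.approx(0.0)

    def test_overestimation_is_negative(self):
        # true 5-y survival 0.6, predictions 0.9 -> MSE ~ -0.3
        rng = np.random.default_rng(2)
        n = 2000
        lam = -np.log(0.6) / 1826.0
        time = rng.exponential(1 / lam, n)
        event = np.ones(n, dtype=int)
        pred = np.full(n, 0.9)
        val = mx.mean_signed_error(pred, time, event)
        assert val == pytest.approx(-0.3, abs=0.04)

    def test_bias_injected_group_negative(self):
        # +0.5 unmeasured log-hazard for one group; a group-blind model
        # overestimates that group's survival
        cfg = syn.CohortConfig(n_records=5000, bias_spec={"Black": 0.5}, seed=1)
        reg = syn.generate_transplant_registry(cfg)
        model = sv.CoxPHModel().fit(reg[cfg.feature_names], sv.survival_target(reg))
        pred = model.predict_survival_prob(reg[cfg.feature_names], 1826.0)
        black = (reg["ethnicity"] == "Black").to_numpy()
        val = mx.mean_signed_error(pred[black], reg["time_days"].to_numpy()[black],
                                   reg["event"].to_numpy()[black])
        rest = mx.mean_signed_error(pred[~black], reg["time_days"].to_numpy()[~black],
                                    reg["event"].to_numpy()[~black])
        assert val < 0 and val < rest


class TestConcordance:
    def test_perfect_ranking(self):
        time = np.array([10.0, 20.0, 30.0, 40.0])
        event = np.array([1, 1, 1, 1])
        pred = np.array([0.1, 0.2, 0.3, 0.4])
        assert mx.c_index(pred, time, event) == 1.0

    def test_constant_predictions_half(self):
        time = np.array([10.0, 20.0, 30.0])
        event = np.array([1, 1, 1])
        assert mx.c_index([0.5, 0.5, 0.5], time, event) == 0.5

    def test_five_record_fixture_vs_enumeration(self):
        pred = np.array([0.3, 0.8, 0.3, 0.6, 0.1])
        time = np.array([5.0, 40.0, 12.0, 12.0, 25.0])
        event = np.array([1, 1, 0, 1, 1])
        assert mx.c_index(pred, time, event) == pytest.approx(
            brute_force_c_index(pred, time, event)
        )

    def test_no_comparable_pairs(self):
        with pytest.raises(UndefinedMetricError):
            mx.c_index([0.5, 0.6], [10.0, 20.0], [0, 1])

    def test_oracle_equivalence_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(5, 31))
            pred, time, event, _ = random_survival_fixture(rng, n)
            oracle = brute_force_c_index(pred, time, event)
            if oracle is None:
                with pytest.raises(UndefinedMetricError):
                    mx.c_index(pred, time, event)
            else:
                assert mx.c_index(pred, time, event) == pytest.approx(oracle)


class TestSubpopulationConcordance:
    def test_whole_population_reduces_exactly(self):
        rng = np.random.default_rng(6)
        pred, time, event, _ = random_survival_fixture(rng, 25)
        full = np.ones(25, dtype=bool)
        assert mx.subpopulation_c_index(pred, time, event, full) == mx.c_index(
            pred, time, event
        )

    def test_six_record_fixture_vs_enumeration(self):
        pred = np.array([0.9, 0.2, 0.5, 0.5, 0.7, 0.1])
        time = np.array([8.0, 15.0, 3.0, 22.0, 30.0, 11.0])
        event = np.array([1, 0, 1, 1, 1, 1])
        group = np.array([True, False, False, True, False, False])
        assert mx.subpopulation_c_index(pred, time, event, group) == pytest.approx(
            brute_force_c_index(pred, time, event, group)
        )

    def test_isolated_member_undefined(self):
        pred = np.array([0.5, 0.6, 0.7])
        time = np.array([10.0, 20.0, 30.0])
        event = np.array([0, 1, 1])  # record 0 censored first: never comparable
        group = np.array([True, False, False])
        with pytest.raises(UndefinedMetricError):
            mx.subpopulation_c_index(pred, time, event, group)

    def test_oracle_equivalence_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(6, 31))
            pred, time, event, group = random_survival_fixture(rng, n, group_levels=3)
            mask = group == 0
            if mask.sum() == 0:
                continue
            oracle = brute_force_c_index(pred, time, event, mask)
            if oracle is None:
                with pytest.raises(UndefinedMetricError):
                    mx.subpopulation_c_index(pred, time, event, mask)
            else:
                assert mx.subpopulation_c_index(
                    pred, time, event, mask
                ) == pytest.approx(oracle)


def _toy_predictions(rng, n_reps=4, n=300, shift_group=None, shift=0.0):
    """Exchangeable per-rep prediction frames with an optional group shift."""
    frames = []
    for rep in range(n_reps):
        time = rng.exponential(2500.0, n)
        event = (rng.random(n) > 0.3).astype(int)
        obs = np.minimum(time, rng.uniform(500, 4000, n))
        censored = obs < time
        group = rng.choice(["a", "b", "c"], n)
        pred = np.clip(np.exp(-obs / 4000) + rng.normal(0, 0.1, n), 0.01, 0.99)
        if shift_group is not None:
            pred = np.where(group == shift_group, np.clip(pred + shift, 0.01, 0.99), pred)
        frames.append(
            pd.DataFrame(
                {
                    "rep": rep, "model": "cox",
                    "pred_prob": pred,
                    "time_days": obs,
                    "event": np.where(censored, 0, event),
                    "grp": group,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestGroupMetricTable:
    def test_identical_groups_no_flags(self):
        rng = np.random.default_rng(8)
        table = mx.group_metric_table(_toy_predictions(rng), ["grp"])
        assert (table.loc[table["group"] != "Overall", "flag"] == "none").all()

    def test_large_group_shift_flagged(self):
        rng = np.random.default_rng(9)
        preds = _toy_predictions(rng, n_reps=6, n=600, shift_group="a", shift=0.35)
        table = mx.group_metric_table(preds, ["grp"])
        cell = table[(table["metric"] == "mean_signed_error") & (table["group"] == "a")]
        assert cell["flag"].iloc[0] == "negative"  # survival overestimated

    def test_overall_row_present_everywhere(self):
        rng = np.random.default_rng(10)
        table = mx.group_metric_table(_toy_predictions(rng), ["grp"])
        for metric in ("brier", "mean_signed_error", "c_index", "subpop_c_index"):
            assert "Overall" in set(table.loc[table["metric"] == metric, "group"])
        assert (table["sd"] >= 0).all()

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        table = mx.group_metric_table(_toy_predictions(rng), ["grp"])
        path = tmp_path / "table.csv"
        mx.write_metric_table_csv(table, path)
        back = mx.read_metric_table_csv(path)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), table.reset_index(drop=True),
            check_dtype=False,
        )


class TestBalanceAfterUndersampling:
    def test_unbiased_generator_rarely_flags(self):
        """Shrinking the majority groups must not manufacture bias flags."""
        clean = 0
        for run in range(20):
            cfg = syn.CohortConfig(n_records=1500, seed=500 + run)
            reg = syn.generate_transplant_registry(cfg)
            reduced = sv.undersample_to_group(
                reg, ["White", "Black"], "Hispanic", "ethnicity", seed=run
            )
            preds = sv.monte_carlo_cv(
                reduced, {"cox": sv.CoxPHModel()},
                sv.CVProtocol(n_reps=5, seed=run),
                feature_cols=cfg.feature_names,
                group_cols=["ethnicity", "gender"],
            )
            table = mx.group_metric_table(preds, ["ethnicity", "gender"])
            clean += (table.loc[table["group"] != "Overall", "flag"] == "none").all()
        assert clean >= 18
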