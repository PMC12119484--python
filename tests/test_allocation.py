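"""Allocation policies and simulator: ABO rules, selection, conservation."""

import numpy as np
import pandas as pd
import pytest

from equialloc import allocation as al
from equialloc import equity, synthetic as syn, survival as sv
from equialloc.errors import ConfigurationError, DataError


class TestABO:
    def test_universal_donor_and_recipient(self):
        assert al.abo_compatible("O", "AB")
        assert not al.abo_compatible("AB", "O")

    def test_full_matrix_nine_true_pairs(self):
        textbook = {
            ("O", "O"), ("O", "A"), ("O", "B"), ("O", "AB"),
            ("A", "A"), ("A", "AB"), ("B", "B"), ("B", "AB"), ("AB", "AB"),
        }
        types = ["O", "A", "B", "AB"]
        observed = {
            (d, r) for d in types for r in types if al.abo_compatible(d, r)
        }
        assert observed == textbook

    def test_unknown_type(self):
        with pytest.raises(DataError):
            al.abo_compatible("C", "O")


def _waitlist(rows):
    return pd.DataFrame(rows)


class TestSelectRecipient:
    ORGAN = {"blood_type": "O", "donor_age": 40.0, "donor_quality": 0.5}

    def test_fifo_picks_longest_wait(self):
        wl = _waitlist(
            [
                {"blood_type": "A", "arrival_day": 0.0},
                {"blood_type": "O", "arrival_day": 50.0},
            ]
        )
        idx = al.select_recipient(al.PolicyConfig("fifo"), wl, self.ORGAN, None, 100.0)
        assert idx == 0  # waited 100 vs 50

    def test_max_survival_with_constant_model_reduces_to_fifo(self):
        wl = _waitlist(
            [
                {"blood_type": "A", "arrival_day": 10.0},
                {"blood_type": "B", "arrival_day": 0.0},
            ]
        )
        model = sv.ConstantRMSTModel().fit(pd.DataFrame())
        idx = al.select_recipient(
            al.PolicyConfig("max_survival"), wl, self.ORGAN, model, 200.0
        )
        assert idx == 1

    def test_hybrid_weight_arithmetic(self):
        class TwoValueModel(sv.ConstantRMSTModel):
            def fit(self, X=None, y=None):
                self.feature_names_ = ["marker"]
                return self

            def predict_rmst(self, X, horizon_days):
                m = np.asarray(X)[:, 0]
                return np.where(m > 0, 2000.0, 1900.0)

        model = TwoValueModel().fit()
        wl = _waitlist(
            [
                {"blood_type": "O", "arrival_day": 990.0, "marker": 1.0},
                {"blood_type": "O", "arrival_day": 100.0, "marker": 0.0},
            ]
        )
        # scores 10*2000+10 = 20,010 vs 10*1900+900 = 19,900
        cfg = al.PolicyConfig("hybrid", w_surv=10.0, w_wait=1.0)
        assert al.select_recipient(cfg, wl, self.ORGAN, model, 1000.0) == 0
        # with w_surv = 1: 2010 vs 2800 -> the long waiter wins
        cfg = al.PolicyConfig("hybrid", w_surv=1.0, w_wait=1.0)
        assert al.select_recipient(cfg, wl, self.ORGAN, model, 1000.0) == 1

    def test_no_compatible_candidate(self):
        wl = _waitlist([{"blood_type": "A", "arrival_day": 0.0}])
        organ = {"blood_type": "B"}
        assert al.select_recipient(al.PolicyConfig("fifo"), wl, organ, None, 10.0) is None

    def test_model_required(self):
        wl = _waitlist([{"blood_type": "O", "arrival_day": 0.0}])
        with pytest.raises(ConfigurationError):
            al.select_recipient(al.PolicyConfig("max_survival"), wl, self.ORGAN, None, 1.0)


def _abundance_streams(n=60):
    """Organs arrive for everyone, all type O, no departures before horizon."""
    days = np.arange(1.0, n + 1.0)
    cand = pd.DataFrame(
        {
            "candidate_id": np.arange(n),
            "arrival_day": days,
            "blood_type": "O",
            "ethnicity": "White",
            "departure_day": 1e9,
        }
    )
    organ = pd.DataFrame(
        {"organ_id": np.arange(n), "arrival_day": days, "blood_type": "O"}
    )
    return cand, organ


class TestSimulate:
    def test_abundance_limit_fifo(self):
        cand, organ = _abundance_streams()
        simcfg = al.SimConfig(horizon_years=1.0, warmup_years=0.0, n_replications=1)
        out = al.simulate(cand, organ, al.PolicyConfig("fifo"), None, simcfg)
        assert out["transplanted"].all()
        assert (out["wait_days"] == 0).all()  # same-day offers

    def test_no_organs(self):
        cand, _ = _abundance_streams()
        organ = pd.DataFrame({"organ_id": [], "arrival_day": [], "blood_type": []})
        simcfg = al.SimConfig(horizon_years=1.0, warmup_years=0.0, n_replications=1)
        out = al.simulate(cand, organ, al.PolicyConfig("fifo"), None, simcfg)
        assert not out["transplanted"].any()

    def test_unordered_stream_rejected(self):
        cand, organ = _abundance_streams()
        cand.loc[0, "arrival_day"] = 999.0
        simcfg = al.SimConfig(horizon_years=1.0, warmup_years=0.0, n_replications=1)
        with pytest.raises(DataError, match="ordered"):
            al.simulate(cand, organ, al.PolicyConfig("fifo"), None, simcfg)

    @pytest.fixture(scope="class")
    def seeded_run(self, fitted_cox):
        cohort = syn.CohortConfig(n_records=10, seed=0)
        stream = syn.StreamConfig(
            cohort=cohort, candidate_rate=500, organ_rate=325,
            horizon_years=6, warmup_years=2, seed=42,
        )
        cand, organ = syn.generate_arrival_streams(stream)
        simcfg = al.SimConfig(horizon_years=6, warmup_years=2, n_replications=1)
        out = al.simulate(cand, organ, al.PolicyConfig("max_survival"),
                          fitted_cox, simcfg)
        return cand, organ, out

    def test_conservation(self, seeded_run):
        cand, organ, out = seeded_run
        tx = out[out["transplanted"]]
        assert len(tx) <= min(len(organ), len(cand))
        # each organ used at most once
        assert tx["organ_id"].is_unique
        # no transplant to a departed candidate or before listing
        assert (tx["wait_days"] >= 0).all()
        day = tx["arrival_day"] + tx["wait_days"]
        assert (day < tx["departure_day"]).all()

    def test_all_transplants_abo_compatible(self, seeded_run):
        cand, organ, out = seeded_run
        tx = out[out["transplanted"]]
        merged = tx.merge(organ[["organ_id", "blood_type"]], on="organ_id",
                          suffixes=("_rec", "_don"))
        assert all(
            al.abo_compatible(d, r)
            for d, r in zip(merged["blood_type_don"], merged["blood_type_rec"])
        )

    def test_determinism(self, fitted_cox, seeded_run):
        cand, organ, out = seeded_run
        simcfg = al.SimConfig(horizon_years=6, warmup_years=2, n_replications=1)
        again = al.simulate(cand, organ, al.PolicyConfig("max_survival"),
                            fitted_cox, simcfg)
        pd.testing.assert_frame_equal(out, again)


class TestPolicyRelations:
    @pytest.fixture(scope="class")
    def shared_streams(self):
        cohort = syn.CohortConfig(n_records=10, seed=0)
        streams = []
        for rep in range(10):
            cfg = syn.StreamConfig(
                cohort=cohort, candidate_rate=200, organ_rate=130,
                horizon_years=6, warmup_years=2, seed=100 + rep,
            )
            streams.append(syn.generate_arrival_streams(cfg))
        return streams

    def test_max_survival_dominates_fifo_on_esat(self, fitted_cox, shared_streams):
        """Paired over common streams: choosing by predicted survival yields
        at least the FIFO policy's mean predicted survival after transplant."""
        simcfg = al.SimConfig(horizon_years=6, warmup_years=2, n_replications=1)
        esat_max, esat_fifo = [], []
        for cand, organ in shared_streams:
            a = al.simulate(cand, organ, al.PolicyConfig("max_survival"),
                            fitted_cox, simcfg)
            b = al.simulate(cand, organ, al.PolicyConfig("fifo"),
                            fitted_cox, simcfg)
            esat_max.append(a.loc[a.post_warmup & a.transplanted, "esat_days"].mean())
            esat_fifo.append(b.loc[b.post_warmup & b.transplanted, "esat_days"].mean())
        assert np.mean(esat_max) >= np.mean(esat_fifo)

    def test_hybrid_converges_to_max_survival(self, fitted_cox, shared_streams):
        cand, organ = shared_streams[0]
        simcfg = al.SimConfig(horizon_years=6, warmup_years=2, n_replications=1)
        huge = al.PolicyConfig("hybrid", w_surv=1e9, w_wait=1.0)
        a = al.simulate(cand, organ, huge, fitted_cox, simcfg)
        b = al.simulate(cand, organ, al.PolicyConfig("max_survival"),
                        fitted_cox, simcfg)
        assert (a["transplanted"] == b["transplanted"]).all()

    def test_hybrid_with_constant_predictions_is_fifo(self, shared_streams):
        cand, organ = shared_streams[1]
        simcfg = al.SimConfig(horizon_years=6, warmup_years=2, n_replications=1)
        const = sv.ConstantRMSTModel().fit(pd.DataFrame())
        a = al.simulate(cand, organ, al.PolicyConfig("hybrid"), const, simcfg)
        b = al.simulate(cand, organ, al.PolicyConfig("fifo"), None, simcfg)
        assert (a["transplanted"] == b["transplanted"]).all()
        np.testing.assert_allclose(
            a.loc[a.transplanted, "wait_days"], b.loc[b.transplanted, "wait_days"]
        )

    def test_fifo_equalizes_group_tp_under_biased_model(
        self, biased_trained_cox, shared_streams
    ):
        model, cfg, feats = biased_trained_cox
        simcfg = al.SimConfig(horizon_years=6, warmup_years=2, n_replications=1)
        ginis = {"max_survival": [], "fifo": []}
        for cand, organ in shared_streams[:5]:
            cand_d, _ = sv.group_dummy_features(
                cand, "ethnicity", levels=cfg.group_dimensions["ethnicity"]
            )
            a = al.simulate(cand_d, organ, al.PolicyConfig("max_survival"),
                            model, simcfg)
            b = al.simulate(cand, organ, al.PolicyConfig("fifo"), None, simcfg)
            for name, out in (("max_survival", a), ("fifo", b)):
                post = out[out.post_warmup]
                tp = post.groupby("ethnicity")["transplanted"].mean().dropna()
                ginis[name].append(equity.gini(tp.to_numpy()))
        assert np.mean(ginis["fifo"]) <= np.mean(ginis["max_survival"])


class TestReplicateAndSummarize:
    def test_same_master_seed_identical_tables(self):
        cohort = syn.CohortConfig(n_records=10, seed=0)
        stream = syn.StreamConfig(cohort=cohort, candidate_rate=150, organ_rate=100,
                                  horizon_years=5, warmup_years=1, seed=0)
        simcfg = al.SimConfig(horizon_years=5, warmup_years=1, n_replications=3, seed=7)
        a = al.replicate_and_summarize(stream, al.PolicyConfig("fifo"), None,
                                       simcfg, group_col="ethnicity")
        b = al.replicate_and_summarize(stream, al.PolicyConfig("fifo"), None,
                                       simcfg, group_col="ethnicity")
        pd.testing.assert_frame_equal(a, b)

    def test_table_layout(self):
        cohort = syn.CohortConfig(n_records=10, seed=0)
        stream = syn.StreamConfig(cohort=cohort, candidate_rate=150, organ_rate=100,
                                  horizon_years=5, warmup_years=1, seed=0)
        simcfg = al.SimConfig(horizon_years=5, warmup_years=1, n_replications=3, seed=7)
        table = al.replicate_and_summarize(stream, al.PolicyConfig("fifo"), None,
                                           simcfg, group_col="ethnicity")
        assert {"TP", "WTUT"} <= set(table["metric"])
        assert "Overall" in set(table["group"])
        assert (table["sd"] >= 0).all()
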