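"""Shared fixtures: small seeded synthetic datasets and fitted models."""

import logging

import numpy as np
import pytest

from equialloc import survival as sv
from equialloc import synthetic as syn

logging.getLogger("equialloc").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    return syn.CohortConfig(n_records=2000, seed=1)


@pytest.fixture(scope="session")
def small_registry(small_cohort):
    return syn.generate_transplant_registry(small_cohort)


@pytest.fixture(scope="session")
def fitted_cox(small_cohort, small_registry):
    model = sv.CoxPHModel()
    model.fit(
        small_registry[small_cohort.feature_names],
        sv.survival_target(small_registry),
    )
    return model


@pytest.fixture(scope="session")
def biased_trained_cox():
    """Cox model that has learned a spurious protective effect for one group.

    Trained with group-indicator features on a registry whose ``Black``
    subpopulation carries a protective unmeasured artifact (log-hazard −0.5)
    absent from the deployment distribution, so the model overestimates that
    group's survival wherever the artifact is gone.
    """
    cfg = syn.CohortConfig(n_records=4000, bias_spec={"Black": -0.5}, seed=11)
    train = syn.generate_transplant_registry(cfg)
    train_d, dummy_cols = sv.group_dummy_features(
        train, "ethnicity", levels=cfg.group_dimensions["ethnicity"]
    )
    feats = cfg.feature_names + dummy_cols
    model = sv.CoxPHModel().fit(train_d[feats], sv.survival_target(train_d))
    return model, cfg, feats


def brute_force_c_index(pred_surv, time, event, group_mask=None):
    """Independent pair-enumeration oracle for Harrell's C.

    A pair (i, j) is comparable when the record with the shorter time has an
    observed event; concordant when that record also has the lower predicted
    survival; prediction ties score half. ``group_mask`` keeps only pairs
    with at least one member in the group.
    """
    n = len(time)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if not (time[i] < time[j] and event[i] == 1):
                continue
            if group_mask is not None and not (group_mask[i] or group_mask[j]):
                continue
            den += 1
            if pred_surv[i] < pred_surv[j]:
                num += 1
            elif pred_surv[i] == pred_surv[j]:
                num += 0.5
    if den == 0:
        return None
    return num / den


def random_survival_fixture(rng, n, censor_frac=0.3, group_levels=2):
    """Small random right-censored dataset with predictions and group labels."""
    time = rng.exponential(100.0, size=n).round(1)
    event = (rng.random(n) > censor_frac).astype(int)
    pred = rng.random(n).round(2)  # rounding induces prediction ties
    group = rng.integers(0, group_levels, size=n)
    return pred, time, event, group
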