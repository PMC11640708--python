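"""Shared fixtures: planted-disparity audit runs and small prediction sets."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.model_selection import train_test_split

import fairdx as fx
from fairdx.fairness import LabeledPredictions, group_confusion
from fairdx.pipeline import _load_cohort, _predictions, fit_baseline

#: Planted-disparity study condition: a 0.16 gap in group outcome rates.
DISPARITY_RATES = {1: 0.42, 2: 0.58}
N_SUBJECTS = 10_000
N_SEEDS = 20


@pytest.fixture(scope="session")
def disparity_runs():
    """Twenty seeded audit runs on planted-disparity cohorts.

    Each entry holds the test-split predictions, the baseline group rates
    and the test-split group sizes, for seeds 0..19.
    """
    runs = []
    for seed in range(N_SEEDS):
        cfg = fx.RunConfig(
            cohort=fx.CohortSpec(
                n_subjects=N_SUBJECTS, seed=seed,
                outcome_rate_by_group=dict(DISPARITY_RATES),
            ),
            seed=seed,
        )
        cohort = _load_cohort(cfg)
        strata = (
            cohort[cfg.outcome].astype(str)
            + "|"
            + cohort[cfg.sensitive_attribute].astype(str)
        )
        train, test = train_test_split(
            cohort, test_size=cfg.test_fraction, random_state=seed,
            stratify=strata,
        )
        model = fit_baseline(train, seed=seed)
        lp = _predictions(model, test, cfg)
        gr = group_confusion(lp, cfg.privileged, cfg.unprivileged)
        runs.append(
            {
                "seed": seed,
                "lp": lp,
                "gr": gr,
                "config": cfg,
                "n_priv": int(np.sum(lp.group == cfg.privileged)),
                "n_unpriv": int(np.sum(lp.group == cfg.unprivileged)),
            }
        )
    return runs


def random_predictions(rng: np.random.Generator, n_max: int = 50) -> LabeledPredictions:
    """A random prediction instance where every group rate is defined."""
    while True:
        n = int(rng.integers(8, n_max + 1))
        y_true = rng.integers(0, 2, size=n)
        y_pred = rng.integers(0, 2, size=n)
        group = rng.integers(0, 2, size=n)
        ok = True
        for g in (0, 1):
            m = group == g
            if not m.any() or len(np.unique(y_true[m])) < 2:
                ok = False
        if ok and np.mean(y_pred[group == 0]) == 0:
            ok = False
        if ok:
            return LabeledPredictions(
                y_true=y_true,
                y_score=rng.uniform(0, 1, size=n),
                y_pred=y_pred,
                group=group,
            )
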