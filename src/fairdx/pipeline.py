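"""End-to-end fairness audit orchestration.

An audit run is: generate (or load) a cohort, split it into train/test
strata, fit a baseline probabilistic classifier, compute the fairness
metric suite on the test split, apply each configured mitigation, re-audit
after each, and optionally run the epidemic simulations.  Every random
stream is derived from the run seed, so a config fully reproduces a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from fairdx._version import __version__ as _pkg_version
from fairdx.cohort import COLUMNS, CohortSpec, generate_cohort, read_cohort_csv
from fairdx.epi import (
    EpiSummary,
    SCIRCarrierParams,
    SCIRConfirmParams,
    SIRParams,
    apply_bias_to_beta,
    integrate,
    summarize,
)
from fairdx.fairness import (
    FairnessReport,
    LabeledPredictions,
    compute_report,
    group_confusion,
)
from fairdx.mitigation import (
    MitigationParams,
    bpa_adjust,
    eq_odds_scale,
    find_k,
    reweight,
    threshold_predict,
)

__all__ = [
    "AuditBundle",
    "RunConfig",
    "correlation_matrix",
    "fit_baseline",
    "run_audit",
    "write_report",
]

logger = logging.getLogger("fairdx")

_FEATURES = [c for c in COLUMNS if c != "cardio"]


@dataclass(frozen=True)
class RunConfig:
    """Full specification of an audit run.

    ``cohort`` is either a :class:`CohortSpec` or a path to a cohort CSV.
    ``mitigations`` lists the post-processing steps to apply, each by name:
    ``"reweight"``, ``"bpa"``, ``"eq_odds"``.  ``epi_runs`` holds epidemic
    model configurations as dicts (keys: model, params, bias, t_end).
    """

    cohort: object = field(default_factory=CohortSpec)
    cohort_delimiter: str = ";"
    sensitive_attribute: str = "gender"
    privileged: object = 2
    unprivileged: object = 1
    outcome: str = "cardio"
    test_fraction: float = 0.2
    seed: int = 0
    mitigations: tuple[str, ...] = ()
    mitigation_params: MitigationParams = field(default_factory=MitigationParams)
    bpa_mode: str = "directed"
    epi_runs: tuple[Mapping, ...] = ()
    outcome_for_mean: str = "true"

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0,1)")
        unknown = set(self.mitigations) - {"reweight", "bpa", "eq_odds"}
        if unknown:
            raise ValueError(f"unknown mitigations: {sorted(unknown)}")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.cohort, CohortSpec):
            d["cohort"] = dataclasses.asdict(self.cohort)
            d["cohort"]["target_correlations"] = [
                list(t) for t in self.cohort.target_correlations
            ]
            d["cohort"]["categorical_probs"] = {
                k: (list(v) if isinstance(v, (tuple, list)) else v)
                for k, v in self.cohort.categorical_probs.items()
            }
        else:
            d["cohort"] = str(self.cohort)
        d["mitigation_params"] = dataclasses.asdict(self.mitigation_params)
        d["mitigation_params"]["k_grid"] = list(self.mitigation_params.k_grid)
        d["mitigations"] = list(self.mitigations)
        d["epi_runs"] = [dict(r) for r in self.epi_runs]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        cohort = d.get("cohort", {})
        if isinstance(cohort, Mapping):
            spec = dict(cohort)
            if "target_correlations" in spec:
                spec["target_correlations"] = tuple(
                    (a, b, float(r)) for a, b, r in spec["target_correlations"]
                )
            if "outcome_rate_by_group" in spec:
                spec["outcome_rate_by_group"] = {
                    int(k): float(v) for k, v in spec["outcome_rate_by_group"].items()
                }
            if "categorical_probs" in spec:
                spec["categorical_probs"] = {
                    k: (list(v) if isinstance(v, (tuple, list)) else v)
                    for k, v in spec["categorical_probs"].items()
                }
            d["cohort"] = CohortSpec(**spec)
        mp = d.get("mitigation_params", {})
        if isinstance(mp, Mapping):
            mp = dict(mp)
            if "k_grid" in mp:
                mp["k_grid"] = tuple(float(k) for k in mp["k_grid"])
            d["mitigation_params"] = MitigationParams(**mp)
        d["mitigations"] = tuple(d.get("mitigations", ()))
        d["epi_runs"] = tuple(d.get("epi_runs", ()))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class AuditBundle:
    """Baseline report, one report per mitigation, epi summaries, provenance."""

    baseline: FairnessReport
    mitigated: Mapping[str, FairnessReport]
    epi: Sequence[EpiSummary]
    provenance: Mapping[str, object]

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.to_dict(),
            "mitigated": {k: v.to_dict() for k, v in self.mitigated.items()},
            "epi": [dataclasses.asdict(e) for e in self.epi],
            "provenance": dict(self.provenance),
        }


def fit_baseline(
    cohort: pd.DataFrame,
    outcome: str = "cardio",
    features: Sequence[str] | None = None,
    seed: int = 0,
    sample_weight: np.ndarray | None = None,
) -> Pipeline:
    """Fit the baseline probabilistic classifier (regularised logistic fit).

    Returns a scikit-learn pipeline exposing ``predict_proba``; the fit is
    deterministic for fixed data and seed.
    """
    features = list(features) if features is not None else list(_FEATURES)
    y = cohort[outcome].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single outcome class")
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(max_iter=1000, random_state=seed)),
        ]
    )
    fit_params = {}
    if sample_weight is not None:
        fit_params["logit__sample_weight"] = np.asarray(sample_weight, dtype=float)
    model.fit(cohort[features], y, **fit_params)
    model.feature_names_ = features  # type: ignore[attr-defined]
    return model


def correlation_matrix(
    cohort: pd.DataFrame, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation matrix over the selected numeric columns.

    Zero-variance columns yield NaN entries and are listed in
    ``result.attrs["degenerate_columns"]`` rather than silently becoming 0.
    """
    if len(cohort) < 2:
        raise ValueError("correlation requires at least 2 rows")
    cols = list(columns) if columns is not None else list(cohort.columns)
    sub = cohort[cols].astype(float)
    corr = sub.corr(method="pearson")
    degenerate = [c for c in cols if sub[c].std(ddof=0) == 0]
    np.fill_diagonal(corr.values, 1.0)
    for c in degenerate:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = np.nan
    corr.attrs["degenerate_columns"] = degenerate
    return corr


def _predictions(
    model: Pipeline,
    test: pd.DataFrame,
    config: RunConfig,
) -> LabeledPredictions:
    proba = model.predict_proba(test[model.feature_names_])[:, 1]
    return LabeledPredictions(
        y_true=test[config.outcome].to_numpy(),
        y_score=proba,
        y_pred=threshold_predict(proba, config.mitigation_params.theta),
        group=test[config.sensitive_attribute].to_numpy(),
    )


def _load_cohort(config: RunConfig) -> pd.DataFrame:
    if isinstance(config.cohort, CohortSpec):
        logger.info("stage=generate_cohort n=%d seed=%d",
                    config.cohort.n_subjects, config.cohort.seed)
        return generate_cohort(config.cohort)
    logger.info("stage=load_cohort path=%s", config.cohort)
    return read_cohort_csv(config.cohort, delimiter=config.cohort_delimiter)


def run_audit(config: RunConfig) -> AuditBundle:
    """Execute the full audit pipeline for one configuration."""
    cohort = _load_cohort(config)

    strata = (
        cohort[config.outcome].astype(str)
        + "|"
        + cohort[config.sensitive_attribute].astype(str)
    )
    train, test = train_test_split(
        cohort,
        test_size=config.test_fraction,
        random_state=config.seed,
        stratify=strata,
    )
    logger.info("stage=split train=%d test=%d", len(train), len(test))

    model = fit_baseline(train, outcome=config.outcome, seed=config.seed)
    lp = _predictions(model, test, config)
    baseline = compute_report(
        lp, config.privileged, config.unprivileged,
        outcome_for_mean=config.outcome_for_mean,
    )
    logger.info("stage=baseline_audit")

    mitigated: dict[str, FairnessReport] = {}
    params = config.mitigation_params
    for name in config.mitigations:
        if name == "reweight":
            p_train = model.predict_proba(train[model.feature_names_])[:, 1]
            y_train = train[config.outcome].to_numpy()
            p_obs = np.where(y_train == 1, p_train, 1.0 - p_train)
            weights = reweight(p_obs)
            refit = fit_baseline(
                train, outcome=config.outcome, seed=config.seed,
                sample_weight=weights,
            )
            lp_m = _predictions(refit, test, config)
        elif name == "bpa":
            gr = group_confusion(lp, config.privileged, config.unprivileged)
            adj = bpa_adjust(lp.y_score, lp.group, gr, params, mode=config.bpa_mode)
            lp_m = lp.replace(
                y_score=adj.adjusted,
                y_pred=threshold_predict(adj.adjusted, params.theta),
            )
        elif name == "eq_odds":
            k, _, _ = find_k(
                lp, config.privileged, params.k_grid, theta=params.theta,
                privileged=config.privileged, unprivileged=config.unprivileged,
            )
            adj = eq_odds_scale(lp.y_score, lp.group, config.privileged, k)
            lp_m = lp.replace(
                y_score=adj.adjusted,
                y_pred=threshold_predict(adj.adjusted, params.theta),
            )
        else:  # pragma: no cover - guarded by RunConfig validation
            raise ValueError(name)
        mitigated[name] = compute_report(
            lp_m, config.privileged, config.unprivileged,
            outcome_for_mean=config.outcome_for_mean,
        )
        logger.info("stage=mitigation name=%s", name)

    epi_summaries = []
    for run in config.epi_runs:
        epi_summaries.append(_run_epi(dict(run)))
        logger.info("stage=epi model=%s", run.get("model"))

    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    provenance = {
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "version": _pkg_version,
    }
    return AuditBundle(
        baseline=baseline, mitigated=mitigated, epi=epi_summaries,
        provenance=provenance,
    )


_EPI_PARAM_TYPES = {
    "sir": SIRParams,
    "scir-confirm": SCIRConfirmParams,
    "scir-carrier": SCIRCarrierParams,
}


def _run_epi(run: dict) -> EpiSummary:
    model = run.get("model", "scir-carrier")
    cls = _EPI_PARAM_TYPES[model]
    pkw = dict(run.get("params", {}))
    bias = float(run.get("bias", 0.0))
    if bias:
        pkw["beta"] = apply_bias_to_beta(float(pkw["beta"]), bias)
    params = cls(**pkw)
    init = run.get("init", (4.0, 4.0, 1.0, 1.0) if model != "sir" else (4.0, 1.0, 1.0))
    t_end = float(run.get("t_end", 50.0))
    n_out = int(run.get("n_out", 501))
    traj = integrate(params, init, np.linspace(0.0, t_end, n_out),
                     method=run.get("method", "RK45"))
    return summarize(
        traj, params,
        total_cases_def=run.get("total_cases_def", "incidence"),
        bias_impact=bias,
    )


def write_report(bundle: AuditBundle, outdir) -> dict[str, Path]:
    """Write the bundle as JSON, flat CSV rows and a Markdown summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": outdir / "report.json",
        "csv": outdir / "report.csv",
        "md": outdir / "report.md",
    }
    paths["json"].write_text(json.dumps(bundle.to_dict(), indent=2, default=str))

    rows = [bundle.baseline.to_csv_row("baseline")]
    rows += [rep.to_csv_row(name) for name, rep in bundle.mitigated.items()]
    pd.DataFrame(rows).to_csv(paths["csv"], index=False)

    lines = ["# Fairness audit report", ""]
    lines.append(f"- config hash: `{bundle.provenance['config_hash'][:12]}`")
    lines.append(f"- seed: {bundle.provenance['seed']}")
    lines.append("")
    for name, rep in [("baseline", bundle.baseline)] + list(bundle.mitigated.items()):
        lines.append(f"## {name}")
        for key, label in FairnessReport._LABELS.items():
            lines.append(f"- {label}: {getattr(rep, key):.6f}")
        lines.append("")
    for i, e in enumerate(bundle.epi):
        lines.append(f"## epidemic run {i}")
        lines.append(f"- total cases: {e.total_cases:.3f}")
        lines.append(f"- total recoveries: {e.total_recoveries:.3f}")
        lines.append(f"- recovery rate: {e.recovery_rate:.2f}")
        lines.append(f"- bias impact on transmission: {e.bias_impact:+.2f}")
        lines.append("")
    paths["md"].write_text("\n".join(lines))
    return paths
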