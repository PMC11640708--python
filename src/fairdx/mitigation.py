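"""Post-processing bias mitigation operators.

Four families are implemented:

* inverse-probability **reweighting** of training points, w_i = 1 / p(y_i|x_i);
* **balanced probability adjustment** (BPA): rescaling predicted
  probabilities by 1 + alpha*dTPR + beta*dFPR and re-thresholding.  Two
  modes are shipped: ``"literal"`` applies the same multiplier to every
  subject; ``"directed"`` (the pipeline default) flips the sign per group
  so each group's error rates are pushed toward parity;
* **equalised-odds scaling**: multiplying non-target-group scores by a
  factor k chosen by grid search to minimise |dTPR| + |dFPR|;
* **counterfactual search**: the nearest point in a discretised feature box
  whose prediction flips to the desired label;

plus the composite fairness loss combinator L = L_task + lambda * L_fair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from fairdx.fairness import GroupRates, LabeledPredictions, group_confusion

__all__ = [
    "AdjustedScores",
    "CounterfactualQuery",
    "CounterfactualResult",
    "MitigationParams",
    "bpa_adjust",
    "composite_fairness_loss",
    "counterfactual_search",
    "eq_odds_scale",
    "find_k",
    "reweight",
    "threshold_predict",
]


@dataclass(frozen=True)
class MitigationParams:
    """Hyperparameters shared by the mitigation operators.

    alpha_bpa / beta_bpa control the BPA sensitivity to the TPR and FPR
    gaps; theta is the decision threshold (strict '>'); k_grid is the
    candidate grid of equalised-odds scaling factors.
    """

    alpha_bpa: float = 0.5
    beta_bpa: float = 0.5
    theta: float = 0.5
    k_grid: tuple[float, ...] = tuple(round(0.5 + 0.1 * i, 10) for i in range(16))
    lambda_fair: float = 1.0
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must be in (0,1), got {self.theta}")
        if self.alpha_bpa < 0 or self.beta_bpa < 0:
            raise ValueError("alpha_bpa and beta_bpa must be >= 0")
        if len(self.k_grid) == 0 or any(k <= 0 for k in self.k_grid):
            raise ValueError("k_grid must be non-empty with all entries > 0")
        if self.lambda_fair < 0 or self.tolerance < 0:
            raise ValueError("lambda_fair and tolerance must be >= 0")


@dataclass(frozen=True)
class AdjustedScores:
    """Original and adjusted probabilities plus adjustment metadata."""

    original: np.ndarray
    adjusted: np.ndarray
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "original", np.asarray(self.original, dtype=float))
        object.__setattr__(self, "adjusted", np.asarray(self.adjusted, dtype=float))
        if self.original.shape != self.adjusted.shape:
            raise ValueError("original and adjusted scores must align")
        if len(self.adjusted) and (
            self.adjusted.min() < 0 or self.adjusted.max() > 1
        ):
            raise ValueError("adjusted scores must lie in [0,1]")


def reweight(
    p_obs_label: np.ndarray, eps: float = 1e-3, clip: bool = True
) -> np.ndarray:
    """Inverse-probability weights w_i = 1 / p(y_i | x_i).

    ``p_obs_label`` is the model's probability of each subject's *observed*
    label.  Probabilities are clipped to [eps, 1] so weights stay bounded;
    with ``clip=False`` a non-positive probability raises instead.
    """
    p = np.asarray(p_obs_label, dtype=float)
    if np.any(p > 1.0):
        raise ValueError("probabilities above 1 are invalid")
    if clip:
        p = np.clip(p, eps, 1.0)
    elif np.any(p <= 0):
        raise ValueError("non-positive probability with clipping disabled")
    return 1.0 / p


def threshold_predict(scores: np.ndarray, theta: float = 0.5) -> np.ndarray:
    """Binary labels: 1 iff score > theta (strict inequality)."""
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must be in (0,1), got {theta}")
    s = np.asarray(scores, dtype=float)
    if len(s) and (s.min() < 0 or s.max() > 1):
        raise ValueError("scores must lie in [0,1]")
    return (s > theta).astype(int)


def bpa_adjust(
    scores: np.ndarray,
    groups: np.ndarray,
    gr: GroupRates,
    params: MitigationParams,
    mode: str = "directed",
) -> AdjustedScores:
    """Balanced probability adjustment of predicted scores.

    ``mode="literal"``: every score is multiplied by
    1 + alpha*dTPR + beta*dFPR (then clipped to [0,1]).

    ``mode="directed"`` (default): per-group signed multiplier.  The group
    with the lower TPR receives the +alpha*dTPR term (boosting its scores
    raises its TPR toward the other group's); the group with the higher
    FPR receives the -beta*dFPR term (damping lowers its FPR).  A group
    holding neither role for a term receives no contribution from it, so
    each gap is closed from its disadvantaged side only and the operator
    does not overshoot.  Groups outside the designated pair are left
    unchanged.
    """
    if mode not in ("literal", "directed"):
        raise ValueError(f"unknown mode {mode!r}")
    p = np.asarray(scores, dtype=float)
    g = np.asarray(groups)
    if p.shape != g.shape:
        raise ValueError("scores and groups must align")
    d_tpr, d_fpr = gr.delta_tpr, gr.delta_fpr
    a, b = params.alpha_bpa, params.beta_bpa

    if mode == "literal":
        mult = np.full_like(p, 1.0 + a * d_tpr + b * d_fpr)
    else:
        mult = np.ones_like(p)
        tpr_u, tpr_p = gr.tpr(gr.unprivileged), gr.tpr(gr.privileged)
        fpr_u, fpr_p = gr.fpr(gr.unprivileged), gr.fpr(gr.privileged)
        for grp in (gr.privileged, gr.unprivileged):
            s_t = s_f = 0.0
            if d_tpr > 0:
                low_tpr = gr.unprivileged if tpr_u < tpr_p else gr.privileged
                s_t = 1.0 if grp == low_tpr else 0.0
            if d_fpr > 0:
                high_fpr = gr.unprivileged if fpr_u > fpr_p else gr.privileged
                s_f = -1.0 if grp == high_fpr else 0.0
            mult[g == grp] = 1.0 + s_t * a * d_tpr + s_f * b * d_fpr
    adjusted = np.clip(p * mult, 0.0, 1.0)
    return AdjustedScores(
        original=p,
        adjusted=adjusted,
        metadata={"mode": mode, "delta_tpr": d_tpr, "delta_fpr": d_fpr,
                  "alpha": a, "beta": b},
    )


def eq_odds_scale(
    scores: np.ndarray,
    groups: np.ndarray,
    target_group: object,
    k: float,
) -> AdjustedScores:
    """Scale non-target-group scores by k (clipped to [0,1])."""
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    p = np.asarray(scores, dtype=float)
    g = np.asarray(groups)
    if p.shape != g.shape:
        raise ValueError("scores and groups must align")
    if not np.any(g == target_group):
        raise ValueError(f"target group {target_group!r} not present")
    adjusted = np.where(g == target_group, p, np.clip(p * k, 0.0, 1.0))
    return AdjustedScores(
        original=p, adjusted=adjusted, metadata={"k": k, "target_group": target_group}
    )


def find_k(
    lp: LabeledPredictions,
    target_group: object,
    k_grid: Sequence[float],
    theta: float = 0.5,
    privileged: object | None = None,
    unprivileged: object | None = None,
) -> tuple[float, GroupRates, float]:
    """Grid-search the equalised-odds scaling factor k.

    Minimises |dTPR| + |dFPR| after scaling and re-thresholding; ties are
    broken toward the k closest to 1 (least intervention), then toward the
    smaller k.  Returns (k, post-adjustment GroupRates, objective).
    """
    if len(k_grid) == 0:
        raise ValueError("k_grid must be non-empty")
    present = [g for g in dict.fromkeys(lp.group.tolist())]
    if privileged is None or unprivileged is None:
        others = [g for g in present if g != target_group]
        if len(others) != 1:
            raise ValueError("specify privileged/unprivileged for >2 groups")
        privileged, unprivileged = target_group, others[0]

    best: tuple[float, float, float, GroupRates] | None = None
    for k in k_grid:
        adj = eq_odds_scale(lp.y_score, lp.group, target_group, k)
        y_pred = threshold_predict(adj.adjusted, theta)
        try:
            gr = group_confusion(
                lp.replace(y_pred=y_pred), privileged, unprivileged
            )
        except ValueError:
            continue
        obj = gr.delta_tpr + gr.delta_fpr
        key = (obj, abs(k - 1.0), k)
        if best is None or key < (best[0], best[1], best[2]):
            best = (obj, abs(k - 1.0), k, gr)
    if best is None:
        raise ValueError("all k in the grid yield undefined rates")
    obj, _, k, gr = best
    return float(k), gr, float(obj)


@dataclass(frozen=True)
class CounterfactualQuery:
    """Search box for the nearest counterfactual of a feature vector.

    ``predictor`` maps an (n, d) array of feature vectors to n labels.
    ``lower``/``upper`` bound each feature; ``steps`` sets the grid pitch.
    """

    x: np.ndarray
    predictor: Callable[[np.ndarray], np.ndarray]
    desired_label: object
    lower: np.ndarray
    upper: np.ndarray
    steps: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "lower", "upper", "steps"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        d = len(self.x)
        if not (len(self.lower) == len(self.upper) == len(self.steps) == d):
            raise ValueError("x, lower, upper, steps must share one length")
        if not np.all(np.isfinite(self.lower)) or not np.all(np.isfinite(self.upper)):
            raise ValueError("bounds must be finite")
        if np.any(self.steps <= 0):
            raise ValueError("steps must be > 0")
        if np.any(self.upper < self.lower):
            raise ValueError("upper must be >= lower")


@dataclass(frozen=True)
class CounterfactualResult:
    found: bool
    x_cf: np.ndarray | None
    distance: float


def counterfactual_search(
    q: CounterfactualQuery, max_grid_points: int = 2_000_000
) -> CounterfactualResult:
    """Exhaustive nearest-counterfactual search on the discretised box.

    Enumerates every grid point of the box, keeps those the predictor maps
    to the desired label and returns the one closest to ``q.x`` in
    Euclidean distance (first in C order on ties).  An infeasible box
    yields a not-found result rather than an exception.
    """
    axes = [
        np.arange(lo, hi + st / 2.0, st)
        for lo, hi, st in zip(q.lower, q.upper, q.steps)
    ]
    n_points = int(np.prod([len(a) for a in axes]))
    if n_points > max_grid_points:
        raise ValueError(
            f"grid of {n_points} points exceeds max_grid_points={max_grid_points}"
        )
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    labels = np.asarray(q.predictor(pts))
    if labels.shape != (len(pts),):
        raise ValueError("predictor must return one label per row")
    feasible = labels == q.desired_label
    if not feasible.any():
        return CounterfactualResult(found=False, x_cf=None, distance=math.inf)
    cand = pts[feasible]
    dist = np.linalg.norm(cand - q.x, axis=1)
    i = int(np.argmin(dist))
    return CounterfactualResult(found=True, x_cf=cand[i], distance=float(dist[i]))


def composite_fairness_loss(
    l_task: float, l_fair: float, lambda_fair: float
) -> float:
    """Composite objective L = L_task + lambda * L_fair."""
    vals = (l_task, l_fair, lambda_fair)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"inputs must be finite, got {vals}")
    return l_task + lambda_fair * l_fair
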