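"""Synthetic cardiovascular cohort generation with planted structure.

The generator emulates a screening cohort with the classic tabular schema
(age in days, height, weight, systolic/diastolic pressure, cholesterol and
glucose grades, smoking/alcohol/activity flags, binary cardiovascular
outcome).  Group-conditional outcome rates and pairwise Pearson
correlations are planted so that every downstream fairness statistic has a
known ground truth.

Correlations across mixed continuous/binary/ordinal columns are induced
with a Gaussian copula: a latent multivariate normal vector is sampled with
a calibrated latent correlation matrix, then each coordinate is pushed
through its marginal transform (linear for continuous columns, threshold
for categorical ones).  The calibration inverts the latent-to-observed
correlation map per pair, so the *observed* Pearson r matches the request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BiasFactorSpec",
    "CohortSpec",
    "generate_bias_factors",
    "generate_cohort",
    "generate_mask_pair",
    "pack_year_category",
    "pack_years",
    "read_cohort_csv",
    "write_bboxes_csv",
    "write_cohort_csv",
    "write_mask_png",
]

#: Column order of the tabular schema.
COLUMNS = (
    "age",
    "gender",
    "height",
    "weight",
    "ap_hi",
    "ap_lo",
    "cholesterol",
    "gluc",
    "smoke",
    "alco",
    "active",
    "cardio",
)

_CONTINUOUS = ("age", "height", "weight", "ap_hi", "ap_lo")

# Marginal defaults approximating a mid-life screening population of this
# schema: age in days (~53 years), blood pressure in mmHg.
_DEFAULT_MEANS = {
    "age": 19468.0,
    "height": 164.4,
    "weight": 74.2,
    "ap_hi": 126.6,
    "ap_lo": 81.7,
}
_DEFAULT_SDS = {
    "age": 2467.0,
    "height": 8.2,
    "weight": 14.4,
    "ap_hi": 16.0,
    "ap_lo": 9.5,
}

# gender: probability of the second category (coded 2); cholesterol/gluc:
# probabilities of grades 1..3; remaining entries: probability of flag 1.
_DEFAULT_CATEGORICALS: dict[str, object] = {
    "gender": 0.35,
    "cholesterol": (0.75, 0.135, 0.115),
    "gluc": (0.85, 0.074, 0.076),
    "smoke": 0.088,
    "alco": 0.054,
    "active": 0.804,
}

# Headline correlation structure of the cohort: age and weight raise
# cardiovascular risk, glucose and cholesterol co-occur, smoking skews by
# gender, and the two pressure readings track each other.
_DEFAULT_CORRELATIONS = (
    ("age", "cardio", 0.24),
    ("age", "cholesterol", 0.15),
    ("weight", "cardio", 0.18),
    ("gender", "smoke", 0.34),
    ("gluc", "cholesterol", 0.45),
    ("smoke", "cardio", -0.02),
    ("ap_hi", "ap_lo", 0.70),
)


class ValidationError(ValueError):
    """Raised when a generator specification violates its invariants."""


# --------------------------------------------------------------------------
# pack-years

def pack_years(cigarettes_per_day: float, years_smoked: float) -> float:
    """Cumulative smoking exposure: (cigarettes per day / 20) x years smoked.

    One pack (20 cigarettes) per day for one year is one pack-year.
    """
    if cigarettes_per_day < 0 or years_smoked < 0:
        raise ValidationError(
            "pack_years requires non-negative inputs, got "
            f"({cigarettes_per_day}, {years_smoked})"
        )
    return (cigarettes_per_day / 20.0) * years_smoked


def pack_year_category(py: float) -> str:
    """Bin pack-years into the categories '0-10', '10-20', '>20'.

    Bins are half-open: [0, 10) -> '0-10', [10, 20) -> '10-20',
    [20, inf) -> '>20'.
    """
    if py < 0:
        raise ValidationError(f"pack-years must be non-negative, got {py}")
    if py < 10:
        return "0-10"
    if py < 20:
        return "10-20"
    return ">20"


# --------------------------------------------------------------------------
# specifications

@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort.

    Parameters
    ----------
    n_subjects:
        Number of rows to generate.
    outcome_rate_by_group:
        Probability of ``cardio == 1`` conditional on the ``gender`` value
        (1 or 2).  The overall prevalence is the mixture over the gender
        marginal.
    feature_means, feature_sds:
        Marginal mean / standard deviation per continuous column.
    categorical_probs:
        Marginal probabilities per categorical column (see module
        defaults for the encoding).
    target_correlations:
        Pairwise Pearson correlations ``(column_a, column_b, r)`` to plant
        via the Gaussian copula.
    with_pack_years:
        Whether to attach a ``pack_years`` column (zero for non-smokers).
    seed:
        Seed of the generator's random stream.
    """

    n_subjects: int = 10_000
    outcome_rate_by_group: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.5}
    )
    feature_means: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MEANS)
    )
    feature_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SDS)
    )
    categorical_probs: Mapping[str, object] = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORICALS)
    )
    target_correlations: Sequence[tuple[str, str, float]] = _DEFAULT_CORRELATIONS
    with_pack_years: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValidationError(f"n_subjects must be >= 0, got {self.n_subjects}")
        for g, p in self.outcome_rate_by_group.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"outcome rate for group {g} not in [0,1]: {p}")
        if set(self.outcome_rate_by_group) != {1, 2}:
            raise ValidationError(
                "outcome_rate_by_group must be keyed by gender codes {1, 2}"
            )
        for col in _CONTINUOUS:
            if col not in self.feature_means or col not in self.feature_sds:
                raise ValidationError(f"missing marginal for continuous column {col!r}")
            if self.feature_sds[col] < 0:
                raise ValidationError(f"negative sd for {col!r}")
        for col, p in self.categorical_probs.items():
            probs = np.atleast_1d(np.asarray(p, dtype=float))
            if np.any(probs < 0) or np.any(probs > 1):
                raise ValidationError(f"probabilities for {col!r} not in [0,1]")
            if probs.size > 1 and not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
                raise ValidationError(f"probabilities for {col!r} do not sum to 1")
        for a, b, r in self.target_correlations:
            if a not in COLUMNS or b not in COLUMNS:
                raise ValidationError(f"unknown column in correlation ({a!r}, {b!r})")
            if not -1.0 <= r <= 1.0:
                raise ValidationError(f"|r| must be <= 1, got {r} for ({a}, {b})")


@dataclass(frozen=True)
class BiasFactorSpec:
    """Specification for per-group relative bias factors on transmission.

    ``mean_bias = -0.10`` encodes a 10% reduction of the transmission rate.
    """

    mean_bias: float = -0.10
    sd_bias: float = 0.02
    group_offsets: Mapping[object, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.sd_bias < 0:
            raise ValidationError(f"sd_bias must be >= 0, got {self.sd_bias}")


# --------------------------------------------------------------------------
# Gaussian copula calibration

def _thresholds(col: str, spec: CohortSpec) -> np.ndarray | None:
    """Latent thresholds of a categorical column; None for continuous."""
    if col in _CONTINUOUS:
        return None
    if col == "cardio":
        pr = spec.outcome_rate_by_group
        p_g2 = float(np.atleast_1d(spec.categorical_probs["gender"])[-1])
        pooled = (1 - p_g2) * pr[1] + p_g2 * pr[2]
        return np.array([stats.norm.ppf(1.0 - pooled)])
    p = spec.categorical_probs[col]
    probs = np.atleast_1d(np.asarray(p, dtype=float))
    if probs.size == 1:  # binary flag or gender
        return np.array([stats.norm.ppf(1.0 - probs[0])])
    cum = np.cumsum(probs)[:-1]
    return stats.norm.ppf(cum)


def _step_moments(thresholds: np.ndarray) -> tuple[float, float]:
    """Mean and sd of D = sum_j 1{Z > c_j} for standard normal Z."""
    p_exceed = 1.0 - stats.norm.cdf(thresholds)
    mean = float(p_exceed.sum())
    # var(D) = sum_jk [P(Z>max(c_j,c_k)) - p_j p_k]
    var = 0.0
    for j, cj in enumerate(thresholds):
        for k, ck in enumerate(thresholds):
            var += (1.0 - stats.norm.cdf(max(cj, ck))) - p_exceed[j] * p_exceed[k]
    return mean, math.sqrt(max(var, 1e-300))


def _biv_upper(c: float, d: float, rho: float) -> float:
    """P(Z1 > c, Z2 > d) for standard bivariate normal with correlation rho."""
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    return float(
        1.0 - stats.norm.cdf(c) - stats.norm.cdf(d) + mvn.cdf(np.array([c, d]))
    )


def _latent_rho(col_a: str, col_b: str, r: float, spec: CohortSpec) -> float:
    """Invert the latent->observed Pearson correlation map for one pair."""
    ca, cb = _thresholds(col_a, spec), _thresholds(col_b, spec)
    if ca is None and cb is None:
        return r
    if (ca is None) != (cb is None):  # continuous-discrete (point-biserial style)
        c = cb if ca is None else ca
        _, sd_d = _step_moments(c)
        # cov(X, D) = rho * sum_j phi(c_j)
        slope = float(stats.norm.pdf(c).sum()) / sd_d
        rho = r / slope
        if not -1.0 < rho < 1.0:
            raise ValidationError(
                f"target correlation r={r} between {col_a!r} and {col_b!r} is "
                "unattainable under the marginals"
            )
        return rho
    # discrete-discrete: solve observed_r(rho) = r numerically
    _, sd_a = _step_moments(ca)
    _, sd_b = _step_moments(cb)
    pa = 1.0 - stats.norm.cdf(ca)
    pb = 1.0 - stats.norm.cdf(cb)

    def observed(rho: float) -> float:
        cov = 0.0
        for j, cj in enumerate(ca):
            for k, dk in enumerate(cb):
                cov += _biv_upper(cj, dk, rho) - pa[j] * pb[k]
        return cov / (sd_a * sd_b)

    lo, hi = -0.999, 0.999
    if not observed(lo) <= r <= observed(hi):
        raise ValidationError(
            f"target correlation r={r} between {col_a!r} and {col_b!r} is "
            "unattainable under the marginals"
        )
    return float(optimize.brentq(lambda rho: observed(rho) - r, lo, hi, xtol=1e-10))


def _latent_matrix(spec: CohortSpec) -> np.ndarray:
    n = len(COLUMNS)
    R = np.eye(n)
    idx = {c: i for i, c in enumerate(COLUMNS)}
    for a, b, r in spec.target_correlations:
        rho = _latent_rho(a, b, r, spec)
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
    # project to the nearest PSD correlation matrix (eigenvalue clipping)
    w, v = np.linalg.eigh(R)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        R = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


# --------------------------------------------------------------------------
# generators

def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort table with the planted structure of *spec*.

    Returns a DataFrame with the schema columns (and ``pack_years`` when
    requested).  Deterministic under a fixed spec (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cols = list(COLUMNS) + (["pack_years"] if spec.with_pack_years else [])
    if spec.n_subjects == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})

    R = _latent_matrix(spec)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(R.shape[0]))
    z = rng.standard_normal((spec.n_subjects, len(COLUMNS))) @ L.T

    idx = {c: i for i, c in enumerate(COLUMNS)}
    out: dict[str, np.ndarray] = {}
    for col in _CONTINUOUS:
        vals = spec.feature_means[col] + spec.feature_sds[col] * z[:, idx[col]]
        out[col] = np.round(vals).astype(int) if col in ("age", "ap_hi", "ap_lo") else np.round(vals, 1)
    for col in ("gender", "smoke", "alco", "active", "cholesterol", "gluc"):
        th = _thresholds(col, spec)
        d = np.zeros(spec.n_subjects, dtype=int)
        for c in th:
            d += (z[:, idx[col]] > c).astype(int)
        if col == "gender":
            out[col] = d + 1
        elif col in ("cholesterol", "gluc"):
            out[col] = d + 1
        else:
            out[col] = d

    # outcome: group-conditional threshold on the latent coordinate, so the
    # planted rates hold per gender while the latent correlations survive
    zc = z[:, idx["cardio"]]
    cardio = np.zeros(spec.n_subjects, dtype=int)
    for g, rate in spec.outcome_rate_by_group.items():
        mask = out["gender"] == g
        cardio[mask] = (zc[mask] > stats.norm.ppf(1.0 - rate)).astype(int)
    out["cardio"] = cardio

    # diastolic must sit below systolic; clip inversions introduced by the
    # independent marginals
    out["ap_lo"] = np.minimum(out["ap_lo"], out["ap_hi"] - 5)

    df = pd.DataFrame({c: out[c] for c in COLUMNS})
    if spec.with_pack_years:
        py = np.zeros(spec.n_subjects)
        smokers = df["smoke"].to_numpy() == 1
        n_s = int(smokers.sum())
        if n_s:
            cigs = rng.lognormal(mean=math.log(15.0), sigma=0.35, size=n_s)
            age_years = df.loc[smokers, "age"].to_numpy() / 365.25
            years = np.maximum(age_years - 18.0, 1.0) * rng.uniform(0.3, 1.0, size=n_s)
            py[smokers] = (cigs / 20.0) * years
        df["pack_years"] = np.round(py, 2)
    return df


def generate_bias_factors(
    groups: Sequence[object], spec: BiasFactorSpec
) -> dict[object, float]:
    """Draw one relative bias factor per group from N(mean_bias, sd_bias^2).

    Group-specific offsets from the spec are added on top.  Deterministic
    under a fixed seed.
    """
    spec.validate()
    if len(groups) == 0:
        raise ValidationError("groups must be non-empty")
    rng = np.random.default_rng(spec.seed)
    draws = rng.normal(spec.mean_bias, spec.sd_bias, size=len(groups))
    return {
        g: float(draws[i] + spec.group_offsets.get(g, 0.0))
        for i, g in enumerate(groups)
    }


# --------------------------------------------------------------------------
# mask-pair generator

def _disk(shape: tuple[int, int], center: tuple[float, float], r: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= r * r).astype(np.uint8)


def _dice_of(a: np.ndarray, b: np.ndarray) -> float:
    inter = int(np.logical_and(a, b).sum())
    tot = int(a.sum()) + int(b.sum())
    return 2.0 * inter / tot if tot else 0.0


def generate_mask_pair(
    shape: tuple[int, int], target_dice: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a (ground-truth, predicted) binary mask pair with a target Dice.

    Both masks are rasterised disks of equal radius; the predicted disk is
    translated until the rasterised Dice coefficient is within +/-0.05 of
    ``target_dice``.  Deterministic under ``seed``.
    """
    if not 0.0 <= target_dice <= 1.0:
        raise ValidationError(f"target_dice must be in [0,1], got {target_dice}")
    rows, cols = shape
    if rows < 16 or cols < 16:
        raise ValidationError(
            f"shape {shape} too small to place a controllable mask pair"
        )
    rng = np.random.default_rng(seed)
    r = min(rows, cols) // 5
    cy = rows / 2.0 + rng.integers(-2, 3)
    cx = cols / 2.0 + rng.integers(-2, 3)

    if target_dice >= 1.0:
        gt = _disk(shape, (cy, cx), r)
        return gt, gt.copy()

    max_shift = 2.0 * r + 2.0
    # centre the pair on the shift axis so both disks stay in frame
    def pair(s: float) -> tuple[np.ndarray, np.ndarray]:
        gt = _disk(shape, (cy, cx - s / 2.0), r)
        pred = _disk(shape, (cy, cx + s / 2.0), r)
        return gt, pred

    if cx - max_shift / 2.0 - r < 1 or cx + max_shift / 2.0 + r > cols - 1:
        raise ValidationError(f"shape {shape} cannot hold two disjoint disks")

    # coarse-to-fine search over the shift for the rasterised Dice
    best_s, best_err = 0.0, math.inf
    grid = np.arange(0.0, max_shift + 0.25, 0.5)
    for s in grid:
        err = abs(_dice_of(*pair(s)) - target_dice)
        if err < best_err:
            best_s, best_err = s, err
    fine = np.arange(max(0.0, best_s - 0.5), best_s + 0.55, 0.05)
    for s in fine:
        err = abs(_dice_of(*pair(s)) - target_dice)
        if err < best_err:
            best_s, best_err = s, err
    gt, pred = pair(best_s)
    if abs(_dice_of(gt, pred) - target_dice) > 0.05:
        raise ValidationError(
            f"cannot achieve Dice {target_dice} on shape {shape} within 0.05"
        )
    return gt, pred


# --------------------------------------------------------------------------
# IO

def write_cohort_csv(df: pd.DataFrame, path, delimiter: str = ";") -> None:
    """Write a cohort as CSV (';' by convention for this schema)."""
    if delimiter not in (";", ","):
        raise ValidationError(f"delimiter must be ';' or ',', got {delimiter!r}")
    df.to_csv(path, sep=delimiter, index=False)


def read_cohort_csv(path, delimiter: str = ";") -> pd.DataFrame:
    if delimiter not in (";", ","):
        raise ValidationError(f"delimiter must be ';' or ',', got {delimiter!r}")
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {missing}")
    return df


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as single-channel 8-bit PNG (0/255)."""
    from PIL import Image

    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)


def write_bboxes_csv(rows: Sequence[Mapping[str, object]], path) -> None:
    """Write bounding boxes with the annotation schema columns."""
    columns = ["label", "x0", "y0", "w", "h", "name", "img_shape_x", "img_shape_y"]
    pd.DataFrame(list(rows), columns=columns).to_csv(path, index=False)
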