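"""Causal-effect estimators and classical diagnostics.

Per-SNP Wald ratios (by/bx with first-order delta SEs) are pooled by
inverse-variance weighting (fixed, multiplicative random effects, or an
automatic policy that switches to random effects when Cochran's Q is
significant).  MR-Egger adds a free intercept as a directional-pleiotropy
test; the weighted median is consistent when at least half of the weight
comes from valid instruments.  Effect-scale helpers convert log-odds
estimates to odds ratios with confidence intervals and compute two-sided
normal p-values tail-stably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AnalysisError
from .harmonize import HarmonizedVariant

__all__ = [
    "RatioEstimate",
    "MrResult",
    "OddsRatioResult",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "mr_egger",
    "weighted_median",
    "leave_one_out",
    "or_from_beta",
    "p_from_z",
]


@dataclass(frozen=True)
class RatioEstimate:
    """Single-SNP causal estimate: ratio = by/bx."""

    rsid: str
    ratio: float
    se_ratio: float


@dataclass(frozen=True)
class MrResult:
    """One method's causal estimate.

    ``intercept`` fields are populated by MR-Egger only; ``q`` fields by
    methods that compute heterogeneity (IVW with >= 2 SNPs).
    """

    method: str
    theta: float
    se: float
    pvalue: float
    n_snp: int
    intercept: float | None = None
    se_intercept: float | None = None
    p_intercept: float | None = None
    q: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None


@dataclass(frozen=True)
class OddsRatioResult:
    or_point: float
    ci_low: float
    ci_high: float
    level: float = 0.95


def p_from_z(theta: float, se: float) -> float:
    """Two-sided normal p-value for theta/se, stable in the far tails."""
    if not se > 0:
        raise AnalysisError(f"se must be positive, got {se}")
    return float(2.0 * stats.norm.sf(abs(theta) / se))


def or_from_beta(theta: float, se: float, level: float = 0.95) -> OddsRatioResult:
    """Odds ratio exp(theta) with a symmetric log-scale confidence interval."""
    if not se > 0:
        raise AnalysisError(f"se must be positive, got {se}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return OddsRatioResult(
        or_point=math.exp(theta),
        ci_low=math.exp(theta - z * se),
        ci_high=math.exp(theta + z * se),
        level=level,
    )


def wald_ratio(v: HarmonizedVariant, second_order: bool = False) -> RatioEstimate:
    """Per-SNP Wald ratio by/bx with delta-method SE.

    First-order SE is se_by/|bx|; with ``second_order`` the term
    by²·se_bx²/bx⁴ is added under the square root.
    """
    if v.bx == 0.0:
        raise AnalysisError(f"{v.rsid}: exposure beta is zero, Wald ratio undefined")
    var = (v.se_by / v.bx) ** 2
    if second_order:
        var += v.by**2 * v.se_bx**2 / v.bx**4
    return RatioEstimate(rsid=v.rsid, ratio=v.by / v.bx, se_ratio=math.sqrt(var))


def _ratios(variants, second_order=False):
    if not variants:
        raise AnalysisError("no variants supplied")
    return [wald_ratio(v, second_order=second_order) for v in variants]


def cochran_q(ratios, theta: float):
    """Cochran's Q heterogeneity statistic around a pooled estimate.

    Returns (Q, df, p) with Q = Σ wj (rj − theta)², wj = 1/se_ratio², df =
    n − 1 and p from the chi-square upper tail.
    """
    if len(ratios) < 2:
        raise AnalysisError("Cochran's Q requires at least two ratios")
    r = np.array([x.ratio for x in ratios])
    w = np.array([x.se_ratio for x in ratios]) ** -2.0
    q = float(np.sum(w * (r - theta) ** 2))
    df = len(ratios) - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw(variants, model: str = "fixed", second_order: bool = False) -> MrResult:
    """Inverse-variance-weighted pooled estimate of the Wald ratios.

    theta = Σ wj rj / Σ wj with wj = 1/se_ratio_j².  The fixed-effects SE
    is (Σ wj)^(-1/2); the multiplicative random-effects model inflates it
    by max(1, sqrt(Q/(n−1))).  ``model='auto'`` uses random effects when
    Q's p-value is below 0.05.  Heterogeneity fields are populated
    whenever n >= 2.
    """
    if model not in ("fixed", "random", "auto"):
        raise AnalysisError(f"unknown IVW model {model!r}")
    ratios = _ratios(variants, second_order)
    r = np.array([x.ratio for x in ratios])
    w = np.array([x.se_ratio for x in ratios]) ** -2.0
    theta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)

    q = q_df = q_p = None
    se = se_fixed
    chosen = "ivw_fixed"
    if len(ratios) >= 2:
        q, q_df, q_p = cochran_q(ratios, theta)
        inflation = max(1.0, math.sqrt(q / q_df))
        if model == "random" or (model == "auto" and q_p < 0.05):
            se = se_fixed * inflation
            chosen = "ivw_random"
    elif model == "random":
        chosen = "ivw_random"

    return MrResult(
        method=chosen,
        theta=theta,
        se=se,
        pvalue=p_from_z(theta, se),
        n_snp=len(ratios),
        q=q,
        q_df=q_df,
        q_pvalue=q_p,
    )


def mr_egger(variants) -> MrResult:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    Variants are first oriented so every bx >= 0 (joint sign flip of bx
    and by), making the fit invariant to arbitrary allele orientation.
    Weights are 1/se_by²; coefficient SEs use the weighted least-squares
    covariance with multiplicative residual inflation max(1, RSS/(J−2)).
    The intercept estimates the mean directional pleiotropic effect.
    """
    if len(variants) < 3:
        raise AnalysisError(
            "MR-Egger needs at least 3 variants; use IVW for smaller sets"
        )
    bx = np.array([v.bx for v in variants], dtype=float)
    by = np.array([v.by for v in variants], dtype=float)
    se_by = np.array([v.se_by for v in variants], dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign

    w = se_by**-2.0
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    try:
        coef = np.linalg.solve(xtwx, xtwy)
        cov_unit = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        raise AnalysisError("MR-Egger design is singular (no spread in bx)") from None
    resid = by - X @ coef
    dof = len(variants) - 2
    sigma2 = max(1.0, float(np.sum(w * resid**2)) / dof)
    se_coef = np.sqrt(sigma2 * np.diag(cov_unit))

    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(se_coef[0]), float(se_coef[1])
    return MrResult(
        method="egger",
        theta=slope,
        se=se_slope,
        pvalue=p_from_z(slope, se_slope),
        n_snp=len(variants),
        intercept=intercept,
        se_intercept=se_int,
        p_intercept=p_from_z(intercept, se_int),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Cumulative-weight interpolation of sorted ratios to weight 0.5."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def weighted_median(variants, n_boot: int = 1000, seed: int | None = None) -> MrResult:
    """Precision-weighted median of the Wald ratios.

    The point estimate interpolates the sorted ratios at cumulative
    normalized weight 0.5 (weights 1/se_ratio²).  The SE comes from a
    seeded parametric bootstrap: resample bx_j ~ N(bx_j, se_bx_j) and
    by_j ~ N(by_j, se_by_j), recompute the estimate, take the SD.
    """
    if len(variants) < 3:
        raise AnalysisError("weighted median needs at least 3 variants")
    if n_boot < 1:
        raise AnalysisError("n_boot must be >= 1")
    if seed is None:
        raise AnalysisError("weighted_median requires an explicit seed")
    ratios = _ratios(variants)
    r = np.array([x.ratio for x in ratios])
    w = np.array([x.se_ratio for x in ratios]) ** -2.0
    theta = _weighted_median_point(r, w)

    bx = np.array([v.bx for v in variants])
    se_bx = np.array([v.se_bx for v in variants])
    by = np.array([v.by for v in variants])
    se_by = np.array([v.se_by for v in variants])
    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, se_bx, size=(n_boot, len(variants)))
    by_star = rng.normal(by, se_by, size=(n_boot, len(variants)))
    bx_star[bx_star == 0.0] = np.finfo(float).tiny  # avoid 0/0 in degenerate draws
    r_star = by_star / bx_star
    w_star = (bx_star / se_by) ** 2

    order = np.argsort(r_star, axis=1)
    r_sorted = np.take_along_axis(r_star, order, axis=1)
    w_sorted = np.take_along_axis(w_star, order, axis=1)
    w_norm = w_sorted / w_sorted.sum(axis=1, keepdims=True)
    s = np.cumsum(w_norm, axis=1) - w_norm / 2.0
    boots = np.array(
        [np.interp(0.5, s[b], r_sorted[b]) for b in range(n_boot)]
    )
    se = float(boots.std(ddof=1)) if n_boot > 1 else float("nan")

    return MrResult(
        method="weighted_median",
        theta=theta,
        se=se,
        pvalue=p_from_z(theta, se) if se > 0 else float("nan"),
        n_snp=len(variants),
    )


def leave_one_out(variants, model: str = "fixed") -> dict[str, MrResult]:
    """IVW on each n−1 subset, keyed by the excluded rsid."""
    if len(variants) < 2:
        raise AnalysisError("leave-one-out needs at least 2 variants")
    out = {}
    for i, v in enumerate(variants):
        rest = [u for j, u in enumerate(variants) if j != i]
        out[v.rsid] = ivw(rest, model=model)
    return out
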