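"""Pleiotropy residual-sum-and-outlier (PRESSO-style) resampling tests.

Three stages share one simulated null: a global test comparing the
observed weighted residual sum of squares (RSS) against parametric
simulations under the no-pleiotropy model; a per-SNP outlier test with
Bonferroni adjustment and an outlier-corrected IVW estimate; and a
distortion test for the relative change between the raw and corrected
estimates.  Each SNP's expected outcome effect is taken from the IVW fit
that leaves that SNP out, so a single pleiotropic SNP cannot mask itself.

Empirical p-values use the plus-one convention and are therefore never
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError
from .estimators import MrResult, ivw

__all__ = [
    "PressoState",
    "PressoResult",
    "presso_global",
    "presso_outliers",
    "presso_distortion",
    "run_presso",
]

MIN_VARIANTS = 4  # inner leave-one-out fits must retain >= 3 SNPs
MIN_SIM = 100


def _loo_thetas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW estimate excluding each SNP in turn, vectorized.

    With first-order ratio weights, IVW equals weighted least squares of
    by on bx through the origin with weights w = 1/se_by², so the
    leave-one-out estimates are rank-one downdates of two running sums.
    Works on 1-D arrays or batched 2-D arrays (replicates x SNPs).
    """
    s1 = np.sum(w * bx * by, axis=-1, keepdims=True)
    s2 = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (s1 - w * bx * by) / (s2 - w * bx * bx)


@dataclass
class PressoState:
    """Observed and simulated residuals from the global stage."""

    rsids: list[str]
    rss_observed: float
    p_global: float
    rss_sim: np.ndarray = field(repr=False)
    d_obs_sq: np.ndarray = field(repr=False)
    d_sim_sq: np.ndarray = field(repr=False)  # (n_sim, J)
    n_sim: int = 0


@dataclass
class PressoResult:
    """Outcome of the outlier stage (plus distortion, when computed)."""

    rss_observed: float
    p_global: float
    outlier_pvalues: dict[str, float]
    outliers: list[str]
    beta_raw: MrResult
    beta_corrected: MrResult | None = None
    distortion_pct: float | None = None
    p_distortion: float | None = None


def _arrays(variants):
    bx = np.array([v.bx for v in variants], dtype=float)
    se_bx = np.array([v.se_bx for v in variants], dtype=float)
    by = np.array([v.by for v in variants], dtype=float)
    se_by = np.array([v.se_by for v in variants], dtype=float)
    return bx, se_bx, by, se_by


def presso_global(variants, n_sim: int = 1000, seed: int | None = None) -> PressoState:
    """Global heterogeneity test via parametric simulation of the RSS.

    For each SNP j the expected outcome effect is theta_{−j}·bx_j with
    theta_{−j} the IVW estimate excluding j; the observed statistic is
    RSS = Σ_j (by_j − theta_{−j}·bx_j)²/se_by_j².  Each replicate redraws
    bx*_j ~ N(bx_j, se_bx_j) and by*_j ~ N(theta_{−j}·bx_j, se_by_j) and
    recomputes the RSS identically.  p_global is the plus-one empirical
    tail probability.
    """
    if len(variants) < MIN_VARIANTS:
        raise AnalysisError(
            f"PRESSO needs at least {MIN_VARIANTS} variants "
            f"(got {len(variants)}); the test is undefined for smaller sets"
        )
    if n_sim < MIN_SIM:
        raise AnalysisError(f"n_sim must be >= {MIN_SIM}")
    if seed is None:
        raise AnalysisError("presso_global requires an explicit seed")

    bx, se_bx, by, se_by = _arrays(variants)
    w = se_by**-2.0

    theta_loo = _loo_thetas(bx, by, w)
    d_obs = by - theta_loo * bx
    rss_obs = float(np.sum(w * d_obs**2))

    rng = np.random.default_rng(seed)
    j = len(variants)
    bx_star = rng.normal(bx, se_bx, size=(n_sim, j))
    by_star = rng.normal(theta_loo * bx, se_by, size=(n_sim, j))
    theta_loo_star = _loo_thetas(bx_star, by_star, w)
    d_star = by_star - theta_loo_star * bx_star
    d_star_sq = d_star**2
    rss_star = np.sum(w * d_star_sq, axis=1)

    p_global = (1.0 + float(np.sum(rss_star >= rss_obs))) / (n_sim + 1.0)
    return PressoState(
        rsids=[v.rsid for v in variants],
        rss_observed=rss_obs,
        p_global=p_global,
        rss_sim=rss_star,
        d_obs_sq=d_obs**2,
        d_sim_sq=d_star_sq,
        n_sim=n_sim,
    )


def presso_outliers(
    variants,
    state: PressoState,
    threshold: float = 0.05,
    model: str = "fixed",
) -> PressoResult:
    """Per-SNP outlier test and outlier-corrected IVW estimate.

    Each SNP's raw empirical p compares its observed squared residual
    with its own simulated distribution; Bonferroni multiplication by the
    SNP count (capped at 1) controls the family-wise rate.  SNPs with
    adjusted p below ``threshold`` are outliers; the corrected estimate
    is IVW on the remainder (absent when no outlier is found).
    """
    if [v.rsid for v in variants] != state.rsids:
        raise AnalysisError("variants do not match the global-stage state")
    j = len(variants)
    exceed = np.sum(state.d_sim_sq >= state.d_obs_sq[None, :], axis=0)
    p_raw = (1.0 + exceed) / (state.n_sim + 1.0)
    p_adj = np.minimum(1.0, p_raw * j)
    pvalues = {rsid: float(p) for rsid, p in zip(state.rsids, p_adj)}
    outliers = [rsid for rsid, p in pvalues.items() if p < threshold]

    beta_raw = ivw(variants, model=model)
    beta_corrected = None
    if outliers:
        keep = [v for v in variants if v.rsid not in outliers]
        if not keep:
            raise AnalysisError("every SNP was flagged as an outlier; no corrected estimate")
        beta_corrected = ivw(keep, model=model)

    return PressoResult(
        rss_observed=state.rss_observed,
        p_global=state.p_global,
        outlier_pvalues=pvalues,
        outliers=outliers,
        beta_raw=beta_raw,
        beta_corrected=beta_corrected,
    )


def presso_distortion(
    variants,
    result: PressoResult,
    n_boot: int = 1000,
    seed: int | None = None,
    model: str = "fixed",
) -> PressoResult:
    """Distortion test: is the raw-vs-corrected change larger than chance?

    Observed distortion D = (theta_raw − theta_corrected)/|theta_corrected|
    × 100%.  The null redraws |outliers| pseudo-outlier SNPs uniformly
    with replacement, recomputes D for each draw, and reports the
    two-sided plus-one empirical p.  Returns a copy of ``result`` with the
    distortion fields filled in.
    """
    if not result.outliers:
        raise AnalysisError("distortion test undefined without outliers")
    if seed is None:
        raise AnalysisError("presso_distortion requires an explicit seed")
    theta_raw = result.beta_raw.theta
    theta_corr = result.beta_corrected.theta
    if theta_corr == 0.0:
        raise AnalysisError("corrected estimate is exactly zero; distortion undefined")
    d_obs = (theta_raw - theta_corr) / abs(theta_corr) * 100.0

    rng = np.random.default_rng(seed)
    j = len(variants)
    k = len(result.outliers)
    d_null = np.empty(n_boot)
    for b in range(n_boot):
        pseudo = set(rng.integers(0, j, size=k).tolist())
        keep = [v for i, v in enumerate(variants) if i not in pseudo]
        theta_b = ivw(keep, model=model).theta
        if theta_b == 0.0:
            d_null[b] = np.inf
        else:
            d_null[b] = (theta_raw - theta_b) / abs(theta_b) * 100.0

    p = (1.0 + float(np.sum(np.abs(d_null) >= abs(d_obs)))) / (n_boot + 1.0)
    return PressoResult(
        rss_observed=result.rss_observed,
        p_global=result.p_global,
        outlier_pvalues=result.outlier_pvalues,
        outliers=result.outliers,
        beta_raw=result.beta_raw,
        beta_corrected=result.beta_corrected,
        distortion_pct=d_obs,
        p_distortion=p,
    )


def run_presso(
    variants,
    n_sim: int = 1000,
    threshold: float = 0.05,
    seed: int | None = None,
    n_boot_distortion: int = 1000,
    model: str = "fixed",
) -> PressoResult:
    """Global + outlier (+ distortion when outliers exist) in one call."""
    state = presso_global(variants, n_sim=n_sim, seed=seed)
    result = presso_outliers(variants, state, threshold=threshold, model=model)
    if result.outliers:
        result = presso_distortion(
            variants, result, n_boot=n_boot_distortion, seed=seed, model=model
        )
    return result
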