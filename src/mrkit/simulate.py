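"""Synthetic two-sample GWAS summary statistics with known ground truth.

Generates paired exposure/outcome tables under a linear causal model
by_j = theta·bx_j + alpha_j, where alpha_j is an optional direct
(pleiotropic) effect.  Observed betas add normal sampling noise matching
the emitted SEs.  Allele pairs, palindromic fractions, allele-frequency
noise between samples and random re-expression of outcome rows on the
opposite allele/strand exercise the harmonization layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .harmonize import COMPLEMENT, HarmonizedVariant
from .io import LdMatrix, SnpAssociation, SummaryTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_pair",
    "block_ld_matrix",
    "demo_fixture",
    "displace_outcome",
]

_NON_PALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]

#: sd of the exposure-vs-outcome allele-frequency discrepancy
EAF_NOISE_SD = 0.01


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic two-sample generator.

    ``pleiotropy_mean != 0`` gives directional pleiotropy (violating the
    exclusion restriction); ``pleiotropy_mean == 0`` with positive sd
    gives balanced pleiotropy.
    """

    j_snps: int = 15
    theta: float = 0.0
    bx_mean: float = 0.15
    bx_sd: float = 0.03
    se_bx_scale: float = 0.005
    se_by_scale: float = 0.01
    pleiotropy_prob: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    palindrome_prob: float = 0.0
    flip_prob: float = 0.0
    n_exposure: int = 10000
    n_outcome: int = 50000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("SimulationConfig requires an explicit seed")
        if self.j_snps < 1:
            raise ConfigError("j_snps must be >= 1")
        for name in ("pleiotropy_prob", "palindrome_prob", "flip_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]; got {v}")
        for name in ("bx_sd", "se_bx_scale", "se_by_scale", "pleiotropy_sd"):
            if getattr(self, name) < 0.0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class SimulationTruth:
    """Latent quantities behind one simulated pair."""

    theta: float
    table: pd.DataFrame = field(repr=False)


def _p_two_sided(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_pair(cfg: SimulationConfig):
    """Draw one exposure/outcome table pair plus its truth record.

    Returns ``(exposure, outcome, truth)``.  Deterministic for a fixed
    config (including seed).
    """
    rng = np.random.default_rng(cfg.seed)
    j = cfg.j_snps
    rsids = [f"rs{900000 + i}" for i in range(j)]

    bx_true = rng.normal(cfg.bx_mean, cfg.bx_sd, size=j)
    has_pleio = rng.random(j) < cfg.pleiotropy_prob
    alpha = np.where(
        has_pleio, rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=j), 0.0
    )
    by_true = cfg.theta * bx_true + alpha

    se_bx = cfg.se_bx_scale * rng.uniform(0.8, 1.2, size=j)
    se_by = cfg.se_by_scale * rng.uniform(0.8, 1.2, size=j)
    bx_obs = bx_true + rng.normal(0.0, se_bx)
    by_obs = by_true + rng.normal(0.0, se_by)

    eaf_x = rng.uniform(0.05, 0.95, size=j)
    eaf_y = np.clip(eaf_x + rng.normal(0.0, EAF_NOISE_SD, size=j), 0.01, 0.99)

    p_x = _p_two_sided(bx_obs, se_bx)
    p_y = _p_two_sided(by_obs, se_by)

    palindromic = rng.random(j) < cfg.palindrome_prob
    pair_choice = rng.integers(0, 4, size=j)
    swap_alleles = rng.random(j) < 0.5
    flip = rng.random(j) < cfg.flip_prob
    flip_mode = rng.integers(0, 3, size=j)  # 0 swap, 1 complement, 2 both

    ex_records, out_records, truth_rows = [], [], []
    for i in range(j):
        if palindromic[i]:
            ea, oa = _PALINDROMIC_PAIRS[pair_choice[i] % 2]
        else:
            ea, oa = _NON_PALINDROMIC_PAIRS[pair_choice[i]]
        if swap_alleles[i]:
            ea, oa = oa, ea

        ex_records.append(
            SnpAssociation(
                rsid=rsids[i], effect_allele=ea, other_allele=oa,
                eaf=float(eaf_x[i]), beta=float(bx_obs[i]), se=float(se_bx[i]),
                pvalue=float(p_x[i]), n=cfg.n_exposure,
                trait_id="sim_exposure",
            )
        )

        o_ea, o_oa, o_beta, o_eaf = ea, oa, float(by_obs[i]), float(eaf_y[i])
        mode = "none"
        if flip[i]:
            if palindromic[i] or flip_mode[i] == 0:  # allele swap
                o_ea, o_oa = o_oa, o_ea
                o_beta, o_eaf = -o_beta, 1.0 - o_eaf
                mode = "swap"
            elif flip_mode[i] == 1:  # strand complement only
                o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
                mode = "complement"
            else:  # complement + swap
                o_ea, o_oa = COMPLEMENT[o_oa], COMPLEMENT[o_ea]
                o_beta, o_eaf = -o_beta, 1.0 - o_eaf
                mode = "complement_swap"
        out_records.append(
            SnpAssociation(
                rsid=rsids[i], effect_allele=o_ea, other_allele=o_oa,
                eaf=o_eaf, beta=o_beta, se=float(se_by[i]),
                pvalue=float(p_y[i]), n=cfg.n_outcome,
                trait_id="sim_outcome",
            )
        )
        truth_rows.append(
            {
                "rsid": rsids[i], "bx_true": bx_true[i], "alpha": alpha[i],
                "by_true": by_true[i], "palindromic": bool(palindromic[i]),
                "flip_mode": mode,
            }
        )

    exposure = SummaryTable(records=ex_records, trait_id="sim_exposure")
    outcome = SummaryTable(records=out_records, trait_id="sim_outcome")
    truth = SimulationTruth(theta=cfg.theta, table=pd.DataFrame(truth_rows))
    return exposure, outcome, truth


def block_ld_matrix(rsids, block_size: int, r2_within: float = 0.5) -> LdMatrix:
    """Block-diagonal LD structure: constant r² inside consecutive blocks,
    zero between blocks.  Exercises greedy clumping deterministically."""
    if not (0.0 <= r2_within <= 1.0):
        raise ConfigError("r2_within must lie in [0, 1]")
    k = len(rsids)
    m = np.zeros((k, k))
    for start in range(0, k, block_size):
        stop = min(start + block_size, k)
        m[start:stop, start:stop] = r2_within
    np.fill_diagonal(m, 1.0)
    return LdMatrix(rsids=list(rsids), r2=m)


# Demo instrument panels.  The rsid lists mirror published uromodulin
# instruments, but every beta/SE/EAF below is SYNTHETIC, generated from a
# fixed seed purely for pipeline smoke tests.
_URINARY_RSIDS = ["rs12917707", "rs4494548"]
_SERUM_RSIDS = [
    "rs12708631", "rs12917707", "rs12930599", "rs7192921", "rs4293393",
    "rs6497476", "rs11864909", "rs13329952", "rs34882080", "rs77924615",
    "rs9928757", "rs164748", "rs4997081", "rs41298212", "rs7203642",
]


def demo_fixture(panel: str):
    """Bundled SYNTHETIC exposure/outcome pair shaped like the published
    uromodulin instrument panels.

    ``panel='urinary'`` gives a 2-instrument pair (IVW-only routing);
    ``panel='serum'`` gives a 15-instrument pair (all methods + PRESSO).
    Values are generated, not measured; trait ids carry a SYNTHETIC tag.
    """
    if panel == "urinary":
        rsids, seed, n_exp = _URINARY_RSIDS, 20210901, 10884
    elif panel == "serum":
        rsids, seed, n_exp = _SERUM_RSIDS, 20210902, 4147
    else:
        raise ConfigError(f"unknown panel {panel!r}; use 'urinary' or 'serum'")

    cfg = SimulationConfig(
        j_snps=len(rsids), theta=0.03, bx_mean=0.3, bx_sd=0.1,
        se_bx_scale=0.01, se_by_scale=0.003, palindrome_prob=0.0,
        flip_prob=0.3, n_exposure=n_exp, n_outcome=46188, seed=seed,
    )
    exposure, outcome, _ = simulate_pair(cfg)
    ex_records = [
        SnpAssociation(
            rsid=rsid, effect_allele=r.effect_allele, other_allele=r.other_allele,
            eaf=r.eaf, beta=r.beta, se=r.se, pvalue=r.pvalue, n=r.n,
            trait_id=f"{panel}_umod_SYNTHETIC",
        )
        for rsid, r in zip(rsids, exposure.records)
    ]
    out_records = [
        SnpAssociation(
            rsid=rsid, effect_allele=r.effect_allele, other_allele=r.other_allele,
            eaf=r.eaf, beta=r.beta, se=r.se, pvalue=r.pvalue, n=r.n,
            trait_id="outcome_SYNTHETIC",
        )
        for rsid, r in zip(rsids, outcome.records)
    ]
    return (
        SummaryTable(records=ex_records, trait_id=f"{panel}_umod_SYNTHETIC"),
        SummaryTable(records=out_records, trait_id="outcome_SYNTHETIC"),
    )


def displace_outcome(variants, index: int, shift_in_se: float):
    """Copy of ``variants`` with one SNP's outcome beta displaced by
    ``shift_in_se`` outcome SEs — an injected outlier for PRESSO tests."""
    out = list(variants)
    v = out[index]
    out[index] = HarmonizedVariant(
        rsid=v.rsid, effect_allele=v.effect_allele, other_allele=v.other_allele,
        bx=v.bx, se_bx=v.se_bx, by=v.by + shift_in_se * v.se_by, se_by=v.se_by,
        eaf_exposure=v.eaf_exposure, eaf_outcome=v.eaf_outcome, status=v.status,
    )
    return out
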