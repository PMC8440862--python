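"""Instrument selection and strength diagnostics.

Selection applies, in order: a genome-wide significance filter
(p <= 5e-8 by default), a minor-allele-frequency floor (MAF > 0.01) and
greedy LD clumping at r² < 0.1.  Strength is quantified per SNP by the
variance explained R² = 2·MAF·(1−MAF)·β² and the F statistic
F = ((n−k−1)/k) · R²/(1−R²); F <= 10 flags a weak instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import AnalysisError, ConfigError, DataError
from .io import LdMatrix, SummaryTable

__all__ = [
    "SelectionConfig",
    "InstrumentStats",
    "select_instruments",
    "variance_explained",
    "f_statistic",
    "combined_f",
    "instrument_strength",
]

WEAK_F_THRESHOLD = 10.0


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for instrument selection."""

    p_threshold: float = 5e-8
    maf_min: float = 0.01
    ld_r2_max: float = 0.1

    def __post_init__(self) -> None:
        for name in ("p_threshold", "maf_min", "ld_r2_max"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1); got {v}")


@dataclass(frozen=True)
class InstrumentStats:
    """Per-instrument strength summary."""

    rsid: str
    r2: float
    f_stat: float
    n: int
    k: int = 1

    @property
    def weak(self) -> bool:
        return self.f_stat <= WEAK_F_THRESHOLD


@dataclass
class SelectionResult:
    table: SummaryTable
    log: pd.DataFrame = field(repr=False, default=None)


def variance_explained(eaf: float, beta: float) -> float:
    """Exposure variance explained by one SNP: 2·m·(1−m)·β² with m = MAF.

    The minor-allele frequency m = min(eaf, 1−eaf) is used regardless of
    which allele is the effect allele.  Raises when the result reaches 1,
    which indicates a non-standardized beta.
    """
    if not (0.0 < eaf < 1.0):
        raise DataError(f"eaf {eaf} outside (0, 1)")
    m = min(eaf, 1.0 - eaf)
    r2 = 2.0 * m * (1.0 - m) * beta * beta
    if r2 >= 1.0:
        raise DataError(
            f"variance explained {r2:.3g} >= 1; beta does not look standardized"
        )
    return r2


def f_statistic(n: int, k: int, r2: float) -> float:
    """Instrument-strength F statistic, ((n−k−1)/k) · r²/(1−r²)."""
    if n <= k + 1:
        raise DataError(f"sample size n={n} must exceed k+1={k + 1}")
    if not (0.0 <= r2 < 1.0):
        raise DataError(f"r2 {r2} outside [0, 1)")
    return (n - k - 1) / k * r2 / (1.0 - r2)


def combined_f(stats_list) -> float:
    """Unweighted arithmetic mean of per-SNP F statistics."""
    values = [s.f_stat for s in stats_list]
    if not values:
        raise AnalysisError("combined F undefined for an empty instrument set")
    return sum(values) / len(values)


def instrument_strength(table: SummaryTable, k: int = 1) -> list[InstrumentStats]:
    """Per-SNP R² and F for every record of an exposure table (k = 1 each)."""
    out = []
    for rec in table:
        if rec.eaf is None:
            raise DataError(f"{rec.rsid}: eaf required to compute variance explained")
        r2 = variance_explained(rec.eaf, rec.beta)
        out.append(
            InstrumentStats(rsid=rec.rsid, r2=r2, f_stat=f_statistic(rec.n, k, r2), n=rec.n, k=k)
        )
    return out


def select_instruments(
    table: SummaryTable,
    ld: LdMatrix | None = None,
    cfg: SelectionConfig | None = None,
    assume_independent: bool = False,
) -> SelectionResult:
    """Filter an exposure table down to valid, mutually independent instruments.

    Marginal filters keep SNPs with ``pvalue <= cfg.p_threshold`` and
    ``min(eaf, 1−eaf) > cfg.maf_min``.  Survivors are then LD-clumped
    greedily: sort by ascending p-value (rsid lexicographic tie-break),
    keep the best, drop every later SNP with r² >= ``cfg.ld_r2_max`` to
    any kept SNP, repeat.  Output preserves the input row order of the
    kept SNPs.

    With more than one marginal survivor an LD matrix is required unless
    ``assume_independent`` is set explicitly.

    Returns
    -------
    SelectionResult
        ``.table`` with the retained records and ``.log`` — one row per
        input SNP with ``status`` in {kept, dropped_p, dropped_maf,
        dropped_ld} and a human-readable ``detail``.
    """
    cfg = cfg or SelectionConfig()
    status: dict[str, tuple[str, str]] = {}
    survivors = []
    for rec in table:
        if rec.pvalue > cfg.p_threshold:
            status[rec.rsid] = ("dropped_p", f"p={rec.pvalue:.3g} > {cfg.p_threshold:g}")
            continue
        if rec.eaf is None or rec.maf <= cfg.maf_min:
            maf = "missing" if rec.eaf is None else f"{rec.maf:.4g}"
            status[rec.rsid] = ("dropped_maf", f"maf={maf} <= {cfg.maf_min:g}")
            continue
        survivors.append(rec)

    if len(survivors) > 1 and ld is None and not assume_independent:
        raise ConfigError(
            f"{len(survivors)} SNPs pass marginal filters but no LD matrix was "
            "given; pass assume_independent=True to skip clumping"
        )
    if ld is not None and not ld.covers([r.rsid for r in survivors]):
        missing = [r.rsid for r in survivors if not ld.covers([r.rsid])]
        raise DataError(f"LD matrix does not cover filtered SNP(s): {missing}")

    kept_rsids: list[str] = []
    if ld is None or len(survivors) <= 1:
        kept_rsids = [r.rsid for r in survivors]
        for rsid in kept_rsids:
            status[rsid] = ("kept", "")
    else:
        # greedy clumping: best p first, deterministic rsid tie-break
        queue = sorted(survivors, key=lambda r: (r.pvalue, r.rsid))
        while queue:
            best = queue.pop(0)
            kept_rsids.append(best.rsid)
            status[best.rsid] = ("kept", "")
            remaining = []
            for rec in queue:
                r2 = ld.lookup(best.rsid, rec.rsid)
                if r2 >= cfg.ld_r2_max:
                    status[rec.rsid] = (
                        "dropped_ld",
                        f"r2={r2:.3g} to {best.rsid} >= {cfg.ld_r2_max:g}",
                    )
                else:
                    remaining.append(rec)
            queue = remaining

    log = pd.DataFrame(
        {
            "rsid": [rec.rsid for rec in table],
            "status": [status[rec.rsid][0] for rec in table],
            "detail": [status[rec.rsid][1] for rec in table],
        }
    )
    return SelectionResult(table=table.subset(kept_rsids), log=log)
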