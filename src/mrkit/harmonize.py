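"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR requires both tables to express each SNP's effect on the
same effect allele.  For every rsid shared between the tables the outcome
record is rewritten onto the exposure's allele pair, resolving allele
swaps (negate beta, complement EAF), strand mismatches (complement the
outcome alleles first) and palindromic A/T or C/G pairs, where strand is
inferable only from allele frequency: if either EAF sits within a window
around 0.5 the SNP is dropped as ambiguous, otherwise the orientation
that puts both EAFs on the same side of 0.5 is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .errors import AnalysisError, DataError
from .io import SummaryTable

__all__ = ["HarmonizedVariant", "HarmonizeResult", "harmonize", "COMPLEMENT"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

RETAINED_STATUSES = frozenset({"aligned", "flipped", "strand_corrected"})
DROPPED_STATUSES = frozenset({"dropped_palindromic", "dropped_incompatible"})


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G pairs are their own reverse complement."""
    return COMPLEMENT[a1] == a2


@dataclass(frozen=True)
class HarmonizedVariant:
    """A SNP with exposure and outcome effects on a shared effect allele."""

    rsid: str
    effect_allele: str
    other_allele: str
    bx: float
    se_bx: float
    by: float
    se_by: float
    eaf_exposure: float | None
    eaf_outcome: float | None
    status: str = "aligned"

    def __post_init__(self) -> None:
        if self.status in RETAINED_STATUSES:
            if not (self.se_bx > 0 and self.se_by > 0):
                raise DataError(f"{self.rsid}: harmonized SEs must be positive")

    @property
    def retained(self) -> bool:
        return self.status in RETAINED_STATUSES

    def flip_signs(self) -> "HarmonizedVariant":
        """Joint sign flip of (bx, by); estimators must be invariant to this."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            bx=-self.bx,
            by=-self.by,
            eaf_exposure=None if self.eaf_exposure is None else 1.0 - self.eaf_exposure,
            eaf_outcome=None if self.eaf_outcome is None else 1.0 - self.eaf_outcome,
        )


@dataclass
class HarmonizeResult:
    """Retained variants plus a per-rsid log covering the full intersection."""

    variants: list[HarmonizedVariant]
    log: pd.DataFrame

    def __len__(self) -> int:
        return len(self.variants)


def _ambiguous(eaf: float | None, window: float) -> bool:
    # inclusive boundary, robust to float representation of the window edge
    return eaf is None or abs(eaf - 0.5) <= window + 1e-12


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizeResult:
    """Harmonize outcome effects onto the exposure's effect alleles.

    Parameters
    ----------
    exposure, outcome : SummaryTable
        Must share at least one rsid.
    palindrome_eaf_window : float
        Half-width of the ambiguity window around EAF 0.5 inside which a
        palindromic SNP is dropped as not inferable (default 0.08, i.e.
        drop when either EAF lies in [0.42, 0.58]).

    Returns
    -------
    HarmonizeResult
        Retained variants (statuses aligned / flipped / strand_corrected)
        and a log whose statuses partition the rsid intersection.
    """
    shared = [r for r in exposure.rsids if outcome.get(r) is not None]
    if not shared:
        raise AnalysisError("exposure and outcome tables share no rsids")

    variants: list[HarmonizedVariant] = []
    rows = []
    for rsid in shared:
        ex = exposure.get(rsid)
        out = outcome.get(rsid)
        v, detail = _harmonize_one(ex, out, palindrome_eaf_window)
        rows.append({"rsid": rsid, "status": v.status, "detail": detail})
        if v.retained:
            variants.append(v)
    return HarmonizeResult(variants=variants, log=pd.DataFrame(rows))


def _harmonize_one(ex, out, window: float):
    """Harmonize a single shared rsid; returns (variant, log detail)."""
    base = dict(
        rsid=ex.rsid,
        effect_allele=ex.effect_allele,
        other_allele=ex.other_allele,
        bx=ex.beta,
        se_bx=ex.se,
        eaf_exposure=ex.eaf,
    )
    ex_set = {ex.effect_allele, ex.other_allele}
    out_ea, out_oa = out.effect_allele, out.other_allele
    by, eaf_out = out.beta, out.eaf

    if is_palindromic(ex.effect_allele, ex.other_allele):
        if {out_ea, out_oa} != ex_set:
            return (
                HarmonizedVariant(
                    **base, by=by, se_by=out.se, eaf_outcome=eaf_out,
                    status="dropped_incompatible",
                ),
                f"outcome alleles {out_ea}/{out_oa} do not match palindromic pair",
            )
        if _ambiguous(ex.eaf, window) or _ambiguous(eaf_out, window):
            return (
                HarmonizedVariant(
                    **base, by=by, se_by=out.se, eaf_outcome=eaf_out,
                    status="dropped_palindromic",
                ),
                "palindromic with intermediate or missing allele frequency",
            )
        # express the outcome on the exposure's effect allele letter first
        changed = False
        if out_ea != ex.effect_allele:
            by, eaf_out, changed = -by, 1.0 - eaf_out, True
        # strand is unknowable from letters: trust EAF concordance
        if (ex.eaf < 0.5) != (eaf_out < 0.5):
            by, eaf_out, changed = -by, 1.0 - eaf_out, True
        status = "strand_corrected" if changed else "aligned"
        return (
            HarmonizedVariant(
                **base, by=by, se_by=out.se, eaf_outcome=eaf_out, status=status
            ),
            "palindromic, oriented by allele-frequency concordance",
        )

    # non-palindromic
    if {out_ea, out_oa} == ex_set:
        if out_ea == ex.effect_allele:
            return (
                HarmonizedVariant(
                    **base, by=by, se_by=out.se, eaf_outcome=eaf_out, status="aligned"
                ),
                "",
            )
        return (
            HarmonizedVariant(
                **base,
                by=-by,
                se_by=out.se,
                eaf_outcome=None if eaf_out is None else 1.0 - eaf_out,
                status="flipped",
            ),
            "outcome effect allele swapped",
        )

    comp_set = {COMPLEMENT[out_ea], COMPLEMENT[out_oa]}
    if comp_set == ex_set:
        out_ea_c = COMPLEMENT[out_ea]
        if out_ea_c == ex.effect_allele:
            return (
                HarmonizedVariant(
                    **base, by=by, se_by=out.se, eaf_outcome=eaf_out,
                    status="strand_corrected",
                ),
                "outcome alleles complemented to exposure strand",
            )
        return (
            HarmonizedVariant(
                **base,
                by=-by,
                se_by=out.se,
                eaf_outcome=None if eaf_out is None else 1.0 - eaf_out,
                status="strand_corrected",
            ),
            "outcome alleles complemented and swapped",
        )

    return (
        HarmonizedVariant(
            **base, by=by, se_by=out.se, eaf_outcome=eaf_out,
            status="dropped_incompatible",
        ),
        f"allele sets {{{ex.effect_allele},{ex.other_allele}}} vs "
        f"{{{out_ea},{out_oa}}} irreconcilable",
    )
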