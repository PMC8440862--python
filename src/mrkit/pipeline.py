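"""End-to-end orchestration: select → harmonize → estimate → diagnose → report.

Method routing follows the instrument count after harmonization: fewer
than 3 instruments gives IVW (plus per-SNP Wald ratios) only; 3 or more
adds MR-Egger and the weighted median; 4 or more additionally runs the
PRESSO outlier framework.  All outputs are TSV plus one YAML manifest
capturing the full configuration and seeds, so any run can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import AnalysisError
from .estimators import (
    ivw,
    leave_one_out,
    mr_egger,
    or_from_beta,
    wald_ratio,
    weighted_median,
)
from .harmonize import HarmonizeResult, harmonize
from .instruments import SelectionConfig, instrument_strength, select_instruments
from .io import read_ld_matrix, read_summary_table
from .presso import MIN_VARIANTS as PRESSO_MIN
from .presso import run_presso

__all__ = ["AnalysisConfig", "ReportBundle", "run_analysis", "analyze", "render_diagnostic_data"]


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one exposure→outcome analysis."""

    exposure_path: str = ""
    outcome_path: str = ""
    ld_path: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    assume_independent: bool = False
    palindrome_eaf_window: float = 0.08
    ivw_model: str = "auto"
    egger_min_snps: int = 3
    presso_n_sim: int = 1000
    presso_threshold: float = 0.05
    presso_seed: int = 1
    wm_n_boot: int = 1000
    wm_seed: int = 1
    confidence_level: float = 0.95
    binary_outcome: bool = False
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["selection"] = dataclasses.asdict(self.selection)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "selection" in d and isinstance(d["selection"], dict):
            d["selection"] = SelectionConfig(**d["selection"])
        return cls(**d)


@dataclass
class ReportBundle:
    """All tables produced by one run."""

    selection_log: pd.DataFrame
    harmonization: HarmonizeResult
    strength: pd.DataFrame
    results: pd.DataFrame
    loo: pd.DataFrame | None
    presso: pd.DataFrame | None
    diagnostics: dict[str, pd.DataFrame]
    manifest: dict


def _result_row(res, trait, dataset, cfg):
    row = {
        "trait": trait,
        "dataset": dataset,
        "method": res.method,
        "n_snp": res.n_snp,
        "beta": res.theta,
        "se": res.se,
        "pvalue": res.pvalue,
        "egger_intercept": res.intercept,
        "egger_intercept_se": res.se_intercept,
        "egger_intercept_p": res.p_intercept,
        "q": res.q,
        "q_df": res.q_df,
        "q_pvalue": res.q_pvalue,
    }
    if cfg.binary_outcome:
        orr = or_from_beta(res.theta, res.se, level=cfg.confidence_level)
        row.update(
            {"or": orr.or_point, "or_ci_low": orr.ci_low, "or_ci_high": orr.ci_high}
        )
    return row


def analyze(exposure, outcome, ld=None, cfg: AnalysisConfig | None = None) -> ReportBundle:
    """Run the full analysis on in-memory tables.  See :func:`run_analysis`
    for the file-based entry point."""
    cfg = cfg or AnalysisConfig()
    selection = select_instruments(
        exposure, ld=ld, cfg=cfg.selection, assume_independent=cfg.assume_independent
    )
    if len(selection.table) == 0:
        raise AnalysisError("no instruments survived selection; see the selection log")

    try:
        strength_rows = [
            {"rsid": s.rsid, "r2": s.r2, "f_stat": s.f_stat, "weak": s.weak}
            for s in instrument_strength(selection.table)
        ]
        if strength_rows:
            mean_f = float(np.mean([r["f_stat"] for r in strength_rows]))
            strength_rows.append(
                {"rsid": "__combined__", "r2": np.nan, "f_stat": mean_f, "weak": mean_f <= 10}
            )
        strength = pd.DataFrame(strength_rows)
    except Exception:  # eaf missing: strength is advisory, not blocking
        strength = pd.DataFrame(columns=["rsid", "r2", "f_stat", "weak"])

    harm = harmonize(
        selection.table, outcome, palindrome_eaf_window=cfg.palindrome_eaf_window
    )
    variants = harm.variants
    n = len(variants)
    if n == 0:
        raise AnalysisError("no instruments survived harmonization; see the log")

    trait, dataset = exposure.trait_id, outcome.trait_id
    rows = []
    for v in variants:
        ratio = wald_ratio(v)
        rows.append(
            {
                "trait": trait, "dataset": dataset, "method": "wald",
                "n_snp": 1, "rsid": v.rsid, "beta": ratio.ratio,
                "se": ratio.se_ratio, "pvalue": None,
            }
        )

    ivw_res = ivw(variants, model=cfg.ivw_model)
    rows.append(_result_row(ivw_res, trait, dataset, cfg))

    loo_df = None
    presso_df = None
    if n >= 2:
        loo = leave_one_out(variants, model=cfg.ivw_model)
        loo_df = pd.DataFrame(
            [
                {"excluded_rsid": rsid, "beta": r.theta, "se": r.se, "pvalue": r.pvalue}
                for rsid, r in loo.items()
            ]
        )
    if n >= cfg.egger_min_snps:
        rows.append(_result_row(mr_egger(variants), trait, dataset, cfg))
        rows.append(
            _result_row(
                weighted_median(variants, n_boot=cfg.wm_n_boot, seed=cfg.wm_seed),
                trait, dataset, cfg,
            )
        )
    if n >= PRESSO_MIN:
        pres = run_presso(
            variants,
            n_sim=cfg.presso_n_sim,
            threshold=cfg.presso_threshold,
            seed=cfg.presso_seed,
        )
        presso_df = pd.DataFrame(
            [
                {
                    "dataset": dataset,
                    "rss_observed": pres.rss_observed,
                    "p_global": pres.p_global,
                    "outliers": ",".join(pres.outliers) if pres.outliers else "NA",
                    "corrected_beta": (
                        pres.beta_corrected.theta if pres.beta_corrected else "NA"
                    ),
                    "corrected_pvalue": (
                        pres.beta_corrected.pvalue if pres.beta_corrected else "NA"
                    ),
                    "p_distortion": (
                        pres.p_distortion if pres.p_distortion is not None else "NA"
                    ),
                }
            ]
        )

    results = pd.DataFrame(rows)
    method_results = {
        r["method"]: r for r in rows if r["method"] != "wald"
    }
    diagnostics = render_diagnostic_data(variants, method_results, loo_df, cfg)

    cfg_dict = cfg.to_dict()
    cfg_dict.pop("out_dir", None)  # output location is not part of the analysis
    manifest = {
        "mrkit_version": __version__,
        "config": cfg_dict,
        "n_selected": len(selection.table),
        "n_harmonized": n,
        "exposure_trait": trait,
        "outcome_dataset": dataset,
    }
    return ReportBundle(
        selection_log=selection.log,
        harmonization=harm,
        strength=strength,
        results=results,
        loo=loo_df,
        presso=presso_df,
        diagnostics=diagnostics,
        manifest=manifest,
    )


def render_diagnostic_data(variants, method_results, loo_df, cfg) -> dict[str, pd.DataFrame]:
    """Plot-ready tables: scatter (per-SNP effects + fitted lines), forest
    (per-SNP Wald ratios with CIs + pooled rows), leave-one-out."""
    from scipy import stats as _st

    z = _st.norm.ppf(0.5 + cfg.confidence_level / 2.0)
    scatter = pd.DataFrame(
        [
            {"rsid": v.rsid, "bx": v.bx, "se_bx": v.se_bx, "by": v.by, "se_by": v.se_by}
            for v in variants
        ]
    )
    for method, row in method_results.items():
        scatter[f"slope_{method}"] = row["beta"]
        scatter[f"intercept_{method}"] = row.get("egger_intercept") or 0.0

    forest_rows = []
    for v in variants:
        r = wald_ratio(v)
        forest_rows.append(
            {
                "label": v.rsid, "kind": "snp", "beta": r.ratio,
                "ci_low": r.ratio - z * r.se_ratio, "ci_high": r.ratio + z * r.se_ratio,
            }
        )
    for method, row in method_results.items():
        forest_rows.append(
            {
                "label": method, "kind": "pooled", "beta": row["beta"],
                "ci_low": row["beta"] - z * row["se"],
                "ci_high": row["beta"] + z * row["se"],
            }
        )
    out = {"scatter": scatter, "forest": pd.DataFrame(forest_rows)}
    if loo_df is not None:
        out["loo"] = loo_df
    return out


def run_analysis(cfg: AnalysisConfig) -> ReportBundle:
    """File-based entry point: read inputs, analyze, write the report bundle."""
    exposure = read_summary_table(
        cfg.exposure_path, trait_id=Path(cfg.exposure_path).stem
    )
    outcome = read_summary_table(cfg.outcome_path, trait_id=Path(cfg.outcome_path).stem)
    ld = read_ld_matrix(cfg.ld_path) if cfg.ld_path else None
    try:
        bundle = analyze(exposure, outcome, ld=ld, cfg=cfg)
    except AnalysisError as exc:
        raise AnalysisError(f"analysis of {cfg.outcome_path} failed: {exc}") from exc
    if cfg.out_dir:
        write_bundle(bundle, cfg.out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", index=False, float_format="%.10g")
    bundle.selection_log.to_csv(out / "selection_log.tsv", **fmt)
    bundle.harmonization.log.to_csv(out / "harmonization_log.tsv", **fmt)
    bundle.strength.to_csv(out / "f_statistics.tsv", **fmt)
    bundle.results.to_csv(out / "results.tsv", **fmt)
    if bundle.presso is not None:
        bundle.presso.to_csv(out / "presso.tsv", **fmt)
    for name, df in bundle.diagnostics.items():
        df.to_csv(out / f"{name}.tsv", **fmt)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(bundle.manifest, fh, sort_keys=True)
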