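"""Panel-level screening: per-pair pipeline, BH FDR, report tables.

A screen runs the full pipeline for every exposure/outcome pair
(select instruments -> clump -> harmonize -> strength filter ->
estimators -> diagnostics) and then applies Benjamini-Hochberg
step-up FDR control to the primary (IVW) p-values, with the family
size fixed at the full panel size: traits that yield no usable
instrument still contribute p = 1 rather than shrinking the family.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import diagnostics, estimators, gwas_io, instruments
from .diagnostics import PressoResult
from .errors import ConfigurationError
from .estimators import EggerIntercept, MrEstimate, QResult

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "bh_adjust",
    "run_screen",
    "run_reverse_screen",
    "render_report",
]


def bh_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the family size; when it exceeds the number of supplied
    p-values, the supplied values are treated as the smallest
    ``len(pvals)`` members of the family (ranks 1..len).  The raw
    adjusted value at rank i is p_i * m / i, made monotone by a
    step-up pass from the largest supplied rank downward, and capped
    at 1.  Values are returned in the input order, unrounded.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ConfigurationError("bh_adjust expects a non-empty 1-d array of p-values")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ConfigurationError("p-values must lie in (0, 1]")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ConfigurationError(f"family size m={m} smaller than number of p-values {k}")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, k + 1)
    raw = p[order] * m / ranks
    adj_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(k)
    adj[order] = adj_sorted
    return adj


class ScreenConfig(BaseModel):
    """All thresholds and seeds of a screen; defaults follow the
    analysis conventions the package implements (suggestive p < 1e-5,
    clump r^2 < 0.001 within 10,000 kb, F > 10, Q-switch and outlier
    alpha 0.05, 1000 bootstrap and simulation replicates)."""

    p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    f_min: float = 10.0
    ambiguity_band: float = 0.08
    q_alpha: float = 0.05
    outlier_alpha: float = 0.05
    n_boot: int = 1000
    n_sim: int = 1000
    family_size: int | None = None  # None -> panel size
    seed: int = 0
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median")
    sensitivity: bool = True

    def lines(self) -> list[str]:
        return [f"{k} = {v}" for k, v in sorted(self.model_dump().items())]


@dataclass
class ScreenResult:
    """Everything computed for one exposure/outcome pair."""

    direction: str
    exposure: str
    outcome: str
    n_snps: int
    estimates: dict[str, MrEstimate] = field(default_factory=dict)
    q_ivw: QResult | None = None
    q_egger: QResult | None = None
    egger_intercept: EggerIntercept | None = None
    presso: PressoResult | None = None
    loo: pd.DataFrame | None = None
    pval_ivw: float = 1.0
    pval_fdr: float | None = None
    outcome_binary: bool = True
    seed: int = 0


def _pair_seed(master_seed: int, exposure: str, outcome: str) -> int:
    """Stable per-pair seed, independent of panel ordering."""
    digest = hashlib.sha256(f"{master_seed}:{exposure}:{outcome}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def _analyse_pair(
    exposure_name: str,
    exposure_stats: pd.DataFrame,
    outcome_name: str,
    outcome_stats: pd.DataFrame,
    config: ScreenConfig,
    direction: str,
    outcome_binary: bool,
    ld: instruments.LdMatrix | None = None,
) -> ScreenResult:
    seed = _pair_seed(config.seed, exposure_name, outcome_name)
    scale = "log-OR" if outcome_binary else "per 1 SD exposure"
    result = ScreenResult(
        direction=direction,
        exposure=exposure_name,
        outcome=outcome_name,
        n_snps=0,
        outcome_binary=outcome_binary,
        seed=seed,
    )

    iv = instruments.select_by_pvalue(exposure_stats, config.p_threshold)
    if iv.empty:
        logger.warning("%s -> %s: no SNP passes p < %g", exposure_name, outcome_name,
                       config.p_threshold)
        return result
    iv = instruments.clump(iv, ld=ld, r2_threshold=config.clump_r2, window_kb=config.clump_kb)
    harmonized = gwas_io.harmonize(iv, outcome_stats, ambiguity_band=config.ambiguity_band)
    kept = gwas_io.kept_instruments(harmonized)
    if kept.empty:
        logger.warning("%s -> %s: no instrument survives harmonization",
                       exposure_name, outcome_name)
        return result

    # weak-instrument filter on the exposure associations
    strength = instruments.instrument_strength(
        kept.rename(
            columns={"exposure_eaf": "eaf", "exposure_beta": "beta", "exposure_n": "n"}
        )[["snp_id", "eaf", "beta", "n"]]
    )
    strong_ids = set(strength.loc[strength["f_stat"] > config.f_min, "snp_id"])
    kept = kept[kept["snp_id"].isin(strong_ids)].reset_index(drop=True)
    j = len(kept)
    result.n_snps = j
    if j == 0:
        logger.warning("%s -> %s: all instruments weak (F <= %g)",
                       exposure_name, outcome_name, config.f_min)
        return result

    ivw_est, q_ivw = estimators.ivw(kept, mode="auto", q_alpha=config.q_alpha, scale=scale)
    result.estimates["ivw"] = ivw_est
    result.q_ivw = q_ivw
    result.pval_ivw = float(ivw_est.pval) if np.isfinite(ivw_est.pval) else 1.0

    if "egger" in config.methods and j >= 3:
        slope, intercept = estimators.egger(kept, scale=scale)
        result.estimates["egger"] = slope
        result.egger_intercept = intercept
        result.q_egger = diagnostics.cochran_q(
            kept, slope.beta, model="egger", intercept=intercept.estimate
        )
    if "weighted_median" in config.methods and j >= 3:
        result.estimates["weighted_median"] = estimators.weighted_median(
            kept, n_boot=config.n_boot, seed=seed, scale=scale
        )
    if config.sensitivity:
        if j >= 3:
            result.loo = diagnostics.leave_one_out(kept, q_alpha=config.q_alpha)
        if j >= 4:
            result.presso = diagnostics.presso(
                kept,
                n_sim=config.n_sim,
                seed=seed + 1,
                outlier_alpha=config.outlier_alpha,
            )
    return result


def _apply_fdr(results: list[ScreenResult], config: ScreenConfig, panel_size: int) -> None:
    m = config.family_size if config.family_size is not None else panel_size
    if m < panel_size:
        raise ConfigurationError(
            f"family_size {m} smaller than the panel ({panel_size} traits)"
        )
    pvals = np.array([r.pval_ivw for r in results])
    adj = bh_adjust(pvals, m=m)
    for r, a in zip(results, adj):
        r.pval_fdr = float(a)


def run_screen(
    panel: dict[str, pd.DataFrame],
    outcome_name: str,
    outcome_stats: pd.DataFrame,
    config: ScreenConfig,
    direction: str = "forward",
    outcome_binary: bool = True,
    ld: instruments.LdMatrix | None = None,
) -> list[ScreenResult]:
    """Screen a panel of exposure traits against one outcome GWAS.

    Returns one :class:`ScreenResult` per trait, in sorted trait order
    (so the output is invariant to the panel's input ordering), with
    BH-adjusted IVW p-values over the full panel family.
    """
    if not panel:
        raise ConfigurationError("exposure panel is empty")
    results = [
        _analyse_pair(name, stats, outcome_name, outcome_stats, config,
                      direction, outcome_binary, ld=ld)
        for name, stats in sorted(panel.items())
    ]
    _apply_fdr(results, config, len(panel))
    return results


def run_reverse_screen(
    exposure_name: str,
    exposure_stats: pd.DataFrame,
    panel: dict[str, pd.DataFrame],
    config: ScreenConfig,
    direction: str = "reverse",
    ld: instruments.LdMatrix | None = None,
) -> list[ScreenResult]:
    """Screen one disease exposure against a panel of cytokine outcomes.

    The mirror image of :func:`run_screen`: the disease GWAS provides
    the instruments and every panel trait serves as a continuous
    outcome in turn; BH control again runs over the panel family.
    """
    if not panel:
        raise ConfigurationError("outcome panel is empty")
    results = [
        _analyse_pair(exposure_name, exposure_stats, name, stats, config,
                      direction, outcome_binary=False, ld=ld)
        for name, stats in sorted(panel.items())
    ]
    _apply_fdr(results, config, len(panel))
    return results


# ---------------------------------------------------------------- reports


def format_pval(p: float) -> str:
    """Three decimals, switching to scientific notation below 0.001."""
    if not np.isfinite(p):
        return "NA"
    if p < 0.001:
        mantissa, exponent = f"{p:.2E}".split("E")
        return f"{mantissa}E{int(exponent)}"
    return f"{p:.3f}"


def _format_estimate(est: MrEstimate, binary: bool) -> str:
    if est.is_empty or not np.isfinite(est.beta):
        return "NA"
    if binary:
        return str(estimators.to_odds_ratio(est))
    return f"{est.beta:.3f} ({est.ci_low:.3f}–{est.ci_high:.3f})"


_METHOD_LABELS = {"egger": "MR-Egger", "weighted_median": "Weighted median", "ivw": "IVW"}


def estimates_table(results: list[ScreenResult]) -> pd.DataFrame:
    """Method-per-row estimate table (OR+CI for binary outcomes,
    beta+CI for continuous); FDR shown on the IVW row."""
    rows = []
    for r in results:
        for key in ("egger", "weighted_median", "ivw"):
            est = r.estimates.get(key)
            rows.append(
                {
                    "exposure": r.exposure,
                    "outcome": r.outcome,
                    "snps": r.n_snps,
                    "method": _METHOD_LABELS[key],
                    "estimate": _format_estimate(est, r.outcome_binary) if est else "NA",
                    "pval": format_pval(est.pval) if est else "NA",
                    "pval_fdr": format_pval(r.pval_fdr)
                    if key == "ivw" and r.pval_fdr is not None
                    else "",
                }
            )
    return pd.DataFrame(rows)


def sensitivity_table(results: list[ScreenResult]) -> pd.DataFrame:
    """Heterogeneity / pleiotropy table: Q and its p per model, the
    Egger intercept test, and the PRESSO global p."""
    rows = []
    for r in results:
        for model, q in (("IVW", r.q_ivw), ("MR-Egger", r.q_egger)):
            rows.append(
                {
                    "exposure": r.exposure,
                    "outcome": r.outcome,
                    "method": model,
                    "Q": f"{q.q:.3f}" if q else "NA",
                    "Q_pval": format_pval(q.pval) if q else "NA",
                    "egger_intercept": f"{r.egger_intercept.estimate:.3f}"
                    if model == "IVW" and r.egger_intercept
                    else "",
                    "intercept_pval": format_pval(r.egger_intercept.pval)
                    if model == "IVW" and r.egger_intercept
                    else "",
                    "presso_pval": format_pval(r.presso.global_pval)
                    if model == "IVW" and r.presso
                    else "",
                }
            )
    return pd.DataFrame(rows)


def _markdown_table(df: pd.DataFrame) -> str:
    header = "| " + " | ".join(df.columns) + " |"
    rule = "| " + " | ".join("---" for _ in df.columns) + " |"
    body = ["| " + " | ".join(str(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, rule, *body]) + "\n"


def render_report(
    results: list[ScreenResult],
    out_dir: str | Path,
    fmt: str = "tsv",
    prefix: str = "screen",
) -> list[Path]:
    """Write the estimate table, sensitivity table and per-pair
    leave-one-out series under ``out_dir``; returns the paths."""
    if fmt not in ("tsv", "markdown"):
        raise ConfigurationError(f"unknown report format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    est = estimates_table(results)
    sens = sensitivity_table(results)
    paths = []
    if fmt == "tsv":
        p1 = out_dir / f"{prefix}_estimates.tsv"
        est.to_csv(p1, sep="\t", index=False)
        p2 = out_dir / f"{prefix}_sensitivity.tsv"
        sens.to_csv(p2, sep="\t", index=False)
    else:
        p1 = out_dir / f"{prefix}_estimates.md"
        p1.write_text(_markdown_table(est))
        p2 = out_dir / f"{prefix}_sensitivity.md"
        p2.write_text(_markdown_table(sens))
    paths += [p1, p2]
    for r in results:
        if r.loo is not None:
            p = out_dir / f"{prefix}_loo_{r.exposure}_{r.outcome}.tsv"
            r.loo.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths.append(p)
    return paths
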