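"""Heterogeneity, pleiotropy and influence diagnostics.

Cochran's Q measures heterogeneity of the per-SNP ratio estimates
around a fitted model (constant slope for IVW, intercept + slope for
Egger) and is chi-square distributed under homogeneity.  Leave-one-out
re-estimates IVW after dropping each instrument in turn.  The
pleiotropy residual-sum-and-outlier test (MR-PRESSO) compares the
observed leave-one-out weighted residual sum of squares against a
parametric null simulated from the observed SEs, flags per-SNP
outliers with Bonferroni-adjusted empirical p-values, and re-fits IVW
without them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .estimators import MrEstimate, QResult, _oriented, ivw, wald_ratios
from .gwas_io import kept_instruments

__all__ = ["PressoResult", "cochran_q", "leave_one_out", "presso"]


def cochran_q(
    instruments: pd.DataFrame,
    slope: float,
    model: str = "ivw",
    intercept: float = 0.0,
) -> QResult:
    """Cochran's Q of the instruments around a fitted slope.

    ``model="ivw"``: Q = sum w_j (ratio_j - slope)^2 over the ratio
    estimates with their inverse-variance weights, df = J - 1.
    ``model="egger"``: residuals are taken on the outcome scale around
    ``intercept + slope * gamma_j`` (instruments oriented to
    gamma_j >= 0) with weights 1/outcome_se^2, df = J - 2.
    """
    if model == "ivw":
        ratios = wald_ratios(instruments)
        j = len(ratios)
        df = j - 1
        if df <= 0:
            raise ValidationError("Cochran's Q for IVW needs at least 2 instruments")
        resid = ratios["ratio"].to_numpy() - slope
        w = ratios["weight"].to_numpy()
    elif model == "egger":
        inst = _oriented(instruments)
        j = len(inst)
        df = j - 2
        if df <= 0:
            raise ValidationError("Cochran's Q for Egger needs at least 3 instruments")
        fitted = intercept + slope * inst["exposure_beta"].to_numpy()
        resid = inst["outcome_beta"].to_numpy() - fitted
        w = 1.0 / inst["outcome_se"].to_numpy() ** 2
    else:
        raise ValidationError(f"unknown Q model {model!r}")
    q = float(np.sum(w * resid**2))
    return QResult(q=q, df=df, pval=float(sps.chi2.sf(q, df)))


def leave_one_out(instruments: pd.DataFrame, q_alpha: float = 0.05) -> pd.DataFrame:
    """IVW (mode auto) on every J-1 subset; one row per dropped SNP."""
    inst = kept_instruments(instruments)
    j = len(inst)
    if j < 3:
        raise ValidationError(f"leave-one-out needs at least 3 instruments, got {j}")
    rows = []
    for i in range(j):
        subset = inst.drop(inst.index[i])
        est, _ = ivw(subset, mode="auto", q_alpha=q_alpha)
        rows.append(
            {
                "dropped_snp": inst["snp_id"].iloc[i],
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "method": est.method,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PressoResult:
    """Global residual-sum test, per-SNP outlier tests and corrected fit."""

    rss_obs: float
    global_pval: float
    outlier_pvals: pd.Series  # Bonferroni-adjusted, indexed by snp_id
    outliers: list[str]
    corrected: MrEstimate | None
    n_sim: int
    seed: int
    distortion: str = "not computed"


def _loo_slopes(gamma: np.ndarray, big_gamma: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes on the (gamma, Gamma) scale.

    The inverse-variance-weighted pooled ratio equals the zero-intercept
    weighted regression slope of Gamma on gamma with weights
    1/outcome_se^2, so each slope drops one term from the two sums.
    Supports a leading simulation axis.
    """
    num = w * gamma * big_gamma
    den = w * gamma**2
    s_num = num.sum(axis=-1, keepdims=True)
    s_den = den.sum(axis=-1, keepdims=True)
    return (s_num - num) / (s_den - den)


def presso(
    instruments: pd.DataFrame,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier test with outlier correction.

    The observed statistic is RSS = sum_j w_j (Gamma_j - b_(-j) gamma_j)^2
    with w_j = 1/outcome_se_j^2 and b_(-j) the leave-one-out IVW slope.
    The null distribution comes from ``n_sim`` parametric replicates:
    gamma*_j ~ N(gamma_j, exposure_se_j^2) and
    Gamma*_j ~ N(b_(-j) gamma_j, outcome_se_j^2), with the statistic
    recomputed identically on each replicate.  Empirical p-values use
    the (r+1)/(n_sim+1) convention; per-SNP outlier p-values are the
    empirical tails of the per-SNP weighted residuals, Bonferroni
    multiplied by J.  SNPs below ``outlier_alpha`` are removed and IVW
    is re-fit as the corrected estimate.  Requires >= 4 instruments.

    The reference method's distortion test is not computed; the result
    carries a placeholder field saying so.
    """
    inst = kept_instruments(instruments)
    j = len(inst)
    if j < 4:
        raise ValidationError(f"insufficient instruments for MR-PRESSO: need >= 4, got {j}")
    if seed is None:
        raise ValidationError("presso requires an explicit seed for reproducibility")

    gamma = inst["exposure_beta"].to_numpy(dtype=float)
    big_gamma = inst["outcome_beta"].to_numpy(dtype=float)
    s_x = inst["exposure_se"].to_numpy(dtype=float)
    s_y = inst["outcome_se"].to_numpy(dtype=float)
    w = 1.0 / s_y**2

    b_loo = _loo_slopes(gamma, big_gamma, w)
    resid_obs = w * (big_gamma - b_loo * gamma) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    gamma_sim = gamma + s_x * rng.standard_normal((n_sim, j))
    big_gamma_sim = b_loo * gamma + s_y * rng.standard_normal((n_sim, j))
    b_loo_sim = _loo_slopes(gamma_sim, big_gamma_sim, w)
    resid_sim = w * (big_gamma_sim - b_loo_sim * gamma_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_pval = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))
    tail = (np.sum(resid_sim >= resid_obs, axis=0) + 1) / (n_sim + 1)
    adj = np.minimum(tail * j, 1.0)
    outlier_pvals = pd.Series(adj, index=inst["snp_id"].to_numpy(), name="outlier_pval")
    outliers = list(outlier_pvals.index[outlier_pvals < outlier_alpha])

    corrected: MrEstimate | None = None
    if outliers:
        keep = inst[~inst["snp_id"].isin(outliers)]
        if len(keep) >= 2:
            corrected, _ = ivw(keep, mode="auto")

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        corrected=corrected,
        n_sim=n_sim,
        seed=seed,
    )
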