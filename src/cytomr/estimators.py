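"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume harmonized instruments: per SNP j an exposure
association gamma_j (SE s_xj) and an outcome association Gamma_j
(SE s_yj) expressed on a shared effect allele.  The per-SNP Wald ratio
is beta_j = Gamma_j / gamma_j with first-order delta SE s_yj/|gamma_j|.

* IVW pools the ratios by inverse variance; the random-effects variant
  inflates the SE multiplicatively by max(1, sqrt(Q/(J-1))) and the
  ``auto`` mode follows the Q_pval < 0.05 switching rule.
* MR-Egger is the weighted regression of Gamma on gamma with a free
  intercept (instruments oriented so gamma_j >= 0); a nonzero intercept
  indicates directional pleiotropy.  Inference is t-based with J-2 df.
* The weighted median takes the ratio at the 50% point of the
  inverse-variance-weighted ordered ratios and is consistent when less
  than half the weight comes from invalid instruments; its SE comes
  from a seeded parametric bootstrap.

Binary-outcome estimates (log odds ratios) can be rendered on the OR
scale with :func:`to_odds_ratio`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ValidationError
from .gwas_io import kept_instruments

logger = logging.getLogger(__name__)

#: 95% Wald interval multiplier
Z95 = 1.959964

IVW_FIXED = "IVW-fixed"
IVW_RANDOM = "IVW-random"
EGGER = "MR-Egger"
WEIGHTED_MEDIAN = "Weighted median"


@dataclass(frozen=True)
class MrEstimate:
    """One causal-effect estimate with a 95% Wald interval."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    scale: str = "log-OR"  # or "per 1 SD exposure"

    @property
    def is_empty(self) -> bool:
        return self.n_snps == 0


@dataclass(frozen=True)
class QResult:
    """Cochran's Q heterogeneity statistic with its chi-square p-value."""

    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class EggerIntercept:
    """MR-Egger intercept: the average directional pleiotropic effect."""

    estimate: float
    se: float
    pval: float


@dataclass(frozen=True)
class OddsRatio:
    """OR-scale rendering of a log-OR estimate."""

    odds_ratio: float
    ci_low: float
    ci_high: float

    def __str__(self) -> str:  # "1.115 (1.024–1.215)"
        return f"{self.odds_ratio:.3f} ({self.ci_low:.3f}–{self.ci_high:.3f})"


def _empty_estimate(method: str, scale: str) -> MrEstimate:
    return MrEstimate(method, np.nan, np.nan, np.nan, np.nan, np.nan, 0, scale)


def wald_ratios(instruments: pd.DataFrame, second_order: bool = False) -> pd.DataFrame:
    """Per-SNP ratio estimates with delta-method SEs and IV weights.

    ``second_order=True`` adds the exposure-uncertainty term
    ``Gamma^2 * s_x^2 / gamma^4`` to the ratio variance.
    """
    inst = kept_instruments(instruments)
    gamma = inst["exposure_beta"].to_numpy(dtype=float)
    zero = inst.loc[gamma == 0, "snp_id"]
    if len(zero):
        raise ValidationError(f"exposure beta is zero for SNP(s) {list(zero)}: ratio undefined")
    big_gamma = inst["outcome_beta"].to_numpy(dtype=float)
    s_y = inst["outcome_se"].to_numpy(dtype=float)
    ratio = big_gamma / gamma
    var = s_y**2 / gamma**2
    if second_order:
        s_x = inst["exposure_se"].to_numpy(dtype=float)
        var = var + big_gamma**2 * s_x**2 / gamma**4
    se = np.sqrt(var)
    return pd.DataFrame(
        {"snp_id": inst["snp_id"], "ratio": ratio, "se": se, "weight": 1.0 / var}
    )


def _wald_pval(beta: float, se: float) -> float:
    z = abs(beta) / se
    return float(min(1.0, max(2.0 * sps.norm.sf(z), np.nextafter(0, 1))))


def ivw(
    instruments: pd.DataFrame,
    mode: str = "auto",
    q_alpha: float = 0.05,
    scale: str = "log-OR",
) -> tuple[MrEstimate, QResult | None]:
    """Inverse-variance-weighted estimate with its heterogeneity Q.

    ``mode`` is ``fixed``, ``random`` (multiplicative overdispersion,
    never deflating below the fixed-effect SE) or ``auto``, which picks
    random effects when Q_pval < ``q_alpha`` and fixed effects
    otherwise.  A single instrument degenerates to its Wald ratio (with
    a warning); zero instruments yield a structured empty estimate.
    """
    if mode not in ("auto", "fixed", "random"):
        raise ValidationError(f"unknown IVW mode {mode!r}")
    ratios = wald_ratios(instruments)
    j = len(ratios)
    if j == 0:
        logger.warning("ivw: no instruments; returning empty estimate")
        return _empty_estimate(IVW_FIXED, scale), None
    b = ratios["ratio"].to_numpy()
    w = ratios["weight"].to_numpy()
    beta = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if j == 1:
        logger.warning("ivw: single instrument; estimate equals its Wald ratio")
        se = se_fixed
        q_res = None
        method = IVW_FIXED
    else:
        q = float(np.sum(w * (b - beta) ** 2))
        q_res = QResult(q=q, df=j - 1, pval=float(sps.chi2.sf(q, j - 1)))
        if mode == "auto":
            mode = "random" if q_res.pval < q_alpha else "fixed"
        if mode == "random":
            se = se_fixed * max(1.0, np.sqrt(q_res.q / (j - 1)))
            method = IVW_RANDOM
        else:
            se = se_fixed
            method = IVW_FIXED
    est = MrEstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=_wald_pval(beta, se),
        n_snps=j,
        scale=scale,
    )
    return est, q_res


def _oriented(instruments: pd.DataFrame) -> pd.DataFrame:
    """Negate both betas where the exposure beta is negative."""
    inst = kept_instruments(instruments).copy()
    neg = inst["exposure_beta"] < 0
    inst.loc[neg, "exposure_beta"] *= -1
    inst.loc[neg, "outcome_beta"] *= -1
    return inst


def egger(
    instruments: pd.DataFrame, scale: str = "log-OR"
) -> tuple[MrEstimate, EggerIntercept]:
    """MR-Egger regression: slope (causal effect) and intercept.

    Weighted least squares of the outcome betas on the exposure betas
    with weights 1/outcome_se^2, instruments oriented to nonnegative
    exposure effect.  SEs are inflated by max(1, sqrt(Q/(J-2))) and
    p-values use a t distribution with J-2 df.  Requires >= 3
    instruments.
    """
    inst = _oriented(instruments)
    j = len(inst)
    if j < 3:
        raise ValidationError(f"MR-Egger needs at least 3 instruments, got {j}")
    gamma = inst["exposure_beta"].to_numpy(dtype=float)
    big_gamma = inst["outcome_beta"].to_numpy(dtype=float)
    w = 1.0 / inst["outcome_se"].to_numpy(dtype=float) ** 2
    x = sm.add_constant(gamma)
    fit = sm.WLS(big_gamma, x, weights=w).fit()
    q = float(fit.ssr)  # weighted residual sum of squares
    dispersion = max(1.0, np.sqrt(q / (j - 2)))
    # unit-scale covariance (X' W X)^-1, then multiplicative inflation
    se_unit = np.sqrt(np.diag(fit.normalized_cov_params))
    se_int, se_slope = se_unit * dispersion
    b_int, b_slope = fit.params

    def t_pval(est: float, se: float) -> float:
        return float(min(1.0, max(2.0 * sps.t.sf(abs(est) / se, j - 2), np.nextafter(0, 1))))

    slope = MrEstimate(
        method=EGGER,
        beta=float(b_slope),
        se=float(se_slope),
        ci_low=float(b_slope - Z95 * se_slope),
        ci_high=float(b_slope + Z95 * se_slope),
        pval=t_pval(b_slope, se_slope),
        n_snps=j,
        scale=scale,
    )
    intercept = EggerIntercept(
        estimate=float(b_int), se=float(se_int), pval=t_pval(b_int, se_int)
    )
    return slope, intercept


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Ratio at the 0.5 crossing of centered cumulative standardized weights."""
    order = np.argsort(ratios, kind="stable")
    b = ratios[order]
    w = weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if p[0] >= 0.5:
        return float(b[0])
    if p[-1] <= 0.5:
        return float(b[-1])
    i = int(np.searchsorted(p, 0.5, side="right")) - 1
    return float(b[i] + (b[i + 1] - b[i]) * (0.5 - p[i]) / (p[i + 1] - p[i]))


def weighted_median(
    instruments: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    scale: str = "log-OR",
) -> MrEstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Ratios are resampled from Normal(ratio_j, ratio_se_j) with the
    observed inverse-variance weights held fixed; ``n_boot`` replicates
    (warning below 100).  Requires >= 3 instruments and an explicit
    seed for reproducible pipelines.
    """
    ratios = wald_ratios(instruments)
    j = len(ratios)
    if j < 3:
        raise ValidationError(f"weighted median needs at least 3 instruments, got {j}")
    if n_boot < 100:
        warnings.warn(f"weighted_median: n_boot={n_boot} < 100 gives an unstable SE")
    b = ratios["ratio"].to_numpy()
    s = ratios["se"].to_numpy()
    w = ratios["weight"].to_numpy()
    beta = _weighted_median_point(b, w)
    rng = np.random.default_rng(seed)
    draws = b + s * rng.standard_normal((n_boot, j))
    boot = np.array([_weighted_median_point(row, w) for row in draws])
    se = float(np.std(boot, ddof=1))
    return MrEstimate(
        method=WEIGHTED_MEDIAN,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=_wald_pval(beta, se),
        n_snps=j,
        scale=scale,
    )


def to_odds_ratio(est: MrEstimate) -> OddsRatio:
    """Render a log-OR estimate as OR with its 95% CI."""
    return OddsRatio(
        odds_ratio=float(np.exp(est.beta)),
        ci_low=float(np.exp(est.ci_low)),
        ci_high=float(np.exp(est.ci_high)),
    )
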