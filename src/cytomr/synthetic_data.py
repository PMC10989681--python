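"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator emulates the structure of a cytokine-panel screen: each
exposure trait carries a modest number of independent instruments
(8-30), measured in a small quantitative-trait GWAS (sample sizes in
the 839-8,293 range typical of population cytokine panels), while the
outcome is a large disease GWAS (hundreds of thousands of samples).

Per SNP j with minor-allele frequency maf_j and per-allele effect
gamma_j on a unit-variance exposure:

    se_exposure_j = (2 maf_j (1-maf_j) n_exposure)^(-1/2)
    gamma_hat_j   ~ Normal(gamma_j, se_exposure_j^2)
    Gamma_j       = theta * gamma_j + alpha_j
    se_outcome_j  = (2 maf_j (1-maf_j) n_outcome)^(-1/2)
    Gamma_hat_j   ~ Normal(Gamma_j, se_outcome_j^2)

theta is the causal effect every estimator targets and alpha_j the
per-SNP direct (pleiotropic) effect, controlled by the regime:

* ``none``             alpha_j = 0 (all instruments valid)
* ``balanced``         alpha_j ~ Normal(0, sigma_alpha^2)
* ``directional``      alpha_j ~ Normal(mu_alpha, sigma_alpha^2)
* ``inside_violating`` alpha_j correlated with gamma_j at rho
  (violating the InSIDE assumption that direct effects are independent
  of instrument strength)

Exposure and outcome noise are drawn independently, matching the
non-overlapping-samples assumption of two-sample MR.  Simulated SNPs
are assigned to loci far enough apart that distance clumping keeps
them all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator
from scipy import stats as sps

from . import gwas_io
from .errors import ValidationError

__all__ = ["SimConfig", "SimTruth", "PanelSim", "simulate_pair", "simulate_panel"]

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

# loci spacing: > 10,000 kb so distance clumping never prunes
_CHROMS = 22
_POS_STRIDE = 25_000_000


class SimConfig(BaseModel):
    """Ground-truth parameters of one synthetic exposure/outcome pair.

    ``n_snps`` / ``n_exposure`` default to None, meaning "draw per
    trait" from ``snp_range`` / ``n_exposure_range``.
    """

    n_snps: int | None = None
    snp_range: tuple[int, int] = (8, 30)
    n_exposure: int | None = None
    n_exposure_range: tuple[int, int] = (839, 8293)
    n_outcome: int = 458_620
    theta: float = 0.0
    regime: Literal["none", "balanced", "directional", "inside_violating"] = "none"
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    rho: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.25
    weak_fraction: float = 0.0
    weak_gamma_sd: float = 0.02
    palindromic_fraction: float = 0.1
    outcome_binary: bool = True

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError(f"degenerate maf_range {self.maf_range}")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")
        if self.sigma_alpha < 0 or self.gamma_sd <= 0 or self.weak_gamma_sd <= 0:
            raise ValueError("scale parameters must be positive")
        if not 0.0 <= self.weak_fraction <= 1.0:
            raise ValueError("weak_fraction must be in [0,1]")
        if not 0.0 <= self.palindromic_fraction <= 1.0:
            raise ValueError("palindromic_fraction must be in [0,1]")
        if self.n_snps is not None and self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        return self


@dataclass(frozen=True)
class SimTruth:
    """What the generator actually drew; the oracle for recovery tests."""

    theta: float
    snp_ids: list[str]
    gamma: np.ndarray
    alpha: np.ndarray
    valid: np.ndarray  # alpha_j == 0
    regime: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "snp_ids": self.snp_ids,
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
            "valid": self.valid.tolist(),
            "regime": self.regime,
            "seed": self.seed,
        }


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * sps.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def _draw_alpha(config: SimConfig, gamma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    j = len(gamma)
    if config.regime == "none":
        return np.zeros(j)
    if config.regime == "balanced":
        return rng.normal(0.0, config.sigma_alpha, j)
    if config.regime == "directional":
        return rng.normal(config.mu_alpha, config.sigma_alpha, j)
    # inside_violating: alpha correlated with gamma at rho
    sd = config.sigma_alpha if config.sigma_alpha > 0 else 0.05
    z = (gamma - gamma.mean()) / (gamma.std() if gamma.std() > 0 else 1.0)
    return sd * (config.rho * z + np.sqrt(1 - config.rho**2) * rng.standard_normal(j))


def simulate_pair(
    config: SimConfig,
    seed: int,
    snp_offset: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """One exposure GWAS, the matching outcome rows, and the truth.

    ``snp_offset`` shifts SNP ids and loci so traits in a panel occupy
    disjoint, well-separated positions.  Same config + seed gives
    identical output.
    """
    rng = np.random.default_rng(seed)
    j = config.n_snps or int(rng.integers(config.snp_range[0], config.snp_range[1] + 1))
    n_exp = config.n_exposure or int(
        rng.integers(config.n_exposure_range[0], config.n_exposure_range[1] + 1)
    )
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, j)

    n_weak = int(round(config.weak_fraction * j))
    weak = np.zeros(j, dtype=bool)
    if n_weak:
        weak[rng.choice(j, size=n_weak, replace=False)] = True
    # effect allele = exposure-increasing allele, so per-allele effects
    # are nonnegative; directional pleiotropy is then well defined
    # relative to the orientation MR-Egger uses
    gamma = np.abs(rng.normal(0.0, config.gamma_sd, j))
    gamma[weak] = np.abs(rng.normal(0.0, config.weak_gamma_sd, n_weak))

    alpha = _draw_alpha(config, gamma, rng)

    het = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(het * n_exp)
    gamma_hat = gamma + se_x * rng.standard_normal(j)
    big_gamma = config.theta * gamma + alpha
    se_y = 1.0 / np.sqrt(het * config.n_outcome)
    big_gamma_hat = big_gamma + se_y * rng.standard_normal(j)

    idx = snp_offset + np.arange(j)
    snp_ids = [f"rs{100000 + i}" for i in idx]
    chrom = (idx % _CHROMS + 1).astype(str)
    pos = 1 + (idx // _CHROMS) * _POS_STRIDE

    pal = rng.random(j) < config.palindromic_fraction
    pairs = [
        _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
        if p
        else _NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))]
        for p in pal
    ]
    ea = [p[0] for p in pairs]
    oa = [p[1] for p in pairs]

    # same source population: outcome eaf is the exposure eaf plus
    # small estimation noise, kept on the same side of 0.5
    eaf_out = np.clip(maf + rng.normal(0.0, 0.005, j), 1e-3, 0.999)

    exposure = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": maf,
            "beta": gamma_hat,
            "se": se_x,
            "pval": _two_sided_p(gamma_hat, se_x),
            "n": n_exp,
        }
    )
    outcome = exposure.copy()
    outcome["eaf"] = eaf_out
    outcome["beta"] = big_gamma_hat
    outcome["se"] = se_y
    outcome["pval"] = _two_sided_p(big_gamma_hat, se_y)
    outcome["n"] = config.n_outcome

    truth = SimTruth(
        theta=config.theta,
        snp_ids=snp_ids,
        gamma=gamma,
        alpha=alpha,
        valid=alpha == 0.0,
        regime=config.regime,
        seed=int(seed),
    )
    return exposure, outcome, truth


@dataclass(frozen=True)
class PanelSim:
    """A simulated cytokine panel plus the shared disease outcome GWAS."""

    manifest: pd.DataFrame
    traits: dict[str, pd.DataFrame]
    outcome: pd.DataFrame
    truths: dict[str, SimTruth]
    causal_traits: list[str] = field(default_factory=list)


def _trait_seed(master_seed: int, index: int) -> int:
    return int((master_seed * 1_000_003 + 7919 * (index + 1)) % 2**31)


def simulate_panel(
    config: SimConfig,
    n_traits: int = 41,
    n_causal: int = 2,
    causal_theta: float = 0.3,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> PanelSim:
    """A panel of exposure traits against one shared disease outcome.

    ``n_causal`` traits receive ``causal_theta`` as the true effect,
    the rest theta = 0; the causal traits are chosen by the seeded RNG.
    With ``out_dir`` set, trait files, the outcome file, a manifest TSV
    and a JSON-lines truth file are written in the TSV dialect
    :mod:`cytomr.gwas_io` reads.
    """
    if n_causal > n_traits:
        raise ValidationError(f"n_causal={n_causal} exceeds n_traits={n_traits}")
    rng = np.random.default_rng(seed)
    causal_idx = set(rng.choice(n_traits, size=n_causal, replace=False).tolist())

    traits: dict[str, pd.DataFrame] = {}
    truths: dict[str, SimTruth] = {}
    outcome_parts: list[pd.DataFrame] = []
    manifest_rows = []
    causal_traits = []
    offset = 0
    for t in range(n_traits):
        name = f"trait_{t + 1:02d}"
        theta = causal_theta if t in causal_idx else 0.0
        cfg_t = config.model_copy(update={"theta": theta})
        ts = _trait_seed(seed, t)
        exp_df, out_df, truth = simulate_pair(cfg_t, seed=ts, snp_offset=offset)
        offset += len(exp_df)
        traits[name] = exp_df
        truths[name] = truth
        outcome_parts.append(out_df)
        if theta != 0.0:
            causal_traits.append(name)
        manifest_rows.append(
            {
                "trait": name,
                "file": f"{name}.tsv",
                "theta": theta,
                "n_snps": len(exp_df),
                "regime": cfg_t.regime,
                "seed": ts,
            }
        )
    outcome = pd.concat(outcome_parts, ignore_index=True)
    manifest = pd.DataFrame(manifest_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in traits.items():
            gwas_io.write_summary_stats(df, out_dir / f"{name}.tsv")
        gwas_io.write_summary_stats(outcome, out_dir / "outcome.tsv")
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
        with open(out_dir / "truth.jsonl", "w") as fh:
            for name, truth in truths.items():
                fh.write(json.dumps({"trait": name, **truth.to_dict()}) + "\n")

    return PanelSim(
        manifest=manifest,
        traits=traits,
        outcome=outcome,
        truths=truths,
        causal_traits=causal_traits,
    )
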