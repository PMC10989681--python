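"""Instrument selection and strength.

Instruments are SNPs suggestively associated with the exposure
(p < 1e-5 by default), pruned to approximate independence by greedy
distance/LD clumping (r^2 < 0.001 within 10,000 kb by default), and
screened for weak-instrument bias via the variance explained

    R^2 = 2 * MAF * (1 - MAF) * b^2,      MAF = min(eaf, 1 - eaf)

and the F-statistic

    F = R^2 * (n - k - 1) / (k * (1 - R^2)),

with k the number of instruments in the model (k = 1 per SNP).
Instruments with F <= 10 are flagged as weak.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "LdMatrix",
    "PooledStrength",
    "select_by_pvalue",
    "clump",
    "instrument_strength",
]


class LdMatrix:
    """Symmetric pairwise-r^2 matrix over a set of SNP ids.

    The diagonal must be exactly 1 and every entry must lie in [0, 1].
    """

    def __init__(self, snp_ids: list[str], r2: np.ndarray):
        r2 = np.asarray(r2, dtype=float)
        if r2.ndim != 2 or r2.shape[0] != r2.shape[1] or r2.shape[0] != len(snp_ids):
            raise ValidationError("LD matrix must be square and match the SNP id list")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0):
            raise ValidationError("LD matrix diagonal must be 1")
        if (r2 < 0).any() or (r2 > 1 + 1e-12).any():
            raise ValidationError("LD r^2 values must lie in [0, 1]")
        self.snp_ids = list(snp_ids)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        self.r2 = r2

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise ConfigurationError(f"LD matrix does not cover SNP {exc.args[0]!r}") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValidationError(f"LD matrix in {path} must have matching row/column ids")
        return cls([str(s) for s in df.index], df.to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", float_format="%.6g"
        )


def select_by_pvalue(stats: pd.DataFrame, threshold: float = 1e-5) -> pd.DataFrame:
    """Rows with ``pval`` strictly below ``threshold``, order preserved."""
    if not 0 < threshold < 1:
        raise ConfigurationError(f"p-value threshold must be in (0,1), got {threshold}")
    return stats[stats["pval"] < threshold].reset_index(drop=True)


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    return (0, int(chrom)) if str(chrom).isdigit() else (1, str(chrom))


def clump(
    stats: pd.DataFrame,
    ld: LdMatrix | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> pd.DataFrame:
    """Greedy p-value clumping.

    Repeatedly keep the smallest-p remaining SNP (ties broken by snp_id)
    and discard every remaining SNP on the same chromosome within
    ``window_kb`` kilobases that is in LD with it (pairwise r^2 >=
    ``r2_threshold``).  Without an LD matrix the distance criterion
    alone prunes.  The result is sorted by chromosome and position.
    """
    if stats.empty:
        return stats.reset_index(drop=True)
    if ld is not None:
        missing = [s for s in stats["snp_id"] if s not in ld]
        if missing:
            raise ConfigurationError(f"LD matrix missing SNP(s): {missing}")

    window_bp = window_kb * 1000.0
    order = stats.sort_values(["pval", "snp_id"], kind="stable")
    remaining = dict(
        zip(order["snp_id"], zip(order["chrom"], order["pos"]))
    )  # insertion order = greedy order
    kept: list[str] = []
    while remaining:
        snp, (chrom, pos) = next(iter(remaining.items()))
        del remaining[snp]
        kept.append(snp)
        for other, (ochrom, opos) in list(remaining.items()):
            if ochrom != chrom or abs(opos - pos) > window_bp:
                continue
            if ld is None or ld.r2_between(snp, other) >= r2_threshold:
                del remaining[other]

    out = stats[stats["snp_id"].isin(kept)].copy()
    out["_ck"] = out["chrom"].map(_chrom_sort_key)
    out = out.sort_values(["_ck", "pos"], kind="stable").drop(columns="_ck")
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class PooledStrength:
    """Instrument strength of a multi-SNP model: R^2 summed over SNPs."""

    r2: float
    f_stat: float
    k: int
    n: int
    weak: bool


def instrument_strength(
    stats: pd.DataFrame, aggregate: str = "per-snp"
) -> pd.DataFrame | tuple[pd.DataFrame, PooledStrength]:
    """Variance explained and F-statistic per instrument.

    ``aggregate="per-snp"`` returns one row per SNP with k = 1;
    ``aggregate="pooled"`` additionally returns a :class:`PooledStrength`
    using R^2 = sum of per-SNP r2, k = number of SNPs, and the smallest
    per-SNP sample size (the per-trait n is constant in practice).
    """
    if aggregate not in ("per-snp", "pooled"):
        raise ConfigurationError(f"aggregate must be 'per-snp' or 'pooled', got {aggregate!r}")
    for col in ("eaf", "n"):
        bad = stats.loc[stats[col].isna(), "snp_id"]
        if len(bad):
            raise ValidationError(
                f"instrument_strength requires {col} for every SNP; missing for {list(bad)}"
            )
    eaf = stats["eaf"].to_numpy(dtype=float)
    maf = np.minimum(eaf, 1.0 - eaf)
    beta = stats["beta"].to_numpy(dtype=float)
    n = stats["n"].to_numpy(dtype=float)
    r2 = 2.0 * maf * (1.0 - maf) * beta**2
    f = r2 * (n - 2.0) / (1.0 - r2)
    per_snp = pd.DataFrame(
        {"snp_id": stats["snp_id"], "r2": r2, "f_stat": f, "weak": f <= 10.0}
    )
    if aggregate == "per-snp":
        return per_snp
    k = len(stats)
    total_r2 = float(r2.sum())
    n_min = int(n.min())
    f_pooled = total_r2 * (n_min - k - 1) / (k * (1.0 - total_r2))
    return per_snp, PooledStrength(
        r2=total_r2, f_stat=f_pooled, k=k, n=n_min, weak=f_pooled <= 10.0
    )
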