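"""Reading, validation and allele harmonization of GWAS summary statistics.

Summary statistics live in tab- or comma-delimited text with a header
row, one row per SNP.  In memory they are plain :class:`pandas.DataFrame`
objects with canonical column names (see :data:`REQUIRED_COLUMNS` and
:data:`OPTIONAL_COLUMNS`); every public function in the package accepts
and returns these frames, so the dataframe is the package's unit of
exchange, not a bespoke container.

Harmonization aligns the outcome association of each shared SNP onto the
exposure's effect allele.  Strand flips are resolved by complementing
alleles; palindromic SNPs (A/T and C/G) are aligned by allele frequency
when both frequencies are informative, and dropped otherwise.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column name -> description
REQUIRED_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
    "n",
)
OPTIONAL_COLUMNS = ("eaf",)
ALL_COLUMNS = REQUIRED_COLUMNS[:5] + ("eaf",) + REQUIRED_COLUMNS[5:]

#: synonyms recognised without an explicit column map
_DEFAULT_SYNONYMS = {
    "snp": "snp_id",
    "rsid": "snp_id",
    "chr": "chrom",
    "chromosome": "chrom",
    "position": "pos",
    "bp": "pos",
    "ea": "effect_allele",
    "oa": "other_allele",
    "a1": "effect_allele",
    "a2": "other_allele",
    "effect_allele_frequency": "eaf",
    "freq": "eaf",
    "p": "pval",
    "p_value": "pval",
    "pvalue": "pval",
    "samplesize": "n",
    "n_samples": "n",
}

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonization action labels
KEPT = "kept"
FLIPPED = "flipped"
DROPPED = "dropped"

HARMONIZED_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "exposure_beta",
    "exposure_se",
    "exposure_eaf",
    "exposure_pval",
    "exposure_n",
    "outcome_beta",
    "outcome_se",
    "outcome_eaf",
    "palindromic",
    "action",
    "reason",
)


def _infer_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_summary_stats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a GWAS summary-statistics file into a validated dataframe.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping from canonical field name (e.g. ``"snp_id"``) to the
        column name used in the file.  Columns already carrying a
        canonical name or a recognised synonym need no entry.
    sep
        Field delimiter; inferred from the header line when omitted.

    Returns
    -------
    DataFrame with canonical columns, original row order preserved.
    A missing ``eaf`` column is tolerated (filled with NaN, with a
    warning); missing required columns raise :class:`ConfigurationError`,
    and rows violating the per-SNP invariants raise
    :class:`ValidationError` listing the offending line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary-statistics file not found: {path}")
    if sep is None:
        sep = _infer_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"chrom": str, "chr": str})

    rename: dict[str, str] = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _DEFAULT_SYNONYMS:
            rename[col] = _DEFAULT_SYNONYMS[key]
        elif key in ALL_COLUMNS:
            rename[col] = key
    if column_map:
        for field, col in column_map.items():
            if field not in ALL_COLUMNS:
                raise ConfigurationError(f"unknown canonical field in column map: {field!r}")
            if col not in df.columns:
                raise ConfigurationError(
                    f"column {col!r} (mapped to {field!r}) not present in {path}"
                )
            rename[col] = field
    df = df.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"missing required column(s) {missing} in {path}; "
            "provide a column_map entry for each"
        )
    if "eaf" not in df.columns:
        logger.warning("no eaf column in %s; palindromic SNPs cannot be aligned", path)
        df["eaf"] = np.nan

    df = df[list(ALL_COLUMNS)].copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    _validate(df, path)
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    return df.reset_index(drop=True)


def _validate(df: pd.DataFrame, path: Path) -> None:
    """Check SNP-level invariants, reporting offending file line numbers."""
    problems: list[str] = []

    def flag(mask: pd.Series, msg: str) -> None:
        if mask.any():
            # +2: header is line 1, first data row is line 2
            lines = (np.flatnonzero(mask.to_numpy()) + 2).tolist()
            problems.append(f"{msg} (line {lines})")

    flag(~df["effect_allele"].isin(_VALID_ALLELES), "effect_allele not one of A/C/G/T")
    flag(~df["other_allele"].isin(_VALID_ALLELES), "other_allele not one of A/C/G/T")
    flag(df["effect_allele"] == df["other_allele"], "effect_allele equals other_allele")
    for col in ("beta", "se", "pval", "n", "pos"):
        flag(df[col].isna(), f"missing {col}")
    flag(df["se"].notna() & (df["se"] <= 0), "se must be > 0")
    flag(df["pval"].notna() & ((df["pval"] <= 0) | (df["pval"] > 1)), "pval outside (0,1]")
    flag(df["pos"].notna() & (df["pos"] < 1), "pos must be >= 1")
    flag(df["n"].notna() & (df["n"] < 1), "n must be a positive integer")
    eaf_bad = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    flag(eaf_bad, "eaf outside [0,1]")
    dup = df["snp_id"].duplicated(keep=False)
    flag(dup, "duplicate snp_id")
    if problems:
        raise ValidationError(f"invalid rows in {path}: " + "; ".join(problems))


def write_summary_stats(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a canonical summary-statistics frame as delimited text."""
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return oa == ea.map(_COMPLEMENT)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ambiguity_band: float = 0.08,
) -> pd.DataFrame:
    """Align outcome associations onto the exposure's effect alleles.

    Only SNPs present in both inputs (keyed by ``snp_id``) are
    considered; each appears exactly once in the output with its
    ``action`` (kept / flipped / dropped) and a ``reason``.

    Rules, per shared SNP:

    * outcome alleles identical (or the strand complement) to the
      exposure's -> kept as is;
    * outcome alleles swapped (or swapped-complement) -> outcome beta
      negated and eaf replaced by 1 - eaf;
    * palindromic SNPs (A/T, C/G) cannot be resolved from alleles: they
      are aligned by effect-allele frequency when both eafs lie outside
      ``0.5 +/- ambiguity_band``, and dropped otherwise;
    * any other allele pair -> dropped as a mismatch.

    An empty intersection returns an empty frame with a warning rather
    than raising.
    """
    merged = exposure.merge(
        outcome, on="snp_id", suffixes=("_x", "_y"), how="inner", sort=False
    )
    if merged.empty:
        logger.warning("harmonize: no SNPs shared between exposure and outcome")
        return pd.DataFrame(columns=list(HARMONIZED_COLUMNS))

    ea_x = merged["effect_allele_x"]
    oa_x = merged["other_allele_x"]
    ea_y = merged["effect_allele_y"]
    oa_y = merged["other_allele_y"]
    comp_ea_x = ea_x.map(_COMPLEMENT)
    comp_oa_x = oa_x.map(_COMPLEMENT)

    palindromic = _is_palindromic(ea_x, oa_x).to_numpy()
    same = ((ea_y == ea_x) & (oa_y == oa_x)).to_numpy()
    swapped = ((ea_y == oa_x) & (oa_y == ea_x)).to_numpy()
    strand_same = ((ea_y == comp_ea_x) & (oa_y == comp_oa_x)).to_numpy()
    strand_swapped = ((ea_y == comp_oa_x) & (oa_y == comp_ea_x)).to_numpy()

    n = len(merged)
    action = np.full(n, DROPPED, dtype=object)
    reason = np.full(n, "allele_mismatch", dtype=object)
    flip = np.zeros(n, dtype=bool)

    nonpal = ~palindromic
    action[nonpal & (same | strand_same)] = KEPT
    reason[nonpal & (same | strand_same)] = "alleles_match"
    keep_flip = nonpal & ~(same | strand_same) & (swapped | strand_swapped)
    action[keep_flip] = FLIPPED
    reason[keep_flip] = "alleles_swapped"
    flip[keep_flip] = True

    # palindromic: allele labels cannot resolve orientation; use eaf
    eaf_x = merged["eaf_x"].to_numpy(dtype=float)
    eaf_y = merged["eaf_y"].to_numpy(dtype=float)
    pal_ok = palindromic & (same | swapped | strand_same | strand_swapped)
    with np.errstate(invalid="ignore"):
        informative = (
            ~np.isnan(eaf_x)
            & ~np.isnan(eaf_y)
            & (np.abs(eaf_x - 0.5) > ambiguity_band)
            & (np.abs(eaf_y - 0.5) > ambiguity_band)
        )
    pal_resolved = pal_ok & informative
    same_side = (eaf_x < 0.5) == (eaf_y < 0.5)
    action[pal_resolved & same_side] = KEPT
    reason[pal_resolved & same_side] = "palindromic_eaf_aligned"
    action[pal_resolved & ~same_side] = FLIPPED
    reason[pal_resolved & ~same_side] = "palindromic_eaf_flipped"
    flip[pal_resolved & ~same_side] = True
    pal_ambiguous = pal_ok & ~informative
    action[pal_ambiguous] = DROPPED
    reason[pal_ambiguous] = "palindromic_ambiguous"

    out_beta = merged["beta_y"].to_numpy(dtype=float).copy()
    out_eaf = eaf_y.copy()
    out_beta[flip] = -out_beta[flip]
    out_eaf[flip] = 1.0 - out_eaf[flip]

    result = pd.DataFrame(
        {
            "snp_id": merged["snp_id"],
            "chrom": merged["chrom_x"],
            "pos": merged["pos_x"],
            "effect_allele": ea_x,
            "other_allele": oa_x,
            "exposure_beta": merged["beta_x"].astype(float),
            "exposure_se": merged["se_x"].astype(float),
            "exposure_eaf": eaf_x,
            "exposure_pval": merged["pval_x"].astype(float),
            "exposure_n": merged["n_x"],
            "outcome_beta": out_beta,
            "outcome_se": merged["se_y"].astype(float),
            "outcome_eaf": out_eaf,
            "palindromic": palindromic,
            "action": action,
            "reason": reason,
        }
    )
    return result.reset_index(drop=True)


def kept_instruments(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows usable by estimators (action kept or flipped)."""
    return harmonized[harmonized["action"] != DROPPED].reset_index(drop=True)


def write_harmonization_log(harmonized: pd.DataFrame, path: str | Path) -> None:
    """Persist the per-SNP harmonization decisions as TSV."""
    harmonized[["snp_id", "action", "reason"]].to_csv(path, sep="\t", index=False)
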