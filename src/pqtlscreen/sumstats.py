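"""Reading, validation and harmonization of GWAS summary statistics.

Summary statistics for a single trait are held in a :class:`SumstatsTable`,
a thin validated wrapper around a :class:`pandas.DataFrame` with one row per
variant.  Coordinates are 1-based and inclusive throughout, following the
usual GWAS summary-statistics convention.

Two-sample analyses (Wald-ratio MR, colocalization) require the exposure and
outcome effect estimates to refer to the same effect allele at every shared
variant; :func:`harmonize` performs that alignment, resolving allele swaps
and strand flips and dropping ambiguous palindromic variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: canonical column order of a summary-statistics table
SUMSTAT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: columns of the MR results table (single-instrument Wald-ratio screen)
MR_TABLE_COLUMNS = ["id.exposure", "b", "se", "P-val", "or", "or_lci95", "or_uci95"]

#: columns of the colocalization results table
COLOC_TABLE_COLUMNS = ["Protein", "N_SNPs", "PPH0", "PPH1", "PPH2", "PPH3", "PPH4"]


class SumstatsError(ValueError):
    """Raised for invalid summary-statistics input."""


@dataclass(frozen=True)
class SumstatRecord:
    """One variant's association summary for one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise SumstatsError(
                f"{self.variant_id}: alleles must be single nucleotides in ACGT, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise SumstatsError(f"{self.variant_id}: effect and other allele are identical")
        if not (0.0 < self.eaf < 1.0):
            raise SumstatsError(f"{self.variant_id}: eaf {self.eaf} outside (0, 1)")
        if self.se <= 0:
            raise SumstatsError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0.0 < self.pval <= 1.0):
            raise SumstatsError(f"{self.variant_id}: pval {self.pval} outside (0, 1]")
        if self.pos < 1:
            raise SumstatsError(f"{self.variant_id}: pos must be >= 1")
        if self.n <= 0:
            raise SumstatsError(f"{self.variant_id}: n must be positive")


@dataclass
class SumstatsTable:
    """Validated, position-sorted summary statistics for one trait.

    Parameters
    ----------
    trait_id
        Identifier of the trait (gene/protein id for pQTL exposures,
        disease name for the outcome).
    trait_type
        ``"quantitative"`` (protein levels, effects in SD units) or
        ``"binary"`` (case-control, effects on the log-odds scale).
    df
        One row per variant with columns :data:`SUMSTAT_COLUMNS`.
    case_n, control_n
        Case and control counts for binary traits (optional).
    """

    trait_id: str
    trait_type: str
    df: pd.DataFrame
    case_n: int | None = None
    control_n: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise SumstatsError(f"unknown trait_type {self.trait_type!r}")
        self.df = self.df.loc[:, SUMSTAT_COLUMNS].copy()
        if self.df.empty:
            raise SumstatsError(f"{self.trait_id}: empty summary-statistics table")
        dup = self.df["variant_id"][self.df["variant_id"].duplicated()]
        if len(dup):
            raise SumstatsError(
                f"{self.trait_id}: duplicate variant_id values: {sorted(set(dup))[:5]}"
            )
        self.df = self.df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[SumstatRecord]:
        return [SumstatRecord(**row) for row in self.df.to_dict("records")]

    @classmethod
    def from_records(
        cls,
        trait_id: str,
        trait_type: str,
        records: Iterable[SumstatRecord],
        **kwargs,
    ) -> "SumstatsTable":
        df = pd.DataFrame([r.__dict__ for r in records], columns=SUMSTAT_COLUMNS)
        return cls(trait_id, trait_type, df, **kwargs)

    @property
    def effective_n(self) -> float:
        """Effective sample size: 4 / (1/cases + 1/controls) for binary traits
        with known case/control split, otherwise the median per-variant n."""
        if self.trait_type == "binary" and self.case_n and self.control_n:
            return 4.0 / (1.0 / self.case_n + 1.0 / self.control_n)
        return float(self.df["n"].median())


def _validate_rows(df: pd.DataFrame, trait_id: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split rows into (valid, rejected-with-reason)."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        new = mask & (reasons == "")
        reasons[new] = reason

    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    flag(df[["pos", "eaf", "beta", "se", "pval", "n"]].isna().any(axis=1), "non_numeric_field")
    flag(~df["effect_allele"].isin(VALID_ALLELES), "invalid_effect_allele")
    flag(~df["other_allele"].isin(VALID_ALLELES), "invalid_other_allele")
    flag(df["effect_allele"] == df["other_allele"], "identical_alleles")
    flag(~((df["eaf"] > 0) & (df["eaf"] < 1)), "eaf_out_of_range")
    flag(df["se"] <= 0, "nonpositive_se")
    flag(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval_out_of_range")
    flag(df["pos"] < 1, "nonpositive_pos")
    flag(df["n"] <= 0, "nonpositive_n")

    bad = reasons != ""
    rejected = df.loc[bad].copy()
    rejected["reject_reason"] = reasons[bad]
    good = df.loc[~bad].copy()
    good["pos"] = good["pos"].astype(np.int64)
    good["n"] = good["n"].astype(np.int64)
    if len(rejected):
        logger.warning(
            "%s: rejected %d malformed row(s): %s",
            trait_id,
            len(rejected),
            rejected["reject_reason"].value_counts().to_dict(),
        )
    return good, rejected


DEFAULT_COLUMN_MAP = {c: c for c in SUMSTAT_COLUMNS}


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "quantitative",
    trait_id: str | None = None,
    case_n: int | None = None,
    control_n: int | None = None,
) -> SumstatsTable:
    """Read a tab-/whitespace-delimited GWAS summary-statistics file.

    Parameters
    ----------
    path
        Input file; gzip-compressed input (``.gz``) is accepted.
    column_map
        Maps canonical field names (:data:`SUMSTAT_COLUMNS`) to the column
        names used in the file.  Fields absent from the map are assumed to
        use their canonical names.
    trait_type
        ``"quantitative"`` or ``"binary"``.

    Malformed rows (non-numeric beta/se, invalid alleles, out-of-range
    frequencies) are rejected with a logged reason; they are counted, never
    silently dropped.

    Raises
    ------
    SumstatsError
        If a mapped column is missing, the table is empty after validation,
        or variant ids are duplicated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=r"\s+", dtype={cmap["chrom"]: str, cmap["variant_id"]: str})
    missing = [src for src in cmap.values() if src not in raw.columns]
    if missing:
        raise SumstatsError(f"{path}: mapped column(s) not found in header: {missing}")
    df = raw.rename(columns={v: k for k, v in cmap.items()})[SUMSTAT_COLUMNS]
    good, rejected = _validate_rows(df, trait_id or path.stem)
    if good.empty:
        raise SumstatsError(f"{path}: no valid rows after validation")
    table = SumstatsTable(
        trait_id=trait_id or path.stem,
        trait_type=trait_type,
        df=good,
        case_n=case_n,
        control_n=control_n,
    )
    table.n_rejected = len(rejected)  # type: ignore[attr-defined]
    table.rejected = rejected  # type: ignore[attr-defined]
    return table


def write_sumstats(table: SumstatsTable, path: str | Path) -> None:
    """Write a table back to tab-delimited text at full float precision."""
    table.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# harmonization


def _is_palindromic(a1: str, a2: str) -> bool:
    return (a1, a2) in PALINDROMIC_PAIRS


def harmonize(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    palindrome_eaf_window: float = 0.08,
) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele, variant by variant.

    Matching is by ``variant_id``.  For each exposure variant the outcome
    record is resolved in this order:

    1. same alleles -> kept unflipped;
    2. swapped alleles -> kept with ``beta_out`` negated and
       ``eaf_out -> 1 - eaf_out`` (``flipped=True``);
    3. strand-complement (or complement-and-swap) alleles -> resolved by
       complementing the outcome alleles first;
    4. anything else -> dropped (``allele_mismatch``).

    Palindromic variants (A/T or C/G) cannot be strand-resolved; they are
    kept only when the allele frequency is informative, i.e. dropped whenever
    either trait's EAF lies within ``palindrome_eaf_window`` of 0.5.

    Returns a DataFrame with one row per exposure variant and columns
    ``variant_id, chrom, pos, effect_allele, other_allele, beta_exp, se_exp,
    eaf_exp, beta_out, se_out, eaf_out, n_out, flipped, dropped_reason``;
    ``dropped_reason`` is ``None`` for retained pairs.  Every exposure
    variant appears exactly once, so kept + dropped counts always sum to the
    exposure variant count.
    """
    if not (0.0 <= palindrome_eaf_window < 0.5):
        raise ValueError("palindrome_eaf_window must be in [0, 0.5)")
    out_idx = outcome.df.set_index("variant_id")
    rows = []
    for exp in exposure.df.itertuples(index=False):
        row = {
            "variant_id": exp.variant_id,
            "chrom": exp.chrom,
            "pos": exp.pos,
            "effect_allele": exp.effect_allele,
            "other_allele": exp.other_allele,
            "beta_exp": exp.beta,
            "se_exp": exp.se,
            "eaf_exp": exp.eaf,
            "beta_out": np.nan,
            "se_out": np.nan,
            "eaf_out": np.nan,
            "n_out": np.nan,
            "flipped": False,
            "dropped_reason": None,
        }
        if exp.variant_id not in out_idx.index:
            row["dropped_reason"] = "missing_in_outcome"
            rows.append(row)
            continue
        out = out_idx.loc[exp.variant_id]
        ea_o, oa_o = out["effect_allele"], out["other_allele"]
        beta_o, eaf_o = float(out["beta"]), float(out["eaf"])

        if _is_palindromic(exp.effect_allele, exp.other_allele):
            if {ea_o, oa_o} != {exp.effect_allele, exp.other_allele}:
                row["dropped_reason"] = "allele_mismatch"
                rows.append(row)
                continue
            ambiguous = (
                abs(exp.eaf - 0.5) < palindrome_eaf_window
                or abs(eaf_o - 0.5) < palindrome_eaf_window
            )
            if ambiguous:
                row["dropped_reason"] = "palindromic_ambiguous"
                rows.append(row)
                continue
            # allele labels are strand-uninformative here; frequency decides
            flipped = (eaf_o > 0.5) != (exp.eaf > 0.5)
            row["flipped"] = flipped
            row["beta_out"] = -beta_o if flipped else beta_o
            row["eaf_out"] = 1.0 - eaf_o if flipped else eaf_o
        else:
            if ea_o not in VALID_ALLELES or oa_o not in VALID_ALLELES:
                row["dropped_reason"] = "allele_mismatch"
                rows.append(row)
                continue
            ea_c, oa_c = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
            if (ea_o, oa_o) == (exp.effect_allele, exp.other_allele):
                flipped = False
            elif (oa_o, ea_o) == (exp.effect_allele, exp.other_allele):
                flipped = True
            elif (ea_c, oa_c) == (exp.effect_allele, exp.other_allele):
                flipped = False  # pure strand flip
            elif (oa_c, ea_c) == (exp.effect_allele, exp.other_allele):
                flipped = True  # strand flip + swap
            else:
                row["dropped_reason"] = "allele_mismatch"
                rows.append(row)
                continue
            row["flipped"] = flipped
            row["beta_out"] = -beta_o if flipped else beta_o
            row["eaf_out"] = 1.0 - eaf_o if flipped else eaf_o
        row["se_out"] = float(out["se"])
        row["n_out"] = float(out["n"])
        rows.append(row)

    result = pd.DataFrame(rows)
    n_kept = int(result["dropped_reason"].isna().sum())
    if n_kept == 0:
        logger.warning(
            "%s vs %s: zero variants retained after harmonization",
            exposure.trait_id,
            outcome.trait_id,
        )
    return result


def harmonized_pairs(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Retained rows of a :func:`harmonize` result."""
    return harmonized[harmonized["dropped_reason"].isna()].reset_index(drop=True)


# ---------------------------------------------------------------------------
# results tables


def write_results_table(rows: Sequence, path: str | Path) -> None:
    """Write MR or colocalization results as a tab-delimited table.

    ``MrResult`` rows produce the 7-column MR screen layout
    (:data:`MR_TABLE_COLUMNS`); ``ColocResult`` rows produce the 7-column
    colocalization layout (:data:`COLOC_TABLE_COLUMNS`).  Numbers are written
    at full precision.
    """
    if not rows:
        raise ValueError("write_results_table: empty rows")
    first = rows[0]
    if hasattr(first, "or_"):
        df = pd.DataFrame(
            {
                "id.exposure": [r.gene_id for r in rows],
                "b": [r.b for r in rows],
                "se": [r.se for r in rows],
                "P-val": [r.pval for r in rows],
                "or": [r.or_ for r in rows],
                "or_lci95": [r.or_lci95 for r in rows],
                "or_uci95": [r.or_uci95 for r in rows],
            }
        )
    elif hasattr(first, "pph4"):
        df = pd.DataFrame(
            {
                "Protein": [r.gene_id for r in rows],
                "N_SNPs": [r.n_snps for r in rows],
                "PPH0": [r.pph0 for r in rows],
                "PPH1": [r.pph1 for r in rows],
                "PPH2": [r.pph2 for r in rows],
                "PPH3": [r.pph3 for r in rows],
                "PPH4": [r.pph4 for r in rows],
            }
        )
    else:
        raise TypeError(f"unsupported result row type {type(first).__name__}")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
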