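"""cis-pQTL instrument selection and instrument-strength statistics.

For each protein the screen keeps a single top cis-SNP: variants in a
window around the encoding gene (default 1 Mb flank) are filtered on
minor-allele frequency and association p-value, LD-clumped, and the
smallest-p survivor becomes the instrument.  Instrument strength is
summarised by the variance explained

    R^2 = 2 * MAF * (1 - MAF) * (beta / sd)^2,   sd = se * sqrt(N)

and the F-statistic

    F = R^2 * (N - 1 - k) / ((1 - R^2) * k)

with k the number of instruments (k = 1 in this pipeline).  F < 10 flags a
potentially weak instrument.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from .sumstats import SumstatsTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRegion:
    """A gene's coordinates plus the cis flank defining its instrument window.

    Coordinates are 1-based inclusive; the cis interval is
    ``[start - cis_flank, end + cis_flank]`` clipped at 1.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    cis_flank: int = 1_000_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1")

    @property
    def cis_start(self) -> int:
        return max(1, self.start - self.cis_flank)

    @property
    def cis_end(self) -> int:
        return self.end + self.cis_flank


@dataclass(frozen=True)
class SelectionThresholds:
    """Filter cascade parameters for instrument selection."""

    pval_max: float = 5e-8
    maf_min: float = 0.01
    ld_r2_max: float = 0.8
    clump_window_kb: int = 10_000
    single_iv_pval_max: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.pval_max <= self.single_iv_pval_max < 1):
            raise ValueError("require 0 < pval_max <= single_iv_pval_max < 1")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if not (0 < self.ld_r2_max <= 1):
            raise ValueError("ld_r2_max must be in (0, 1]")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")


@dataclass(frozen=True)
class Instrument:
    """The selected top cis-SNP for a protein with strength statistics."""

    gene_id: str
    variant_id: str
    beta_exp: float
    se_exp: float
    eaf: float
    pval: float
    n: int
    r2: float
    f_stat: float
    k: int = 1
    relaxed: bool = False

    @property
    def weak(self) -> bool:
        return self.f_stat < 10.0


class LdLookup(Protocol):
    """Pairwise LD provider: returns r^2 in [0, 1] for two variant ids."""

    def r2(self, variant_a: str, variant_b: str) -> float: ...


class ExplicitLd:
    """LD lookup backed by an explicit symmetric r^2 mapping.

    Missing pairs raise ``KeyError`` — independence is never silently
    assumed for a pair the caller should know about.
    """

    def __init__(self, r2_map: dict[tuple[str, str], float]):
        self._map = {}
        for (a, b), v in r2_map.items():
            self._map[(a, b)] = float(v)
            self._map[(b, a)] = float(v)

    def r2(self, variant_a: str, variant_b: str) -> float:
        if variant_a == variant_b:
            return 1.0
        return self._map[(variant_a, variant_b)]


class Ar1Ld:
    """AR(1) LD along an ordered variant list: r(i, j) = rho^|i-j|.

    This is the LD contract emitted by the synthetic-data generator; real
    analyses plug in an :class:`ExplicitLd` (or any object with an ``r2``
    method) computed from a reference panel.
    """

    def __init__(self, variant_order: list[str], rho: float):
        if not (0.0 <= rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        self._index = {v: i for i, v in enumerate(variant_order)}
        self.rho = rho

    def r2(self, variant_a: str, variant_b: str) -> float:
        d = abs(self._index[variant_a] - self._index[variant_b])
        return self.rho ** (2 * d)


def cis_filter(table: SumstatsTable, region: GeneRegion) -> pd.DataFrame:
    """Variants of ``table`` on the gene's chromosome inside its cis interval.

    Boundaries are inclusive: a variant exactly ``cis_flank`` bp from a gene
    edge is retained.
    """
    df = table.df
    mask = (
        (df["chrom"] == region.chrom)
        & (df["pos"] >= region.cis_start)
        & (df["pos"] <= region.cis_end)
    )
    return df.loc[mask].reset_index(drop=True)


def ld_clump(
    records: pd.DataFrame,
    ld: LdLookup,
    r2_max: float = 0.8,
    window_kb: int = 10_000,
) -> pd.DataFrame:
    """Greedy LD clumping of single-chromosome records.

    Repeatedly keep the record with the smallest p-value (ties broken by
    smaller position), then remove every other record within ``window_kb``
    kilobases whose r^2 with it is >= ``r2_max``.  The output is sorted by
    p-value.  An LD lookup failure for an in-window pair is an error:
    independence is never silently assumed.
    """
    if records.empty:
        return records.copy()
    if records["chrom"].nunique() > 1:
        raise ValueError("ld_clump expects records from a single chromosome")
    pool = records.sort_values(["pval", "pos"], kind="mergesort").reset_index(drop=True)
    window_bp = window_kb * 1000
    kept: list[pd.Series] = []
    while not pool.empty:
        lead = pool.iloc[0]
        kept.append(lead)
        rest = pool.iloc[1:]
        in_window = (rest["pos"] - lead["pos"]).abs() <= window_bp
        drop_mask = np.zeros(len(rest), dtype=bool)
        for i, row in enumerate(rest.itertuples(index=False)):
            if not in_window.iloc[i]:
                continue
            try:
                r2 = ld.r2(lead["variant_id"], row.variant_id)
            except KeyError as exc:
                raise LookupError(
                    f"no LD value for in-window pair "
                    f"({lead['variant_id']}, {row.variant_id})"
                ) from exc
            drop_mask[i] = r2 >= r2_max
        pool = rest.loc[~drop_mask].reset_index(drop=True)
    return pd.DataFrame(kept).reset_index(drop=True)


def variance_explained(eaf: float, beta: float, se: float, n: float) -> float:
    """Proportion of trait variance explained by one variant.

    Uses MAF folding (``maf = min(eaf, 1 - eaf)``) and the standardized
    effect ``beta / (se * sqrt(n))``.  Values exceeding 1 (possible for
    pathological inputs) are clipped just below 1 with a warning.
    """
    if not (0.0 < eaf < 1.0):
        raise ValueError("eaf must be in (0, 1)")
    if se <= 0:
        raise ValueError("se must be > 0")
    if n <= 1:
        raise ValueError("n must exceed 1")
    maf = min(eaf, 1.0 - eaf)
    sd = se * math.sqrt(n)
    r2 = 2.0 * maf * (1.0 - maf) * (beta / sd) ** 2
    cap = 1.0 - 1e-12
    if r2 > cap:
        warnings.warn(f"variance_explained formula produced {r2:.3g} > 1; clipped")
        r2 = cap
    return r2


def f_statistic(r2: float, n: float, k: int = 1) -> float:
    """Instrument-strength F-statistic for k instruments jointly explaining r2."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must be in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("n must exceed k + 1")
    return r2 * (n - 1 - k) / ((1.0 - r2) * k)


def select_top_instrument(
    table: SumstatsTable,
    region: GeneRegion,
    thresholds: SelectionThresholds = SelectionThresholds(),
    ld: LdLookup | None = None,
) -> Instrument | None:
    """Select the top cis instrument for one protein, or ``None``.

    Filter cascade: cis window -> MAF -> p-value at ``pval_max`` (retried at
    ``single_iv_pval_max`` with ``relaxed=True`` when the primary threshold
    leaves nothing) -> greedy LD clumping -> smallest-p survivor.  Absence of
    any qualifying variant is a legitimate outcome, not an error.
    """
    cis = cis_filter(table, region)
    if cis.empty:
        logger.info("%s: no variants in cis window", region.gene_id)
        return None
    maf = np.minimum(cis["eaf"], 1.0 - cis["eaf"])
    cis = cis.loc[maf > thresholds.maf_min]
    if cis.empty:
        logger.info("%s: no variants pass MAF filter", region.gene_id)
        return None
    relaxed = False
    passing = cis.loc[cis["pval"] < thresholds.pval_max]
    if passing.empty:
        passing = cis.loc[cis["pval"] < thresholds.single_iv_pval_max]
        relaxed = True
        if passing.empty:
            logger.info("%s: no variants pass either p-value threshold", region.gene_id)
            return None
    if ld is not None and len(passing) > 1:
        passing = ld_clump(
            passing, ld, r2_max=thresholds.ld_r2_max, window_kb=thresholds.clump_window_kb
        )
    top = passing.sort_values(["pval", "pos"], kind="mergesort").iloc[0]
    r2 = variance_explained(top["eaf"], top["beta"], top["se"], top["n"])
    f = f_statistic(r2, top["n"], k=1)
    return Instrument(
        gene_id=region.gene_id,
        variant_id=top["variant_id"],
        beta_exp=float(top["beta"]),
        se_exp=float(top["se"]),
        eaf=float(top["eaf"]),
        pval=float(top["pval"]),
        n=int(top["n"]),
        r2=r2,
        f_stat=f,
        k=1,
        relaxed=relaxed,
    )


def read_gene_regions(path, cis_flank: int = 1_000_000, bed: bool = False) -> list[GeneRegion]:
    """Load gene regions from a tab-delimited file.

    Default format has a header ``gene_id chrom start end`` with 1-based
    inclusive coordinates (an optional ``rho`` column is ignored here).
    With ``bed=True`` the file is headerless BED (``chrom start end name``),
    0-based half-open, converted to 1-based inclusive on load.
    """
    if bed:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"],
            dtype={"chrom": str},
        )
        df["start"] = df["start"] + 1  # BED 0-based half-open -> 1-based inclusive
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneRegion(
            gene_id=str(r.gene_id), chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            cis_flank=cis_flank,
        )
        for r in df.itertuples(index=False)
    ]
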