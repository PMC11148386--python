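"""Synthetic regional GWAS summary statistics with LD structure.

Summary statistics are simulated directly on the z-score scale, without
individual-level genotypes: for a region of m variants with LD correlation
matrix R and standardized causal effect vector lambda, the expected z-scores
are sqrt(N) * R * lambda and the observed z-scores are multivariate normal
around them with covariance R.  Per-variant standard errors follow
1 / sqrt(2 * maf * (1 - maf) * N), so beta = z * se is on the familiar
per-allele scale (SD units for the protein, log-odds for the disease).

Scenarios cover the five colocalization hypotheses (H0-H4) plus a causal
protein -> disease configuration (MR_CAUSAL) in which the shared variant's
outcome effect equals theta times its exposure effect — exactly the
structure the Wald ratio estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import SUMSTAT_COLUMNS, SumstatsTable
from .mr import wald_pvalue

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4", "MR_CAUSAL")


@dataclass(frozen=True)
class SimScenario:
    """Generative specification for one synthetic region pair.

    Defaults describe a realistic cis-pQTL locus: 100 variants under
    moderate AR(1) LD (rho = 0.5), a strong protein effect (0.5 SD per
    allele) measured in a large plasma-proteomics cohort (n1 = 35,000), and
    a well-powered disease GWAS (n2 = 50,000 effective samples).
    """

    m: int = 100
    rho: float = 0.5
    hypothesis: str = "H4"
    causal_idx_1: int | None = None
    causal_idx_2: int | None = None
    beta_causal_1: float = 0.5
    beta_causal_2: float = 0.3
    theta: float = 0.3
    n1: int = 35_000
    n2: int = 50_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 5_000
    gene_id: str = "GENE"

    def __post_init__(self) -> None:
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0.01, 0.5]")

    def resolve(self) -> "SimScenario":
        """Fill in causal indices consistent with the hypothesis."""
        mid = self.m // 2
        c1, c2 = self.causal_idx_1, self.causal_idx_2
        if self.hypothesis in ("H1", "H3"):
            c1 = mid if c1 is None else c1
        if self.hypothesis in ("H2", "H3"):
            c2 = (self.m // 4 if self.hypothesis == "H3" else mid) if c2 is None else c2
        if self.hypothesis in ("H4", "MR_CAUSAL"):
            c1 = mid if c1 is None else c1
            c2 = c1 if c2 is None else c2
            if c1 != c2:
                raise ValueError(f"{self.hypothesis} requires a shared causal variant")
        if self.hypothesis == "H0":
            c1 = c2 = None
        if self.hypothesis == "H3" and c1 == c2:
            raise ValueError("H3 requires distinct causal variants")
        return replace(self, causal_idx_1=c1, causal_idx_2=c2)


def ar1_ld(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix: entry (i, j) = rho^|i-j| (positive definite)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must be in [0, 1)")
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _check_psd(ld: np.ndarray) -> np.ndarray:
    ld = np.asarray(ld, dtype=float)
    if ld.ndim != 2 or ld.shape[0] != ld.shape[1]:
        raise ValueError("LD matrix must be square")
    if not np.allclose(ld, ld.T, atol=1e-10):
        raise ValueError("LD matrix must be symmetric")
    w = np.linalg.eigvalsh(ld)
    if w.min() < -1e-8:
        raise ValueError(f"LD matrix is not positive semidefinite (min eigenvalue {w.min():.3g})")
    return ld


def _mvn_sqrt(ld: np.ndarray) -> np.ndarray:
    """Matrix square root for correlated noise; tolerant of tiny negative modes."""
    try:
        return np.linalg.cholesky(ld)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(ld)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _trait_sumstats(
    z: np.ndarray,
    maf: np.ndarray,
    n: int,
    variant_ids: list[str],
    chrom: str,
    pos: np.ndarray,
    effect_alleles: np.ndarray,
    other_alleles: np.ndarray,
) -> pd.DataFrame:
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    beta = z * se
    pvals = np.array([max(wald_pvalue(b, s), 5e-324) for b, s in zip(beta, se)])
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": effect_alleles,
            "other_allele": other_alleles,
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pval": pvals,
            "n": n,
        },
        columns=SUMSTAT_COLUMNS,
    )


def simulate_region(scn: SimScenario) -> tuple[SumstatsTable, SumstatsTable]:
    """Simulate one (exposure, outcome) summary-statistics pair.

    Deterministic given ``scn.seed``: the same scenario yields bit-identical
    tables.  The effect allele is simulated as the minor allele, so EAF
    equals MAF.
    """
    scn = scn.resolve()
    rng = np.random.default_rng(scn.seed)
    ld = _check_psd(ar1_ld(scn.m, scn.rho))
    chol = _mvn_sqrt(ld)

    maf = rng.uniform(scn.maf_range[0], scn.maf_range[1], size=scn.m)
    pos = scn.pos_start + scn.pos_step * np.arange(scn.m)
    variant_ids = [f"{scn.gene_id}_snp{i:04d}" for i in range(scn.m)]
    allele_pairs = np.array([("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")])
    pick = rng.integers(0, len(allele_pairs), size=scn.m)
    eff, oth = allele_pairs[pick, 0], allele_pairs[pick, 1]

    # standardized causal effects per trait
    lam1 = np.zeros(scn.m)
    lam2 = np.zeros(scn.m)
    scale = np.sqrt(2.0 * maf * (1.0 - maf))
    if scn.causal_idx_1 is not None:
        lam1[scn.causal_idx_1] = scn.beta_causal_1 * scale[scn.causal_idx_1]
    if scn.hypothesis == "MR_CAUSAL":
        if scn.causal_idx_1 is not None:
            lam2[scn.causal_idx_1] = scn.theta * scn.beta_causal_1 * scale[scn.causal_idx_1]
    elif scn.causal_idx_2 is not None:
        lam2[scn.causal_idx_2] = scn.beta_causal_2 * scale[scn.causal_idx_2]

    z1 = np.sqrt(scn.n1) * ld @ lam1 + chol @ rng.standard_normal(scn.m)
    z2 = np.sqrt(scn.n2) * ld @ lam2 + chol @ rng.standard_normal(scn.m)

    exp_df = _trait_sumstats(z1, maf, scn.n1, variant_ids, scn.chrom, pos, eff, oth)
    out_df = _trait_sumstats(z2, maf, scn.n2, variant_ids, scn.chrom, pos, eff, oth)
    exposure = SumstatsTable(trait_id=scn.gene_id, trait_type="quantitative", df=exp_df)
    outcome = SumstatsTable(trait_id="outcome", trait_type="binary", df=out_df)
    return exposure, outcome


def effective_n(case_n: int, control_n: int) -> float:
    """Effective GWAS sample size 4 / (1/cases + 1/controls) for a binary trait."""
    return 4.0 / (1.0 / case_n + 1.0 / control_n)


def child_seed(master_seed: int, index: int) -> int:
    """Per-protein seed derived from the master seed by a counter scheme."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_screen(
    n_proteins: int = 200,
    frac_causal: float = 0.05,
    theta: float = 0.4,
    n1: int = 20_000,
    n2: int = 50_000,
    m: int = 60,
    rho: float = 0.5,
    beta_causal: float = 0.5,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Simulate a proteome-wide screen: one cis region pair per protein.

    Every protein carries a genuine cis-pQTL (so an instrument exists); a
    fraction ``frac_causal`` of proteins additionally has a causal effect
    ``theta`` on the outcome (sign alternating between causal proteins), the
    rest have none.  Returns the in-memory dataset and a truth table
    ``(gene_id, true_theta)``; with ``out_dir`` the same layout the pipeline
    consumes is written to disk: ``exposure/<gene>.tsv``, ``outcome.tsv``,
    ``regions.tsv`` (with the per-region AR(1) ``rho``) and ``truth.tsv``.
    """
    if not (0.0 <= frac_causal <= 1.0):
        raise ValueError("frac_causal must be in [0, 1]")
    n_causal = int(round(n_proteins * frac_causal))
    exposures: dict[str, SumstatsTable] = {}
    outcome_parts = []
    regions = []
    truth = []
    for i in range(n_proteins):
        gene = f"PROT{i:04d}"
        chrom = str(i % 22 + 1)
        pos_start = 1_000_000 + 10_000_000 * (i // 22)
        causal = i < n_causal
        true_theta = theta * (1 if i % 2 == 0 else -1) if causal else 0.0
        scn = SimScenario(
            m=m,
            rho=rho,
            hypothesis="MR_CAUSAL",
            beta_causal_1=beta_causal,
            theta=true_theta,
            n1=n1,
            n2=n2,
            seed=child_seed(seed, i),
            chrom=chrom,
            pos_start=pos_start,
            gene_id=gene,
        )
        expo, outc = simulate_region(scn)
        exposures[gene] = expo
        outcome_parts.append(outc.df)
        regions.append(
            {
                "gene_id": gene,
                "chrom": chrom,
                "start": int(pos_start + (m // 2) * 5_000 - 5_000),
                "end": int(pos_start + (m // 2) * 5_000 + 5_000),
                "rho": rho,
            }
        )
        truth.append({"gene_id": gene, "true_theta": true_theta})

    outcome = SumstatsTable(
        trait_id="outcome",
        trait_type="binary",
        df=pd.concat(outcome_parts, ignore_index=True),
    )
    regions_df = pd.DataFrame(regions)
    truth_df = pd.DataFrame(truth)
    dataset = {
        "exposures": exposures,
        "outcome": outcome,
        "regions": regions_df,
        "truth": truth_df,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "exposure").mkdir(parents=True, exist_ok=True)
        for gene, table in exposures.items():
            table.df.to_csv(out_dir / "exposure" / f"{gene}.tsv", sep="\t", index=False,
                            float_format="%.17g")
        outcome.df.to_csv(out_dir / "outcome.tsv", sep="\t", index=False, float_format="%.17g")
        regions_df.to_csv(out_dir / "regions.tsv", sep="\t", index=False)
        truth_df.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return dataset
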