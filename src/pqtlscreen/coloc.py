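"""Bayesian colocalization of two association signals in a shared region.

Under a single-causal-variant assumption per trait, each SNP's evidence is a
Wakefield approximate Bayes factor computed from its effect estimate, its
standard error and a prior effect-size standard deviation W:

    log ABF = 1/2 * [ log(1 - r) + z^2 * r ],   r = W^2 / (W^2 + se^2)

Summing Bayes factors over causal configurations yields posterior
probabilities for five hypotheses:

    H0  no association with either trait
    H1  association with trait 1 only
    H2  association with trait 2 only
    H3  both traits, distinct causal variants
    H4  both traits, one shared causal variant

All sums run in log space: strong cis-pQTL signals reach log-ABFs of
several hundred nats and would overflow naive exponentiation.  Proteins are
ranked into drug-target credibility tiers from PPH4 (tier 1 above 0.8,
tier 2 between 0.5 and 0.8, tier 3 otherwise).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .instruments import GeneRegion
from .sumstats import SumstatsTable, harmonize, harmonized_pairs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColocConfig:
    """Priors and effect-size scales for colocalization.

    p1, p2 : prior probability a SNP is causal for trait 1 / trait 2.
    p12    : prior probability a SNP is causal for both.
    sd_prior_quant, sd_prior_binary : prior effect-size SD (W) for
        quantitative traits (SD units) and binary traits (log-odds).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    sd_prior_quant: float = 0.15
    sd_prior_binary: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.p12 < self.p1 < 1 and self.p12 < self.p2 < 1):
            raise ValueError("require 0 < p12 < p1 < 1 and p12 < p2 < 1")
        if self.sd_prior_quant <= 0 or self.sd_prior_binary <= 0:
            raise ValueError("prior effect-size SDs must be positive")

    def prior_sd(self, trait_type: str) -> float:
        return self.sd_prior_binary if trait_type == "binary" else self.sd_prior_quant


@dataclass(frozen=True)
class ColocResult:
    """Posterior hypothesis probabilities for one region/protein."""

    gene_id: str
    n_snps: int
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    tier: int

    @property
    def pph(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])


def wakefield_labf(beta, se, prior_sd: float):
    """Natural-log Wakefield approximate Bayes factor, vectorised over SNPs.

    Accepts scalars or arrays; ``se`` must be positive and ``prior_sd > 0``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + z**2 * r)
    return out if out.ndim else float(out)


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when the difference vanishes."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_posteriors(labf1, labf2, cfg: ColocConfig = ColocConfig(), gene_id: str = "") -> ColocResult:
    """Posterior probabilities of H0-H4 from aligned per-SNP log-ABF vectors.

    ``labf1`` and ``labf2`` must refer to the same SNPs in the same order.
    H3 (two distinct causal variants) uses the O(m) exclusion-sum identity
    sum_{i != j} BF1_i BF2_j = sum_i BF1_i (S2 - BF2_i) in log space; the
    leave-one-out sums are evaluated by logdiffexp except at a dominating
    SNP, where an explicit exclusion logsumexp avoids catastrophic
    cancellation.  With a single SNP there is no H3 configuration and PPH3
    is exactly 0.
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape or labf1.ndim != 1 or labf1.size == 0:
        raise ValueError("labf1 and labf2 must be equal-length non-empty 1-d vectors")
    m = labf1.size
    lsum1 = logsumexp(labf1)
    lsum2 = logsumexp(labf2)
    lsum12 = logsumexp(labf1 + labf2)

    lh0 = 0.0
    lh1 = np.log(cfg.p1) + lsum1
    lh2 = np.log(cfg.p2) + lsum2
    lh4 = np.log(cfg.p12) + lsum12
    if m == 1:
        lh3 = -np.inf
    else:
        # leave-one-out log-sums of trait-2 Bayes factors
        lexcl = np.array([_logdiffexp(lsum2, lb) for lb in labf2])
        dominant = labf2 - lsum2 > np.log(0.5)  # at most one index
        for i in np.flatnonzero(dominant):
            lexcl[i] = logsumexp(np.delete(labf2, i))
        ldiff = logsumexp(labf1 + lexcl)
        if not np.isfinite(ldiff):
            logger.warning("%s: H3 term vanished, clamped to 0", gene_id or "region")
        lh3 = np.log(cfg.p1) + np.log(cfg.p2) + ldiff

    lall = np.array([lh0, lh1, lh2, lh3, lh4])
    pph = np.exp(lall - logsumexp(lall))
    pph = pph / pph.sum()
    return ColocResult(
        gene_id=gene_id,
        n_snps=m,
        pph0=float(pph[0]),
        pph1=float(pph[1]),
        pph2=float(pph[2]),
        pph3=float(pph[3]),
        pph4=float(pph[4]),
        tier=assign_tier(float(pph[4])),
    )


def coloc_posteriors_enumerated(labf1, labf2, cfg: ColocConfig = ColocConfig()) -> np.ndarray:
    """Reference posteriors by explicit enumeration of causal configurations.

    Sums over all (m+1)^2 (trait-1 causal SNP or none, trait-2 causal SNP or
    none) configurations with per-configuration priors 1, p1, p2, p1*p2 and
    p12.  O(m^2); intended for small regions as an independent cross-check
    of :func:`coloc_posteriors`.
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    m = labf1.size
    terms: dict[int, list[float]] = {0: [0.0], 1: [], 2: [], 3: [], 4: []}
    for i in range(m):
        terms[1].append(np.log(cfg.p1) + labf1[i])
        terms[2].append(np.log(cfg.p2) + labf2[i])
        for j in range(m):
            if i == j:
                terms[4].append(np.log(cfg.p12) + labf1[i] + labf2[i])
            else:
                terms[3].append(np.log(cfg.p1) + np.log(cfg.p2) + labf1[i] + labf2[j])
    lh = np.array([
        logsumexp(terms[h]) if terms[h] else -np.inf for h in range(5)
    ])
    pph = np.exp(lh - logsumexp(lh))
    return pph / pph.sum()


def assign_tier(pph4: float) -> int:
    """Drug-target credibility tier from the shared-variant posterior.

    Tier 1 for PPH4 > 0.8, tier 2 for 0.5 < PPH4 <= 0.8, tier 3 otherwise;
    each boundary value resolves to the lower (less confident) tier.
    """
    if not (0.0 <= pph4 <= 1.0):
        raise ValueError("pph4 must be in [0, 1]")
    if pph4 > 0.8:
        return 1
    if pph4 > 0.5:
        return 2
    return 3


def coloc_region(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    region: GeneRegion,
    cfg: ColocConfig = ColocConfig(),
    palindrome_eaf_window: float = 0.08,
) -> ColocResult | None:
    """Colocalize a protein's cis region against the outcome signal.

    Harmonizes the two tables, restricts to the cis interval, computes
    per-trait log-ABFs with trait-type-appropriate prior SDs, and returns
    posteriors with the tier assignment.  Returns ``None`` (logged) when no
    shared variants survive harmonization.
    """
    harm = harmonize(exposure, outcome, palindrome_eaf_window=palindrome_eaf_window)
    pairs = harmonized_pairs(harm)
    pairs = pairs[
        (pairs["chrom"] == region.chrom)
        & (pairs["pos"] >= region.cis_start)
        & (pairs["pos"] <= region.cis_end)
    ]
    if pairs.empty:
        logger.warning("%s: no shared variants in region; colocalization skipped", region.gene_id)
        return None
    labf1 = wakefield_labf(
        pairs["beta_exp"].to_numpy(), pairs["se_exp"].to_numpy(), cfg.prior_sd(exposure.trait_type)
    )
    labf2 = wakefield_labf(
        pairs["beta_out"].to_numpy(), pairs["se_out"].to_numpy(), cfg.prior_sd(outcome.trait_type)
    )
    return coloc_posteriors(labf1, labf2, cfg, gene_id=region.gene_id)
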