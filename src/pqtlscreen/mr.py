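"""Single-instrument Wald-ratio Mendelian randomization.

With one genetic instrument the causal effect of exposure on outcome is the
Wald ratio b = beta_out / beta_exp, with first-order (delta-method) standard
error se_out / |beta_exp|.  For a binary outcome b is a log-odds ratio per
SD of exposure; exp(b) and exp(b +/- z* se) give the odds ratio and its
confidence interval.  Across a proteome-wide screen, significance is
controlled family-wise by Bonferroni correction (alpha / m proteins).

p-values are computed on the log scale so that extreme signals (|z| well
beyond 40, p below 1e-300) never underflow to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: exact two-sided 95% standard-normal quantile (not the 1.96 shorthand)
Z_975 = stats.norm.ppf(0.975)


class WaldRatioError(ValueError):
    """Raised when the Wald ratio is undefined (zero exposure effect)."""


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    second_order: bool = False,
) -> tuple[float, float]:
    """Wald-ratio causal estimate and standard error.

    The default first-order delta method ignores ``se_exp``, the standard
    single-instrument convention when the exposure association is strong
    (cis-pQTLs with large F).  ``second_order=True`` adds the exposure
    uncertainty term se^2 = se_out^2/beta_exp^2 + beta_out^2 se_exp^2 / beta_exp^4.
    """
    if beta_exp == 0:
        raise WaldRatioError("Wald ratio undefined: exposure effect is zero")
    b = beta_out / beta_exp
    if second_order:
        var = se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4
        se = math.sqrt(var)
    else:
        se = se_out / abs(beta_exp)
    return b, se


def or_ci(b: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio and symmetric (on the log scale) confidence interval."""
    if se <= 0:
        raise ValueError("se must be > 0")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    zstar = stats.norm.ppf(0.5 + level / 2.0)
    return math.exp(b), math.exp(b - zstar * se), math.exp(b + zstar * se)


def wald_pvalue(b: float, se: float) -> float:
    """Two-sided normal p-value for b/se, tail-accurate far beyond |z| = 40."""
    if se <= 0:
        raise ValueError("se must be > 0")
    z = abs(b / se)
    # logsf keeps precision where the survival function itself would underflow
    return float(np.exp(stats.norm.logsf(z) + math.log(2.0)))


def wald_log10_pvalue(b: float, se: float) -> float:
    """log10 of the two-sided p-value; finite even when the float p underflows."""
    if se <= 0:
        raise ValueError("se must be > 0")
    z = abs(b / se)
    return float((stats.norm.logsf(z) + math.log(2.0)) / math.log(10.0))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m for m tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1 or int(m) != m:
        raise ValueError("m must be a positive integer")
    return alpha / m


@dataclass(frozen=True)
class MrResult:
    """Wald-ratio estimate for one protein against the outcome."""

    gene_id: str
    variant_id: str
    b: float
    se: float
    pval: float
    log10_pval: float
    or_: float
    or_lci95: float
    or_uci95: float
    direction: str  # "risk_increasing" | "protective"
    significant: bool
    bonferroni_alpha: float
    relaxed: bool = False
    f_stat: float = float("nan")


def mr_result(
    gene_id: str,
    variant_id: str,
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    bonferroni_alpha: float = 0.05,
    relaxed: bool = False,
    f_stat: float = float("nan"),
    second_order: bool = False,
) -> MrResult:
    """Assemble a full :class:`MrResult` from harmonized effect estimates."""
    b, se = wald_ratio(beta_exp, se_exp, beta_out, se_out, second_order=second_order)
    p = wald_pvalue(b, se)
    or_, lo, hi = or_ci(b, se)
    return MrResult(
        gene_id=gene_id,
        variant_id=variant_id,
        b=b,
        se=se,
        pval=p,
        log10_pval=wald_log10_pvalue(b, se),
        or_=or_,
        or_lci95=lo,
        or_uci95=hi,
        direction="risk_increasing" if b > 0 else "protective",
        significant=p < bonferroni_alpha,
        bonferroni_alpha=bonferroni_alpha,
        relaxed=relaxed,
        f_stat=f_stat,
    )


@dataclass
class ScreenSummary:
    """Direction and significance counts across a proteome-wide screen."""

    n_tested: int
    n_positive: int
    n_negative: int
    n_significant: int
    alpha: float
    m: int
    threshold: float
    significant_genes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_significant": self.n_significant,
            "alpha": self.alpha,
            "m": self.m,
            "threshold": self.threshold,
            "significant_genes": self.significant_genes,
        }


def classify_screen(results: list[MrResult], alpha: float = 0.05, m: int | None = None) -> ScreenSummary:
    """Summarise a screen: direction counts and the Bonferroni-significant set.

    ``m`` defaults to the number of tested proteins, i.e. the number of
    results; the significant set is ordered by ascending p-value.
    """
    if not results:
        raise ValueError("classify_screen: empty results")
    if m is None:
        m = len(results)
    threshold = bonferroni_threshold(alpha, m)
    positive = sum(1 for r in results if r.b > 0)
    negative = sum(1 for r in results if r.b < 0)
    sig = sorted((r for r in results if r.pval < threshold), key=lambda r: (r.pval, r.gene_id))
    return ScreenSummary(
        n_tested=len(results),
        n_positive=positive,
        n_negative=negative,
        n_significant=len(sig),
        alpha=alpha,
        m=m,
        threshold=threshold,
        significant_genes=[r.gene_id for r in sig],
    )
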