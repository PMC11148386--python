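"""Bundled reference tables.

Two small published reference tables from a proteome-wide ankylosing
spondylitis drug-target screen (FinnGen outcome, 2,860 cases / 270,964
controls; plasma cis-pQTL exposures) ship with the package:

* the Wald-ratio MR estimates for the 18 Bonferroni-significant plasma
  proteins (b, se, p, OR with 95% CI), and
* their colocalization posterior probabilities (PPH0-PPH4 per protein).

They serve as self-consistency anchors — every OR/CI/p column is
re-derivable from (b, se) alone, and tiers are re-derivable from PPH4 —
and as small worked-example inputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: number of proteins tested in the published screen (Bonferroni family size)
PUBLISHED_SCREEN_M = 1654
#: outcome GWAS case/control split of the published screen
PUBLISHED_CASE_N = 2860
PUBLISHED_CONTROL_N = 270_964


def _load(name: str) -> pd.DataFrame:
    with resources.files("pqtlscreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_mr_top_hits() -> pd.DataFrame:
    """The 18 Bonferroni-significant Wald-ratio MR rows (published screen)."""
    return _load("as_mr_top18.tsv")


def load_coloc_top_hits() -> pd.DataFrame:
    """Colocalization posteriors (PPH0-PPH4) for the same 18 proteins."""
    return _load("as_coloc_top18.tsv")
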