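"""End-to-end proteome-wide screen: instruments -> Wald MR -> Bonferroni -> coloc.

For each protein the pipeline selects the top cis instrument, harmonizes it
against the outcome GWAS, and computes the Wald-ratio estimate.  After all
proteins are processed, the Bonferroni threshold uses m = number of proteins
actually tested; colocalization then runs on the Bonferroni-significant set
(optionally on everything) and assigns drug-target tiers.  Failures are
isolated per protein, and a manifest records a status for every input
protein so the filter cascade is auditable.
"""

from __future__ import annotations

import glob
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coloc import ColocConfig, ColocResult, coloc_posteriors, wakefield_labf
from .instruments import (
    Ar1Ld,
    GeneRegion,
    SelectionThresholds,
    select_top_instrument,
)
from .mr import MrResult, ScreenSummary, classify_screen, mr_result
from .sumstats import (
    SumstatsTable,
    harmonize,
    harmonized_pairs,
    read_sumstats,
    write_results_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full screen run."""

    exposure_glob: str
    outcome_path: str
    regions_path: str
    out_dir: str
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    coloc_config: ColocConfig = field(default_factory=ColocConfig)
    alpha: float = 0.05
    cis_flank: int = 1_000_000
    palindrome_eaf_window: float = 0.08
    coloc_all: bool = False
    seed: int = 0
    outcome_case_n: int | None = None
    outcome_control_n: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thresholds = SelectionThresholds(**raw.pop("thresholds", {}))
        coloc_cfg = ColocConfig(**raw.pop("coloc", {}))
        return cls(thresholds=thresholds, coloc_config=coloc_cfg, **raw)

    def validate(self) -> None:
        if not glob.glob(self.exposure_glob):
            raise FileNotFoundError(f"no exposure files match {self.exposure_glob}")
        for p in (self.outcome_path, self.regions_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _load_regions(path: str | Path, cis_flank: int) -> tuple[dict[str, GeneRegion], dict[str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    regions = {}
    rhos = {}
    for r in df.itertuples(index=False):
        regions[str(r.gene_id)] = GeneRegion(
            gene_id=str(r.gene_id), chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            cis_flank=cis_flank,
        )
        if hasattr(r, "rho"):
            rhos[str(r.gene_id)] = float(r.rho)
    return regions, rhos


def run_screen(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full screen; returns (mr_table, coloc_table, manifest).

    Deterministic given inputs and configuration: re-running with the same
    config produces byte-identical output tables.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    outcome = read_sumstats(
        cfg.outcome_path,
        trait_type="binary",
        trait_id="outcome",
        case_n=cfg.outcome_case_n,
        control_n=cfg.outcome_control_n,
    )
    regions, rhos = _load_regions(cfg.regions_path, cfg.cis_flank)

    statuses: dict[str, dict] = {}
    mr_results: list[MrResult] = []
    harmonized_cache: dict[str, pd.DataFrame] = {}
    exposure_paths = sorted(glob.glob(cfg.exposure_glob))

    for path in exposure_paths:
        gene = Path(path).stem
        try:
            if gene not in regions:
                statuses[gene] = {"status": "no_region", "reason": "gene absent from regions file"}
                continue
            exposure = read_sumstats(path, trait_type="quantitative", trait_id=gene)
            harm = harmonize(exposure, outcome, cfg.palindrome_eaf_window)
            pairs = harmonized_pairs(harm)
            if pairs.empty:
                statuses[gene] = {"status": "no_instrument",
                                  "reason": "no variants shared with outcome"}
                continue
            # instrument must be measurable in the outcome: restrict selection
            # to variants that survived harmonization
            shared = exposure.df[exposure.df["variant_id"].isin(pairs["variant_id"])]
            shared_table = SumstatsTable(gene, "quantitative", shared)
            ld = Ar1Ld(list(shared["variant_id"]), rhos[gene]) if gene in rhos else None
            inst = select_top_instrument(shared_table, regions[gene], cfg.thresholds, ld)
            if inst is None:
                statuses[gene] = {"status": "no_instrument",
                                  "reason": "no variant passed the filter cascade"}
                continue
            pair = pairs.set_index("variant_id").loc[inst.variant_id]
            res = mr_result(
                gene_id=gene,
                variant_id=inst.variant_id,
                beta_exp=inst.beta_exp,
                se_exp=inst.se_exp,
                beta_out=float(pair["beta_out"]),
                se_out=float(pair["se_out"]),
                relaxed=inst.relaxed,
                f_stat=inst.f_stat,
            )
            mr_results.append(res)
            harmonized_cache[gene] = pairs
            statuses[gene] = {
                "status": "tested",
                "variant_id": inst.variant_id,
                "f_stat": inst.f_stat,
                "weak_instrument": inst.weak,
                "relaxed_pval_threshold": inst.relaxed,
            }
        except Exception as exc:  # single-protein failures must not kill the screen
            logger.exception("%s: protein-level failure, skipping", gene)
            statuses[gene] = {"status": "failed", "reason": str(exc)}

    coloc_results: list[ColocResult] = []
    summary: ScreenSummary | None = None
    if mr_results:
        m = len(mr_results)
        summary = classify_screen(mr_results, alpha=cfg.alpha, m=m)
        threshold = summary.threshold
        # re-evaluate significance at the screen-level threshold
        mr_results = [
            MrResult(**{**r.__dict__, "significant": r.pval < threshold,
                        "bonferroni_alpha": threshold})
            for r in mr_results
        ]
        to_coloc = [r for r in mr_results if cfg.coloc_all or r.significant]
        for res in to_coloc:
            gene = res.gene_id
            pairs = harmonized_cache[gene]
            region = regions[gene]
            in_region = pairs[
                (pairs["chrom"] == region.chrom)
                & (pairs["pos"] >= region.cis_start)
                & (pairs["pos"] <= region.cis_end)
            ]
            if in_region.empty:
                statuses[gene]["coloc"] = "skipped: no shared variants in region"
                continue
            labf1 = wakefield_labf(
                in_region["beta_exp"].to_numpy(), in_region["se_exp"].to_numpy(),
                cfg.coloc_config.prior_sd("quantitative"),
            )
            labf2 = wakefield_labf(
                in_region["beta_out"].to_numpy(), in_region["se_out"].to_numpy(),
                cfg.coloc_config.prior_sd("binary"),
            )
            cres = coloc_posteriors(labf1, labf2, cfg.coloc_config, gene_id=gene)
            coloc_results.append(cres)
            statuses[gene]["coloc_tier"] = cres.tier
            statuses[gene]["pph4"] = cres.pph4

    mr_table = pd.DataFrame(
        {
            "id.exposure": [r.gene_id for r in mr_results],
            "b": [r.b for r in mr_results],
            "se": [r.se for r in mr_results],
            "P-val": [r.pval for r in mr_results],
            "or": [r.or_ for r in mr_results],
            "or_lci95": [r.or_lci95 for r in mr_results],
            "or_uci95": [r.or_uci95 for r in mr_results],
        }
    )
    coloc_table = pd.DataFrame(
        {
            "Protein": [r.gene_id for r in coloc_results],
            "N_SNPs": [r.n_snps for r in coloc_results],
            "PPH0": [r.pph0 for r in coloc_results],
            "PPH1": [r.pph1 for r in coloc_results],
            "PPH2": [r.pph2 for r in coloc_results],
            "PPH3": [r.pph3 for r in coloc_results],
            "PPH4": [r.pph4 for r in coloc_results],
        }
    )

    manifest = {
        "tool_version": __version__,
        "config": {
            "exposure_glob": cfg.exposure_glob,
            "outcome_path": cfg.outcome_path,
            "regions_path": cfg.regions_path,
            "alpha": cfg.alpha,
            "cis_flank": cfg.cis_flank,
            "palindrome_eaf_window": cfg.palindrome_eaf_window,
            "coloc_all": cfg.coloc_all,
            "seed": cfg.seed,
            "thresholds": cfg.thresholds.__dict__,
            "coloc_priors": {
                "p1": cfg.coloc_config.p1,
                "p2": cfg.coloc_config.p2,
                "p12": cfg.coloc_config.p12,
            },
        },
        "n_proteins_input": len(exposure_paths),
        "bonferroni_m": len(mr_results),
        "bonferroni_threshold": summary.threshold if summary else None,
        "summary": summary.as_dict() if summary else None,
        "proteins": statuses,
    }

    if len(mr_results):
        write_results_table(mr_results, out_dir / "mr_results.tsv")
    else:
        mr_table.to_csv(out_dir / "mr_results.tsv", sep="\t", index=False)
    if len(coloc_results):
        write_results_table(coloc_results, out_dir / "coloc_results.tsv")
    else:
        coloc_table.to_csv(out_dir / "coloc_results.tsv", sep="\t", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return mr_table, coloc_table, manifest


def _json_default(obj):
    try:
        return bool(obj) if isinstance(obj, (bool,)) else float(obj)
    except Exception:
        return str(obj)


def summarize(mr_table: pd.DataFrame, alpha: float = 0.05, m: int | None = None) -> dict:
    """Screen-level summary of an MR results table.

    Reports totals, direction counts, the Bonferroni-significant count and
    the top hits by p-value; an empty table yields an explicit empty
    summary rather than an error downstream.
    """
    if mr_table.empty:
        return {"n_tested": 0, "n_positive": 0, "n_negative": 0,
                "n_significant": 0, "top_hits": []}
    if m is None:
        m = len(mr_table)
    threshold = alpha / m
    positive = int((mr_table["b"] > 0).sum())
    negative = int((mr_table["b"] < 0).sum())
    sig = mr_table[mr_table["P-val"] < threshold].sort_values("P-val")
    top = mr_table.sort_values("P-val").head(10)
    return {
        "n_tested": int(len(mr_table)),
        "n_positive": positive,
        "n_negative": negative,
        "n_significant": int(len(sig)),
        "alpha": alpha,
        "m": m,
        "threshold": threshold,
        "significant_genes": sig["id.exposure"].tolist(),
        "top_hits": [
            {"gene": r["id.exposure"], "b": float(r["b"]), "or": float(r["or"]),
             "pval": float(r["P-val"])}
            for _, r in top.iterrows()
        ],
    }
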