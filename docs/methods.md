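# Methods

## Scope and data model

`pqtlscreen` screens circulating proteins for causal effects on a binary
disease outcome using only GWAS summary statistics: one table per protein
(cis region around the encoding gene) and one outcome table. Tables are
validated on load (single-nucleotide alleles, 0 < EAF < 1, se > 0,
p ∈ (0, 1], unique variant ids) and sorted by (chromosome, position);
coordinates are 1-based inclusive throughout. BED input for gene regions is
converted from 0-based half-open on load. Malformed rows are rejected with
a per-row reason and counted, never silently dropped.

## Harmonization

Exposure and outcome are matched by variant id (rsID). Outcome effects are
aligned to the exposure effect allele: identical allele pairs pass
unchanged; swapped pairs negate β_out and take 1−EAF; strand-complement
pairs are resolved by complementing first. Palindromic variants (A/T, C/G)
carry no strand information in their labels, so they are oriented purely by
allele frequency, and dropped as ambiguous whenever either trait's EAF lies
within a window (default 0.08) of 0.5. The window default is the common
two-sample MR convention; it is configurable because the appropriate value
depends on the ancestry match between studies. Every exposure variant
appears in the harmonization output exactly once, kept or with a drop
reason, so the filter cascade is fully auditable.

## Instrument selection

The cascade per protein: cis window (gene interval ± 1 Mb flank, boundaries
inclusive, clipped at position 1) → MAF > 0.01 → P < 5e-8 → greedy LD
clumping (keep the smallest-p variant, ties broken by smaller position;
remove in-window variants with r² ≥ 0.8; window 10,000 kb) → smallest-p
survivor. When the genome-wide threshold leaves nothing, selection retries
at P < 1e-5 and records `relaxed=True`, keeping the provenance of the
looser single-instrument criterion separate from the primary one. An LD
lookup failure for an in-window pair is an error: independence is never
assumed silently. Because the clump leader is always the smallest-p
variant, the selected top instrument is invariant to the LD source; the LD
provider is pluggable (explicit r² matrix, or the AR(1) contract the
simulator emits) and matters only when multiple instruments are retained.

Instrument strength: R² = 2·MAF(1−MAF)(β/sd)², sd = se·√N, with MAF folded
as min(EAF, 1−EAF) because input records carry effect-allele frequency.
R² values above 1 (possible only for inconsistent inputs) are clipped just
below 1 with a warning. F = R²(N−1−k)/((1−R²)k) is implemented for general
k although the screen fixes k = 1; F < 10 marks the instrument weak.

## Wald-ratio MR

b = β_out/β_exp, se = se_out/|β_exp| (first-order delta method). The
first-order form ignores exposure-side uncertainty — the no-measurement-
error convention, appropriate for strong cis-pQTLs where |β_exp|/se_exp is
large. A `second_order=True` flag adds the β_out²·se_exp²/β_exp⁴ term.
Consequence, quantified by the replicate experiments in the acceptance
checks: at the default simulation conditions (exposure z ≈ 40) first-order
95% intervals cover the true effect in roughly 93–95% of replicates; the
residual undercoverage is the neglected exposure-error term and shrinks
with instrument strength.

p-values are two-sided normal, computed from the log survival function, so
|z| ≈ 25 (p ≈ 1e-134) and far beyond remain exact; a log10(p) accessor
covers tails past the float underflow limit (|z| > 40). The 95% CI uses
the exact 0.975 quantile (1.959964…), not 1.96. Bonferroni control uses
α/m with m = proteins actually tested in the run, recorded in the manifest.

## Colocalization

Per-SNP Wakefield log approximate Bayes factors,
log ABF = ½[log(1−r) + z²r] with r = W²/(W²+se²), with prior effect-size
SD W = 0.15 for quantitative traits and 0.2 for binary traits (the
conventional defaults), and configuration priors p1 = p2 = 1e-4,
p12 = 1e-5. Hypothesis sums run entirely in log space. H3 (distinct causal
variants) uses the exclusion-sum identity Σ_{i≠j} BF1_i BF2_j =
Σ_i BF1_i(S2 − BF2_i); each leave-one-out sum is a logdiffexp except at a
SNP holding more than half of S2's mass, where an explicit exclusion
logsumexp avoids the catastrophic cancellation that a plain
S1·S2 − S12 subtraction incurs when one SNP dominates both traits. A
brute-force enumeration over all (m+1)² causal-configuration pairs is
retained as an independent cross-check and agrees to 1e-10 relative error
on small regions. With m = 1 no H3 configuration exists and PPH3 is
exactly 0.

Tier rule: PPH4 > 0.8 → tier 1, 0.5 < PPH4 ≤ 0.8 → tier 2, else tier 3.
The published rule leaves the boundary values unspecified; both resolve
here to the lower-confidence tier. Colocalization regions default to the
instrument-selection cis window; the screen colocalizes only
Bonferroni-significant proteins unless `coloc_all` is set.

## Synthetic data

Regional summary statistics are drawn directly on the z-score scale:
z ~ N(√N·R·λ, R) with R the AR(1) correlation matrix (entry ρ^|i−j|,
always positive definite) and λ the standardized causal effects
(β·√(2·maf(1−maf)) at causal indices). Per-variant se = 1/√(2·maf(1−maf)N)
converts z to per-allele β. This is the standard multivariate-normal
summary-statistics model: exact for quantitative traits under
Hardy-Weinberg, and a good approximation for binary traits on the log-odds
scale with N interpreted as effective sample size
(4/(1/cases + 1/controls) for imbalanced designs, available as
`effective_n`).

Scenario defaults, chosen once as a realistic cis-pQTL locus: m = 100
variants, ρ = 0.5, MAF ~ U(0.05, 0.5), causal protein effect 0.5 SD per
allele, exposure N = 35,000 (the scale of current plasma-proteomics
cohorts, where the strong-instrument assumption behind the first-order
Wald SE holds), outcome N = 50,000, causal protein→disease effect
θ = 0.3. The screen generator gives every protein a true cis-pQTL and a
fraction of proteins (default 5% of 200) a causal effect θ = ±0.4 with
alternating sign, exposure N = 20,000, 60 variants per region — sized so
the full pipeline runs in seconds while leaving instrument discovery and
Bonferroni significance unsaturated. Simulated p-values are floored at
5e-324 (the smallest positive float) to stay within (0, 1]; ordering among
such extreme variants falls back to position, which leaves Wald estimates
unaffected because under the generative model the ratio β_out/β_exp equals
θ at every variant tagging the causal SNP.

Seeding: one master seed; per-protein children derived via
`SeedSequence(master, spawn_key=(i,))`, reproducible under any execution
order. Re-running any simulation or the whole pipeline with the same seed
and config is byte-identical.

What the generator does not emulate: genotype panels and realistic LD
blocks (AR(1) only), population stratification, trans effects, horizontal
pleiotropy, sample overlap between exposure and outcome, allele-frequency
mismatch between studies, strand errors, and case-control ascertainment
beyond the effective-N approximation. Passing tests therefore demonstrate
the statistical machinery is correct under the stated model, not that real
screens are free of pleiotropy or winner's-curse biases.

## Pipeline

Per protein: read → harmonize against the outcome → restrict instrument
selection to variants measurable in the outcome → select instrument →
Wald ratio. Any single-protein failure is caught, logged and recorded; the
screen continues. After all proteins, m = number tested sets the Bonferroni
threshold, significance flags are finalised, and colocalization runs on the
significant set. Outputs: `mr_results.tsv` (columns
`id.exposure b se P-val or or_lci95 or_uci95`), `coloc_results.tsv`
(columns `Protein N_SNPs PPH0 PPH1 PPH2 PPH3 PPH4`), and `manifest.json`
whose per-protein statuses (tested / no_instrument / no_region / failed,
plus coloc tier for colocalized proteins) partition the input list.

## Numerical and edge-case choices

- Zero exposure effect → explicit Wald-ratio error, never inf.
- Zero overlapping variants at harmonization → empty result with a
  warning, not an exception; a region with no shared variants skips
  colocalization with a logged reason.
- Equal p-values tie-break on smaller position everywhere, making all
  outputs deterministic.
- Uniform-[−10, 50+] log-ABF stress inputs and 900-nat signals are exercised
  in tests to confirm log-space stability.

## Known limitations

- Single-instrument Wald ratio only; multi-SNP estimators (IVW, Egger,
  weighted median) are out of scope, as is SuSiE-style multi-causal
  colocalization.
- The published screen's full-size counts (1,654 proteins tested, 868/786
  direction split, the exact PPH values of its Table of colocalization
  results) depend on the complete external pQTL and FinnGen datasets and
  are not reproducible from summary fixtures; the package reproduces the
  derivable quantities (OR/CI/p reconstruction, threshold, direction
  counts among the 18 hits, tier mapping) exactly and substitutes
  simulation-based operating characteristics for the rest.
- H3 vs H4 discrimination degrades as LD between the two causal variants
  rises; the simulator's H3 tests use low-LD configurations deliberately,
  and real-data users should treat PPH3/PPH4 splits in high-LD regions
  with caution.
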