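# Methods

This note documents the models implemented in `mtaging`, the conventions and
numerical choices behind them, what the synthetic-cohort generator does and
does not emulate, and the known limitations.

## Reference genome and feature catalog

All coordinates are 1-based inclusive on the revised Cambridge Reference
Sequence (rCRS, NC_012920.1; 16,569 bp, with the historical placeholder `N`
at position 3,107). The vendored copy was cross-validated against a battery
of independent anchors before being frozen: clean translation of all 13
protein-coding genes under the vertebrate mitochondrial code (correct start
codons, no internal stops, terminal stops completed by polyadenylation),
the canonical 13-bp common-deletion repeat `ACCTCCCTCACCA` at exactly
8,470–8,482 and 13,447–13,459, the documented reference alleles at several
dozen well-known variant positions, and the genome length and base
composition. Circularity is handled by allowing "wrapping" spans
(`start > end`), permitted for the control region and for deletion spans.

The catalog hard-codes the standard rCRS coordinates for the 13 proteins
(with complex assignments: 7 genes in Complex I, MT-CYB alone in III, the
three MT-CO genes in IV, MT-ATP6/8 in V), 22 tRNAs, 2 rRNAs, the two
replication origins (OH 110–441, OL 5,721–5,798), the control region
(16,024–576) and 11 microprotein ORFs. Feature spans sum to 1,141 bp for
Complex III, 3,010 bp for IV, 888 bp for V and 6,356 bp for Complex I. Some
published round-ups quote Complex I as 6,536 bp; that figure is
inconsistent with the standard per-gene coordinates (it transposes two
digits of the coordinate sum), so the package reports the computed 6,356 bp.

Microprotein coordinates: mtALTND4 (11,557–11,856), SHMOOSE (12,234–12,410)
and gau (6,288–6,590) are as reported in the microprotein literature; an
occasionally seen "122,410" for the SHMOOSE end is an obvious typographical
slip for 12,410 (a <100 aa ORF inside MT-ND5). Humanin, MOTS-c and SHLP1–6
lie inside the two rRNA genes between positions 1,343 and 3,052; only that
enclosing range is firmly established across sources, so the per-ORF spans
used here are representative literature values constrained to it. All
analyses aggregate at the whole-ORF level, so modest uncertainty in those
eight spans does not move any reported number.

The minor arc is the short span bounded by the OH-bearing control region and
OL (operationally: features wholly inside 442–5,798); everything else is
major arc. This reproduces the standard assignment — the rRNA-hosted
microproteins minor-arc, gau/mtALTND4/SHMOOSE major-arc — and the major arc
is where the deletion catalog lives.

## Deletion conventions and burden metrics

A junction is reported as `(bp5, bp3)` = (last retained 5′ base, first
retained 3′ base); the deleted span is `[bp5+1, bp3−1]` and the size
`bp3 − bp5 − 1`. This convention makes the common deletion (8,471, 13,449)
the familiar 4,977-bp event. Junctions wrapping the origin are accepted,
flagged, and sized circularly.

Per-sample metrics: deletions per 10k coverage (unique junctions /
benchmark × 10⁴), cumulative deletion read % (sum of per-junction read
percents), the <1 kb / ≥1 kb split of that sum, the catalog ("Top 30")
read %, and the common-deletion read %. "Unique junctions" counts distinct
`(bp5, bp3)` pairs with no minimum-read filter by default (a configurable
floor exists); duplicate rows for one junction are merged by summing read
support. Only the common deletion ships in the default Top-30 catalog —
it is the only member with universally published exact breakpoints — and a
study-specific catalog can be supplied as JSON (`{"junctions": [[bp5, bp3],
...]}`); Top-30 membership is matched by exact junction. Impact annotation
classifies a deletion as affecting a complex when its deleted span removes
or truncates any member gene; tRNA and microprotein impact follow the same
remove-or-truncate rule. Percentages are kept on the 0–100 scale
throughout.

## Junction direct repeats

The repeat associated with a junction is defined on the *junction
diagonal*: compare `seq[bp5 + t]` with `seq[bp3 − 1 + t]` for offsets
`|t| ≤ w` (default `w = 15`) and take the longest run of consecutive
matches; `N` never matches, matching is case-insensitive, and ties between
equally long runs go to the leftmost (most 5′) run. The shared offset is
the substantive choice: in the deleted molecule the two flanks are joined
in register, so only equally shifted substring pairs can mediate the
mispairing that forms the deletion. A free search over all substring pairs
in the two windows (which we also implemented as the test oracle's
enumeration baseline) picks up unrelated coincidental matches a few bases
away and fails to show the allele effects; the diagonal definition
reproduces all three published (reference, alternate) pairs — (6,7) for
T14798C at 7,816–14,807, (7,3) for G12372A at 12,369–14,004, (8,5) for
C14766T at 8,775–14,771 — including the exact underlined motifs. The
15-bp window comfortably covers reported repeat motifs (~6–22 nt) while
staying local to the breakpoints; it is configurable. Windows may not
cross the genome ends unless circular wrapping is enabled (no analysed
junction is near the origin).

## SNVs, haplogroups, copy number

Variant calls are classed by the caller's variant allele frequency:
homoplasmic at VAF ≥ 0.9 (boundary inclusive), heteroplasmic for
0.1 < VAF < 0.9, excluded at or below 0.1. ("Minor allele frequency ≥ 0.9"
in common usage of these thresholds can only mean the variant allele's
frequency; a literal minor-allele frequency cannot reach 0.9.) Counting is
per distinct (position, alternate allele); substitutions only. The binary
genotype matrix used by the association scan is 1 iff a homoplasmic call
exists for (sample, position, alt). Haplogroup stratification is purely
label-based: labels starting with H, V or HV are "HV", everything else
"Non-HV" — K, J, T and U remain Non-HV regardless of phylogenetic descent,
matching the coarse dichotomy's intent (genetic similarity to the
H-lineage-derived rCRS). Copy number per diploid cell is
`2 × MT depth / autosomal depth`, consuming precomputed mean depths; it is
invariant to joint depth rescaling.

## Statistics

* **OLS** via statsmodels with two-sided t tests. A constant response is
  reported as zero slopes with p = 1 (no evidence), and constant design
  columns raise immediately.
* **Exponential (log-linear) regression** is OLS on `ln(metric + 0.01)`;
  the 0.01 pseudo-count represents a burden below any observable read %.
  Age-bin changes are `exp(η(a+15)) − exp(η(a))` with covariates fixed at
  their sample means by default (the covariate profile is configurable;
  for a linear fit the bin change is just slope × 15).
* **Rank-based regression**: Jaeckel dispersion with Wilcoxon scores,
  minimised by a derivative-free Powell search started at the OLS solution
  (the objective is convex piecewise-linear; the optimiser's final value is
  checked against the start and failure raises with diagnostics;
  tolerances 1e-10/1e-12). The intercept is the median of residuals. Wald
  SEs use τ = [√12 ∫f²]⁻¹ with ∫f² estimated by a Gaussian-kernel density
  overlap on the fitted residuals and a √(n/(n−p−1)) small-sample
  correction; intercept inference uses the sign-score scale 1/(2f̂(0)).
  Different τ estimators (window widths, kernels) shift p-values slightly;
  slopes are unaffected. With a single binary predictor the slope equals
  the Hodges–Lehmann two-sample shift, which the tests verify, and under
  Normal errors the SE ratio to OLS matches the asymptotic √(π/3).
* **Kruskal–Wallis / Dunn**: tie-corrected H from scipy; Dunn z uses the
  standard pooled-rank variance with tie term, Bonferroni-adjusted across
  all pairs. All-identical pooled data short-circuits to H = 0, p = 1.
* **2×2 chi-squared** uses Yates' continuity correction (capped at zero),
  requiring non-negative integer cells and positive margins.
* **Multiplicity** is Bonferroni only (α/m), recomputed within each brain
  region for the association scan.

## MT-GWAS

Eligible pairs require, within a region: ≥ 10 carriers of the exact
junction (≥ 1 supporting read), ≥ 10 samples in each homoplasmic allele
class, and SNP-to-nearest-breakpoint distance ≤ 10 bp. Each pair is fitted
as `SNP presence/absence ~ deletion read % + benchmark coverage + age +
sex` — the binary variant as response, which mirrors how such scans are
reported even though the reverse orientation is more conventional (a flag
exposes the reverse model for sensitivity checks). Samples without the
deletion contribute read % 0. Pairs with a constant response in the region
are reported untestable but still count toward the Bonferroni denominator.
The report joins each association's sign with the repeat-length change of
its SNP and flags mechanistic consistency: the allele with the longer
perfect repeat should carry more of the deletion.

## Synthetic cohort generator

The generator emulates the data *structure* of a two-region postmortem
brain WGS study — 143 frontal cortex (FC) and 149 cerebellum (CER) samples,
ages uniform on 0.4–100 y, balanced sexes, HV fractions 60/143 and 72/149 —
with these calibration anchors:

* **Copy number**: region means 4,536.8 (FC) and 1,367.2 (CER) (a 3.318
  contrast) with SDs 1,376.7/687.7 and linear age slopes of −193.23 and
  −37.14 copies per 15 y; the age-slope variance share is removed from the
  residual SD so the marginal SD matches the target. Coverage summaries
  are emitted as autosomal depth ~ Normal(34.28, 4.04) with MT depth
  back-computed from the copy number.
* **Deletions**: a fixed 50-junction catalog (deterministic, including the
  common deletion and the three repeat-mechanism junctions) with rank-decay
  weights; FC draws 80% of junction picks from the ≥1 kb class, CER 20%.
  Per sample, cumulative read % follows `exp(c0_region + b1·age + ε) −
  0.01` truncated at 0 with ε ~ N(0, 1), and the unique-junction count is
  Poisson with rate `exp(a0_region + b1·age) · benchmark/10⁴`; intercepts
  are solved in closed form so the cohort means hit 0.780%/0.135%
  (cumulative) and 9.759/3.189 (deletions per 10k). The shared exponential
  slope is b1 = ln 2 / 26 ≈ 0.0267/y, chosen once so a 60–75 y bin gains
  more than twice a 30–45 y bin. Reads are integers: the cumulative mass
  is converted to a read total (rounding to zero is the detection limit
  and the source of zero-inflation), every detected junction gets at least
  one read, and at least one junction exists whenever there are reads to
  carry — reads must land on some junction; without that constraint the
  observation layer would silently discard generated burden in young
  samples and bias slope-recovery tests upward. Benchmark coverage is
  ~N(10,000, 1,200), a deliberately scaled depth at which the Poisson
  count calibration and the 50-junction catalog are compatible across the
  whole age range.
* **SNVs**: homoplasmic counts per sample are Normal draws by region ×
  haplogroup category (33.89/31.03 Non-HV, 11.93/11.71 HV), realised as a
  uniform subset of a fixed ~70-site marker pool that includes the three
  repeat-modulating SNPs and a handful of sites placed within 10 bp of
  catalog breakpoints (null material for the association filters);
  homoplasmic VAFs are U(0.92, 0.999). Heteroplasmic counts are Poisson
  with a positive age slope in FC only (0.30 + 0.012·age vs 2.0 flat in
  CER), VAFs U(0.15, 0.85), positions random.
* **Planting**: `plant_association` shifts a chosen junction's read % by
  `effect_sd` × its cohort-wide SD in carriers of a chosen SNP's alternate
  allele (deterministically, reads re-derived), leaving everything else
  untouched; the generating parameters, including any planted effect, are
  embedded as `ground_truth`.

Everything is drawn from a single seeded `numpy` generator, so cohorts are
bit-identically reproducible from (config, seed).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: per-junction heterogeneity of age slopes (every
junction shares the cohort slope, so a size-by-age contingency contrast
among junctions degenerates); the empirically larger small-deletion burden
in cortex (the 80/20 size-class mix makes the <1 kb metric CER-leaning);
linkage between haplogroup labels and specific marker alleles (markers are
drawn independently of the label); cell-to-cell heteroplasmy
heterogeneity; and any read-level error structure (no FASTQ/BAM is
simulated). Analyses that depend on those features need real cohorts.

## Problem sizes and numerical checks

The test suite runs the full stack at the default cohort size (292
samples); the property batteries use 1,000 random junctions for annotation
oracle equivalence, 500 for the repeat-engine oracle, 100 seeded cohorts
for slope-recovery coverage and 50 for association power and family-wise
error — sizes at which the binomial tolerances in the assertions are
meaningful while the whole suite stays fast. Degenerate inputs are
exercised explicitly: empty deletion tables, deletion-free samples,
constant responses, all-identical groups, zero margins, junctions at
window boundaries, and origin-wrapping spans.
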