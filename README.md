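# mtaging

Toolkit for quantifying mitochondrial DNA (mtDNA) variation in aging-cohort
whole-genome sequencing studies: **copy number**, **large deletions** and
**single-nucleotide variants**, with the statistical models that connect them
to age, brain region and haplogroup, and an association scan linking
homoplasmic SNPs to deletion junctions through their shared direct-repeat
mechanism.

It is written for analysts who already have per-sample summary tables from
the standard callers — a breakpoint table per sample (junction caller style:
5′/3′ breakpoints, supporting reads, read %, benchmark coverage), a variant
table (position, ref, alt, variant allele frequency), coverage summaries,
and sample metadata — and need the downstream quantification, annotation and
statistics. Raw read alignment, junction discovery and pileup variant
calling are upstream concerns and out of scope.

## The quantities and models

With 1-based rCRS (NC_012920.1) coordinates throughout:

* **mtDNA copy number** per diploid cell: `CN = 2 · d_MT / d_autosomal`
  from mean MT and autosomal depths.
* **Deletion size** for a junction `(bp5, bp3)` (last retained 5′ base,
  first retained 3′ base): `bp3 − bp5 − 1`; the canonical common deletion
  `(8471, 13449)` is 4,977 bp.
* **Deletion read %** = supporting reads / benchmark coverage × 100, where
  benchmark coverage is the mean depth over two 250-bp segments in MT-RNR1
  and MT-CYB; **cumulative read %** sums over all junctions in a sample;
  **deletions per 10k** = unique junctions / benchmark × 10,000.
* **Impact annotation**: a deletion impacts a respiratory-chain complex
  (I/III/IV/V), tRNA or microprotein (humanin, MOTS-c, SHLP1–6, gau,
  mtALTND4, SHMOOSE) when its deleted span removes or truncates the
  feature on the hard-coded rCRS catalog.
* **Exponential age model**: `ln(metric + 0.01) ~ age + benchmark + sex`
  (OLS), with 15-year age-bin changes evaluated from the fitted curve.
* **Rank-based regression** (for group contrasts): slopes minimise
  Jaeckel's dispersion `Σ a(R(e_i)) e_i` with Wilcoxon scores
  `a(i) = √12 (i/(n+1) − ½)`; Wald tests use the τ scale parameter.
* **Junction direct repeats**: the repeat tied to a junction is the longest
  perfect match run on the junction diagonal — position `bp5 + t` against
  `bp3 − 1 + t` for `|t| ≤ 15` — reflecting that the two flanks pair in
  register when the deletion forms. A SNP near a breakpoint can lengthen or
  shorten this repeat; the association scan tests whether the longer-repeat
  allele carries more of that deletion
  (`SNP presence ~ deletion read % + benchmark + age + sex`, Bonferroni
  `α/n_tests` per region).

A seeded synthetic-cohort generator (`mtaging.simulate`) emulates a
two-brain-region study (frontal cortex vs cerebellum) with realistic
region contrasts so every stage can be exercised end-to-end; its generating
parameters are embedded for recovery tests. See `docs/methods.md` for model
details, calibration targets and limitations.

## Worked example

The repeat engine on the best-characterised SNP:deletion couple — the
alternate allele of T14798C lengthens the perfect repeat at junction
7816–14,807 from 6 to 7 bp:

```bash
$ mtaging repeats --junction 7816:14807 --snp 14798:T>C
{
  "junction": [7816, 14807],
  "snp": "T14798C",
  "window": 15,
  "reference": {"repeat_length": 6, "copy5_span": [7809, 7814],
                "copy3_span": [14799, 14804], "repeat_sequence": "TCATCG", ...},
  "alternate": {"repeat_length": 7, "copy5_span": [7808, 7814],
                "copy3_span": [14798, 14804], "repeat_sequence": "CTCATCG", ...},
  "classification": "lengthens"
}
```

The repeat copies sit just upstream of each breakpoint; with the alternate
allele the C at 14,798 extends the 3′ copy so that both flanks share
`CTCATCG`. The same engine reports G12372A shrinking its junction's repeat
from 7 to 3 bp and C14766T from 8 to 5 bp.

The full analysis sequence runs over a synthetic cohort:

```bash
$ python analysis/01_simulate_cohort.py --seed 1 --plant
$ python analysis/02_copy_number.py
copy number: FC 4479 ± 1225 vs CER 1381 ± 669 (3.24-fold, rank-regression p = 5.64e-84)
FC: -109.8 copies per 15 y (age p = 0.0332)
$ python analysis/03_deletion_burden.py
deletions_per_10k: FC/CER fold 3.92
cumulative_read_pct: FC/CER fold 4.77
FC cumulative read %: age slope 0.0249/y (p = 1.18e-17); 60-75 bin gain 0.225 vs 30-45 0.106
$ python analysis/06_mtgwas_repeats.py
FC: 22 tests, threshold 2.27e-03, 1 significant
  14798:T>C x 7816-14807: beta +2.97, p 3.24e-20, repeat 6->7 bp, mechanism-consistent: True
```

Copy number is ~3.3-fold higher in cortex and declines with age there;
deletion burden is several-fold higher in cortex and grows exponentially
with age (the 60–75 year bin gains roughly twice what the 30–45 bin does);
and the planted SNP:deletion coupling is recovered below the per-region
Bonferroni threshold with the direction the repeat mechanism predicts.
`analysis/04_impact_annotation.py` and `05_snv_haplogroups.py` cover the
complex/tRNA/microprotein burden comparisons and the homoplasmic vs
heteroplasmic SNV strata. Each step writes its tables under `results/`.

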