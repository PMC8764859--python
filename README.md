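# pgtmosaic

Dual-platform analysis of embryo mosaicism for preimplantation genetic
testing for aneuploidies (PGT-A).

In PGT-A, a 5–10-cell trophectoderm biopsy is amplified once by multiple
displacement amplification (MDA) and screened for chromosomal abnormalities.
Mosaicism — two or more cell lines with different karyotypes in one embryo —
is never observed directly: it is inferred from *intermediate copy-number
signal*, between monosomy and disomy or between disomy and trisomy. The two
most common platforms read that signal very differently: an SNP array uses
the log R ratio (LogR) and B-allele frequency (BAF) of ~300k markers, while
low-pass NGS estimates a CNV value from ≥0.7 million reads binned along the
genome. `pgtmosaic` implements both calling rules over a shared simulator,
classifies their agreement embryo by embryo, and aggregates cohort-level
concordance statistics — the toolkit a lab would use to study how often, and
why, the two platforms disagree about mosaic embryos.

## What is implemented

* **Simulator** (`pgtmosaic.simulate`) — mixtures of cell lines in a small
  biopsy (binomial cell sampling quantizes the mosaic fraction), one
  log-normal per-tile MDA amplification-bias field shared by both assays, an
  SNP-array renderer (LogR = log2 of dosage, BAF = mixture-weighted B-allele
  share) and an NGS renderer (negative-binomial bin counts with a GC
  efficiency curve).
* **SNP caller** (`pgtmosaic.snp`) — QC (median LogR deviation < 0.2, median
  call rate > 0.98); an arm is mosaic when the heterozygous BAF scatter is
  not concentrated at 0.5 *and* |median LogR| > 0.2; dosage near copy number
  1 or 3 is pure aneuploidy; windowed changepoint scan for ≥10 Mb segments.
  The array cannot quantify the mosaic level.
* **NGS caller** (`pgtmosaic.ngs`) — QC (reads ≥ 0.7 M, map ratio ≥ 80%,
  GC 39–45%, SD < 3.5); GC-decile normalization; per-arm segmentation of the
  CNV profile with a 4 Mb segmental floor; classification by CNV value:
  < 1.20 / > 2.80 pure aneuploidy, [1.20, 1.80] ∪ [2.20, 2.80] mosaic with
  level |CNV − 2| × 100 %, (1.80, 2.20) euploid.
* **Concordance** (`pgtmosaic.concordance`) — arm-level agreement keyed by
  (chromosome, whole|p|q, gain|loss): complete / partial /
  discordant-mosaic / aneuploid-by-NGS / euploid-by-NGS; transferability
  (euploid or all mosaic levels ≤ 50%).
* **Cohort statistics** (`pgtmosaic.stats`) — Pearson chi-square without
  continuity correction, Fisher's exact fallback when any expected count
  < 5, five-way concordance accounting, stratified comparisons (maternal
  age at 35, whole-chromosome vs segmental mosaicism, embryo quality).
* **Synthetic reference cohort** (`pgtmosaic.cohort`) — a deterministic
  105-embryo per-embryo diagnosis table with a specified aggregate
  composition, used as the package's worked example and regression fixture.
* **CLI** (`pgtmosaic`) — `simulate | call-snp | call-ngs | concord |
  stats | report` over TSV/JSON interchange formats.

## Worked example

Simulate an embryo in which 60% of cells carry a 2q deletion, call both
platforms, and classify their agreement:

```sh
pgtmosaic simulate --event "-2q" --fraction 0.6 --n-cells 10 --exact \
    --seed 11 --outdir demo
pgtmosaic call-snp --signal demo/snp_signal.tsv --embryo-id E1 --out demo/snp.tsv
pgtmosaic call-ngs --signal demo/ngs_signal.tsv --embryo-id E1 --out demo/ngs.tsv
pgtmosaic concord --snp demo/snp.tsv --ngs demo/ngs.tsv --out demo/concord.tsv
```

prints `E1	complete`: both platforms report `-mos(2q)` — a mosaic loss of
the long arm of chromosome 2 (the NGS diagnosis additionally carries
CNV ≈ 1.42, i.e. a level of ~58%, close to the simulated 60%).

The cohort summary on the synthetic reference cohort:

```sh
pgtmosaic stats --out summary.json
pgtmosaic report --summary summary.json
```

```
Between-platform concordance
  complete               50  (47.62%)
  partial                19  (18.10%)
  discordant_mosaic      11  (10.48%)
  aneuploid_by_ngs       14  (13.33%)
  euploid_by_ngs         11  (10.48%)
...
Stratified complete-concordance comparisons
  maternal_age    under_35 37/82 (45.12%) vs 35_and_over 13/23 (56.52%)  [chi2] P = 0.333
  mosaic_type     whole_chromosome 21/49 (42.86%) vs segmental 29/55 (52.73%)  [chi2] P = 0.315
  embryo_quality  good 38/80 (47.5%) vs low 12/25 (48.0%)  [chi2] P = 0.965
```

The complete-concordance rate of 47.62% means fewer than half of the
embryos judged mosaic by the array receive the same mosaicism diagnosis
from sequencing; about a quarter are re-diagnosed as outright aneuploid or
euploid — the clinically consequential disagreements.

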