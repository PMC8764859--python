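# Methods

## The measurement problem

A mosaic embryo contains at least two cell lines with different karyotypes.
A trophectoderm biopsy samples 5–10 of its outer cells; a single MDA
amplification of that biopsy supplies the template for both assays. Neither
platform sees cells: both see a dosage signal averaged over the mixture, so
a region present at copy number c₁ in a fraction f of cells and c₂ in the
rest yields mean copy number f·c₁ + (1−f)·c₂. Every design choice below
follows from modelling that average and the noise around it.

Two consequences are built in as analytic oracles. First, *complementary
errors*: any two mixtures with the same mean copy number are
indistinguishable to a dosage assay — 40% monosomy + 60% trisomy and 80%
disomy + 20% trisomy both average 2.2 and both read as a "20% mosaic gain";
a balanced monosomy/trisomy mixture averages exactly 2 and reads euploid.
Second, *quantization*: with n cells in the biopsy the realized abnormal
fraction is Binomial(n, f)/n, so a 5-cell biopsy can only express fractions
in steps of 0.2 regardless of the embryo's true composition.

## Simulator

**Biopsy.** `make_biopsy` draws the abnormal cell count binomially;
`BiopsyTruth.from_fraction` builds the exact mixture when the quantization
is not under study. Cell lines are integer copy states on a disomic
baseline (1 for loss, 3 for gain by default; arbitrary states supported).

**Amplification bias.** MDA amplifies loci unevenly. We model one
multiplicative weight per genomic tile (default 1 Mb), w = 2^(σ·Z) with Z
standard normal, mean-normalized; σ is interpreted on the log2 scale so it
adds in quadrature with the array's LogR noise. The same weight field feeds
both renderers — the single-amplification, dual-aliquot design is the
mechanistic reason the two assays share locus-level artifacts, and
simulating it any other way would overstate their independence.

**SNP renderer.** Markers are placed uniformly, ~300k genome-wide, with
baseline genotypes AA/AB/BB (heterozygosity 0.5). Per marker, each cell
line contributes its total and B-allele copy numbers (gains duplicate a
uniformly chosen resident allele; losses keep a without-replacement
sample); the mixture-weighted totals give BAF = b/c and
LogR = log2((c/2)·w) + N(0, σ_lrr), with BAF noise N(0, σ_baf) truncated to
[0, 1] and a per-marker no-call probability.

**NGS renderer.** Bins of 1 Mb tile each chromosome. Bin expectation is
width × (copy number/2) × MDA weight × GC efficiency (a quadratic curve in
the bin's GC fraction), normalized so expected mapped reads total the
configured budget (700k mapped; reported total reads are mapped/map-ratio,
so the 0.7 M generated-read QC gate passes by construction at defaults).
Counts are negative-binomial via a gamma–Poisson mixture with variance
λ(1 + od) — od is an extra-Poisson variance *factor*, not a λ² dispersion
coefficient; at the default od = 0.1 the bin noise is dominated by the MDA
field, which is the empirically realistic regime for single-cell-scale WGA.
A `deterministic` flag returns exact expectations for noiseless-limit
oracle tests.

**Default noise** (σ_lrr 0.15, σ_baf 0.03, MDA σ 0.2, od 0.1, no-call 1%)
was chosen once so that default QC passes on both platforms with margin and
the 20–80% mosaic window is detectable by NGS; no published noise
magnitudes exist for either instrument at this protocol, so these are the
package's study conditions, stated rather than fitted. What the simulator
deliberately omits: chimeric MDA artifacts, allele dropout correlated along
haplotypes, read-level duplicates, and real GC tracks — so passing tests
demonstrate correctness of the calling rules under the stated noise model,
not instrument-level realism.

## SNP-array caller

QC: median over autosomal called markers of |LogR − genome median| must be
< 0.2 and the call rate > 0.98.

Per arm, the caller scans windowed median LogR (2 Mb windows, so the
changepoint statistics see independent window noise rather than the
tile-correlated MDA field) with the interval-scan segmentation described
below, then classifies each ≥10 Mb segment on marker-level statistics:

* **BAF scatter**: among called loci with BAF in [0.15, 0.85]
  ("heterozygous-pattern"), the fraction deviating from 0.5 by more than
  τ = 0.1. When almost no heterozygous-pattern loci remain (< 10% of
  markers), the arm shows loss of heterozygosity and scatter is defined as
  1 — full monosomy is maximally un-concentrated at 0.5 by absence.
* **Dosage**: mosaic gain/loss when scatter > 0.5 and median LogR beyond
  ±0.2; pure aneuploidy when the median reaches log2(1.45) ≈ 0.54 or
  log2(0.55) ≈ −0.86 (dosage within 10% of copy number 3 or 1). The
  mosaic-vs-full boundary is not a published quantity; it is exposed as a
  parameter.

A consistent direction across (nearly) a whole arm is one arm event even if
pieces straddle the mosaic/full dosage boundary; two arms agreeing in
direction and dosage merge into a whole-chromosome event whose mosaic/full
kind is re-decided on chromosome-wide markers (small arms otherwise flip
across the boundary by chance). SNP events never carry a level — the
array's dosage resolution does not support one, which is precisely why the
NGS re-test exists.

A useful emergent property: a 40% whole-chromosome trisomy mosaic is *not*
called by the array at defaults — its heterozygous BAF bands sit 1/2.4 and
1.4/2.4, only 0.083 from 0.5, inside the τ = 0.1 concentration band — while
at 60% the bands clear τ and the call fires. The array's practical
detection floor for mosaic gains therefore sits between 40% and 60% under
this model, consistent with arrays being reliable only for mid-range mosaic
fractions.

## NGS caller

QC gates: total reads ≥ 700,000; map ratio ≥ 80%; GC content 39–45%;
SD < 3.5. The vendor's SD statistic is opaque; ours is defined
operationally as the standard deviation of per-bin CNV estimates
(2 × GC-normalized ratio) over autosomal bins, and the 3.5 gate is a
configurable parameter on that scale. The duplicate rate is recorded but
not gated (no published threshold).

GC normalization divides each bin's count density by the median density of
its GC decile (deciles from autosomal bins; empty deciles fall back to the
global median), then rescales the autosomal median ratio to 1. It is
deterministic and removes a quadratic GC curve to ~1–2%.

Segmentation runs per arm on the CNV profile (2 × ratio) with the interval
scan, minimum 4 bins; segments not exceeding the 4 Mb floor are absorbed
into their longer neighbor (the floor is strict: "above 4 Mb" detectable, a
3 Mb event smeared across 4 bins is not reported). A segment covering ≥90%
of its arm is promoted to arm scope; two non-euploid arms agreeing in
direction with CNV gap ≤ 0.4 merge into a whole-chromosome event classified
on the pooled, bin-weighted CNV. Residual same-direction pieces of a merged
chromosome are absorbed into the whole-chromosome event.

Classification intervals: CNV < 1.20 or > 2.80 pure aneuploidy;
[1.20, 1.80] and [2.20, 2.80] mosaic with level |CNV − 2| × 100, rounded to
integer percent; (1.80, 2.20) euploid. The shared endpoints 1.80 and 2.20
belong to the *mosaic* class — the complementary-error example (mean copy
number exactly 2.2) must read "20% mosaic", not euploid — and boundary
comparisons carry a 1e-9 tolerance so that floating-point sums landing on
an endpoint classify as written. The level formula is the only one
consistent with the 20% example and with the ≤50%/＞50% transferability
split falling at CNV 1.5/2.5.

**Evidence gate.** Classification by value alone would call any arm whose
median drifts past ±0.2, so candidate events must also clear
|CNV − 2| ≥ 3.5 × se, where se is the robust standard error of the segment
median (1.2533·σ_bin/√n, σ_bin from the MAD of first differences). This is
a detection-confidence gate, not a change to the published intervals: it
decides *whether* an aberration is called, the intervals decide *what* it
is. At default noise it suppresses disomic false calls to ≪1 per genome
while leaving a 40% whole-chromosome mosaic at ≈6 σ.

## Changepoint scan

Both callers share a recursive *interval* scan: find the contiguous
interval whose mean contrasts most with its complement (exact SSE reduction
for the two-mean model, computed from cumulative sums), accept if the gain
exceeds `penalty_factor · σ² · log n` per new changepoint, recurse on the
three pieces. Classic one-split binary segmentation dilutes short interior
CNVs (a 20-bin dip in a 133-bin arm can fail every single-split test while
being overwhelming as an interval); the interval scan is exact for that
geometry. σ is estimated from the MAD of first differences, so real jumps
do not inflate it; with σ = 0 (noiseless fixtures) any exact mean change is
split out. Penalty factors: 4 (SNP windows — classification adds a second
gate, so liberal splitting is safe) and 5 (NGS bins).

## Concordance and transferability

Agreement is scored on mosaicism *types*: keys (chromosome, whole|p|q,
direction) from each platform's mosaic events. Deletion vs duplication of
the same arm, and whole-chromosome vs single-arm mosaicism of the same
chromosome, are different types; segment coordinates within an arm are
ignored. Categories: identical key sets → complete; overlapping → partial
(the NGS-superset case is a subset of partial, not a separate category);
disjoint with NGS mosaicism present → discordant-mosaic; NGS with no mosaic
events → aneuploid-by-NGS (pure aneuploidy present) or euploid-by-NGS
(nothing). When NGS reports both mosaic and pure-aneuploid events the
mosaic keys drive the category — the only reading consistent with a
five-way accounting in which the aneuploid/euploid branches require *no*
NGS mosaicism. Whole-vs-arm same-direction overlaps score as
discordant-mosaic per the type rule but are flagged in the result
(`whole_vs_arm:<chrom>:<dir>`) so a cohort can be re-tallied under the
opposite convention; whether such pairs were ever scored partial in
practice is not decidable from published descriptions.

Transferable: no pure aneuploidy and every mosaic level ≤ 50% (inclusive).
A mosaic event without a level (e.g. from the SNP platform) is an error —
transferability is defined on quantified NGS diagnoses only.

## Cohort statistics

Group comparisons use Pearson's chi-square (1 df) *without* continuity
correction — with Yates' correction the whole-vs-segmental stratum gives
p ≈ 0.418 instead of 0.315, so the uncorrected statistic is the one that
reproduces the reference values — falling back to Fisher's exact two-sided
test when any expected count is below 5. Fisher p-values are verified in
the tests against exhaustive hypergeometric enumeration. Strata: maternal
age dichotomized at 35 years; whole-chromosome vs segmental SNP mosaicism
(an embryo showing both is excluded from this stratum only); good vs low
embryo quality (the Gardner-score flag is supplied per record; scoring
itself is out of scope). Rates print to two decimals.

## Synthetic reference cohort

No per-embryo dataset for this dual-platform design is publicly
retrievable, so `pgtmosaic.cohort` constructs one: 105 embryos whose
*aggregate* composition — five-way concordance counts 50/19/11/14/11, a
57:23 low/high level split, and the three stratification margins — is
specified as generator parameters, while every per-embryo notation is built
so that parsing + classification reproduce the requested category. The
cohort summary therefore recomputes all rates and p-values from rows; the
generator fixes only the composition, exactly as a retrospective cohort
fixes who was enrolled. The table is deterministic (no RNG) and labelled
synthetic throughout.

## Genome model

Chromosome lengths are hg19; centromere midpoints are approximate; the
cytoband table (`data/cytobands_schematic.tsv`) is *schematic* — ISCN-style
names generated by uniform ~6 Mb subdivision of each arm, three sub-bands
per band, numbered away from the centromere. Band-range notation like
`16p12.2-q21` resolves against this table and round-trips exactly; the
coordinates are not those of any curated ideogram and the package is
explicit about that limitation. Coordinates are 1-based inclusive
everywhere. Simulation and calling default to an XX baseline (autosomes
+ X); Y is present in the genome model for completeness.

## Problem sizes and determinism

Default simulations run the full genome at 300k markers / 1 Mb bins; test
fixtures use 20–40k markers where marker density is not under test. The
parameter-recovery experiment uses 200 replicates of the NGS pipeline at
fraction 0.40 on an exact mixture (the binomial biopsy would quantize 0.4
to multiples of 0.1 and the recovery question would conflate sampling with
measurement; quantization is tested separately). Every stochastic function
takes an explicit seed and spawns sub-seeds via `SeedSequence`; identical
seed and configuration produce byte-identical output files.

## Known limitations

* The schematic cytoband table means segment *coordinates* are only
  self-consistent, not portable to real annotation.
* The SNP mosaic-vs-full boundary and segmental resolution, and the
  vendor's SD scale, are undocumented externally; all three are parameters
  with stated defaults.
* Whole-chromosome dosage near the full-aneuploidy threshold (e.g. a small
  chromosome at copy number 3 with median LogR ≈ 0.585 against the 0.536
  cut) misclassifies as mosaic in a few percent of default-noise runs —
  an irreducible consequence of thresholding a noisy median near the
  boundary.
* X/Y handling beyond an XX baseline (XY embryos, sex-chromosome
  mosaicism) is not modelled.
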