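# Methods

`rrdkit` operationalizes the biomarker layer used to characterize
hypermutant, replication-repair deficient (RRD) gliomas under immune
checkpoint inhibition. This note records the models each stage implements,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Consensus variants and TMB

Per-caller somatic call sets are merged on the key (chrom, pos, ref, alt)
after allele normalization; a variant is retained iff supported by at
least `min_callers` (default 2) distinct callers, with SNVs and indels
merged separately and unioned. Duplicate calls by one caller count once.
Consensus VAF and depth are medians across supporting callers — a robust
choice; callers disagree and no convention is canonical.

Allele normalization trims the shared suffix, then the shared prefix
(advancing the position), always leaving at least one base per allele.
This unifies padded and context-bearing representations of the same
event. Representations that differ by shifting through a repeat run can
only be unified by left-alignment against the reference sequence; the
pipeline deliberately takes no reference genome as input (calling and
alignment are upstream), so such pairs remain distinct keys. In practice
consensus VCF merging tools face the same limit unless handed a FASTA.

TMB is the number of consensus somatic **SNVs** divided by the callable
territory in megabases (default 50, the conventional whole-exome callable
size); indels are excluded from the numerator. Immune-escape screening
counts consensus variants in a configurable panel defaulting to B2M,
JAK1, JAK2, IFNGR1, IFNGR2, TYK2, STAT1, STAT2, STAT5A, STAT5B and IRF;
"IRF" is kept as a single configurable symbol because no family-member
number is specified in the source material, and matching is
case-insensitive after whitespace strip.

## Cancer cell fraction and clonality

For a mutation with observed variant allele fraction `vaf`, tumor purity
`p`, local tumor copy number `c`, normal copy number `c_n` (2 for
autosomes) and multiplicity `m` (mutated copies per tumor cell):

    CCF = vaf · (p·c + (1 − p)·c_n) / (m · p)

Purity and copy number are inputs (ASCAT-class estimation is upstream).
The raw estimate is retained; for classification it is capped at 1.0,
because sampling noise inflates VAF and the clonality rule presumes
CCF ≤ 1. A mutation is **clonal** iff capped CCF > 0.85, strictly. When
`m` is unknown it is inferred as round(vaf·(p·c + (1−p)·c_n)/p) clipped
to [1, c] — the integer multiplicity that brings the CCF closest to 1,
the common practice in clonality reconstruction. The formula lives in a
single function so an alternative rendering can be swapped in one place.

At sequencing depth 500 the binomial VAF noise translates to a CCF
standard error of roughly 0.045 for a diploid heterozygous clonal
mutation, so the 0.85 threshold separates CCF 1.0 from CCF 0.4
essentially perfectly; the acceptance suite verifies ≥ 95% classification
accuracy at those conditions and exact (1e-9) recovery on noiseless VAFs.

## MMRDness (microsatellite instability) score

Mismatch-repair deficient genomes slip at homopolymers. For each
A-homopolymer locus of length 10–15 bases (inclusive) with coverage at
least `min_coverage` (default 10 reads — proportion estimates below that
are unstable; no floor is prescribed in the source, so the package states
its own), the score sums the per-locus proportion of reads carrying a
single-base deletion (insertions and ≥2-base deletions do not count) and
reports

    score = log10(Σ proportions) + 1.1 .

A zero sum is reported as an explicit below-detection status, never −∞.
One row per locus is enforced. With 100 informative loci, a deficient
tissue at mean deletion proportion 0.05 sits near log10(5)+1.1 ≈ 1.80 and
a proficient one at 0.005 near 0.80; these regime means are calibration
placeholders for recovery tests, not biological claims — the source does
not print per-locus magnitudes.

## Panel normalization and the TIS

QC: per sample, the geometric mean of the four housekeeping genes'
**raw** counts (DDX50, EIF2B4, MRPS5, SAP130); samples below 100 are
excluded (strict: exactly 100 passes). Any zero housekeeping count makes
the geometric mean 0 and excludes the sample.

Normalization runs the same step twice — first on positive controls,
then on housekeeping genes: compute each sample's control geometric mean,
take the grand geometric mean of those across samples, and multiply all
of the sample's counts by grand/per-sample. Two consequences are worth
stating because they are easy to get wrong. First, the procedure is
idempotent at the count level, but renormalizing returns *reciprocal*
per-step factors whose product is exactly 1 — the per-step factors are
not individually 1. Second, multiplying one sample's raw counts by k
does not leave its normalized counts bit-identical: the grand geometric
mean shifts by k^(1/n), scaling every sample by that global constant.
Between-sample ratios and within-matrix structure are invariant, and that
is the property the tests assert. Negative controls are read but unused —
no background subtraction is performed.

The tumor inflammation signature is score_s = Σ_g w_g · log₂(count_{g,s} + 1)
over the genes of a user-supplied weights TSV. The pseudocount of 1
handles zeros, which occur in panel data; no zero-handling rule is
prescribed upstream. The bundled `tis_weights_unit.tsv` assigns unit
weight to the 17 printed TIS genes and is a documented placeholder: the
published weights belong to the signature's reference publication and are
not reproduced here, and the weights file — not the code — defines the
operative gene set (so an 18-gene file including CMKLR1 is a drop-in).

## Indel-signature refitting

Catalogs are counts over the standard 83 indel context channels (1-bp
insertions/deletions by pyrimidine class and homopolymer length, longer
events by repeat number, microhomology-flanked deletions). Refitting
solves the nonnegative least-squares problem
min_{w≥0} ‖catalog − S·w‖₂ (via `scipy.optimize.nnls`); absolute
contributions are the fitted weights, relative contributions their
normalized vector. No sparsity penalty or signature pre-selection is
applied — plain fitting. An all-zero catalog yields an explicit
undefined-relatives status. A zero relative contribution is a legitimate
scientific result (absence of the radiation signature ID8).

The bundled signature matrix is **synthetic**: ID1/ID2/ID8-like column
shapes (replication-slippage insertions, slippage deletions, and
end-joining deletion spectra respectively) constructed deterministically
by `synthetic_id83_matrix()` so the package builds and tests without any
download. A real COSMIC matrix in the same channel × signature TSV layout
is a drop-in replacement; results against the synthetic matrix validate
the fitting machinery, not any biological attribution. The refit is
checked against an independent grid-search oracle (mixing-fraction scan
with analytic scale) to 1e-3 on two-signature problems, and recovers a
0.7/0.3 multinomial mix within ±0.03 at 10,000 indels.

A helper classifies 1-bp indels from normalized variant records into
their homopolymer channels given a run-length provider; full ID-83
classification of complex indels requires reference context and is out of
scope, with such events counted as unclassified and excluded from refit.

## HLA loss of heterozygosity

Per HLA gene, the two typed alleles are compared at their sequence-
mismatch positions: d_i = log((t1+0.5)/(t2+0.5)) − log((n1+0.5)/(n2+0.5)),
tumor ratios normalized by matched-normal ratios to remove allele-
specific capture bias, with a +0.5 coverage pseudocount. A paired
two-sided test (paired t by default; Wilcoxon signed-rank available)
asks whether d departs from zero. Fewer than 5 mismatch positions yields
an explicit insufficient status rather than a fabricated p-value; all-
zero differences yield p = 1.

The decision rule is deliberately minimal: **LOH iff p < 0.01**, strict,
per allele, with no multiple-testing correction across genes. A copy-
number estimate may be carried in the output but never gates the call —
in hypermutation-driven tumors copy-number losses are rare and a combined
copy-number cutoff under-calls LOH. The null calibration of the test
(rejection rate at 0.01 within ±0.005 over 10,000 balanced replicates) is
part of the acceptance suite.

## TCR repertoire

Libraries are sequenced to varying depth, so clonotype tables are down-
sampled to a common total (default 1,000,000 reads) by a multivariate
hypergeometric draw without replacement — the count-level equivalent of
down-sampling raw reads, which preserves the statistics of interest
without needing fastq input. Tables with fewer reads than the target are
returned unchanged with a warning status. Metrics: unique clonotype
count, clonotypes per 1,000 reads (= count / (total/1000)), and Shannon
diversity H = −Σ f_i ln f_i in natural log (stated explicitly because
conventions differ).

## Survival and contingency statistics

Interval conventions: PFS1 (ICI monotherapy start → radiologic
progression), OS1 (monotherapy start → death), PFS2 (salvage start →
progression or death, whichever first), OS2 (salvage start → death);
censoring at last follow-up. Times are converted as month = 30.4375 days
(365.25/12); no conversion rule is prescribed upstream, so the package
fixes one. Subjects lacking an interval's start anchor are skipped; a
stop before start is an error naming the subject.

Kaplan–Meier estimation and the log-rank test delegate to `lifelines`;
the median is the earliest time with S(t) ≤ 0.5 and its 95% CI derives
from the log(−log) survival-function interval (stated explicitly because
no method is named upstream). Fisher's exact test is two-sided by the
point-probability method with the conditional-MLE odds ratio
(`scipy.stats`); the test suite verifies it against full hypergeometric
enumeration for every 2×2 table with all margins ≤ 15. Wilcoxon–Mann–
Whitney uses the exact distribution for combined n ≤ 20 without ties and
the tie-corrected normal approximation otherwise. Percentages round half
away from zero (banker's rounding would print 12.5% of 24 as 12%), to
one decimal where the source prints one.

## Synthetic data: what it emulates, and what it does not

Each generator draws from a `numpy` Generator seeded as (seed, stage
substream), so identical configuration and seed reproduce outputs
byte-for-byte, and stages can be re-run independently.

- **Variant call sets.** Truth CCF is 1.0 for a clonal fraction of
  variants (default 0.6) and uniform on (0.1, 0.6) otherwise; copy-number
  states are drawn from a small profile (default diploid-het, diploid
  double-multiplicity, triploid); expected VAF follows the CCF equation;
  depth is Poisson (default mean 150) and observed VAF binomial. Each true
  variant is emitted by k of 4 pseudo-callers with k drawn from
  {1: 0.05, 2: 0.15, 3: 0.30, 4: 0.50} — chosen to exercise the 2-of-4
  rule on both sides — plus caller-private false positives (default rate
  0.02 per true variant). Not emulated: caller-specific error modes,
  alignment artifacts, indel left-alignment disagreements (an optional
  concern the generator sidesteps by construction), germline leakage.
- **Microsatellites.** Constant per-locus deletion proportion at the
  regime mean with binomial read counts at fixed depth 100; real data
  would show locus-to-locus dispersion and length-dependent slippage.
- **Panel counts.** Negative binomial (dispersion 0.1, mild
  overdispersion typical of count panels) around gene means × a lognormal
  per-sample technical factor (σ = 0.4); a four-fold positive-control
  titration ladder; 103 endogenous genes including the TIS set. Not
  emulated: probe-level background structure, FFPE degradation gradients.
- **Survival.** Exponential event times with rate ln2/median per group
  (defaults 11.6 vs 1.2 months, the contrast scale of interest);
  censoring with probability 0.2, uniform before the event time.

Passing recovery tests on these generators demonstrates that the
estimators invert the stated generating models at the stated sizes; it
does not validate performance against the unmodeled features of real
sequencing data listed above.

## Problem sizes and runtime

The test and acceptance workloads are sized for a single CPU: 1,000
variants at depth 500 for clonality recovery; 50 samples per arm × 100
loci for the MMRDness separation; 10,000-indel catalogs for mix recovery
(100,000–200,000 for distributional checks of the generator itself);
2,000 subjects for median recovery; 10,000 replicates for each type-I
calibration (log-rank at n = 50/arm, allelic imbalance at 50 positions);
exhaustive Fisher enumeration over all 2×2 tables with margins ≤ 15
(~15,000 tables). The full pipeline on default synthetic fixtures
completes in well under two minutes.

## Known limitations

- No reference genome handling: indel left-alignment and ID-83
  classification of complex indels are upstream concerns.
- The CCF equation is implemented in its standard rendering; it is
  confined to one function precisely so a variant form can be swapped.
- LOHHLA's full coverage model is not reproduced — only a simplified
  paired allelic-imbalance test feeding the published decision rule.
- The bundled signature matrix and TIS weights are synthetic/placeholder
  artifacts; biological conclusions require the real COSMIC matrix and
  published weights in the same file formats.
- Survival medians printed for the clinical cohorts are not recomputable
  without patient-level times, which are not public; the survival layer
  is therefore validated by simulation calibration, not against cohort
  numbers.
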