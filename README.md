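# rrdkit

Biomarker computations for hypermutant, **replication-repair deficient
(RRD)** high-grade gliomas treated with immune checkpoint inhibition (ICI),
packaged as a tested, reusable pipeline. RRD tumors — arising from
mismatch-repair deficiency (Lynch syndrome, CMMRD) with or without
secondary polymerase-proofreading mutations — carry extreme mutation
burdens and microsatellite instability, which makes them candidates for
immune-directed therapy and calls for a specific set of genomic and
immunologic readouts. `rrdkit` implements that readout layer for analysts
working with somatic call sets, low-pass genome sequencing, expression
panels, HLA typing output, TCR repertoires, and clinical follow-up tables.

## What it computes

| Stage | Statistic |
|---|---|
| `variants` | Consensus somatic call set (variants shared by ≥2 of 4 callers, SNVs and indels merged separately); TMB = somatic SNVs / callable Mb (default 50); hits in an immune-escape gene panel (*B2M, JAK1, JAK2, IFNGR1, IFNGR2, TYK2, STAT1, STAT2, STAT5A, STAT5B, IRF*) |
| `clonality` | Cancer cell fraction CCF = VAF·(p·c + (1−p)·c_n)/(m·p) from purity p, local copy number c, multiplicity m; clonal iff CCF > 0.85 |
| `msi` | MMRDness score = log₁₀(Σ per-locus single-base-deletion proportions at A-homopolymers 10–15 bp) + 1.1 |
| `nanostring` | Housekeeping-geomean QC (< 100 excluded); two-step geometric-mean normalization (positive controls, then *DDX50/EIF2B4/MRPS5/SAP130*); tumor inflammation signature (TIS) = Σ w_g·log₂(count+1) |
| `signatures` | Nonnegative-least-squares refit of 83-channel indel catalogs against reference signatures; relative contribution of the radiation signature ID8 |
| `hla` | Paired allelic-imbalance test on tumor/normal allele coverage; LOH iff p < 0.01 (copy number reported, never gating) |
| `repertoire` | Clonotype down-sampling (multivariate hypergeometric), clonotypes per 1,000 reads, Shannon diversity |
| `survival` | PFS1/OS1/PFS2/OS2 interval construction, Kaplan–Meier with median + 95% CI, log-rank, Fisher exact, Wilcoxon–Mann–Whitney, response-rate summaries |
| `synthetic` | Seeded generators for every input above, with ground-truth tables |

## Worked example

```python
from rrdkit import (CCFInput, compute_ccf, merge_consensus, compute_tmb,
                    MicrosatelliteLocus, mmrdness_score)
from rrdkit.synthetic import SimulationConfig, simulate_variant_callsets

# four synthetic caller VCF-equivalents with known truth
callsets, truth = simulate_variant_callsets(SimulationConfig(seed=1))
consensus = merge_consensus(callsets, min_callers=2)
tmb = compute_tmb(consensus, callable_mb=50)
print(len(consensus), tmb.n_snv, tmb.tmb)
# 948 857 17.14          (948 of 1000 simulated variants pass 2-of-4;
#                          857 SNVs over 50 Mb -> 17.14 mutations/Mb)

rec = compute_ccf(CCFInput(vaf=0.25, p=0.5, c=2, m=1))
print(rec.ccf, rec.clonal)
# 1.0 True               (VAF 0.25 at purity 0.5, diploid het -> clonal)

loci = [MicrosatelliteLocus(f"l{i}", "A", 12, 100, 5) for i in range(100)]
print(round(mmrdness_score(loci).score, 4))
# 1.799                  (sum of proportions 5.0 -> log10(5) + 1.1)
```

The same stages are available from a shell:

```bash
rrdkit simulate variants --seed 1 --out sim/
rrdkit consensus sim/caller*.vcf --min-callers 2 --out consensus.vcf
rrdkit tmb consensus.vcf --callable-mb 50
rrdkit run --seed 1 --outdir out/     # full pipeline + JSON report
```

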