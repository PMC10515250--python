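# bsamap

Mapping-by-sequencing for forward genetics: a toolkit for locating a
recessive causal point mutation by bulked-segregant analysis (BSA), written
around the classic tomato EMS-mutant design — a homozygous mutant crossed to
its non-mutagenized parent, a BC1F2 population phenotyped and bulked, and
the two bulks pool-sequenced so that the causal locus appears as an
allele-frequency skew along the genome.

It is aimed at researchers building or teaching MutMap-style pipelines who
want every stage — population simulation, variant filtering, the
allele-frequency scan, variant-effect prioritization, recombinant fine
mapping, and the downstream expression/composition summaries — as tested,
composable library functions rather than a monolithic script.

## What it computes

For each biallelic SNV with alt-read count *a* and depth *d* in a bulk, the
mutant allele frequency is AF = *a*/*d*. AFs are smoothed per chromosome
with a sliding window of *W* = 10 SNPs (step 1), and a window is
causal-like when

    mean AF_mut > 0.95   and   mean AF_wt < 0.40

where AF_mut / AF_wt are the mutant-phenotype and phenotypically wild-type
bulk frequencies. Under a monogenic recessive model every plant in the
mutant bulk is homozygous causal (AF → 1 − ε at the causal site, with ε the
sequencing error rate), while the wild-type-like bulk mixes heterozygotes
and homozygous wild type 2:1 (AF → 1/3). Passing windows merge into
candidate regions ranked by their AF evidence.

Supporting stages:

- **popsim** — forward simulator: EMS variant sets (98% G/C→A/T
  transitions), Haldane meiosis (Poisson crossovers, uniform positions),
  BC1F2 populations, phenotype-selected bulks, and read-by-read pooled
  sequencing with Poisson depth and per-read error.
- **variant_io** — two-sample VCF in/out (AD/DP per bulk) and the variant
  filters: read depth within [10, 100] in both bulks, substitution class.
- **effect_annot** — a miniature consequence annotator: codon-resolved
  synonymous/missense/nonsense/stop-loss calls, splice-site and UTR/intron
  classes, multi-isoform aware, with K114N-style protein notation.
- **finemap** — recombinant counts per marker among recessive-class
  individuals and the zero-recombinant interval; Pearson χ² test of the
  3:1 phenotypic ratio.
- **exocarp_stats** — DEG threshold filter (|log2FC| ≥ 1, q < 0.05,
  FPKM > 5 in either genotype), functional-category counts, fold-change and
  pooled-variance t summaries, cell-wall ratios ((Ara+Gal)/Rha,
  GalA/(Rha+Ara+Gal), Xyl/Man) and pectin esterification degrees (DM, DA).

## Worked example

Simulate one experiment at the study design (216 BC1F2 plants, bulks of 38,
mean depth 32, error 0.002, ~1300 EMS SNVs, causal G→T at ch12:2,751,259)
and scan it:

```python
from bsamap import pipeline, afscan
from bsamap.finemap import chi_square_segregation
from bsamap.popsim import MUTANT_PHENOTYPE

res = pipeline.scan_simulation(seed=0)
n_mut = sum(i.phenotype == MUTANT_PHENOTYPE for i in res.population)
stat, df, p = chi_square_segregation(n_mut, len(res.population) - n_mut)
print(f"phenotypes: {n_mut} mutant / {len(res.population) - n_mut} WT-like "
      f"(chi2={stat:.2f}, p={p:.2f})")
print(f"SNVs after depth filter: {len(res.table)}")
for r in afscan.rank_regions(res.regions):
    print(f"region {r.chrom}:{r.start:,}-{r.end:,}  "
          f"min AF_mut={r.min_af_mut:.3f}  max AF_wt={r.max_af_wt:.3f}  "
          f"windows={r.n_windows}  contains_causal={r.contains_causal}")
print(f"causal window: AF_mut={res.causal_window_af_mut:.3f}, "
      f"AF_wt={res.causal_window_af_wt:.3f}")
```

prints

```
phenotypes: 52 mutant / 164 WT-like (chi2=0.10, p=0.75)
SNVs after depth filter: 1301
region ch12:328,935-10,611,865  min AF_mut=0.953  max AF_wt=0.388  windows=7  contains_causal=True
causal window: AF_mut=0.983, AF_wt=0.357
```

The population segregates ~3:1 (the χ² goodness-of-fit test does not reject
the recessive model), and the scan calls a single candidate region on
chromosome 12 that contains the true causal position: the mutant bulk is
nearly fixed for the mutant allele there (AF ≈ 0.98) while the wild-type-like
bulk sits near the expected 1/3.

The same stages are available from a shell via the `bsamap` CLI
(`simulate`, `filter`, `scan`, `annotate`, `finemap`, `degfilter`); see
`bsamap --help`.

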