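# Methods

## The mapping design being modeled

A homozygous recessive point-mutant line (EMS-mutagenized background) is
crossed to its non-mutagenized parent; a single BC1F1 — heterozygous at the
causal variant and at every other EMS-induced SNV — is selfed to give a
BC1F2 population. The trait segregates 1:2:1 by genotype and 3:1 by
phenotype. Plants of each phenotype class are pooled into bulks and each
bulk is whole-genome sequenced as a pool. Because every mutant-phenotype
plant is homozygous causal, the mutant-allele frequency in the mutant bulk
approaches 1 at and around the causal site, while the wild-type-like bulk
(heterozygote : homozygous wild type = 2:1 among carriers of a recessive
trait's non-expressing classes) approaches 1/3. Everywhere unlinked, both
bulks hover near 1/2.

## Simulator

**Genome.** A 12-chromosome tomato-like preset with SL3.0-scale physical
lengths (~800 Mb total). Genetic lengths use a uniform 1.5 cM/Mb rate
(~1210 cM genome-wide, consistent with published tomato linkage maps);
crossover positions are uniform on the physical map. This deliberately
ignores the strong pericentromeric suppression of recombination in real
tomato; see Limitations.

**EMS variants.** `n_background` SNVs (default 1300 — a preset, not a
measured value) are placed uniformly, chromosomes weighted by length, with
position collisions resolved by resampling. The substitution spectrum is
98% G/C→A/T transitions (canonical EMS); the causal variant — by default
the G→T transversion at ch12:2,751,259 — is always included verbatim.
Exactly one variant carries the causal flag.

**Meiosis.** Haldane model: per chromosome the crossover count is
Poisson(genetic length in Morgans), no interference; coincident breakpoints
cancel in pairs. Each BC1F2 individual receives two independent BC1F1
gametes per chromosome, represented as parental-origin segment lists. All
EMS variants ride the "mutant" parental haplotype, so genotypes anywhere
derive purely from segment origins.

**Phenotype.** Recessive, fully penetrant by default: mutant phenotype iff
homozygous causal. A `penetrance < 1` option exists (real expressivity of
such traits is variable) but defaults off so that the simulated conditions
stay crisp.

**Pooled sequencing.** Per site, depth ~ Poisson(mean depth, default 32).
Each read picks one of the 2·n chromosome copies in the bulk uniformly,
reports the allele that copy carries, and is flipped with the per-read
error probability (default 0.002). The equivalent closed form
(alt ~ Binomial(depth, p(1−e)+(1−p)e) with p the bulk carrier fraction) is
used only as an independent oracle in the tests, never as the
implementation.

**Introgression block.** `inject_introgression_block` overwrites alt
fractions inside an interval in *both* bulks (alt redrawn as
Binomial(depth, af)), modeling a fixed divergent segment — e.g. a
wild-relative introgression — that mimics a high-AF region irrespective of
phenotype.

## Scan

AF = alt/depth per site per bulk, computed after the depth filter (both
bulks within [10, 100], inclusive; a summed-depth variant of the filter is
available). Windows are 10 consecutive SNPs per chromosome, step 1
(configurable); chromosomes with fewer SNPs than the window emit no windows
rather than a shrunken one, keeping window statistics identically
distributed. Window means are arithmetic means (a median variant was
considered and rejected for transparency against the brute-force oracle).

Region calling uses the dual-threshold rule with strict inequalities:
mean AF_mut > 0.95 and mean AF_wt < 0.40. Overlapping or adjacent passing
windows merge; region bounds are the outermost member-SNP positions
(1-based, closed). A `mutant_only` rule (AF_mut > 0.95 alone) exists for
surfacing high-AF regions that fail the wt-like criterion — exactly the
introgression-block situation — after which `rank_regions` orders regions:
dual-rule regions first, then by descending minimum AF_mut, ascending
maximum AF_wt, descending window support, and genomic position. The ΔAF
column in the AF track is for plotting only and never drives calling.

## Effect annotation

Transcript models carry exon and CDS intervals (1-based closed, genomic
order); several isoforms per gene are supported and a variant is classified
against each overlapping transcript, the most severe consequence winning at
prioritization (a mutation in a domain shared by two splice variants is
reported on both). Coding positions are mapped through the spliced CDS with
strand handling; codon and protein changes use compact single-letter
notation (AAG>AAT, K114N). Splice sites are the first/last 2 intron bases
(the common annotator default; the window is a parameter). Exonic bases at
exon/intron boundaries classify by their coding consequence, not as splice
sites. Deleterious = missense, nonsense, stop-loss or splice-site.
Severity order for prioritization: nonsense/stop-loss/splice-site >
missense > synonymous/UTR > intronic > intergenic; ties break by an
optional region rank, then position. Indels and MNVs are out of scope.

## Fine mapping

Only phenotypically mutant (recessive-class) plants are informative by
default: they are inferred homozygous causal, so a non-hom-mut genotype at
a marker is a recombinant; heterozygous calls count (one crossover) and
missing calls are excluded from numerator and denominator. The causal
interval is the maximal contiguous run of zero-recombinant markers, open at
the nearest flanking markers with recombinants (chromosome end if none).
All-zero counts span all markers but are flagged unresolved; all-nonzero
counts return an empty interval with a diagnostic.

The segregation check is a Pearson χ² goodness-of-fit (df = 1) of observed
phenotype counts against 1:3.

## Downstream tables

DEG filtering keeps |log2FC| ≥ 1 AND q < 0.05 AND — when FPKM columns are
present — FPKM strictly greater than 5 in at least one genotype ("greater
than", per the stated cut-off wording). The q threshold defaults to 0.05;
0.07 (used in one plotting context upstream) is available as an option.
q-values are inputs: no expression testing or multiple-testing correction
is performed here. Category counts are exact multiset counts over manually
assigned labels; missing labels are an error naming the genes.

The packaged DEG tables are clean transcriptions of the study's printed
gene lists. Their internal accounting is reproduced as printed, including
its rough edges (category sums quoted in prose do not always match the
table rows); the tables are authoritative here.

Composition calculators implement the stated definitions directly:
RGI branching (Ara+Gal)/Rha, pectin linearity GalA/(Rha+Ara+Gal), Xyl/Man;
DM = mol methanol per 100 mol uronic acid; DA = mass acetic acid per mass
polysaccharide (a raw mass ratio — a ×100 view is formatting only);
cellulose = second-hydrolysis glucose, pectin = uronic acid, hemicellulose
= total neutral sugars minus cellulosic glucose. Zero denominators yield a
flagged not-computable ratio (e.g. rhamnose below detection), not an error;
negative partitions are rejected as inconsistent input.

The synthetic locus fixture (`datasets.synthetic_shn2_locus`) is a
fully specified stand-in for the real gene: three exons, two isoforms
sharing exons 1–2, CDS arranged so the last base of exon 2 is the third
base of codon 114 (AAG); the G→T change there yields K114N on both
isoforms. A mirrored minus-strand version supports strand-symmetry checks.

## Problem sizes and numerical choices

- Default study conditions: 216 plants, bulks of 38, depth 32, error
  0.002, 1300 background SNVs, 10-SNP windows, thresholds 0.95/0.40,
  depth window 10–100.
- The test suite exercises scaled replicates (e.g. 2,000–4,000-plant
  populations for segregation convergence, 20 fine-mapping replicates of
  150 plants) and the acceptance checks run the full design: a
  10,000-plant population for the segregation fraction and 50 independent
  end-to-end experiments for the scan statistics.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); composite runs derive child seeds via
  `SeedSequence`. No hidden global state.
- Windows use cumulative sums (exact for these magnitudes); thresholds are
  compared with strict inequalities exactly as specified.

## Limitations

- The uniform cM↔bp map overstates recombination near real tomato
  pericentromeres; genuine EMS scans there would show wider, flatter AF
  plateaus and easier detection. Consequently the simulated detection rate
  is conservative: with 38-plant bulks the wild-type-like bulk's carrier
  fraction alone has a standard deviation of ~0.034 around its 1/3
  expectation, so individual experiments occasionally graze the 0.40
  threshold even when the design is sound. Median behaviour is robust;
  single-run guarantees are not, and that is a property of the design, not
  of the implementation.
- Counts are generated directly; there is no read-level FASTQ simulation,
  alignment, or variant calling.
- The annotator handles biallelic SNVs only and has no regulatory-region
  or distance annotations.
- Sequencing error is a symmetric per-read flip; no base-quality model.
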