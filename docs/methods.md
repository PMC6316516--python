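# Methods

## Scope and data model

The package analyses targeted bisulfite amplicon sequencing of two
short nuclear-mitochondrial (NUMT) regions in an *A. thaliana*
Col × Ler cross, and simulates the same experiment with known ground
truth. Everything is top-strand only: the amplicon is a fixed,
primer-defined fragment, cytosines on the bottom strand (G positions)
are ignored, and the simulator emits top-strand-converted fragments
only. Coordinates are 1-based inclusive. Alleles are assumed
indel-free (the two study regions differ only by substitutions at
amplicon scale); unequal-length allele pairs are rejected rather than
aligned.

Cytosine context is determined solely by the two bases downstream of
the cytosine: G at +1 gives CpG, otherwise G at +2 gives CpHpG, else
CpHpH. Cytosines within two bases of the 3' end are resolved through
an optional flank sequence; without a flank they are dropped with a
warning (no authoritative edge policy exists for these amplicons, and
dropping is conservative: it can only remove sites, never mislabel
them). Shared sites are positions that are cytosines with identical
context in both alleles; positions overlapping a SNP are excluded so
that a site's counts never depend on which allele a read matched. A
SNP is *informative* when the possible read-base sets of the two
alleles after conversion are disjoint, treating a reference C as
readable {C, T} and every other base as itself — so C/T SNPs are
uninformative by construction.

## Reference sequences

The study's amplicon sequences are not deposited, so the default
references are deterministic synthetic stand-ins
(`reference.default_regions`): seeded random sequences with the real
amplicons' lengths (133 and 201 bp), genomic spans, and informative
SNP counts (4 and 2, A↔G substitutions). SNPs are placed inside the
window covered by both 150-base mates so every read pair covers at
least one informative SNP. Consequently shared-site context counts
(8/6/25 and 11/7/41 for CpG/CpHpG/CpHpH) do not reproduce the real
regions' counts (2/5/23 and 10/6/33); analyses that depend only on
amplicon geometry, chemistry and statistics are unaffected. Real
sequences can be supplied as a FASTA with `<region>|<Col|Ler>` record
ids.

## Simulator

The generator's defaults are the study conditions:

* **Design** — 2 + 2 parents, reciprocal F1 of 18 and 19, four selfed
  F2 populations of 30/28/30/30 (159 individuals).
* **Pedigree** — parents homozygous, F1 all CL, F2 i.i.d. from
  (0.25, 0.5, 0.25).
* **Methylation** — each individual × allele × motif draws one
  probability from a beta law; the (mean, s.d.) hyperparameters per
  population group, allele and motif reproduce the experiment's
  published per-population summary for both regions. Parental lines,
  whose dispersion is not estimable from two individuals, use a
  near-point-mass beta (concentration ν = 1000). The drawn
  probability applies to every cytosine of that motif on that allele;
  there is no per-site heterogeneity, because the weighted estimator
  pools counts across sites and is insensitive to it.
* **Heterozygote coupling** — in CL individuals the two alleles'
  draws are coupled per motif by a Gaussian copula whose correlation
  is set to 2·sin(πρ/6), making the population Spearman correlation
  equal ρ exactly. Region 1 defaults to ρ = 0.57/0.75/0.97
  (CpG/CpHpG/CpHpH), the trans-allelic correlations observed in F2
  heterozygotes; region 2, for which no correlation was reported,
  defaults to 0. The same coupling is applied to F1 heterozygotes
  for lack of a separate estimate.
* **Chemistry** — unmethylated C is read as T with probability
  ε = 0.99 (conversion efficiency), methylated C as C with
  probability 1.0 (protection); the two failure modes are modelled
  separately so tests can isolate each. Uniform substitution errors
  at 0.001 per base. The expected apparent level of a site with true
  probability p is p·protection + (1−p)(1−ε).
* **Reads** — fragments span the whole amplicon; the fragment count
  per individual per region is Poisson with mean `coverage` (default
  50,000, mirroring the experiment's >40,000 mapped reads;
  tests and the acceptance script use 25–2,000). Mates of 150 bases
  read the two ends, R2 reverse-complemented; reads longer than the
  amplicon are truncated to it, so for the 133 bp region both mates
  cover every position. Methylation state is drawn independently per
  fragment per site (no epihaplotype structure). Qualities are
  constant Q37 except error-injected bases, which get Q12 so the
  trimming stage has something real to act on.

Every read id embeds individual, region, fragment and source allele;
the truth tables (genotypes, drawn probabilities) are written beside
the FASTQ files. The whole simulate→FASTQ path is deterministic given
the seed (one generator consumed in fixed design order).

What the simulator does **not** emulate: PCR duplicates and chimeras,
index hopping, PhiX, quality decay along the read, strand mixtures,
per-site probability heterogeneity within a motif, and any mechanistic
link between generations (each population's levels are drawn from its
own hyperparameters rather than inherited read-by-read). Passing
tests therefore validate the pipeline's arithmetic, assignment logic
and statistics under the study's design and noise scales — not
robustness to real library artefacts.

## Analysis pipeline

* **QC** — trailing bases below Q20 are trimmed; pairs are dropped
  when either mate falls under 100 bases. Only trailing-quality
  trimming is implemented; interior low-quality bases are left to the
  mismatch budget.
* **Assignment** — ungapped bisulfite-space comparison at the mate's
  fixed offset (R1 at the start, reoriented R2 at the end) against
  both alleles of every region; the pair is attributed to the region
  with the smaller combined best-allele mismatch count, then each
  mate to the allele with the strictly smaller count, requiring
  ≤ `max_mismatch` (default 5 per 150-mer, ≈3%; no threshold is
  stated for the original analysis) and coverage of an informative
  SNP. Ties and SNP-less reads are ambiguous; mates with conflicting
  calls are both demoted to ambiguous. Ambiguous and unmapped reads
  enter neither genotyping nor methylation counts.
* **Mapping-error rule** — per individual × region, if the minor
  allele holds strictly less than 5% of mapped reads those reads are
  discarded as mapping error (applied per individual × region; the
  rule's original granularity is not stated). Zero mapped reads flag
  the individual failed-QC.
* **Counting** — both mates are scored independently, so positions in
  the mate overlap are counted twice; this doubles nominal coverage
  there but leaves level estimates unbiased, and no deduplication is
  attempted. Observed A/G bases at a shared site are tallied as
  sequencing error, not as counts. Motif contexts come from the
  reference annotation only.
* **Estimators** — weighted methylation (pooled counts) is the
  per-individual statistic; fractional methylation (mean of per-site
  ratios) is used only for region-level strain comparisons from
  external per-site tables. Zero-coverage sites and groups give NaN
  ("undefined") levels, excluded from summaries; zero-coverage sites
  are silently excluded from fractional means.
* **Statistics** — segregation: Pearson chi-square against 1:2:1,
  df = 2, no continuity correction. Reciprocal comparison: two-sided
  Mann–Whitney with midranks per region × allele × motif on F1
  individuals; the crosses merge only if every comparison has
  p ≥ 0.001, and undefined comparisons (n < 2) merge by default. No
  multiplicity correction is applied across motifs/alleles.
  Correlation: Spearman's ρ over F2 heterozygotes with both alleles
  defined (≥ 3 required), OLS of Ler on Col with pointwise 95%
  confidence bounds of the regression mean. Summaries use the sample
  s.d. (n−1), blank for n = 1.

## Numerical and design choices

* Chi-square type-I error at n = 30 runs slightly conservative
  (≈0.042 at nominal 0.05, df = 2) — a property of the asymptotic
  test at this sample size, verified by simulation in the test suite.
* The copula calibration r = 2·sin(πρ/6) is exact for the Spearman
  correlation of a Gaussian copula; beta marginals preserve it
  (monotone transforms).
* Problem sizes: the test suite and acceptance script run the full
  159-individual design at 25–150 fragments per individual per
  region, and single-individual checks at up to 10,000 fragments —
  scales at which every asserted tolerance (3 binomial s.d., ±0.05 on
  ρ recovery) is meaningful while a run stays in seconds.
* Exit codes of the CLI: 0 ok, 1 user error, 2 internal error.

## Known limitations

* No indel handling and no general alignment; references must match
  read geometry exactly.
* Single-strand model: data from the opposite bisulfite strand would
  need reorientation before use.
* The mapping-error rule assumes a two-allele world; contamination
  from a third haplotype would be silently absorbed.
* With the default synthetic references, absolute site counts per
  motif differ from the real amplicons; analyses of per-motif site
  numbers should supply the real FASTA.
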