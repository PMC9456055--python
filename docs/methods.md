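# Methods

## Exact star-allele matching

A gene's definition set declares an ordered list of biallelic variant
sites (identified by exact `(chrom, pos, ref, alt)` string match; no
indel normalization or left-alignment is attempted — a representation
mismatch surfaces as "site absent") and a list of star alleles, each a
mapping from defining sites to required alleles. Exactly one allele per
gene is the reference; its requirement set is empty.

A haplotype matches an allele iff every defining site is observed with
the required allele **and** every other observed declared site is
reference. Consequences worth spelling out:

- the reference allele matches exactly the all-observed-reference
  haplotype;
- an allele whose defining sites are a subset of another's is excluded
  whenever the extra sites are observed non-reference (a \*2-pattern
  haplotype that also carries the \*3-specific variant matches \*3 only);
- if any declared site of the gene is missing on either haplotype, the
  diplotype is *Not available*. No partial or probabilistic matching is
  done: imputation uncertainty should be handled upstream, not absorbed
  silently into calls.

When one haplotype matches several alleles, the allele satisfying the
most defining sites wins; if several tie at that count they are
genuinely indistinguishable under exact matching and the diplotype is
reported *ambiguous* (lexicographic name order is used only to make the
reported match list deterministic). Called pairs are emitted in
canonical order — reference allele first, then lexicographic — so calls
are invariant under swapping the two physical haplotypes.

Structural variants and copy number are not modeled; genes whose common
alleles require them (CYP2D6 above all) inherit this limitation, and in
practice their calls concentrate in *Not available*/*Indeterminate*.

## Phenotypes, nontypical status and burden

Nontypical status is data, not logic: the knowledge fixture carries a
per-(gene, phenotype) flag, because whether CPIC recommends an alternate
drug/dose is an external clinical judgement, not derivable from the
genotype. Two labels are reserved and always typical: *Not available*
(uncalled) and *Indeterminate* (called pair absent from the map).

Per-sample burden counts **genes** (at most one unit per gene), and the
at-risk drug set is the union of level-A drugs over the sample's
nontypical genes — so warfarin, linked to CYP2C9, CYP4F2 and VKORC1, is
counted once however many of those genes are nontypical. Per-drug risk
is likewise the fraction of individuals nontypical in *any* gene linked
to the drug, an individual-level union rather than a per-gene maximum.
Percentages are printed half-up to 2 decimals, frequencies to 8.

## Marker filtering and allele frequencies

The post-imputation filter retains markers with imputation quality
(dosage r², INFO key `RSQR` by default) above 0.3 at MAF ≥ 1%, above 0.6
at MAF < 1%, and all directly genotyped markers (absent quality key).
Frequency denominators count non-missing haplotypes only; a genotype
with any missing allele is missing as a unit. Heterozygous unphased
genotypes are rejected by default (the caller requires phase) but can be
demoted to missing; homozygotes are accepted regardless of separator.

## IBD estimation and pruning

Pairwise IBD proportion uses the method-of-moments IBS→IBD
decomposition with allele frequencies estimated from the cohort: the
observed counts of IBS 0/1/2 over jointly observed markers are equated
with their expectations under IBD 0/1/2, solved sequentially for
Z₀, Z₁, Z₂, and π̂ = Z₁/2 + Z₂ clipped to [0, 1]. Monomorphic markers
are dropped; fewer than 50 usable markers is an error (IBD from a
handful of sites is meaningless, which is also why the profiling CLI
refuses to prune from a gene-panel VCF).

Pruning is deterministic and greedy: flag all pairs with π̂ above the
threshold (default 0.05); remove every trio offspring involved in a
flagged pair; then repeatedly remove the sample with the largest summed
π̂ over remaining flagged pairs (ties broken by sample identifier),
recomputing after each removal. The retained set has max pairwise
π̂ ≤ threshold by construction.

For testing, the marker-panel simulator uses 20,000 unlinked SNPs with
MAF uniform on [0.05, 0.5]. At that size the unrelated-pair π̂ standard
deviation is ≈ 0.005, so a 0.05 threshold separates parent–offspring
pairs (π̂ ≈ 0.5) from noise with a wide margin; at 2,000 markers the
noise (sd ≈ 0.018) already flags a few percent of unrelated pairs. Real
analyses use orders of magnitude more markers; the panel size here is a
desk-scale choice that preserves the statistical geometry.

## Fisher exact test and FDR

The two-sided Fisher p-value follows the point-probability rule: the
sum, over the margin-fixed hypergeometric support, of outcome
probabilities no larger than the observed table's. Tables with total
N ≤ 500 are evaluated in exact integer arithmetic (binomial-coefficient
numerators compared exactly, so ties are decided without tolerance);
larger tables use log-space probabilities with the customary 1 + 1e-7
relative tie tolerance. Benjamini–Hochberg q-values use the standard
step-up formula, clipped at 1, returned in input order; q ≥ p and
monotonicity in the p-ordering hold by construction.

Phenotype-frequency testing needs counts on both sides, but reference
cohorts are often published as frequencies; the reference cohort size is
therefore a required input and counts are reconstructed as
`round(freq · n_ref)`. This makes reference p-values reproducible only
up to that rounding — published p-values computed from unpublished raw
counts are not exactly recoverable.

## Differentiation screen conventions

Delta is signed on the ALT allele declared in the study table. When the
reference table declares swapped ref/alt, its frequency is flipped;
strand-ambiguous A/T and C/G sites are dropped with a warning rather
than guessed. A variant carrying several clinical annotations is
assigned its strongest tier (1A < 1B < 2A < 2B < 3 < 4). Screen
thresholds (|Δ| ≥ 0.05 for high-evidence, ±0.10 for the up/down tiers)
are configurable; the implementation applies them to the signed ALT
delta, which is how the source tables report "MAF ≥ x% higher".

## The synthetic generator

Per gene, the two haplotypes of each sample are i.i.d. draws from a
star-allele frequency table (Hardy–Weinberg), rendered to site codes via
the definitions. The bundled default frequencies are realistic European/
isolate-population values, with the VKORC1 promoter variant at its
published study frequency 0.509 and the two promoter-region sites locked
to r² = 1 (they are carried by the same defining allele, mirroring the
reported perfect LD). Missingness hits genotypes (both alleles at once)
with the configured rate; unphasing hits only heterozygotes, since
homozygote phase is vacuous. Trio children receive one whole-gene
haplotype per parent, giving expected parent–offspring π = 0.5 exactly.

What the generator does **not** emulate: background LD beyond explicit
locks, demography/founder effects, imputation-error structure (quality
values correlated with frequency), multi-site genes with dozens of
alleles, or structural variation. Passing recovery tests therefore show
the pipeline's bookkeeping and matching logic are correct, not that real
cohort calls at noisy sites would be this clean.

A separate constructor rebuilds a phenotype-call cohort directly from a
published per-gene count table (labels dealt deterministically to sample
identifiers). Its joint distribution across genes is arbitrary; it
exists to verify marginal summaries — frequencies and per-gene at-risk
fractions — against published arithmetic, not joint quantities like the
burden histogram.

## Problem sizes used in tests and acceptance runs

Caller recovery: 500 samples, 14 genes, 3 seeds, missingness 0 and 0.2.
Relatedness: 100 unrelated + 50 trios over 20,000 markers. Fisher
calibration: 2,000 null tables of 1,500 per group; oracle agreement: 200
random small tables at 1e-12. All chosen so the full suite runs in well
under a minute on one CPU while keeping each statistical check far from
its noise floor.

## Known limitations

- Exact matching over toy definitions (1–2 sites per gene) understates
  the ambiguity real PharmCAT tables produce; composite allele labels
  (e.g. "\*2 + \*3") are treated as opaque names.
- The drugs-over-threshold count depends entirely on the gene–drug
  table supplied; with the toy level-A table it is not comparable to
  counts computed from a full CPIC export.
- No dosing recommendations, no prescription-weighted risk, no
  imputation, phasing, liftover, or multiallelic decomposition beyond a
  reject/skip switch.
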