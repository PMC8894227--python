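# Methods

## Scope

`tetrahap` re-implements, as a tested pipeline, a candidate-gene haplotype
analysis for autotetraploid crops: a single gene region is re-sequenced in
two amplicons across a cultivar panel, every SNP is *quantitatively* scored
(allele copy number 0–4 per individual rather than a discrete genotype
call), and the collective dosage information is used to (i) infer each
individual's four-allele haplotype configuration, (ii) describe the
panel's autotetraploid diversity, (iii) check parent–offspring transmission
in the breeding pedigree, and (iv) associate haplotype dosage with a
quantitative phenotype (starch-bound phosphate, nmol PO₄/mg starch). A
synthetic-data generator reproduces the statistical structure of such a
study so that every stage can be validated against known truth.

## Haplotype calling from dosages

**Model.** For amplicon *m*, let `M` be the binary haplotype × variant
incidence matrix and `c_i` the vector of haplotype copy numbers of
individual *i* (entries ≥ 0, summing to the ploidy). The noise-free dosage
of variant *v* is `(c_i M)_v`; observed dosages add Gaussian error (sd
`noise_sd`, clipped to [0, 4]) and may be missing. Multi-allelic sites are
encoded as one variant row per non-reference base; the reference base per
aligned column is the frequency-weighted majority.

**De novo route** (`call_de_novo`): squared Pearson correlation between
variant dosage profiles (pairwise-complete individuals) defines a graph;
connected components at r² ≥ 0.9 are co-segregating SNP blocks. Connected
components rather than complete linkage: one noisy pair should not split a
block. The threshold is configurable; 0.9 separates same-haplotype variants
(r² ≈ 0.95 at the preset noise) from blocks shared between common
haplotypes (r² ≲ 0.7).

Each cluster is represented by its minimal-total-dosage, best-quantifiable
variant (min missingness, then max variance, then lowest position). The
minimal-dosage restriction matters: a cluster may also contain variants
shared with a rare second haplotype, or complement-encoded variants
(minority base where the haplotype's base is the majority), whose dosage
profiles are strictly larger.

Clusters are then reduced to *atoms* (putative haplotypes) by profile
algebra: visiting clusters in decreasing total dosage, a cluster whose
integer-rounded profile equals the sum of two surviving clusters' profiles
— or the ploidy-complement of such a sum — is a shared block and is peeled
away. Visiting larger profiles first keeps the symmetric complement
relation from ever peeling a true atom; restricting decompositions to
survivors keeps the relation acyclic. Up to `max(3, 2% of n)` disagreeing
entries are tolerated (Gaussian noise at sd 0.15 flips a rounded dosage
with p ≈ 9·10⁻⁴, i.e. about one flip per three-profile comparison at
n = 400, while a wrong decomposition disagrees at every carrier of the
extra allele — ≈ 16 entries at the preset's rarest-allele frequency).
Atoms are matched across amplicons by integer-profile agreement (≥ 98%)
and given common names.

**Known-panel route** (`rules_from_incidence`): haplotypes with identical
incidence rows within an amplicon are identical-in-state there and merge
into one resolvable unit. Units with a variant carried by them alone get a
unique tag SNP; units without one are resolved by subtraction — the dosage
of a shared variant minus the copies of its already-resolved co-carriers —
in a topologically ordered rule chain; a unit carrying no variant resolves
last as the ploidy complement. An unorderable dependency set raises an
error naming the offending units.

**Resolution** (`resolve_genotypes`): variant dosages are rounded to
integers per variant *before* rule evaluation (the quantitative scores are
approximations of integer copy numbers; at 16 tags × sd 0.15 the unrounded
copies sum to 4 ± 0.6, which would spuriously fail ~40% of individuals
against the ±0.5 sum check). The rule outputs must then sum to the ploidy
within 0.5 or the amplicon is discarded as failed — never silently
repaired; largest-remainder rounding reconciles fractional outputs in the
optional unrounded mode. Amplicons must agree on every haplotype copy they
both resolve, or the individual is `failed`. A haplotype resolvable only
inside an identical-in-state unit yields a group-level allele and status
`grouped-only`, unless the other amplicon resolves the subtypes
(cross-amplicon rescue).

On noise-free data the rule solver provably returns the least-squares
four-multiset; the test suite checks it against exhaustive search over all
C(K+3, 4) multisets.

## Autotetraploid diversity

* `Ai`: mean number of distinct alleles per individual (1–4).
* `Ho`: mean fraction of the six unordered within-individual allele pairs
  that are heterozygous; by multiplicity pattern this weights the Gallais
  classes 1 (abcd), 5/6 (aabc), 4/6 (aabb), 3/6 (aaab), 0 (aaaa).
* `He`: bias-corrected gene diversity `(n/(n−1))(1 − Σ p²)` over the
  n = 4N allele copies, the natural expectation under random chromosome
  segregation.
* `F = 1 − Ho/He`; deviation from tetrasomic Hardy–Weinberg equilibrium is
  assessed by a permutation test (default 999 permutations) that shuffles
  all allele copies and re-forms individuals in blocks of four, using |F|
  as statistic; the analytic χ² (`N·F²(k−1)`, df `k(k−1)/2`) is reported
  only as a labelled approximation.

π (nucleotide diversity) is the mean pairwise per-site p-distance over the
haplotype sequences, amplicons concatenated, columns with a gap in either
sequence excluded pairwise; the frequency-weighted variant is
`Σ_{i≠j} p_i p_j d_ij`. Raw p-distance is used here (Jukes–Cantor is
reserved for the dendrogram); `1/π` gives the average SNP spacing in bp.
Codon effects translate every coding alternate base in its reference-codon
context (distinct mutated codons counted once) into synonymous /
non-synonymous / premature-stop tallies, with intronic variants counted
separately. The dendrogram uses Jukes–Cantor distances
`−(3/4)ln(1 − 4p/3)` (pairs at p ≥ 3/4 are reported as saturated),
neighbor-joining (scikit-bio's canonical implementation), optional
outgroup rooting, and bootstrap support from column resampling of the
concatenated alignment.

## Pedigree transmission

Gametes under random chromosome segregation: each of a tetraploid's six
unordered chromosome pairs with probability 1/6 (double reduction is
excluded; the config flag is reserved). A trio is compatible iff the
offspring multiset equals the union of one gamete from each parent (6×6
enumeration); a duo is compatible iff some gamete-sized sub-multiset of the
offspring is contained in the known parent. Genotypes resolved only to
group level are compared at group resolution to avoid false mismatches.
Mismatches are aggregated per implicated parent; parents implicated in ≥ 3
mismatching pairs are flagged as recurrent offenders. Offspring
distributions of crosses/selfings are exact convolutions of the gamete
distributions (exact rationals), optionally marginalized to a focal
allele's dosage.

## Association

Fixed-effects OLS of (replicate-averaged) phenotype on haplotype dosages.
No population-structure correction is applied — a deliberate
simplification, validated by the permutation cross-check in the test
suite. Grouped subtypes (A1–A5) enter as one summed group dosage plus
nested subtype deviations (most frequent subtype as nested reference).
Because dosages sum to the ploidy, the most frequent ungrouped haplotype is
omitted as reference; any further rank deficiency is refused with the
offending columns named, never silently dropped. Marginal explained
variance is the R² of the single-regressor model in percent. Per-class
phenotype summaries use one-vs-rest Welch tests restricted to classes with
≥ 4 members (below that the Welch standard error estimate is unstable and
the family-wise error rate is badly inflated; smaller classes are reported
descriptively), Bonferroni-corrected. Segregating-population comparisons
bin offspring by focal-allele dosage, with pairwise Welch tests and a
dosage-trend regression.

## Synthetic-data generator

The generator defines the study conditions; its defaults are the
`panel-2012` preset:

* **Panel**: 16 haplotypes over two amplicons of 627 and 606 bp, tuned to
  unweighted π = 0.0185 (realized within site granularity, ≈ 0.0186).
  Sites are added until the target pairwise-mismatch budget is met: one
  private tag site per haplotype per amplicon first, then sites shared by
  random haplotype pairs (mimicking co-segregating blocks). Shared sites
  use pair carriers only; higher-order sharing is supported in the
  known-rules route but not emitted by the generator.
* **Frequencies**: the reference allele-frequency spectrum (A3 31.8%,
  B 20.8%, …, ten alleles below 5%) with a 1% floor on the ultra-rare
  alleles, renormalized. The floor is an identifiability requirement, not a
  convenience: a 0.1% allele is entirely absent from a 400-individual
  cohort with probability ≈ 0.2, and an allele with only a handful of
  carriers cannot be separated from a shared SNP block by co-segregation
  statistics (in the real study such alleles were confirmed by cloned
  amplicon sequencing — information dosage data does not contain). At 1%
  (≈ 16 expected copies) every haplotype is statistically identifiable.
* **Cohorts**: four allele copies i.i.d. from the panel frequencies
  (tetrasomic HWE); n = 398 by default with 3.5% whole-amplicon dropout.
* **Dosage observation**: incidence × copies + N(0, 0.15), clipped to
  [0, 4]; independent missingness; noise is continuous and unrounded
  (rounding is the caller's decision).
* **Pedigrees**: HWE founders, offspring by random-segregation gametes.
* **Phenotypes**: `y = μ + β_A(x_A − E x_A) + β_H(x_H − E x_H) + Σ_q g_q + ε`
  with μ = 22.5, total sd 4.3, heritability h² = 0.83, marginal variance
  fractions 13.4% (grouped A, negative) and 4.7% (H, positive). The two
  effects are solved from the marginal-R² equations *jointly*, including
  the multinomial covariance `Cov(x_A, x_H) = −4 p_A p_H` (ignoring it
  overshoots the A fraction by ≈ 2 points). Two unlinked biallelic
  background QTLs (frequency 0.5) absorb the remaining heritable variance
  (≈ 32% each) and ε the rest. Centring the genetic terms makes the
  population mean exactly μ.

What the generator does *not* emulate: chromatogram traces and their
base-caller error structure (noise is Gaussian by assumption; the real
scoring error model is unpublished), within-gene recombination, double
reduction, population structure and pedigree-induced disequilibrium in the
association cohort, genotype–environment interaction, and linkage between
the candidate gene and the background QTLs. Passing tests therefore
demonstrate correctness of the algorithms under these idealized study
conditions, not robustness to every artefact of real Sanger data.

## Numerical choices

* Dosage rounding precedes rule evaluation (above); Σ-tolerance 0.5.
* Largest-remainder rounding breaks ties toward the lower index.
* Cluster-peel tolerance `max(3, 2% of n)` mismatching entries; duplicate
  profiles merge at ≤ 1 mismatch.
* NJ join ties are resolved deterministically by input order; bootstrap
  support is reported on internal edges as % of replicates containing the
  same bipartition.
* Permutation p-values use the add-one estimator `(1 + #extreme)/(R + 1)`.
* Degenerate inputs: monomorphic variants are flagged and excluded from
  clustering; constant dosages make marginal association untestable
  (explicit status, not an exception); saturated sequence pairs make JC
  undefined (explicit error).

## Problem sizes used in validation

Test and acceptance runs use the cohort sizes the study design calls for:
n = 400 for end-to-end calling, n = 203 × 50 replicate cohorts for
phenotype calibration, 10⁵ draws for distributional checks, 100–400
replicates for error-rate calibration, 999/199 permutations for
full/replicated permutation tests. Mean sample marginal R² at n = 203
slightly exceeds the population fraction (≈ +0.7 for A, ≈ +0.8 for H);
this is the standard upward bias of R² in finite samples and sits well
inside the calibration tolerances.

## Known limitations

* De novo atom identification assumes shared SNP blocks involve two
  haplotypes (pair-sums and their complements); a block shared by three or
  more haplotypes with no nested sub-block would survive peeling. The
  known-panel route has no such restriction.
* Group-level (identical-in-state) genotypes participate in transmission
  checks at group resolution only; a subtype-level mismatch hidden inside a
  group is undetectable by construction.
* The analytic χ² HWE test is an approximation whose null distribution is
  not exact for highly skewed frequency spectra; the permutation test is
  the reference.
* VCF output is export-only (dosage in a DS-style field); round-tripping
  through VCF is not supported.
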