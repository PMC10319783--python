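# Methods

## The filtering model

`famvar` targets the standard family-based design for dominant Mendelian
and oligogenic disorders: a small number of multiplex pedigrees are
sequenced, and within each family candidate variants must satisfy three
independent predicates.

**Co-segregation (pedigree stage).** Under an autosomal-dominant model a
causal variant is carried heterozygously by every affected member and by no
unaffected member. `check_autosomal_dominant` counts, among genotyped
members with a known phenotype, affected non-carriers and unaffected
carriers, and passes a variant iff both counts are within configurable
tolerances (`SegregationPolicy`, defaults 0 and 0 — strict full
segregation). By default an affected homozygous-alternate member also fails
the variant (`require_het_in_affected`), reflecting the heterozygous
carrier model; the flag exists because consanguineous pedigrees can
legitimately produce affected homozygotes. Members with unknown phenotype
never contribute. Missing genotypes are non-informative by default (not
every pedigree member is sequenced); the alternative `fail` rule counts a
missing genotype as a violation of its phenotype class, for analyses that
require complete data. A variant with no informative affected genotype
fails outright — absence of evidence is not segregation.

**Rarity and consequence.** Only protein-altering classes pass: missense,
frameshift, stopgain, splice site. The aggregate MAF is the maximum over
all available frequency sources — the most conservative choice when
several databases are consulted and no combination rule is specified — and
must be strictly below 0.01. A variant absent from every source passes by
default (`missing_maf_is_rare`): novelty is itself evidence of rarity, and
observed candidate sets include database-absent variants.

**Deleteriousness consensus.** Four predictors with strict thresholds:
SIFT < 0.05 (lower = less tolerated substitution), PolyPhen2 > 0.825
(probably-damaging regime), CADD > 20 (PHRED scale: top 1% of ranked
substitutions), GERP++ > 2 (evolutionary constraint). A missense variant
must be called damaging by at least `min_damaging = 3` of the four. Two
policies soften this rule where it cannot apply:

- *LoF bypass*: frameshift, stopgain and splice-site variants are presumed
  damaging and skip the consensus — the predictors are missense-oriented
  and return no score for these classes.
- *Adaptive availability*: when only `k < 4` predictors are annotated the
  requirement becomes `min(3, k)` (at least 1); an entirely unscored
  missense variant fails. A strict-4 analysis is obtained by supplying all
  four scores, in which case the full 3-of-4 rule applies unchanged.

All inequalities are strict, exactly as the thresholds are conventionally
quoted; boundary values (MAF = 0.01, CADD = 20) therefore fail.

## Aggregation and two-stage reconciliation

Within-family filtering is hypothesis-generating; evidence accumulates
across families. `aggregate_by_gene` rolls retained variants up to one
record per gene (distinct families, distinct variant keys, stage labels),
flagging variant keys observed in ≥ 2 families as identical shared
variants. `reconcile_stages` marks a discovery gene *exactly replicated*
when the validation stage retains any variant in the same gene, and —
given an anchored prefix pattern such as `LRR` — *group replicated* when
its prefix-defined gene family contains at least one validation gene.
Prefix grouping is deliberately explicit and user-configurable because
"gene family" is an informal notion; an anchored regex makes the grouping
rule auditable. Ranking of candidates is deterministic (family count
descending, then minimum aggregate MAF ascending with database-absent
variants first, then symbol); biological prioritization (e.g. neural
function) is delegated to a user-supplied category map
(`annotate_categories`) rather than hard-coded.

## Enrichment statistic

Candidate gene sets are tested against a GMT library with the two-sided
Fisher exact test: for each term a 2×2 table over the gene universe
(default: the union of the library; the original web-server universe of
any given study is not reproducible offline, so the universe is an
explicit knob). The two-sided p-value follows the probability-mass rule —
the sum of hypergeometric outcomes no more probable than the observed
table — computed by exact integer enumeration of the support
(`math.comb`), so ties are resolved exactly; a 10⁻⁷ relative tolerance is
applied when comparing probabilities, matching the convention of mainstream
statistical libraries (the test-suite cross-checks against
`scipy.stats.fisher_exact` and an independent exact-fraction enumerator).
Benjamini–Hochberg q-values (via `statsmodels`) are reported alongside raw
p-values; raw p drives the ordering.

## The synthetic cohort generator

The generator exists so every stage can be tested, end to end and at
scale, without access to human genotype data. It emulates:

- **Pedigree shape** — 3 large discovery families (3 generations,
  19 members) and 49 small validation families (2 generations, 6 members)
  by default, matching the two-stage design scale; members marry in as
  founders and the structure is deterministic given the configuration.
- **Transmission** — one causal variant per family (families are
  genetically heterogeneous, mirroring the observed one-gene-per-family
  pattern), introduced heterozygously in one founder and gene-dropped with
  fair-coin gamete draws; background variants give founders Hardy–Weinberg
  genotypes at their simulated MAF and transmit identically. Every
  non-founder genotype is Mendelian-consistent by construction.
- **Phenotype model** — carrier ⇒ affected with probability `penetrance`
  (default 1.0), non-carrier ⇒ affected with probability `phenocopy_rate`
  (default 0.0). Non-default values let tests measure how recovery
  degrades under misspecification.
- **Annotations** — causal variants draw scores uniformly inside the
  damaging regions (SIFT ∈ (0, 0.05), PolyPhen2 ∈ (0.825, 1),
  CADD ∈ (20, 40), GERP ∈ (2, 6)) and carry `causal_maf` (default 0 =
  absent from all sources, i.e. novel). Background variants draw a
  consequence class (missense 0.40, synonymous 0.30, other 0.12, splicing
  / frameshift / stopgain 0.06 each — protein-altering classes are a
  minority of exonic variation), a MAF from a 50/50 mixture of
  Uniform(0.01, 0.5) (common) and Uniform(0, 0.01) (rare), and benign-like
  scores except for a 10% annotation-noise fraction with causal-like
  scores. Non-missense variants carry no predictor scores, as annotation
  tools behave.

Under this model the probability that a background variant survives the
annotation filter has the closed form
`P = P(MAF < 0.01) · [P(LoF class) + P(missense) · P(causal-like scores)]`
(= 0.5 · (0.18 + 0.40 · 0.1) = 0.11 at the defaults), which the test-suite
compares against the empirical rate over 5000 simulated variants.

What the generator does **not** emulate: linkage disequilibrium and
recombination, relatedness between families, sex chromosomes, genotyping
error and missingness patterns, realistic site-frequency spectra, and
correlated predictor scores. Passing tests therefore demonstrate that the
filtering logic is correct under its stated model, not that the model
captures every property of real cohorts.

## Numerical and formatting choices

- Variant identity is the normalized tuple (chromosome without `chr`
  prefix, 1-based position, upper-case ref, alt); multi-allelic VCF records
  are split into bi-allelic records before filtering, with per-allele
  alternate counts (a `1/2` genotype is heterozygous for each split
  allele). Phase is ignored.
- `NA` (case-insensitive) and the empty string both denote missing values
  in annotation TSVs; reports print numbers with 12 significant digits so
  write-then-read is the identity.
- Fisher p-values are exact rationals evaluated in double precision; the
  tie comparison is performed on integers, so no floating-point tie
  artifacts arise.
- The segregation, filtering and aggregation paths contain no randomness;
  the simulator derives all draws from a single `numpy` generator seeded
  by `SimulationConfig.seed`, making cohorts byte-reproducible.

## Problem sizes used in the checks

The reproduction script and acceptance checks use the fixture tables as-is
(6 + 12 + 3 variants), an exhaustive 3⁶ genotype grid on a six-member
pedigree against an enumeration oracle, 100 simulated families for
causal-variant recovery, 5000 background variants for the survival-rate
comparison, every 2×2 table with total ≤ 60 for Fisher correctness, and
2000 random candidate draws for null calibration of the enrichment scan.

## Known limitations

- Only the autosomal-dominant model is implemented; X-linked and recessive
  segregation (and compound heterozygotes) are out of scope.
- Predictor scores are inputs; the package never runs SIFT/PolyPhen2/
  CADD/GERP++ itself.
- Whether "nonsense" should include stop-loss is treated conservatively:
  stop-loss maps to the `other` class and is filtered out unless the
  allowed-consequence set is extended.
- No LOD-score linkage analysis, haplotype phasing or IBD inference; the
  co-segregation check is a per-variant predicate, not a likelihood model.
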