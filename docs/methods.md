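# Methods

## Scope and data model

The package consumes per-site trio genotype records — genotype, allelic
depths, total depth, genotype quality per individual, plus the six
variant-site annotations (QD, FS, MQ, MQRankSum, ReadPosRankSum, SOR) — in
a base-pair-resolution VCF dialect where non-variant sites appear as
records with no alternative allele. It does not map reads or call
genotypes; upstream read processing is represented only through its
products (the records) and through the curation false-positive rate β.
Analyses are restricted to biallelic autosomal SNVs; multi-allelic sites
are excluded from both candidacy and callability, since a de novo
candidate is defined on a single alternative allele. Coordinates are
1-based inclusive everywhere.

Internally each trio's records are held as dense numpy arrays over
positions 1..n (`pedmut.sites.TrioSites`); the record-stream interface
converts to and from this container, so every filter exists exactly once,
vectorized. Cohorts are one VCF per trio, mirroring per-trio joint
genotyping; a parent shared by several trios appears in each of them.

## The candidate funnel

Candidates start as Mendelian violations with both parents homozygous
reference and the offspring heterozygous. Four filters follow, in order:

1. **Site annotations** — strict threshold comparisons as printed (QD < 2.0
   fails; QD = 2.0 passes). A missing annotation passes: rank-sum
   statistics are undefined at sites lacking one allele, and absence
   carries no evidence against the site.
2. **Allelic balance** — offspring alternative-read fraction within
   [0.30, 0.70], bounds inclusive ("30–70%" names a closed range); zero
   depth fails.
3. **Depth** — all three individuals within [0.5, 2] × the trio's mean
   depth, where the trio mean is the mean of the three individuals'
   genome-wide mean depths (a trio-level constant, not a per-site mean);
   this targets the excess of spurious violations at low coverage.
4. **Genotype quality** — GQ ≥ 60 in all three individuals.

Finally, any site carried by two or more offspring among whom some pair
shares no parent is removed for all carriers; sibling- and
half-sibling-shared sites are retained as candidate postzygotic events.
Funnel counts per stage are reported per trio and are non-increasing by
construction.

## Rate estimation

Per trio, μ = m(1 − β)/((1 − α)·2·C).

- **Callability C** counts sites where both parents are HomRef and all
  three individuals pass the depth and GQ filters. The allelic-balance and
  annotation filters are deliberately excluded from C — they act only on
  variant sites, and their loss is carried by α instead.
- **False negatives α** are estimated from heterozygous transmission sites
  (one parent HomRef, the other HomAlt, offspring Het), pooled across
  trios: α_ab is the fraction of such offspring whose allelic balance
  falls outside the filter bounds; α_site is the tail mass of normal
  distributions fitted to FS, MQRankSum and ReadPosRankSum at those sites,
  beyond the hard thresholds — upper tail only for FS, both tails for the
  rank sums, matching the directionality of the printed thresholds. QD,
  MQ and SOR are excluded from the normal model. The two components are
  composed as independent losses, α = 1 − (1 − α_ab)(1 − α_site), because
  they act on disjoint evidence (offspring read support vs site-level
  mapping statistics).
- **False positives β** are a configuration constant (default 0.1089, the
  curation estimate); the package does not re-derive curation from data.

The aggregate rate is the arithmetic mean of per-trio rates with a
symmetric t-based 95% CI (quantile t₀.₉₇₅ with n−1 degrees of freedom).
A plain ±1.96·SE normal interval undercovers noticeably at n = 19 trios
(~93% instead of 95%), so the t quantile is used; with one trio the CI is
flagged unavailable.

## Parental origin and age effects

Phasing operates on read-pair co-occurrence abstractions rather than raw
reads: an informant is a nearby heterozygous variant carried by exactly
one parent, together with a flag saying whether its alternative allele
rides the same haplotype as the mutation within the insert-size window
(default 230 bp, the library insert size). Same haplotype ⇒ the carrier
parent; opposite ⇒ the other parent; conflicting informants leave the
mutation unphased. The simulator supplies co-occurrence truth; with real
data these flags would come from read-backed phasing upstream.

The paternal fraction is the mean of per-trio paternal fractions among
phased mutations, tested against 0.5 with a one-sample t-test across
trios (df = number of trios − 1; reporting one observation per trio is
the defensible unit of replication here).

Upscaled per-parent totals apply the phased paternal:maternal ratio to the
trio's full count, optionally normalizing each phased count by the total
SNPs phased to that parent first; totals conserve m exactly. Per-parent
count-on-age regressions are fitted independently (two simple least
squares fits, or Poisson GLMs with log link), and trios with zero phased
mutations are excluded from upscaled fits while remaining in the
rate-on-age regressions. Second-generation transmission is tested with an
exact two-sided binomial test against 50% inheritance.

## Characterization

Substitutions are collapsed onto the pyrimidine/adenine strand into six
classes; CpG status is a mutated C immediately followed by G, or a mutated
G immediately preceded by C, read from the reference context. Clusters
default to single-linkage chaining of same-chromosome mutations with
successive gaps ≤ 20 kb — order-invariant and equivalent to pair-based
counting; a fixed tiled-window mode is available behind a flag since a
"window where more than one mutation occurred" is ambiguous between the
two readings. The uniform null for inter-mutation distances redraws the
same number of positions uniformly with carrier labels permuted, and
compares stratified quantiles (within-individual / related / unrelated
successive pairs). Shared (postzygotic) mutations are identical sites in
offspring with a common parent; parental mosaic support is an alternative
read fraction in (0, 0.05] in the common parent, and maternal- vs
paternal-pair sharing proportions are compared with a Fisher exact test.
CDS overlap uses 1-based inclusive intervals; synonymous/non-synonymous
annotation is out of scope.

## Molecular dating

The count model evaluated at mean wild reproduction ages (mother 10 y,
father 12 y), with the (1 − β)/((1 − α)·2C) correction applied to the whole
predicted count, gives the per-generation rate; dividing by the generation
time G = 11 y gives the yearly rate. The division by G is required for the
printed per-generation and yearly quantities to be mutually consistent, so
it is explicit here even though compact renderings of the conversion
sometimes leave it implicit. N_e = π/(4μ) (Watterson), divergence time is
branch length over yearly rate, and speciation time subtracts 2·N_e·G,
floored at zero with a warning. Rate CIs propagate through these strictly
monotone maps by transforming the interval endpoints; the CI on the yearly
rate comes from the regression CI of the predicted count (CI of the mean
prediction). Ancestral N_e values are user inputs, not packaged constants.

## The synthetic cohort generator

`pedmut.simulate` emulates the study conditions at the genotype-record
level:

- **Depth**: negative binomial per site around each individual's mean
  (default 76×, between-individual SD 5×, dispersion 10), producing the
  low-coverage tail the depth filter targets.
- **Genotype quality**: ~3 phred per concordant read (10·log₁₀ 2(1−e) per
  read under a binomial read model), capped at 99, with additive Gaussian
  noise (SD 8) so the GQ = 60 threshold is exercised by construction.
- **Background variants**: heterozygous transmission sites (one parent
  HomAlt) at density 0.00247 — the species' nucleotide diversity — used
  for α estimation and as phasing denominators.
- **Germline mutations**: per-parent Poisson counts with the linear age
  means (maternal 4.6497 + 0.3042/yr, paternal 4.8399 + 1.8364/yr; log-link
  option available), offspring alternative reads Binomial(DP, 0.5),
  transition fraction 0.675 (ti/tv ≈ 2.08), 32.1% of transitions at CpG
  sites, ~3.5% of mutations relocated into 2–3-mutation clusters within
  20 kb.
- **Errors**: spurious Mendelian violations at 4 × 10⁻⁶ per site (matching
  the observed density of filtered violations), with Beta(2, 8) allele
  fractions (mode near 0.2, the somatic/artefact signature) and
  shifted annotation distributions.
- **Shared postzygotic events**: planted in ≥ 2 offspring of one parent at
  a rate giving ~3.5% shared mutations, with the common parent's
  alternative reads capped at 5% of its depth, consistently across all
  trios containing that parent.
- **Phasing truth**: each mutation carries an informant with probability
  0.5 (matching the observed phased fraction), placed within the insert
  window with a truth-consistent haplotype flag.

Every planted event is logged in a truth table. One pseudo-random
generator seeded from the configuration drives all draws, so runs are
byte-reproducible. The generator does not emulate read-level artefacts
(mapping error haplotypes, index hopping), indels, sex chromosomes, or
linkage between background variants; passing tests therefore demonstrate
the correctness and calibration of the statistical pipeline under the
stated noise model, not robustness to every artefact class in real data.
The error-site allele-fraction law is a free choice (only its mode near
0.2 is constrained by observation) and is exposed in the configuration.

## Problem sizes and numerical choices

Simulation-based tests run on runtime-scaled genomes (tens of kb to 1 Mb)
with the published per-trio mutation-count model kept intact, so per-site
rates are proportionally higher than genome scale; recovery checks compare
against the planted rate, which makes them scale-free. The end-to-end
recovery experiment uses 19 trios × 200 kb × 100 replicates and checks the
mean estimate within two standard errors of the planted value. Position
collisions between trios at this genome size remove ~0.3% of true
mutations via the cross-family filter, well inside that band. Annotation
values are carried at four-decimal precision end to end, which makes VCF
round trips exact. Degenerate inputs (zero depth, zero phased mutations,
constant ages, single trio, fewer than 50 transmission sites) raise
explicit errors or flagged results rather than propagating NaNs.

## Known limitations

- β is an input, not estimated; transmission-based false-positive
  estimation is deliberately out of scope.
- α_site assumes annotation values at true variant sites are normal; the
  FS distribution is truncated at zero, so its fitted upper tail is
  approximate (it is also the smallest component by an order of
  magnitude).
- Phasing consumes haplotype co-occurrence flags; it does not parse BAMs.
- The cluster and sharing summaries count occurrences per offspring, so a
  site shared by two siblings contributes two mutations, matching the
  convention used for the published percentages.
- Dating assumes a constant yearly rate along the focal branch and a
  constant ancestral population size; both are known simplifications for
  deep nodes.
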