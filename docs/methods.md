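# Methods

`exomefunnel` re-implements, as a tested library, the analysis chain used to
identify a recessive causal variant in a small multiplex deafness family from
whole-exome data, together with two companion analyses: exact statistics for
tricellular-contact localization counts, and plausibility/stability screens
for homo-trimer structural models of an Ig-like extracellular domain.  This
note records the models, the tunable parameters and their defaults, the
numerical choices, what the synthetic data do and do not emulate, and the
design decisions taken where the procedure was genuinely open.

## The prioritization model

The setting is a non-consanguineous family with unaffected parents and three
affected siblings, two of whom were exome-sequenced.  Variants enter the
pipeline already called and annotated (alignment, calling and annotation are
out of scope; the pipeline consumes a multi-sample VCF plus an
ANNOVAR-style annotation table).  Coordinates are 1-based VCF convention;
multiallelic sites are split into biallelic records before any filtering,
because every rule below is per-allele.  Genotypes are treated as unphased
throughout: nothing in the discovery design phases variants, so
compound-heterozygote reasoning is gene-level.

### Pre-inheritance cascade

Four per-variant pure predicates, applied in funnel order with the first
failing stage recorded per variant:

| filter      | rule (defaults)                                                   |
|-------------|-------------------------------------------------------------------|
| consequence | keep nonsynonymous, stopgain, splicing and small indels; drop synonymous |
| frequency   | drop if AF > 1% (strict) in any configured database (ESP6500, 1000 Genomes, in-house) |
| novelty     | drop if present in the discovery-time dbSNP build                  |
| quality     | drop if, in **any** sequenced affected sibling, DP < 20, GQ < 30, or variant-allele fraction < 0.2 |

Because the verdicts are pure per-variant functions, the survivor set is
independent of filter order; the funnel order only distributes exclusion
reasons.  Two contracts deserve emphasis:

* **Absent is not zero.**  A variant with no entry in a frequency database
  (a `-` cell) passes that database's test; novel variants must survive.
  Readers propagate `-` as absent, never as `0.0`.
* **Missing metrics skip their clause.**  VAF is undefined without allelic
  depths and positive depth; a call without DP or GQ likewise cannot fail
  that clause.  A genotype missing altogether in a sequenced affected
  sibling, however, excludes the variant (`missing-genotype`) — the design
  requires the variant to be soundly observed in every sequenced affected.

The two dbSNP builds are modeled as generic *discovery* and *revalidation*
membership fields: the logic is version-agnostic even though the motivating
data used builds 137 and 138.

### Recessive model

A surviving variant is a **homozygous candidate** iff every sequenced
affected sibling is homozygous-alternate.  A gene is a **compound-het
candidate** iff it carries at least two distinct variants, each heterozygous
in every sequenced affected sibling.  With only two sequenced siblings and
no phasing, the trans configuration cannot be established at this stage; it
is enforced later, during cosegregation, once parental genotypes exist.  A
gene may contribute both model types.  Classification is invariant to
variant and sample order (candidates are sorted; this is asserted by test).

### Cosegregation

Combining exome genotypes with targeted (Sanger) genotypes of additional
family members: a homozygous candidate is consistent iff every typed
affected member is homozygous-alternate and no typed unaffected member is;
a compound-het candidate is consistent iff some pair of its variants is
carried jointly by all typed affecteds, by no unaffected typed at both
sites, and — when both parents are typed at both sites — the two variants
are attributable to different parents.  Members without a genotype at a
site cannot contradict and are skipped; an evidence genotype conflicting
with the exome genotype for the same sample raises an error naming the
sample rather than silently preferring either source.

### Validation cascade

Candidates then pass four sequential evidence filters, in the study's
narrative order, each recording a first exclusion reason: (1) Sanger
failure; (2) cosegregation inconsistency; (3) membership in the
revalidation dbSNP build; (4) a control-cohort screen that, by default,
excludes a variant seen in **any** control chromosome
(`control_max_carriers = 0`, configurable) — the motivating study dismissed
a variant seen in 3 of 276 control chromosomes as a population-specific
polymorphism, so the strictest reading is the default.  When an exclusion
leaves a compound-het candidate with fewer than two variants, its orphaned
partners are excluded at the same stage (`compound-partner`); this cannot
occur in the encoded study data but is needed so reasons partition the set.

On the hand-encoded candidate table (14 variants, 11 genes, published
DP/GQ) this cascade reproduces the published funnel exactly:
14 → 11 → 7 → 3 → 1, the survivor being the novel homozygous missense
variant in *ILDR1* (chr3:121725861 G>T, c.C206A, p.P69H).  Details absent
from the published record — which family member broke segregation for the
two non-cosegregating genes, per-variant allelic depths — are encoded as
minimal synthetic counterexamples and labelled as such in the fixture's
docstring.

## Localization statistics

Counts of tricellular contacts (TCs) with and without protein accumulation
form 2×2 tables (condition × localized/not).  The association in the
motivating data is extreme (hundreds of discordant counts), so the exact
test is computed entirely in log space: hypergeometric point probabilities
from log-gamma factorials, tail sums by log-sum-exp.  The two-sided p-value
is the sum of point probabilities at most the observed one; probabilities
within relative tolerance 1e-7 of the observed are counted as ties and
included.  That tolerance is part of the statistic's definition here, and
the test-suite oracle — an exact big-rational enumeration — applies the
same tie rule in integer arithmetic, so the comparison checks numerics, not
definitions.  Agreement is exhaustive over all 628,055 non-degenerate
tables with N ≤ 60 (observed max relative error ~1e-13) and spot-checked on
the published-scale table.  Degenerate tables (a zero margin) raise.

The published p-values (1.14×10⁻⁶⁰, 7.34×10⁻⁶⁵) are *not* reproduced or
asserted: the report does not name the test behind them, and bare p-values
without a named statistic are not a recoverable target.  The package
reports its own exact-test p alongside the proportions (411/722 ≈ 56.9%
vs. 593/618 ≈ 96.0% for the tagged protein; 360/722 ≈ 49.9% vs. 573/618 ≈
92.7% for tricellulin recruitment), which are direct quotients of the
published counts.

Companion statistics: the odds ratio uses the Haldane–Anscombe 0.5
correction on zero cells (flagged in the result) and a Woolf log-normal
interval; multi-clone comparisons against a reference are Holm-adjusted by
default (the study reported two pairwise tests without an adjustment
policy; Holm is conservative and assumption-free).  Interval calibration is
checked by a seeded binomial simulation (500 replicates, nominal 95%,
tolerance three Monte-Carlo standard errors).

## Structural screens

Candidate docked homo-trimer models are screened by three criteria.  The
interface energy is consumed as input metadata — re-deriving a docking
score is out of scope and unverifiable — so the screen takes the best
`ceil(top_fraction · N)` models by energy (default 1%), then:

* **Membrane plausibility.**  Each chain's C-terminus must point out of the
  complex (toward its cell membrane).  No numeric burial criterion was
  published; burial is operationalized as more than `max_neighbors` (default
  10) foreign-chain heavy atoms within `radius` (default 10 Å) of the
  C-terminal Cα.  The threshold was calibrated once on the package's
  synthetic convex/dense-core fixtures, where exposed termini see ~0 foreign
  atoms and buried ones ~40; any threshold in between separates them, and 10
  sits near the low end to keep the criterion strict.
* **Polar interface contacts.**  Cross-chain N/O heavy-atom pairs within
  3.5 Å, no angular term (the published criterion says only "capable of
  forming hydrogen bonds").  Unknown elements are warned about and skipped.

Ranking is deterministic: (energy ascending, contacts descending, input
order).  Rigid-transform invariance and agreement with O(n²) brute-force
distance scans are asserted by property tests.

For trajectories (multi-model PDB, the portable lowest common denominator;
native MD formats are out of scope), per-residue RMSD uses a standard
Kabsch least-squares superposition on a chosen reference selection, then
RMSD over the target selection.  Convergence of a series is judged by the
spread (max − min) of its final `window_fraction` (default 0.5, at least 10
frames): converged iff spread ≤ `spread_tol` (default 1.0 Å).  This mirrors
the qualitative published contrast — a stable site settling near one level
versus an unstable one wandering over several Å — without asserting the
published ~5 Å level, which depends on unreleased coordinates and an
unstated MD protocol.

## What the synthetic data emulate — and what they do not

`simulate_family` emulates the discovery setting: two unaffected parents,
three affected siblings (two sequenced), one planted recessive causal
variant (parents obligate carriers; for the compound-het model, one allele
per parent), and `n_decoy_variants = 2000` annotated decoys.  The decoy
count is a desk-scale choice for a post-annotation exome testbed — large
enough that every filter does real work, small enough that a 200-replicate
recovery study runs in under a minute.  Decoys split 50/30/20 into common
(AF ~ U(0.01, 0.5)), rare (U(0.0005, 0.01)) and novel (absent from all
databases, latent AF U(0.0005, 0.005)); founder genotypes are
Hardy–Weinberg draws at the latent AF and children inherit one allele from
each parent (both properties are asserted by test).  DP is
negative-binomial with mean 80 and dispersion 8, matching the reported
>80× mean coverage; correct calls draw GQ from U(60, 99), error-injected
calls from U(0, 29).  Allelic depths are binomial with alt-read probability
0.02/0.5/0.98 for hom-ref/het/hom-alt.  The planted variant's DP is drawn
from the same depth model left-truncated at 20, encoding the study
condition that the causal variant was well covered (its published DP was
25/40); without that conditioning a "discovery" would occasionally be
impossible by construction rather than by method failure.

Under a fixed seed all emitted artifacts (VCF, PED, TSVs, truth record) are
byte-identical.  With error-free genotypes the pipeline recovers the
planted variant in 100% of replicates, and recovery degrades monotonically
as the genotype error rate rises (asserted as a non-increasing trend over a
seeded grid).

Not emulated: read-level data, linkage disequilibrium between decoys,
exome capture bias, population structure in the frequency databases, caller
artifacts correlated across samples.  Passing the recovery tests therefore
shows the *logic* of the cascade is sound under idealized sampling, not
that its thresholds are optimal for any particular real capture kit or
caller.  Note also that most decoys at which both sequenced siblings are
homozygous-reference fall at the quality stage (their VAF ≈ 0.02 is below
0.2) rather than at the inheritance stage; this mirrors the requirement
that a variant be genuinely observed in both siblings, but it means the
per-stage decoy counts should not be read as a forecast of a real exome's
funnel shape.

## Known limitations

* The 27,648 → 141 portion of the published funnel is not reproducible:
  the raw exome data were never deposited, so the pre-inheritance stages
  are validated by property tests and simulation, not against published
  counts.  Everything from the recessive-model stage forward is reproduced
  from the in-study candidate table.
* The published trimer's 4.21 nm lateral size and ~5 Å RMSD convergence
  level depend on unreleased coordinates/trajectories and are not targets.
* X-linked and mitochondrial inheritance are not modeled (all candidate
  variants in the motivating data are autosomal); de novo and dominant
  models are out of scope.
* HGVS strings and pathogenicity scores (SIFT, PolyPhen2, GERP++) are
  pass-through metadata, never validated or recomputed.
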