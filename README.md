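# exomefunnel

Family-based recessive variant prioritization for small multiplex pedigrees,
with companion modules for exact tricellular-contact localization statistics
and homo-trimer structural-model screening.

## Who this is for

Analysts working up a Mendelian-disease family from whole-exome data: called,
annotated variants go in; a short, evidence-ranked list of recessive
candidates comes out, with every exclusion accounted for.  The package was
built around the discovery of a hearing-loss missense variant in *ILDR1*
(angulin-2), a tricellular tight-junction protein, and so also ships the two
downstream analyses that study design needs: exact 2×2 tests on
localization counts that stay accurate at p ~ 1e-70, and geometric screens
for docked trimer models of an Ig-like domain.

## The method

**Filter cascade.**  Per-variant pure predicates applied in funnel order —
consequence (keep protein-affecting, drop synonymous), population frequency
(drop AF > 1% in any database; an *absent* frequency is not zero), novelty
(drop variants in the discovery-time dbSNP build), and call quality (drop if
any sequenced affected sibling has DP < 20, GQ < 30, or variant-allele
fraction < 0.2).

**Recessive model.**  Survivors are classified as shared-homozygous
candidates (all sequenced affected siblings alt/alt) or gene-level
compound heterozygotes (≥ 2 variants in one gene, each het in all sequenced
affecteds; genotypes are unphased, so trans configuration is checked only
once parental genotypes exist).

**Validation cascade.**  Candidates then face Sanger confirmation,
cosegregation across the full pedigree, membership in a later dbSNP build,
and a normal-hearing control-cohort screen, in that order, producing a
funnel report in which every variant is either a survivor or carries exactly
one first-exclusion reason.

**Localization statistics.**  Fisher's exact test computed in log space
(log-gamma point probabilities, log-sum-exp tails), so two-sided p-values
remain exact to >10 significant digits down to the smallest representable
doubles; plus odds ratios with Haldane–Anscombe-corrected Woolf intervals
and Holm-adjusted multi-clone comparisons.

**Structural screens.**  Docked trimer models are shortlisted by external
interface energy, a membrane-plausibility test (no chain's C-terminal Cα
may be buried under foreign-chain atoms), and cross-chain N/O polar-contact
counts; trajectories get per-residue RMSD after Kabsch superposition and a
window-spread convergence verdict.

**Synthetic data.**  A seeded generator emulates the discovery setting
(carrier parents, affected siblings, planted causal variant,
Hardy–Weinberg decoys with Mendelian transmission, negative-binomial depth)
so that every stage is testable without any external download, plus a
hand-encoded copy of the study's 14-variant candidate table.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```bash
python examples/run_family_prioritization.py
```

```
8 homozygous candidates: ATXN3, ILDR1, MICA, MUC12, NR1H2, PLK1S1, VSIG10L, ZSCAN26
6 compound-het variants in: ABCA10, BRCA1, CHD3
11 genes in total

validation funnel (variants remaining after each stage):
  recessive-candidates   14
  sanger                 11
  cosegregation          7
  dbsnp-revalidation     3
  control-cohort         1

survivor: ILDR1 chr3:121725861:G:T (c.C206A, p.P69H)
```

Fourteen recessive candidate variants enter the validation cascade; three
fall to Sanger failure, four to non-cosegregation, four to revalidation
dbSNP membership and two to control-cohort carriers, leaving the single
novel homozygous missense variant that tracks the hearing loss through the
family.  The other examples (`run_localization_stats.py`,
`run_simulation_recovery.py`, `run_trimer_screen.py`) walk the statistics,
simulator and structural modules the same way.

A thin CLI wraps the same functions for shell use:

```bash
exomefunnel simulate --seed 7 --outdir sim/
exomefunnel filter --vcf sim/family.vcf --annotations sim/annotations.tsv \
    --ped sim/family.ped --survivors surv.tsv --report funnel.json
exomefunnel prioritize --survivors surv.tsv --vcf sim/family.vcf \
    --ped sim/family.ped --evidence sim/evidence.tsv \
    --candidates cand.tsv --report validation.json
exomefunnel tcstats --counts counts.tsv --reference WT --out tc.tsv
```

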