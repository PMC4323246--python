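"""Recessive inheritance classification and family-evidence validation.

Given the variants surviving the pre-inheritance cascade and the genotypes of
the exome-sequenced affected siblings, this module

1. classifies candidates under an autosomal recessive model — shared
   homozygous-alternate variants, and gene-level compound heterozygotes
   (two or more distinct variants in one gene, each heterozygous in every
   sequenced affected sibling; genotypes are unphased, so the trans
   configuration is only enforced when parental genotypes become available);
2. checks cosegregation of a candidate with the disease phenotype once
   genotypes of additional family members are known; and
3. applies the validation cascade in the study's narrative order —
   Sanger confirmation, cosegregation, membership in the revalidation dbSNP
   build, and a normal-hearing control-cohort screen — producing a funnel
   report with one first-exclusion reason per variant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .variants import (
    AnnotatedVariant,
    EvidenceRecord,
    FunnelReport,
    Pedigree,
    VariantKey,
)

__all__ = [
    "RecessiveCandidate",
    "RecessiveResult",
    "ValidationConfig",
    "GenotypeConflictError",
    "classify_recessive",
    "check_cosegregation",
    "apply_validation_filters",
]


class GenotypeConflictError(ValueError):
    """An evidence genotype contradicts the WES genotype for the same sample."""


@dataclass(frozen=True)
class RecessiveCandidate:
    gene: str
    model: str  # "homozygous" | "compound_heterozygous"
    variant_keys: tuple
    supporting_samples: tuple

    def __post_init__(self) -> None:
        if self.model == "homozygous":
            if len(self.variant_keys) != 1:
                raise ValueError("homozygous candidate must carry exactly one variant")
        elif self.model == "compound_heterozygous":
            if len(set(self.variant_keys)) < 2:
                raise ValueError("compound-het candidate needs >= 2 distinct variants")
        else:
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class RecessiveResult:
    candidates: list
    exclusions: dict  # VariantKey -> reason ("inheritance" | "missing-genotype")

    @property
    def candidate_variant_keys(self) -> list:
        seen: dict = {}
        for c in self.candidates:
            for k in c.variant_keys:
                seen[k] = None
        return list(seen)


def classify_recessive(
    variants: Iterable[AnnotatedVariant],
    genotypes: Mapping,
    ped: Pedigree,
) -> RecessiveResult:
    """Classify surviving variants under the autosomal recessive model.

    ``genotypes`` maps variant_key -> {sample_id: GenotypeCall}.  A variant is
    a homozygous candidate iff every sequenced affected sample is
    homozygous-alternate; a gene is a compound-het candidate iff it carries
    >= 2 distinct variants each heterozygous in every sequenced affected.
    A gene can contribute both model types.  Variants with a missing genotype
    in any sequenced affected are excluded with reason ``missing-genotype``;
    variants fitting neither pattern with reason ``inheritance``.

    The result is invariant to input variant order and sample order:
    candidates are sorted by (gene, model) and variant keys positionally.
    """
    affected = sorted(ped.sequenced_affected_ids)
    if not affected:
        raise ValueError("pedigree has no sequenced affected samples")

    variants = sorted(variants, key=lambda v: v.key)
    hom_candidates: list[RecessiveCandidate] = []
    het_by_gene: dict[str, list[VariantKey]] = {}
    status: dict[VariantKey, str] = {}

    for v in variants:
        calls = genotypes.get(v.key, {})
        if any(calls.get(s) is None or calls[s].is_missing for s in affected):
            status[v.key] = "missing-genotype"
            continue
        if all(calls[s].is_hom_alt for s in affected):
            hom_candidates.append(
                RecessiveCandidate(
                    gene=v.gene or "",
                    model="homozygous",
                    variant_keys=(v.key,),
                    supporting_samples=tuple(affected),
                )
            )
            status[v.key] = "candidate"
        elif all(calls[s].is_het for s in affected) and v.gene is not None:
            het_by_gene.setdefault(v.gene, []).append(v.key)
            status[v.key] = "shared-het"
        else:
            status[v.key] = "inheritance"

    comphet_candidates = []
    for gene in sorted(het_by_gene):
        keys = sorted(het_by_gene[gene])
        if len(keys) >= 2:
            comphet_candidates.append(
                RecessiveCandidate(
                    gene=gene,
                    model="compound_heterozygous",
                    variant_keys=tuple(keys),
                    supporting_samples=tuple(affected),
                )
            )
            for k in keys:
                status[k] = "candidate"

    exclusions = {
        k: ("inheritance" if reason == "shared-het" else reason)
        for k, reason in status.items()
        if reason not in ("candidate",)
    }
    candidates = sorted(hom_candidates + comphet_candidates, key=lambda c: (c.gene, c.model))
    return RecessiveResult(candidates=candidates, exclusions=exclusions)


# ---------------------------------------------------------------------------
# Cosegregation
# ---------------------------------------------------------------------------


def _combined_genotypes(
    candidate: RecessiveCandidate,
    evidence_map: Mapping[VariantKey, EvidenceRecord],
    ped: Pedigree,
    wes_genotypes: Mapping,
) -> dict:
    """Merge WES and evidence genotypes into {sample_id: {vk: GenotypeCall}}.

    Raises :class:`GenotypeConflictError` when both sources type the same
    sample at the same site with different alleles (unphased comparison).
    """
    merged: dict = {m.sample_id: {} for m in ped}
    for vk in candidate.variant_keys:
        wes_calls = wes_genotypes.get(vk, {})
        ev = evidence_map.get(vk)
        ev_calls = ev.family_genotypes if ev is not None else {}
        for sid in merged:
            wes = wes_calls.get(sid)
            evc = ev_calls.get(sid)
            if wes is not None and not wes.is_missing and evc is not None and not evc.is_missing:
                if tuple(sorted(wes.alleles)) != tuple(sorted(evc.alleles)):
                    raise GenotypeConflictError(
                        f"evidence genotype conflicts with WES genotype for sample "
                        f"{sid!r} at {vk}"
                    )
            call = wes if wes is not None and not wes.is_missing else evc
            if call is not None and not call.is_missing:
                merged[sid][vk] = call
    return merged


def check_cosegregation(
    candidate: RecessiveCandidate,
    evidence_map: Mapping[VariantKey, EvidenceRecord],
    ped: Pedigree,
    wes_genotypes: Mapping,
) -> bool:
    """True iff the candidate's genotypes cosegregate with the phenotype.

    With WES and evidence genotypes combined (members without a genotype at a
    site cannot contradict and are skipped):

    * homozygous model — every typed affected member is homozygous-alternate
      and no typed unaffected member is;
    * compound-het model — some pair of the candidate's variants is carried
      jointly by every affected typed at both sites, by no unaffected typed
      at both sites, and, when both parents are typed at both sites, the two
      variants are attributable to different parents (trans configuration).
    """
    geno = _combined_genotypes(candidate, evidence_map, ped, wes_genotypes)
    affected = set(ped.affected_ids)
    unaffected = set(ped.unaffected_ids)

    if candidate.model == "homozygous":
        (vk,) = candidate.variant_keys
        for sid, calls in geno.items():
            call = calls.get(vk)
            if call is None:
                continue
            if sid in affected and not call.is_hom_alt:
                return False
            if sid in unaffected and call.is_hom_alt:
                return False
        return True

    # compound heterozygous: find one valid trans-compatible pair
    parent_ids = sorted(ped.parent_ids)
    for v1, v2 in itertools.combinations(candidate.variant_keys, 2):
        ok = True
        for sid in affected:
            c1, c2 = geno[sid].get(v1), geno[sid].get(v2)
            if c1 is not None and not c1.carries_alt:
                ok = False
                break
            if c2 is not None and not c2.carries_alt:
                ok = False
                break
        if not ok:
            continue
        for sid in unaffected:
            c1, c2 = geno[sid].get(v1), geno[sid].get(v2)
            if c1 is not None and c2 is not None and c1.carries_alt and c2.carries_alt:
                ok = False
                break
        if not ok:
            continue
        # trans rule, only when both parents are typed at both sites
        typed_parents = [
            sid
            for sid in parent_ids
            if geno[sid].get(v1) is not None and geno[sid].get(v2) is not None
        ]
        if len(typed_parents) >= 2:
            p1, p2 = typed_parents[:2]
            trans = (
                geno[p1][v1].carries_alt and geno[p2][v2].carries_alt
            ) or (geno[p1][v2].carries_alt and geno[p2][v1].carries_alt)
            if not trans:
                continue
        return True
    return False


# ---------------------------------------------------------------------------
# Validation cascade
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationConfig:
    """Control-cohort exclusion threshold: a candidate is dismissed as a
    population-specific polymorphism when more than ``control_max_carriers``
    alternate alleles are seen among screened control chromosomes."""

    control_max_carriers: int = 0


def apply_validation_filters(
    candidates: Iterable[RecessiveCandidate],
    evidence_map: Mapping[VariantKey, EvidenceRecord],
    ped: Pedigree,
    wes_genotypes: Mapping,
    variants: Optional[Mapping[VariantKey, AnnotatedVariant]] = None,
    cfg: ValidationConfig = ValidationConfig(),
) -> tuple:
    """Run the post-calling validation cascade and report the funnel.

    Stages, in narrative order, each recording the FIRST exclusion reason:

    1. ``sanger`` — variants whose Sanger status is ``failed``;
    2. ``cosegregation`` — candidates inconsistent with the phenotype across
       all typed family members (skipped for a candidate with no evidence
       genotypes beyond the sequenced pair);
    3. ``dbsnp-revalidation`` — variants present in the later dbSNP build
       (requires ``variants`` annotations);
    4. ``control-cohort`` — variants seen in more than
       ``cfg.control_max_carriers`` control alleles, given a positive number
       of screened control chromosomes.

    A compound-het candidate reduced below two variants drops out; orphaned
    partner variants are excluded with reason ``compound-partner``.

    Returns ``(FunnelReport, surviving_candidates)``.
    """
    candidates = list(candidates)
    alive: dict[VariantKey, None] = {}
    for c in candidates:
        for k in c.variant_keys:
            alive.setdefault(k, None)
    exclusions: dict = {}
    stages = [("recessive-candidates", len(alive))]

    def surviving(c: RecessiveCandidate) -> list:
        return [k for k in c.variant_keys if k not in exclusions]

    def prune_candidates() -> None:
        # a comp-het candidate reduced below two variants loses its orphaned
        # partners too, unless another candidate still carries them
        for c in candidates:
            keys = surviving(c)
            if c.model == "compound_heterozygous" and 0 < len(keys) < 2:
                for k in keys:
                    held_elsewhere = any(
                        other is not c and k in surviving(other) for other in candidates
                    )
                    if not held_elsewhere:
                        exclusions[k] = "compound-partner"

    # 1. Sanger
    for k in list(alive):
        ev = evidence_map.get(k)
        if ev is not None and ev.sanger_status == "failed":
            exclusions[k] = "sanger"
    prune_candidates()
    stages.append(("sanger", sum(1 for k in alive if k not in exclusions)))

    # 2. cosegregation
    for c in candidates:
        keys = surviving(c)
        if not keys:
            continue
        has_evidence = any(
            evidence_map.get(k) is not None and evidence_map[k].family_genotypes
            for k in keys
        )
        if not has_evidence:
            continue
        pruned = RecessiveCandidate(
            gene=c.gene,
            model=c.model,
            variant_keys=tuple(keys),
            supporting_samples=c.supporting_samples,
        ) if (c.model == "homozygous" or len(keys) >= 2) else None
        if pruned is None:
            continue
        if not check_cosegregation(pruned, evidence_map, ped, wes_genotypes):
            for k in keys:
                exclusions[k] = "cosegregation"
    prune_candidates()
    stages.append(("cosegregation", sum(1 for k in alive if k not in exclusions)))

    # 3. revalidation dbSNP membership
    if variants is not None:
        for k in list(alive):
            if k in exclusions:
                continue
            v = variants.get(k)
            if v is not None and v.dbsnp_v2_id is not None:
                exclusions[k] = "dbsnp-revalidation"
    prune_candidates()
    stages.append(("dbsnp-revalidation", sum(1 for k in alive if k not in exclusions)))

    # 4. control cohort
    for k in list(alive):
        if k in exclusions:
            continue
        ev = evidence_map.get(k)
        if ev is not None and ev.control_chromosomes > 0:
            if ev.control_alt_alleles > cfg.control_max_carriers:
                exclusions[k] = "control-cohort"
    prune_candidates()
    stages.append(("control-cohort", sum(1 for k in alive if k not in exclusions)))

    survivors = [k for k in alive if k not in exclusions]
    report = FunnelReport(stages=stages, exclusions=exclusions, survivors=survivors)
    surviving_candidates = []
    for c in candidates:
        keys = surviving(c)
        if c.model == "homozygous" and keys:
            surviving_candidates.append(c)
        elif c.model == "compound_heterozygous" and len(keys) >= 2:
            surviving_candidates.append(
                RecessiveCandidate(c.gene, c.model, tuple(keys), c.supporting_samples)
            )
    return report, surviving_candidates
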