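"""Pre-inheritance filter cascade: consequence, frequency, novelty, quality.

The cascade reduces an annotated family exome to rare, protein-affecting,
novel, well-supported variants before any inheritance-model reasoning:

* **consequence** — keep exonic/splicing variants that can alter protein
  (non-synonymous SNVs, stopgains, splice-site changes, small indels);
  synonymous changes are discarded.
* **frequency** — discard variants with allele frequency above 1% in any
  configured population database; a variant *absent* from a database is not
  penalized (absent frequency is not zero frequency).
* **novelty** — discard variants already present in the discovery-time dbSNP
  build.
* **quality** — discard variants whose genotype call in any sequenced
  affected sibling has read depth < 20, genotype quality < 30, or variant
  allele fraction < 0.2.

Each verdict is a pure per-variant function; the funnel records the first
failing stage per variant, so reasons partition the excluded set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .variants import (
    CONSEQUENCES,
    AnnotatedVariant,
    FunnelReport,
    GenotypeCall,
    Pedigree,
)

__all__ = [
    "FilterConfig",
    "Verdict",
    "quality_filter",
    "variant_quality_filter",
    "consequence_filter",
    "frequency_filter",
    "novelty_filter",
    "run_prefilters",
]

DEFAULT_WHITELIST = frozenset(
    {
        "nonsynonymous",
        "stopgain",
        "splicing",
        "frameshift-insertion",
        "frameshift-deletion",
        "nonframeshift-insertion",
        "nonframeshift-deletion",
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade; defaults reproduce the discovery pipeline
    (DP >= 20, GQ >= 30, VAF >= 0.2, AF <= 1% strict, dbSNP-discovery
    novelty, synonymous variants excluded)."""

    min_depth: int = 20
    min_gq: int = 30
    min_vaf: float = 0.2
    max_af: float = 0.01
    frequency_dbs: tuple = ("esp6500", "1000g", "inhouse")
    consequence_whitelist: frozenset = DEFAULT_WHITELIST

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_gq < 0:
            raise ValueError("quality thresholds must be >= 0")
        if not (0.0 <= self.min_vaf <= 1.0) or not (0.0 <= self.max_af <= 1.0):
            raise ValueError("fractional thresholds must lie in [0, 1]")
        if not self.consequence_whitelist:
            raise ValueError("consequence whitelist must be non-empty")
        unknown = set(self.consequence_whitelist) - CONSEQUENCES
        if unknown:
            raise ValueError(f"whitelist entries outside vocabulary: {sorted(unknown)}")


@dataclass(frozen=True)
class Verdict:
    passed: bool
    reason: Optional[str] = None

    def __bool__(self) -> bool:
        return self.passed


def quality_filter(call: GenotypeCall, cfg: FilterConfig = FilterConfig()) -> Verdict:
    """Per-call quality verdict: fail on low DP, then low GQ, then low VAF.

    A metric that is absent on the call skips its clause (mirroring the VAF
    contract: VAF is undefined without allelic depths and positive depth).
    """
    if call.depth is not None and call.depth < cfg.min_depth:
        return Verdict(False, "quality:depth")
    if call.genotype_quality is not None and call.genotype_quality < cfg.min_gq:
        return Verdict(False, "quality:gq")
    vaf = call.vaf
    if vaf is not None and vaf < cfg.min_vaf:
        return Verdict(False, "quality:vaf")
    return Verdict(True)


def variant_quality_filter(
    calls: Mapping[str, GenotypeCall],
    affected_ids: Iterable[str],
    cfg: FilterConfig = FilterConfig(),
) -> Verdict:
    """Variant-level quality: the variant fails if its call fails (or is
    absent/missing) in *any* sequenced affected sample — the discovery
    design requires the variant to be soundly observed in every affected
    sibling that was sequenced."""
    for sid in affected_ids:
        call = calls.get(sid)
        if call is None or call.is_missing:
            return Verdict(False, "missing-genotype")
        v = quality_filter(call, cfg)
        if not v:
            return v
    return Verdict(True)


def consequence_filter(v: AnnotatedVariant, cfg: FilterConfig = FilterConfig()) -> Verdict:
    if v.consequence is None or v.consequence not in CONSEQUENCES:
        raise ValueError(f"unknown consequence {v.consequence!r} for {v.chrom}:{v.pos}")
    if v.consequence in cfg.consequence_whitelist:
        return Verdict(True)
    return Verdict(False, "consequence")


def frequency_filter(v: AnnotatedVariant, cfg: FilterConfig = FilterConfig()) -> Verdict:
    """Fail iff AF strictly exceeds ``max_af`` in any configured database;
    a database without an entry for the variant contributes no failure."""
    for db in cfg.frequency_dbs:
        af = v.pop_afs.get(db)
        if af is not None and af > cfg.max_af:
            return Verdict(False, "frequency")
    return Verdict(True)


def novelty_filter(v: AnnotatedVariant, cfg: FilterConfig = FilterConfig()) -> Verdict:
    """Fail iff the variant is a member of the discovery-time dbSNP build."""
    if v.dbsnp_v1_id is not None:
        return Verdict(False, "novelty")
    return Verdict(True)


def run_prefilters(
    variants: Iterable[AnnotatedVariant],
    genotypes: Mapping,
    ped: Pedigree,
    cfg: FilterConfig = FilterConfig(),
) -> FunnelReport:
    """Apply the cascade in funnel order and report per-stage counts.

    ``genotypes`` maps variant_key -> {sample_id: GenotypeCall}.  Stage
    order: consequence, frequency, novelty, quality; the first failing stage
    is recorded as the variant's exclusion reason.
    """
    variants = list(variants)
    affected = ped.sequenced_affected_ids
    if not affected:
        raise ValueError("pedigree has no sequenced affected samples")

    order = ["consequence", "frequency", "novelty", "quality"]
    fns = {
        "consequence": lambda v: consequence_filter(v, cfg),
        "frequency": lambda v: frequency_filter(v, cfg),
        "novelty": lambda v: novelty_filter(v, cfg),
        "quality": lambda v: variant_quality_filter(genotypes.get(v.key, {}), affected, cfg),
    }

    exclusions: dict = {}
    first_fail_idx: dict = {}
    survivors: list = []
    for v in variants:
        for i, stage in enumerate(order):
            verdict = fns[stage](v)
            if not verdict:
                exclusions[v.key] = verdict.reason or stage
                first_fail_idx[v.key] = i
                break
        else:
            survivors.append(v.key)

    stages = [("input", len(variants))]
    for i, stage in enumerate(order):
        n = sum(1 for v in variants if first_fail_idx.get(v.key, len(order)) > i)
        stages.append((stage, n))

    return FunnelReport(stages=stages, exclusions=exclusions, survivors=survivors)
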