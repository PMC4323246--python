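"""End-to-end convenience driver: cascade -> recessive model -> validation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .filters import FilterConfig, run_prefilters
from .recessive import (
    RecessiveResult,
    ValidationConfig,
    apply_validation_filters,
    classify_recessive,
)
from .variants import FunnelReport, Pedigree

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    prefilter_report: FunnelReport
    recessive: RecessiveResult
    validation_report: Optional[FunnelReport]
    surviving_candidates: list

    @property
    def survivors(self) -> list:
        if self.validation_report is not None:
            return list(self.validation_report.survivors)
        return [k for c in self.surviving_candidates for k in c.variant_keys]


def run_pipeline(
    variants: Mapping,
    genotypes: Mapping,
    ped: Pedigree,
    evidence: Optional[Mapping] = None,
    filter_cfg: FilterConfig = FilterConfig(),
    validation_cfg: ValidationConfig = ValidationConfig(),
) -> PipelineResult:
    """Run quality/consequence/frequency/novelty filters, classify recessive
    candidates, and (when evidence is given) the validation cascade.

    ``variants`` maps variant_key -> AnnotatedVariant and ``genotypes``
    variant_key -> {sample_id: GenotypeCall}.
    """
    pre = run_prefilters(variants.values(), genotypes, ped, filter_cfg)
    surviving_variants = [variants[k] for k in pre.survivors]
    rec = classify_recessive(surviving_variants, genotypes, ped)
    if evidence is None:
        return PipelineResult(pre, rec, None, rec.candidates)
    report, surviving = apply_validation_filters(
        rec.candidates, evidence, ped, genotypes, variants, validation_cfg
    )
    return PipelineResult(pre, rec, report, surviving)
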