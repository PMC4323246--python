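"""Domain types and file readers/writers for family-exome variant triage.

The in-memory model mirrors what a small Mendelian-disease exome study works
with after alignment, calling and annotation: per-sample genotype calls with
quality metadata (DP, GQ, allelic depths), annotated variant sites carrying
functional consequence, population allele frequencies and dbSNP membership at
two database versions, a pedigree with affected status, and per-variant wet-lab
evidence (Sanger outcome, extended-family genotypes, control-cohort counts).

Conventions
-----------
* Coordinates are 1-based VCF-style; alleles are reported as in the source.
* Genotypes are unphased everywhere; compound-heterozygote reasoning is
  gene-level.
* An annotation cell of ``-`` means *no data* and is propagated as absent
  (``None`` / missing key), never as ``0.0``: a variant with no recorded
  population frequency is a novel variant, not a variant at frequency zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "CONSEQUENCES",
    "FUNC_CODES",
    "VariantKey",
    "GenotypeCall",
    "AnnotatedVariant",
    "PedigreeMember",
    "Pedigree",
    "EvidenceRecord",
    "FunnelReport",
    "ParseError",
    "variant_key_str",
    "parse_variant_key",
    "read_vcf",
    "write_vcf",
    "read_annotation_table",
    "write_annotation_table",
    "read_pedigree",
    "write_pedigree",
    "read_evidence_table",
    "write_evidence_table",
]

#: Closed vocabulary of functional consequences handled by the cascade.
CONSEQUENCES = frozenset(
    {
        "nonsynonymous",
        "synonymous",
        "frameshift-insertion",
        "frameshift-deletion",
        "nonframeshift-insertion",
        "nonframeshift-deletion",
        "stopgain",
        "splicing",
        "other",
    }
)

#: ANNOVAR-style shorthand codes accepted by the table readers.
FUNC_CODES = {
    "NS": "nonsynonymous",
    "SYN": "synonymous",
    "FI": "frameshift-insertion",
    "FD": "frameshift-deletion",
    "NI": "nonframeshift-insertion",
    "ND": "nonframeshift-deletion",
    "SG": "stopgain",
    "SP": "splicing",
    "-": "other",
}

VariantKey = tuple  # (chrom: str, pos: int, ref: str, alt: str)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def variant_key_str(key: VariantKey) -> str:
    chrom, pos, ref, alt = key
    return f"{chrom}:{pos}:{ref}:{alt}"


def parse_variant_key(text: str) -> VariantKey:
    chrom, pos, ref, alt = text.split(":")
    return (chrom, int(pos), ref, alt)


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one biallelic site.

    ``alleles`` is an unphased ordered pair of allele indices (0 = reference,
    1 = alternate) or ``None`` for a missing genotype.  ``depth`` (DP),
    ``genotype_quality`` (GQ) and ``allele_depths`` (AD, ref then alt) are
    optional: a missing metric is ``None``, never zero.
    """

    sample_id: str
    alleles: Optional[tuple[int, int]]
    depth: Optional[int] = None
    genotype_quality: Optional[int] = None
    allele_depths: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.genotype_quality is not None and self.genotype_quality < 0:
            raise ValueError("genotype_quality must be >= 0")
        if self.allele_depths is not None and self.depth is not None:
            if sum(self.allele_depths) > self.depth:
                raise ValueError("sum of allele_depths exceeds depth")

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def n_alt(self) -> Optional[int]:
        if self.alleles is None:
            return None
        return sum(1 for a in self.alleles if a != 0)

    @property
    def is_hom_alt(self) -> bool:
        return self.alleles is not None and self.n_alt == 2

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.n_alt == 1

    @property
    def is_hom_ref(self) -> bool:
        return self.alleles is not None and self.n_alt == 0

    @property
    def carries_alt(self) -> bool:
        return self.alleles is not None and self.n_alt >= 1

    @property
    def vaf(self) -> Optional[float]:
        """Variant allele fraction: alt AD / DP; defined only when DP > 0."""
        if self.allele_depths is None or self.depth is None or self.depth <= 0:
            return None
        return self.allele_depths[1] / self.depth


@dataclass
class AnnotatedVariant:
    """One called, annotated biallelic variant site.

    ``pop_afs`` maps a frequency-database name to an allele frequency in
    [0, 1]; absence of a key means the variant is unobserved in that database.
    ``dbsnp_v1_id`` / ``dbsnp_v2_id`` record membership in the discovery-time
    and revalidation dbSNP builds (dbSNP137 / dbSNP138 in the motivating
    study); the logic is version-generic.  ``scores`` carries pathogenicity
    predictors (SIFT, PolyPhen2, GERP++) as pass-through metadata.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    consequence: Optional[str] = None
    exon_label: Optional[str] = None
    chgvs: Optional[str] = None
    phgvs: Optional[str] = None
    pop_afs: dict = field(default_factory=dict)
    dbsnp_v1_id: Optional[str] = None
    dbsnp_v2_id: Optional[str] = None
    scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based coordinates)")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        for db, af in self.pop_afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"allele frequency for {db} outside [0, 1]: {af}")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence: {self.consequence!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    sex: Optional[int] = None  # 1 male, 2 female, None unknown
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    affected: bool = False
    sequenced: bool = False


@dataclass
class Pedigree:
    """A family: members with affected status, parental links, and whether
    each member was exome-sequenced (vs. genotyped only by targeted assay)."""

    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        ids = {m.sample_id for m in self.members}
        if len(ids) != len(self.members):
            raise ValueError("duplicate sample ids in pedigree")
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise ValueError(f"unknown parent id {pid!r} for {m.sample_id}")
        self._check_acyclic()
        if not any(m.affected for m in self.members):
            raise ValueError("pedigree must contain at least one affected member")

    def _check_acyclic(self) -> None:
        by_id = {m.sample_id: m for m in self.members}
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        def visit(sid: str, stack: tuple[str, ...]) -> None:
            if sid in stack:
                raise ValueError(f"cyclic parentage involving {sid!r}")
            if state.get(sid) == 1:
                return
            m = by_id[sid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid, stack + (sid,))
            state[sid] = 1

        for m in self.members:
            visit(m.sample_id, ())

    def __iter__(self):
        return iter(self.members)

    def member(self, sample_id: str) -> PedigreeMember:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    @property
    def affected_ids(self) -> list[str]:
        return [m.sample_id for m in self.members if m.affected]

    @property
    def unaffected_ids(self) -> list[str]:
        return [m.sample_id for m in self.members if not m.affected]

    @property
    def sequenced_affected_ids(self) -> list[str]:
        return [m.sample_id for m in self.members if m.affected and m.sequenced]

    @property
    def parent_ids(self) -> set[str]:
        out: set[str] = set()
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    out.add(pid)
        return out

    def with_sequenced(self, sample_ids: Iterable[str]) -> "Pedigree":
        sids = set(sample_ids)
        unknown = sids - {m.sample_id for m in self.members}
        if unknown:
            raise ValueError(f"sequenced ids not in pedigree: {sorted(unknown)}")
        return Pedigree(
            [
                PedigreeMember(
                    m.sample_id, m.sex, m.father_id, m.mother_id, m.affected, m.sample_id in sids
                )
                for m in self.members
            ]
        )


SANGER_STATUSES = ("confirmed", "failed", "untested")


@dataclass
class EvidenceRecord:
    """Per-variant wet-lab follow-up: Sanger outcome, genotypes of family
    members outside the exome-sequenced pair, and control-cohort screening."""

    variant_key: VariantKey
    sanger_status: str = "untested"
    family_genotypes: dict = field(default_factory=dict)  # sample_id -> GenotypeCall
    control_alt_alleles: int = 0
    control_chromosomes: int = 0

    def __post_init__(self) -> None:
        if self.sanger_status not in SANGER_STATUSES:
            raise ValueError(f"unknown sanger_status: {self.sanger_status!r}")
        if self.control_chromosomes < 0:
            raise ValueError("control_chromosomes must be >= 0")
        if self.control_alt_alleles > self.control_chromosomes:
            raise ValueError("control_alt_alleles exceeds control_chromosomes")


@dataclass
class FunnelReport:
    """Ordered record of variant counts and first exclusion reasons across
    sequential filtering stages."""

    stages: list  # [(stage_name, variant_count), ...]
    exclusions: dict  # VariantKey -> first exclusion reason
    survivors: list  # [VariantKey]

    def __post_init__(self) -> None:
        counts = [c for _, c in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("stage counts must be non-increasing")
        if counts and counts[-1] != len(self.survivors):
            raise ValueError("final stage count must equal survivor count")
        overlap = set(self.exclusions) & set(self.survivors)
        if overlap:
            raise ValueError(f"variants both excluded and surviving: {overlap}")

    def to_dict(self) -> dict:
        return {
            "stages": [[name, count] for name, count in self.stages],
            "exclusions": {variant_key_str(k): v for k, v in self.exclusions.items()},
            "survivors": [variant_key_str(k) for k in self.survivors],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FunnelReport":
        return cls(
            stages=[(name, count) for name, count in d["stages"]],
            exclusions={parse_variant_key(k): v for k, v in d["exclusions"].items()},
            survivors=[parse_variant_key(k) for k in d["survivors"]],
        )


# ---------------------------------------------------------------------------
# VCF input/output (pysam-backed)
# ---------------------------------------------------------------------------


def read_vcf(path, sample_subset: Optional[Sequence[str]] = None):
    """Read a VCF into (AnnotatedVariant skeleton, {sample_id: GenotypeCall}).

    Multiallelic sites are split into biallelic records: for alt allele *j*,
    genotype allele indices equal to *j* map to 1 and all other alleles map
    to 0, and AD keeps the reference and that alt's depths.  Missing DP/GQ/AD
    yield ``None`` fields, never zeros.
    """
    import pysam

    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc

    header_samples = list(vcf.header.samples)
    if sample_subset is not None:
        for s in sample_subset:
            if s not in header_samples:
                raise ParseError(f"sample {s!r} not present in VCF header")
        samples = list(sample_subset)
    else:
        samples = header_samples

    records = []
    try:
        for rec in vcf:
            alts = rec.alts or ()
            for j, alt in enumerate(alts, start=1):
                skeleton = AnnotatedVariant(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt)
                calls = {}
                for s in samples:
                    fmt = rec.samples[s]
                    gt = fmt.get("GT")
                    if gt is None or all(a is None for a in gt):
                        alleles = None
                    else:
                        mapped = tuple(1 if a == j else 0 for a in gt if a is not None)
                        if len(mapped) == 1:
                            mapped = (mapped[0], mapped[0])
                        alleles = mapped[:2]
                    dp = fmt.get("DP")
                    gq = fmt.get("GQ")
                    ad = fmt.get("AD")
                    allele_depths = None
                    if ad is not None and len(ad) > j and ad[0] is not None and ad[j] is not None:
                        allele_depths = (int(ad[0]), int(ad[j]))
                    calls[s] = GenotypeCall(
                        sample_id=s,
                        alleles=alleles,
                        depth=None if dp is None else int(dp),
                        genotype_quality=None if gq is None else int(gq),
                        allele_depths=allele_depths,
                    )
                records.append((skeleton, calls))
    except (OSError, ValueError) as exc:
        raise ParseError(f"malformed VCF record in {path}: {exc}") from exc
    finally:
        vcf.close()
    return records


def write_vcf(records, path, sample_ids: Sequence[str]) -> None:
    """Write biallelic (variant, {sample: GenotypeCall}) records as VCF v4.2.

    Emits GT/DP/GQ/AD; ``None`` fields become VCF missing values.  Contig
    lines are generated from the records in order of first appearance.
    """
    import pysam

    header = pysam.VariantHeader()
    seen_contigs: list[str] = []
    max_pos: dict[str, int] = {}
    for variant, _ in records:
        if variant.chrom not in max_pos:
            seen_contigs.append(variant.chrom)
        max_pos[variant.chrom] = max(max_pos.get(variant.chrom, 0), variant.pos)
    for contig in seen_contigs:
        header.contigs.add(contig, length=max_pos[contig] + 1000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for s in sample_ids:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for variant, calls in records:
            rec = out.new_record(
                contig=variant.chrom,
                start=variant.pos - 1,
                stop=variant.pos - 1 + len(variant.ref),
                alleles=(variant.ref, variant.alt),
            )
            for s in sample_ids:
                call = calls.get(s)
                fmt = rec.samples[s]
                if call is None or call.alleles is None:
                    fmt["GT"] = (None, None)
                else:
                    fmt["GT"] = tuple(call.alleles)
                fmt.phased = False
                if call is not None:
                    if call.depth is not None:
                        fmt["DP"] = call.depth
                    if call.genotype_quality is not None:
                        fmt["GQ"] = call.genotype_quality
                    if call.allele_depths is not None:
                        fmt["AD"] = tuple(call.allele_depths)
            out.write(rec)


# ---------------------------------------------------------------------------
# Annotation table (TSV)
# ---------------------------------------------------------------------------

_ANNOT_FIXED = ["chrom", "pos", "ref", "alt", "gene", "consequence", "exon", "chgvs", "phgvs"]
_ANNOT_DBSNP = ["dbsnp_v1", "dbsnp_v2"]


def _absent(cell) -> bool:
    return cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() in ("-", "")


def read_annotation_table(path) -> dict:
    """Read a variant annotation TSV into {variant_key: AnnotatedVariant}.

    Expected columns: the fixed block ``chrom pos ref alt gene consequence
    exon chgvs phgvs``, zero or more frequency columns named ``af_<db>``,
    optional ``dbsnp_v1``/``dbsnp_v2`` membership columns, and zero or more
    ``score_<name>`` columns.  A ``-`` cell denotes *no data* and maps to an
    absent field, never to ``0.0``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOT_FIXED[:6] if c not in df.columns]
    if missing:
        raise ParseError(f"annotation table missing columns: {missing}")
    af_cols = [c for c in df.columns if c.startswith("af_")]
    score_cols = [c for c in df.columns if c.startswith("score_")]

    out: dict = {}
    for i, row in df.iterrows():
        consequence = row["consequence"].strip()
        consequence = FUNC_CODES.get(consequence, consequence)
        pop_afs = {}
        for c in af_cols:
            if not _absent(row[c]):
                af = float(row[c])
                if not (0.0 <= af <= 1.0):
                    raise ParseError(f"row {i}: allele frequency {af} outside [0, 1] in {c}")
                pop_afs[c[3:]] = af
        scores = {c[6:]: float(row[c]) for c in score_cols if not _absent(row[c])}
        try:
            v = AnnotatedVariant(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene=None if _absent(row["gene"]) else row["gene"],
                consequence=consequence,
                exon_label=None if _absent(row.get("exon")) else row["exon"],
                chgvs=None if _absent(row.get("chgvs")) else row["chgvs"],
                phgvs=None if _absent(row.get("phgvs")) else row["phgvs"],
                pop_afs=pop_afs,
                dbsnp_v1_id=None if _absent(row.get("dbsnp_v1")) else row["dbsnp_v1"],
                dbsnp_v2_id=None if _absent(row.get("dbsnp_v2")) else row["dbsnp_v2"],
                scores=scores,
            )
        except ValueError as exc:
            raise ParseError(f"row {i}: {exc}") from exc
        if v.key in out:
            raise ParseError(f"duplicate variant key {variant_key_str(v.key)}")
        out[v.key] = v
    return out


def write_annotation_table(variants: Iterable[AnnotatedVariant], path, af_dbs=None) -> None:
    variants = list(variants)
    if af_dbs is None:
        af_dbs = sorted({db for v in variants for db in v.pop_afs})
    score_names = sorted({s for v in variants for s in v.scores})
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene or "-",
            "consequence": v.consequence or "-",
            "exon": v.exon_label or "-",
            "chgvs": v.chgvs or "-",
            "phgvs": v.phgvs or "-",
        }
        for db in af_dbs:
            row[f"af_{db}"] = v.pop_afs.get(db, "-")
        row["dbsnp_v1"] = v.dbsnp_v1_id or "-"
        row["dbsnp_v2"] = v.dbsnp_v2_id or "-"
        for s in score_names:
            row[f"score_{s}"] = v.scores.get(s, "-")
        rows.append(row)
    cols = (
        _ANNOT_FIXED
        + [f"af_{db}" for db in af_dbs]
        + _ANNOT_DBSNP
        + [f"score_{s}" for s in score_names]
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Pedigree (PED-like)
# ---------------------------------------------------------------------------


def read_pedigree(path, sequenced: Optional[Iterable[str]] = None) -> Pedigree:
    """Read a whitespace-delimited PED-like file.

    Columns: family, sample, father (0 = none), mother (0 = none), sex
    (1/2/0), phenotype (2 = affected, 1 = unaffected, 0 = unknown treated as
    unaffected), and an optional 7th column flagging exome-sequenced members
    (1/0).  ``sequenced``, when given, overrides the 7th column.
    """
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ParseError(f"empty pedigree file: {path}")
    members = []
    for lineno, ln in enumerate(lines, start=1):
        fields = ln.split()
        if len(fields) < 6:
            raise ParseError(f"pedigree line {lineno}: expected >= 6 columns, got {len(fields)}")
        _fid, sid, fat, mot, sex, pheno = fields[:6]
        seq_flag = len(fields) >= 7 and fields[6] == "1"
        members.append(
            PedigreeMember(
                sample_id=sid,
                sex=int(sex) if sex in ("1", "2") else None,
                father_id=None if fat == "0" else fat,
                mother_id=None if mot == "0" else mot,
                affected=pheno == "2",
                sequenced=seq_flag,
            )
        )
    try:
        ped = Pedigree(members)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc
    if sequenced is not None:
        ped = ped.with_sequenced(sequenced)
    return ped


def write_pedigree(ped: Pedigree, path, family_id: str = "FAM1") -> None:
    lines = []
    for m in ped:
        lines.append(
            "\t".join(
                [
                    family_id,
                    m.sample_id,
                    m.father_id or "0",
                    m.mother_id or "0",
                    str(m.sex or 0),
                    "2" if m.affected else "1",
                    "1" if m.sequenced else "0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Evidence table (TSV)
# ---------------------------------------------------------------------------


def _format_family_genotypes(genotypes: Mapping[str, GenotypeCall]) -> str:
    if not genotypes:
        return "-"
    parts = []
    for sid in sorted(genotypes):
        call = genotypes[sid]
        gt = "./." if call.alleles is None else "/".join(str(a) for a in call.alleles)
        parts.append(f"{sid}:{gt}")
    return ";".join(parts)


def _parse_family_genotypes(cell: str) -> dict:
    out = {}
    if _absent(cell):
        return out
    for part in cell.split(";"):
        sid, gt = part.split(":")
        if gt == "./.":
            alleles = None
        else:
            a, b = gt.split("/")
            alleles = (int(a), int(b))
        out[sid] = GenotypeCall(sample_id=sid, alleles=alleles)
    return out


def read_evidence_table(path) -> dict:
    """Read a per-variant evidence TSV into {variant_key: EvidenceRecord}.

    Columns: ``chrom pos ref alt sanger_status control_alt_alleles
    control_chromosomes family_genotypes``; family genotypes are encoded
    ``SAMPLE:0/1;SAMPLE2:1/1`` and cover members outside the sequenced pair.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict = {}
    for i, row in df.iterrows():
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        if key in out:
            raise ParseError(f"duplicate evidence for {variant_key_str(key)}")
        try:
            out[key] = EvidenceRecord(
                variant_key=key,
                sanger_status=row.get("sanger_status", "untested") or "untested",
                family_genotypes=_parse_family_genotypes(row.get("family_genotypes", "-")),
                control_alt_alleles=int(row.get("control_alt_alleles", 0) or 0),
                control_chromosomes=int(row.get("control_chromosomes", 0) or 0),
            )
        except ValueError as exc:
            raise ParseError(f"row {i}: {exc}") from exc
    return out


def write_evidence_table(evidence: Mapping[VariantKey, EvidenceRecord], path) -> None:
    rows = []
    for key in evidence:
        ev = evidence[key]
        chrom, pos, ref, alt = key
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "sanger_status": ev.sanger_status,
                "control_alt_alleles": ev.control_alt_alleles,
                "control_chromosomes": ev.control_chromosomes,
                "family_genotypes": _format_family_genotypes(ev.family_genotypes),
            }
        )
    cols = [
        "chrom",
        "pos",
        "ref",
        "alt",
        "sanger_status",
        "control_alt_alleles",
        "control_chromosomes",
        "family_genotypes",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, lineterminator="\n")
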