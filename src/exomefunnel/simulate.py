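"""Synthetic data with the statistical structure the pipeline assumes.

Three generators and one hand-encoded fixture:

* :func:`simulate_family` — a small multiplex family exome: unaffected
  parents, three affected siblings (two exome-sequenced), a planted recessive
  causal variant (parents obligate carriers), and annotated decoy variants
  whose genotypes follow Hardy-Weinberg at their allele frequency with
  Mendelian transmission to the children.  DP is negative-binomial, GQ and
  allelic depths reflect call correctness, and genotype errors are injected
  at a configurable rate.  Output is byte-identical under a fixed seed.
* :func:`table1_fixture` — the study family's 14-variant candidate set
  (8 shared-homozygous + 6 compound-heterozygous variants in 11 genes) with
  published per-sibling DP/GQ, plus the follow-up evidence that drives the
  validation cascade to its single survivor.  Zygosity is reconstructed from
  the inheritance labels (the only reading consistent with a recessive
  model); allelic depths and the extended-family genotypes are synthetic
  minimal encodings of the reported outcomes.
* :func:`simulate_tc_counts` — seeded binomial counts of tricellular
  contacts with protein accumulation.
* :func:`make_synthetic_trimer` — C3-arranged synthetic point-cloud chains
  with controllable C-terminus burial and planted cross-chain N-O pairs at
  exact distances, with ground-truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .structure import Chain, TrimerModel
from .variants import (
    AnnotatedVariant,
    EvidenceRecord,
    GenotypeCall,
    Pedigree,
    PedigreeMember,
    write_annotation_table,
    write_evidence_table,
    write_pedigree,
    write_vcf,
)

__all__ = [
    "CausalSpec",
    "SimConfig",
    "SimulatedFamily",
    "simulate_family",
    "table1_fixture",
    "Table1Fixture",
    "simulate_tc_counts",
    "make_synthetic_trimer",
]

FATHER, MOTHER = "SH23-97", "SH23-54"
SIBS = ("SH23-98", "SH23-99", "SH23-52")
SEQUENCED = ("SH23-98", "SH23-52")
FREQ_DBS = ("esp6500", "1000g", "inhouse")


def family_pedigree() -> Pedigree:
    """The study family: unaffected parents, three affected siblings, two of
    whom were exome-sequenced."""
    members = [
        PedigreeMember(FATHER, sex=1, affected=False),
        PedigreeMember(MOTHER, sex=2, affected=False),
    ]
    for sib in SIBS:
        members.append(
            PedigreeMember(
                sib,
                father_id=FATHER,
                mother_id=MOTHER,
                affected=True,
                sequenced=sib in SEQUENCED,
            )
        )
    return Pedigree(members)


# ---------------------------------------------------------------------------
# Family exome simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CausalSpec:
    gene: str = "ILDR1"
    chrom: str = "chr3"
    pos: int = 121_725_861
    ref: str = "G"
    alt: str = "T"
    consequence: str = "nonsynonymous"
    model: str = "homozygous"  # or "compound_het"

    def __post_init__(self) -> None:
        if self.model not in ("homozygous", "compound_het"):
            raise ValueError(f"unknown causal model {self.model!r}")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    ``af_mixture`` splits decoys into common (AF ~ U(0.01, 0.5)), rare
    (AF ~ U(0.0005, 0.01)) and novel (no database entry; a small latent AF
    still drives genotypes).  ``depth_model`` is (mean, dispersion) of a
    negative-binomial DP; correct calls draw GQ from ``gq_good`` and
    error-injected calls from ``gq_bad``.
    """

    seed: int = 0
    n_decoy_variants: int = 2000
    af_mixture: tuple = (0.5, 0.3, 0.2)  # common, rare, novel
    genotype_error_rate: float = 0.0
    depth_model: tuple = (80.0, 8.0)  # (mean, dispersion)
    gq_good: tuple = (60, 99)
    gq_bad: tuple = (0, 29)
    p_db_entry: float = 0.9  # a non-novel AF appears in each frequency db
    p_dbsnp_common: float = 0.95
    p_dbsnp_rare: float = 0.6
    p_synonymous: float = 0.45
    causal_spec: CausalSpec = CausalSpec()

    def __post_init__(self) -> None:
        if abs(sum(self.af_mixture) - 1.0) > 1e-9:
            raise ValueError("af_mixture fractions must sum to 1")
        for r in (
            self.genotype_error_rate,
            self.p_db_entry,
            self.p_dbsnp_common,
            self.p_dbsnp_rare,
            self.p_synonymous,
        ):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


_BASES = ("A", "C", "G", "T")
_NONSYN_CONSEQUENCES = (
    "nonsynonymous",
    "stopgain",
    "splicing",
    "frameshift-insertion",
    "frameshift-deletion",
    "nonframeshift-insertion",
    "nonframeshift-deletion",
    "other",
)
_NONSYN_WEIGHTS = np.array([0.72, 0.04, 0.05, 0.04, 0.04, 0.04, 0.04, 0.03])


@dataclass
class SimulatedFamily:
    config: SimConfig
    pedigree: Pedigree
    variants: dict  # vk -> AnnotatedVariant
    genotypes: dict  # vk -> {sample_id: GenotypeCall}
    truth: dict  # {"causal_keys": [...], "gene": ..., "model": ...}
    evidence: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list:
        return [m.sample_id for m in self.pedigree]

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        keys = sorted(self.variants)
        records = [(self.variants[k], self.genotypes[k]) for k in keys]
        paths = {
            "vcf": outdir / "family.vcf",
            "ped": outdir / "family.ped",
            "annotations": outdir / "annotations.tsv",
            "evidence": outdir / "evidence.tsv",
            "truth": outdir / "truth.json",
        }
        write_vcf(records, paths["vcf"], self.sample_ids)
        write_pedigree(self.pedigree, paths["ped"], family_id="SNUH23")
        write_annotation_table(
            [self.variants[k] for k in keys], paths["annotations"], af_dbs=list(FREQ_DBS)
        )
        write_evidence_table(self.evidence, paths["evidence"])
        import json

        truth = dict(self.truth)
        truth["causal_keys"] = [list(k) for k in truth["causal_keys"]]
        paths["truth"].write_text(json.dumps(truth, indent=1) + "\n")
        return paths


def _draw_depth(rng, mean: float, dispersion: float, minimum: int = 0) -> int:
    p = dispersion / (dispersion + mean)
    while True:
        dp = int(rng.negative_binomial(dispersion, p))
        if dp >= minimum:
            return dp


def _make_call(rng, cfg: SimConfig, sample_id: str, alleles, *, min_depth: int = 0,
               inject_error: bool = False) -> GenotypeCall:
    dp = _draw_depth(rng, cfg.depth_model[0], cfg.depth_model[1], minimum=max(min_depth, 1))
    if inject_error:
        choices = [(0, 0), (0, 1), (1, 1)]
        choices.remove(tuple(sorted(alleles)))
        alleles = choices[int(rng.integers(len(choices)))]
        gq = int(rng.integers(cfg.gq_bad[0], cfg.gq_bad[1] + 1))
    else:
        gq = int(rng.integers(cfg.gq_good[0], cfg.gq_good[1] + 1))
    n_alt = sum(alleles)
    p_alt = {0: 0.02, 1: 0.5, 2: 0.98}[n_alt]
    alt_reads = int(rng.binomial(dp, p_alt))
    return GenotypeCall(
        sample_id=sample_id,
        alleles=tuple(alleles),
        depth=dp,
        genotype_quality=gq,
        allele_depths=(dp - alt_reads, alt_reads),
    )


def simulate_family(cfg: SimConfig = SimConfig()) -> SimulatedFamily:
    """Simulate one annotated family exome with a planted causal variant.

    Parents are obligate heterozygous carriers of the planted allele(s);
    all affected siblings are homozygous (or carry both compound-het
    alleles).  Decoy founder genotypes are Hardy-Weinberg draws at each
    variant's latent allele frequency; children inherit one allele from each
    parent.  Genotype errors are injected per call at
    ``cfg.genotype_error_rate`` (erroneous calls receive low GQ).
    """
    rng = np.random.default_rng(cfg.seed)
    ped = family_pedigree()
    variants: dict = {}
    genotypes: dict = {}

    # --- planted causal variant(s) -------------------------------------
    spec = cfg.causal_spec
    causal_defs = []  # (AnnotatedVariant, father_alleles, mother_alleles, sib_alleles)
    if spec.model == "homozygous":
        v = AnnotatedVariant(
            chrom=spec.chrom, pos=spec.pos, ref=spec.ref, alt=spec.alt,
            gene=spec.gene, consequence=spec.consequence,
        )
        causal_defs.append((v, (0, 1), (0, 1), (1, 1)))
    else:
        v1 = AnnotatedVariant(
            chrom=spec.chrom, pos=spec.pos, ref=spec.ref, alt=spec.alt,
            gene=spec.gene, consequence=spec.consequence,
        )
        alt2 = next(b for b in _BASES if b != spec.ref and b != spec.alt)
        v2 = AnnotatedVariant(
            chrom=spec.chrom, pos=spec.pos + 60, ref=spec.ref, alt=alt2,
            gene=spec.gene, consequence=spec.consequence,
        )
        causal_defs.append((v1, (0, 1), (0, 0), (0, 1)))
        causal_defs.append((v2, (0, 0), (0, 1), (0, 1)))

    for v, fat_al, mot_al, sib_al in causal_defs:
        variants[v.key] = v
        calls = {}
        err = rng.random(len(ped.members)) < cfg.genotype_error_rate
        for i, (sid, alleles) in enumerate(
            [(FATHER, fat_al), (MOTHER, mot_al)] + [(s, sib_al) for s in SIBS]
        ):
            calls[sid] = _make_call(
                rng, cfg, sid, alleles, min_depth=20, inject_error=bool(err[i])
            )
        genotypes[v.key] = calls

    # --- decoys ---------------------------------------------------------
    n_genes = max(10, cfg.n_decoy_variants // 3)
    used_positions = {(v.chrom, v.pos) for v in variants.values()}
    p_common, p_rare, _p_novel = cfg.af_mixture
    for i in range(cfg.n_decoy_variants):
        gene = f"GENE{int(rng.integers(n_genes)):05d}"
        while gene == spec.gene:  # regenerate on collision with the causal gene
            gene = f"GENE{int(rng.integers(n_genes)):05d}"
        while True:
            chrom = f"chr{int(rng.integers(1, 23))}"
            pos = int(rng.integers(1, 250_000_000))
            if (chrom, pos) not in used_positions:
                used_positions.add((chrom, pos))
                break
        ref = _BASES[int(rng.integers(4))]
        alt = next(b for b in np.array(_BASES)[rng.permutation(4)] if b != ref)

        u = rng.random()
        if u < p_common:
            af = float(rng.uniform(0.01, 0.5))
            p_dbsnp = cfg.p_dbsnp_common
            observed = True
        elif u < p_common + p_rare:
            af = float(rng.uniform(0.0005, 0.01))
            p_dbsnp = cfg.p_dbsnp_rare
            observed = True
        else:
            af = float(rng.uniform(0.0005, 0.005))
            p_dbsnp = 0.0
            observed = False

        pop_afs = {}
        if observed:
            for db in FREQ_DBS:
                if rng.random() < cfg.p_db_entry:
                    pop_afs[db] = float(np.clip(af * (1 + rng.normal(0, 0.1)), 0.0, 1.0))
        dbsnp_v1 = f"rs{int(rng.integers(10**6, 10**8))}" if rng.random() < p_dbsnp else None
        dbsnp_v2 = dbsnp_v1
        if dbsnp_v2 is None and rng.random() < 0.02:
            dbsnp_v2 = f"rs{int(rng.integers(10**6, 10**8))}"

        if rng.random() < cfg.p_synonymous:
            consequence = "synonymous"
        else:
            consequence = str(rng.choice(_NONSYN_CONSEQUENCES, p=_NONSYN_WEIGHTS))

        v = AnnotatedVariant(
            chrom=chrom, pos=pos, ref=str(ref), alt=str(alt), gene=gene,
            consequence=consequence, pop_afs=pop_afs,
            dbsnp_v1_id=dbsnp_v1, dbsnp_v2_id=dbsnp_v2,
        )
        variants[v.key] = v

        fat = tuple(sorted(rng.binomial(1, af, size=2)))
        mot = tuple(sorted(rng.binomial(1, af, size=2)))
        calls = {}
        err = rng.random(len(ped.members)) < cfg.genotype_error_rate
        calls[FATHER] = _make_call(rng, cfg, FATHER, fat, inject_error=bool(err[0]))
        calls[MOTHER] = _make_call(rng, cfg, MOTHER, mot, inject_error=bool(err[1]))
        for k, sib in enumerate(SIBS):
            alleles = tuple(
                sorted((fat[int(rng.integers(2))], mot[int(rng.integers(2))]))
            )
            calls[sib] = _make_call(rng, cfg, sib, alleles, inject_error=bool(err[2 + k]))
        genotypes[v.key] = calls

    truth = {
        "causal_keys": [v.key for v, *_ in causal_defs],
        "gene": spec.gene,
        "model": spec.model,
    }
    return SimulatedFamily(
        config=cfg, pedigree=ped, variants=variants, genotypes=genotypes, truth=truth
    )


# ---------------------------------------------------------------------------
# Hand-encoded candidate-set fixture
# ---------------------------------------------------------------------------

# Columns: inheritance, gene, func, genbank, exon, chgvs, phgvs,
#          chrom, pos, ref, alt, DP/GQ (SH23-52), DP/GQ (SH23-98)
_TABLE1_ROWS = [
    ("Homo", "ILDR1", "NS", "NM_001199799", "Exon2", "c.C206A", "p.P69H",
     "chr3", 121725861, "G", "T", 25, 75, 40, 99),
    ("Homo", "ZSCAN26", "-", None, None, None, None,
     "chr6", 28239932, "-", "G", 28, 84, 40, 78),
    ("Homo", "MICA", "FI", "NM_000247", "exon6", "c.949-1->CTGCTGCTGCT", None,
     "chr6", 31380161, "-", "CTGCTGCTGCT", 23, 66, 24, 72),
    ("Homo", "MUC12", "NS", "NM_001164462", "exon2", "c.C7682T", "p.T2561M",
     "chr7", 100641526, "C", "T", 203, 99, 238, 99),
    ("Homo", "ATXN3", "NI", "NM_001164782", "exon2", "c.68_69insAGCAGCAGCAGC",
     "p.G23delinsGAAAA", "chr14", 92537353, "-", "GCTGCTGCTGCT", 50, 99, 66, 99),
    ("Homo", "NR1H2", "NI", "NM_001256647", "exon5", "c.225_226insCAG", "p.K75delinsKQ",
     "chr19", 50881822, "-", "CAG", 64, 99, 73, 99),
    ("Homo", "VSIG10L", "FI", "NM_001163922", "exon10", "c.2577dupC", "p.A859fs",
     "chr19", 51835892, "-", "G", 47, 99, 72, 99),
    ("Homo", "PLK1S1", "-", None, None, None, None,
     "chr20", 21186161, "-", "G", 67, 99, 96, 99),
    ("Com het", "CHD3", "NS", "NM_001005271", "exon5", "c.G898C", "p.A300P",
     "chr17", 7796815, "G", "C", 60, 99, 84, 99),
    ("Com het", "CHD3", "NS", "NM_001005271", "exon5", "c.T902C", "p.L301P",
     "chr17", 7796819, "T", "C", 70, 87, 102, 99),
    ("Com het", "BRCA1", "NS", "NM_007297", "exon9", "c.T1789A", "p.C597S",
     "chr17", 41245618, "A", "T", 138, 99, 206, 99),
    ("Com het", "BRCA1", "NS", "NM_007297", "exon3", "c.C13T", "p.L5F",
     "chr17", 41258531, "G", "A", 52, 99, 61, 99),
    ("Com het", "ABCA10", "NS", "NM_080282", "exon32", "c.C3779T", "p.A1260V",
     "chr17", 67150383, "G", "A", 107, 99, 158, 99),
    ("Com het", "ABCA10", "NS", "NM_080282", "exon32", "c.G3778C", "p.A1260P",
     "chr17", 67150384, "C", "G", 109, 99, 162, 99),
]

#: Revalidation-build dbSNP identifiers reported for four of the homozygous
#: candidates.
_DBSNP_V2_IDS = {
    "ZSCAN26": "rs61622742",
    "NR1H2": "rs34296657",
    "VSIG10L": "rs11402251",
    "PLK1S1": "rs11087346",
}

#: Control-cohort screening outcomes (alt alleles seen, chromosomes screened).
_CONTROL_SCREEN = {
    "ILDR1": (0, 476),
    "MICA": (3, 276),
    "ATXN3": (4, 276),
}

_SANGER_FAILED_GENES = {"MUC12", "CHD3"}
_NONSEGREGATING_GENES = {"BRCA1", "ABCA10"}

_FUNC = {"NS": "nonsynonymous", "FI": "frameshift-insertion",
         "NI": "nonframeshift-insertion", "-": "other"}


@dataclass
class Table1Fixture:
    variants: dict  # vk -> AnnotatedVariant
    genotypes: dict  # vk -> {sample_id: GenotypeCall}
    pedigree: Pedigree
    evidence: dict  # vk -> EvidenceRecord


def _fixture_call(sample_id: str, alleles, dp: int, gq: int) -> GenotypeCall:
    # synthetic allelic depths: alt reads at half depth for hets, (nearly)
    # full depth for hom-alt; only zygosity and DP/GQ are published
    n_alt = sum(alleles)
    alt_reads = {0: 0, 1: dp // 2, 2: dp}[n_alt]
    return GenotypeCall(
        sample_id=sample_id,
        alleles=tuple(alleles),
        depth=dp,
        genotype_quality=gq,
        allele_depths=(dp - alt_reads, alt_reads),
    )


def table1_fixture() -> Table1Fixture:
    """The 14-variant candidate set of the study family, with follow-up
    evidence.

    Zygosity in the sequenced siblings follows the inheritance label
    (homozygous rows alt/alt in both; compound-het gene pairs het/het).
    Evidence encodes the reported exclusions: Sanger failure for the MUC12
    and CHD3 variants; non-cosegregation for BRCA1 and ABCA10 (the affected
    non-sequenced sibling lacks the second variant of each pair — a
    synthetic minimal counterexample); revalidation dbSNP ids for ZSCAN26,
    NR1H2, VSIG10L and PLK1S1; control-cohort counts 3/276 (MICA), 4/276
    (ATXN3) and 0/476 (ILDR1).
    """
    ped = family_pedigree()
    variants: dict = {}
    genotypes: dict = {}
    evidence: dict = {}
    second_of_pair: dict = {}

    for (inh, gene, func, genbank, exon, chgvs, phgvs,
         chrom, pos, ref, alt, dp52, gq52, dp98, gq98) in _TABLE1_ROWS:
        scores = {}
        if gene == "ILDR1":
            scores = {"sift": 0.03, "polyphen2_hvar": 1.0, "gerp": 5.64}
        v = AnnotatedVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            consequence=_FUNC[func], exon_label=exon, chgvs=chgvs, phgvs=phgvs,
            dbsnp_v2_id=_DBSNP_V2_IDS.get(gene), scores=scores,
        )
        variants[v.key] = v
        alleles = (1, 1) if inh == "Homo" else (0, 1)
        genotypes[v.key] = {
            "SH23-52": _fixture_call("SH23-52", alleles, dp52, gq52),
            "SH23-98": _fixture_call("SH23-98", alleles, dp98, gq98),
        }
        if inh == "Com het":
            second_of_pair[gene] = v.key  # later row of the pair wins

        sanger = "failed" if gene in _SANGER_FAILED_GENES else "confirmed"
        ctrl_alt, ctrl_n = _CONTROL_SCREEN.get(gene, (0, 0))
        evidence[v.key] = EvidenceRecord(
            variant_key=v.key,
            sanger_status=sanger,
            control_alt_alleles=ctrl_alt,
            control_chromosomes=ctrl_n,
        )

    # extended-family genotypes (Sanger): the non-sequenced affected sibling
    # and both parents, consistent for the surviving homozygous candidates,
    # broken for the non-cosegregating compound-het genes
    for vk, v in variants.items():
        gene = v.gene
        if gene in _SANGER_FAILED_GENES:
            continue
        fam: dict = {}
        if genotypes[vk]["SH23-52"].is_hom_alt:
            fam = {
                "SH23-99": GenotypeCall("SH23-99", (1, 1)),
                FATHER: GenotypeCall(FATHER, (0, 1)),
                MOTHER: GenotypeCall(MOTHER, (0, 1)),
            }
        elif gene in _NONSEGREGATING_GENES:
            carries = vk != second_of_pair[gene]
            fam = {"SH23-99": GenotypeCall("SH23-99", (0, 1) if carries else (0, 0))}
        ev = evidence[vk]
        evidence[vk] = EvidenceRecord(
            variant_key=vk,
            sanger_status=ev.sanger_status,
            family_genotypes=fam,
            control_alt_alleles=ev.control_alt_alleles,
            control_chromosomes=ev.control_chromosomes,
        )

    return Table1Fixture(
        variants=variants, genotypes=genotypes, pedigree=ped, evidence=evidence
    )


# ---------------------------------------------------------------------------
# Tricellular-contact counts
# ---------------------------------------------------------------------------


def simulate_tc_counts(n_tc: int, p_localized: float, seed: int = 0) -> tuple:
    """Seeded binomial count of TCs showing accumulation: (localized, total)."""
    if n_tc <= 0:
        raise ValueError("n_tc must be positive")
    if not (0.0 <= p_localized <= 1.0):
        raise ValueError("p_localized must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return int(rng.binomial(n_tc, p_localized)), n_tc


# ---------------------------------------------------------------------------
# Synthetic trimers
# ---------------------------------------------------------------------------

_BACKBONE = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))


def make_synthetic_trimer(
    preset: str = "exposed",
    n_residues: int = 20,
    ring_radius: float = 18.0,
    n_polar_pairs: int = 0,
    polar_distance: float = 3.2,
    noise: float = 0.0,
    seed: int = 0,
    external_score: Optional[float] = None,
    name: str = "",
) -> tuple:
    """Build a C3-arranged synthetic trimer with known ground truth.

    ``preset="exposed"`` keeps each chain a compact blob at ``ring_radius``
    from the origin, so every C-terminal Calpha is far from foreign atoms;
    ``preset="buried"`` additionally sinks each chain's last five residues
    into a shared dense core at the origin, burying all three C-termini.
    ``n_polar_pairs`` cross-chain N-O pairs are planted at exactly
    ``polar_distance`` Angstrom in otherwise empty space, so they are the
    only cross-chain polar contacts within hydrogen-bond range.

    Returns ``(TrimerModel, truth)`` with truth labels
    ``{"exposed": bool, "n_polar_pairs": int}``.
    """
    if preset not in ("exposed", "buried"):
        raise ValueError(f"unknown preset {preset!r}")
    rng = np.random.default_rng(seed)
    centers = [
        ring_radius * np.array([np.cos(a), np.sin(a), 0.0])
        for a in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)
    ]

    chains = []
    for ci, (cid, center) in enumerate(zip("ABC", centers)):
        res_ids, res_names, atom_names, elements, coords = [], [], [], [], []
        n_core = 5 if preset == "buried" else 0
        for r in range(1, n_residues + 1):
            if preset == "buried" and r > n_residues - n_core:
                # sink the tail into a shared dense core at the origin
                depth = n_residues - r
                base = np.array(
                    [0.9 * np.cos(ci + depth), 0.9 * np.sin(ci + depth), 0.4 * depth - 1.0]
                )
            else:
                # compact local blob (~6 A box) around the chain center
                base = center + np.array(
                    [1.6 * (r % 4), 1.6 * ((r // 4) % 4), 1.3 * ((r * 7) % 5)]
                ) - np.array([2.4, 2.4, 2.6])
            for k, (aname, elem) in enumerate(_BACKBONE):
                res_ids.append(r)
                res_names.append("ALA")
                atom_names.append(aname)
                elements.append(elem)
                coords.append(base + 0.45 * np.array([k, (k * 2) % 3, (k * 5) % 3]))
        coords = np.asarray(coords, dtype=float)
        if noise > 0:
            coords = coords + rng.normal(0.0, noise, size=coords.shape)
        chains.append(
            dict(
                chain_id=cid,
                res_ids=list(res_ids),
                res_names=list(res_names),
                atom_names=list(atom_names),
                elements=list(elements),
                coords=coords,
                c_term_index=n_residues,
            )
        )

    # plant isolated cross-chain N-O pairs in the empty outskirts
    for p in range(n_polar_pairs):
        i, j = p % 3, (p + 1) % 3
        mid = (centers[i] + centers[j]) / 2.0
        direction = mid / np.linalg.norm(mid)
        anchor = direction * (ring_radius + 12.0 + 8.0 * p)
        partner = anchor + np.array([0.0, 0.0, polar_distance])
        for chain_idx, pos, aname, elem in (
            (i, anchor, "ND1", "N"),
            (j, partner, "OD1", "O"),
        ):
            ch = chains[chain_idx]
            ch["res_ids"].append(n_residues + 1 + p)
            ch["res_names"].append("ASX")
            ch["atom_names"].append(aname)
            ch["elements"].append(elem)
            ch["coords"] = np.vstack([ch["coords"], pos])

    model = TrimerModel(
        chains=tuple(
            Chain(
                chain_id=ch["chain_id"],
                res_ids=np.asarray(ch["res_ids"], dtype=int),
                res_names=np.asarray(ch["res_names"], dtype=str),
                atom_names=np.asarray(ch["atom_names"], dtype=str),
                elements=np.asarray(ch["elements"], dtype=str),
                coords=np.asarray(ch["coords"], dtype=float),
                c_term_index=ch["c_term_index"],
            )
            for ch in chains
        ),
        external_score=external_score,
        name=name or f"synthetic-{preset}-{seed}",
    )
    truth = {"exposed": preset == "exposed", "n_polar_pairs": n_polar_pairs}
    return model, truth
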