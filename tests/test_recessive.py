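"""Recessive classification, cosegregation, and the validation cascade."""

import pytest

from oracles import cosegregation_bruteforce, recessive_candidates_bruteforce

from exomefunnel.recessive import (
    GenotypeConflictError,
    RecessiveCandidate,
    ValidationConfig,
    apply_validation_filters,
    check_cosegregation,
    classify_recessive,
)
from exomefunnel.simulate import family_pedigree
from exomefunnel.variants import (
    AnnotatedVariant,
    EvidenceRecord,
    GenotypeCall,
    Pedigree,
    PedigreeMember,
)


def _gt(sid, alleles):
    return GenotypeCall(sid, alleles)


class TestClassifyRecessive:
    def test_candidate_table_yields_8_hom_6_comphet_in_11_genes(self, table1):
        res = classify_recessive(table1.variants.values(), table1.genotypes, table1.pedigree)
        hom = [c for c in res.candidates if c.model == "homozygous"]
        ch = [c for c in res.candidates if c.model == "compound_heterozygous"]
        assert len(hom) == 8
        assert sorted(c.gene for c in ch) == ["ABCA10", "BRCA1", "CHD3"]
        assert sum(len(c.variant_keys) for c in ch) == 6
        assert len({c.gene for c in res.candidates}) == 11

    def test_single_shared_het_is_no_candidate(self):
        ped = family_pedigree()
        v = AnnotatedVariant("chr1", 10, "A", "T", gene="G1", consequence="nonsynonymous")
        genotypes = {v.key: {s: _gt(s, (0, 1)) for s in ped.sequenced_affected_ids}}
        res = classify_recessive([v], genotypes, ped)
        assert res.candidates == []
        assert res.exclusions[v.key] == "inheritance"

    def test_missing_genotype_excluded_not_silently_passed(self):
        ped = family_pedigree()
        v = AnnotatedVariant("chr1", 10, "A", "T", gene="G1", consequence="nonsynonymous")
        genotypes = {v.key: {"SH23-98": _gt("SH23-98", (1, 1))}}  # SH23-52 absent
        res = classify_recessive([v], genotypes, ped)
        assert res.exclusions[v.key] == "missing-genotype"

    def test_matches_bruteforce_enumeration_on_random_matrices(self, rng):
        for trial in range(60):
            n_samples = int(rng.integers(1, 4))
            sample_ids = [f"A{i}" for i in range(n_samples)]
            ped = Pedigree(
                [PedigreeMember(s, affected=True, sequenced=True) for s in sample_ids]
            )
            n_sites = int(rng.integers(1, 21))
            variants, genotypes, variant_genes, matrix = [], {}, {}, {}
            for i in range(n_sites):
                v = AnnotatedVariant(
                    "chr1", i + 1, "A", "T",
                    gene=f"G{int(rng.integers(5))}", consequence="nonsynonymous",
                )
                variants.append(v)
                variant_genes[v.key] = v.gene
                calls, plain = {}, {}
                for s in sample_ids:
                    if rng.random() < 0.1:
                        calls[s] = _gt(s, None)
                        plain[s] = None
                    else:
                        alleles = [(0, 0), (0, 1), (1, 1)][int(rng.integers(3))]
                        calls[s] = _gt(s, alleles)
                        plain[s] = alleles
                genotypes[v.key] = calls
                matrix[v.key] = plain
            res = classify_recessive(variants, genotypes, ped)
            hom = {
                c.variant_keys[0] for c in res.candidates if c.model == "homozygous"
            }
            ch = {
                c.gene: frozenset(c.variant_keys)
                for c in res.candidates
                if c.model == "compound_heterozygous"
            }
            oracle_hom, oracle_ch = recessive_candidates_bruteforce(
                variant_genes, matrix, sample_ids
            )
            assert hom == oracle_hom, f"trial {trial}"
            assert ch == oracle_ch, f"trial {trial}"

    def test_invariant_to_variant_and_sample_order(self, table1, rng):
        base = classify_recessive(table1.variants.values(), table1.genotypes, table1.pedigree)
        shuffled = list(table1.variants.values())
        rng.shuffle(shuffled)
        again = classify_recessive(shuffled, table1.genotypes, table1.pedigree)
        assert base.candidates == again.candidates
        assert base.exclusions == again.exclusions


class TestCosegregation:
    def _homo_candidate(self, vk):
        return RecessiveCandidate("G", "homozygous", (vk,), ("SH23-98", "SH23-52"))

    def test_causal_configuration_consistent(self, table1):
        # three affected sibs hom-alt, both parents het
        vk = ("chr3", 121725861, "G", "T")
        cand = self._homo_candidate(vk)
        assert check_cosegregation(cand, table1.evidence, table1.pedigree, table1.genotypes)

    def test_unaffected_parent_hom_alt_is_inconsistent(self):
        ped = family_pedigree()
        vk = ("chr1", 10, "A", "T")
        cand = self._homo_candidate(vk)
        wes = {vk: {s: _gt(s, (1, 1)) for s in ("SH23-98", "SH23-52")}}
        ev = {
            vk: EvidenceRecord(
                vk, family_genotypes={"SH23-97": _gt("SH23-97", (1, 1))}
            )
        }
        assert not check_cosegregation(cand, ev, ped, wes)

    def test_conflicting_evidence_genotype_raises_naming_sample(self):
        ped = family_pedigree()
        vk = ("chr1", 10, "A", "T")
        cand = self._homo_candidate(vk)
        wes = {vk: {"SH23-98": _gt("SH23-98", (1, 1)), "SH23-52": _gt("SH23-52", (1, 1))}}
        ev = {vk: EvidenceRecord(vk, family_genotypes={"SH23-98": _gt("SH23-98", (0, 1))})}
        with pytest.raises(GenotypeConflictError, match="SH23-98"):
            check_cosegregation(cand, ev, ped, wes)

    def test_comphet_same_parent_transmission_inconsistent(self):
        ped = family_pedigree()
        v1, v2 = ("chr1", 10, "A", "T"), ("chr1", 99, "G", "C")
        cand = RecessiveCandidate(
            "G", "compound_heterozygous", (v1, v2), ("SH23-98", "SH23-52")
        )
        wes = {
            vk: {s: _gt(s, (0, 1)) for s in ("SH23-98", "SH23-52")} for vk in (v1, v2)
        }
        # both variants carried by the father only: cis configuration
        ev = {
            vk: EvidenceRecord(
                vk,
                family_genotypes={
                    "SH23-97": _gt("SH23-97", (0, 1)),
                    "SH23-54": _gt("SH23-54", (0, 0)),
                },
            )
            for vk in (v1, v2)
        }
        assert not check_cosegregation(cand, ev, ped, wes)
        # trans configuration: one variant per parent
        ev_trans = {
            v1: EvidenceRecord(
                v1,
                family_genotypes={
                    "SH23-97": _gt("SH23-97", (0, 1)),
                    "SH23-54": _gt("SH23-54", (0, 0)),
                },
            ),
            v2: EvidenceRecord(
                v2,
                family_genotypes={
                    "SH23-97": _gt("SH23-97", (0, 0)),
                    "SH23-54": _gt("SH23-54", (0, 1)),
                },
            ),
        }
        assert check_cosegregation(cand, ev_trans, ped, wes)

    def test_matches_truth_table_oracle_on_random_pedigrees(self, rng):
        for trial in range(120):
            n_extra = int(rng.integers(0, 3))
            members = [
                PedigreeMember("FA", sex=1, affected=False),
                PedigreeMember("MO", sex=2, affected=False),
                PedigreeMember("A1", father_id="FA", mother_id="MO",
                               affected=True, sequenced=True),
                PedigreeMember("A2", father_id="FA", mother_id="MO",
                               affected=True, sequenced=True),
            ]
            for i in range(n_extra):
                members.append(
                    PedigreeMember(
                        f"X{i}", father_id="FA", mother_id="MO",
                        affected=bool(rng.random() < 0.5),
                    )
                )
            ped = Pedigree(members)
            model = "homozygous" if rng.random() < 0.5 else "compound_heterozygous"
            n_vars = 1 if model == "homozygous" else int(rng.integers(2, 4))
            vks = [("chr1", 10 * (i + 1), "A", "T") for i in range(n_vars)]
            cand = RecessiveCandidate("G", model, tuple(vks), ("A1", "A2"))

            wes, ev, plain = {}, {}, {}
            for vk in vks:
                wes[vk] = {}
                fam = {}
                for m in members:
                    if rng.random() < 0.25:
                        continue  # untyped
                    alleles = [(0, 0), (0, 1), (1, 1)][int(rng.integers(3))]
                    plain.setdefault(m.sample_id, {})[vk] = alleles
                    if m.sequenced:
                        wes[vk][m.sample_id] = _gt(m.sample_id, alleles)
                    else:
                        fam[m.sample_id] = _gt(m.sample_id, alleles)
                ev[vk] = EvidenceRecord(vk, family_genotypes=fam)

            got = check_cosegregation(cand, ev, ped, wes)
            want = cosegregation_bruteforce(
                model,
                vks,
                plain,
                affected=[m.sample_id for m in members if m.affected],
                unaffected=[m.sample_id for m in members if not m.affected],
                parents=["FA", "MO"],
            )
            assert got == want, f"trial {trial}: {model} {plain}"


class TestValidationCascade:
    def test_published_evidence_leaves_single_survivor(self, table1):
        res = classify_recessive(table1.variants.values(), table1.genotypes, table1.pedigree)
        report, surviving = apply_validation_filters(
            res.candidates, table1.evidence, table1.pedigree, table1.genotypes,
            table1.variants,
        )
        assert report.stages == [
            ("recessive-candidates", 14),
            ("sanger", 11),
            ("cosegregation", 7),
            ("dbsnp-revalidation", 3),
            ("control-cohort", 1),
        ]
        assert report.survivors == [("chr3", 121725861, "G", "T")]
        assert len(surviving) == 1 and surviving[0].gene == "ILDR1"
        reasons = list(report.exclusions.values())
        assert reasons.count("sanger") == 3
        assert reasons.count("cosegregation") == 4
        assert reasons.count("dbsnp-revalidation") == 4
        assert reasons.count("control-cohort") == 2

    def test_all_untested_evidence_vacuously_passes(self, table1):
        res = classify_recessive(table1.variants.values(), table1.genotypes, table1.pedigree)
        report, surviving = apply_validation_filters(
            res.candidates, {}, table1.pedigree, table1.genotypes, variants=None
        )
        assert len(report.survivors) == 14
        assert report.exclusions == {}

    def test_zero_of_476_control_alleles_retained(self):
        ped = family_pedigree()
        vk = ("chr3", 121725861, "G", "T")
        cand = RecessiveCandidate("ILDR1", "homozygous", (vk,), ("SH23-98", "SH23-52"))
        wes = {vk: {s: _gt(s, (1, 1)) for s in ("SH23-98", "SH23-52")}}
        ev = {vk: EvidenceRecord(vk, sanger_status="confirmed",
                                 control_alt_alleles=0, control_chromosomes=476)}
        report, _ = apply_validation_filters([cand], ev, ped, wes)
        assert report.survivors == [vk]

    def test_any_control_carrier_excludes_by_default(self):
        ped = family_pedigree()
        vk = ("chr6", 31380161, "-", "CTGCTGCTGCT")
        cand = RecessiveCandidate("MICA", "homozygous", (vk,), ("SH23-98", "SH23-52"))
        wes = {vk: {s: _gt(s, (1, 1)) for s in ("SH23-98", "SH23-52")}}
        ev = {vk: EvidenceRecord(vk, control_alt_alleles=3, control_chromosomes=276)}
        report, _ = apply_validation_filters([cand], ev, ped, wes)
        assert report.exclusions[vk] == "control-cohort"
        # a laxer threshold keeps it
        report2, _ = apply_validation_filters(
            [cand], ev, ped, wes, cfg=ValidationConfig(control_max_carriers=5)
        )
        assert report2.survivors == [vk]
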