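"""Chimerism detection, shared cancer genotype, BTN calls, mito sexing."""
import numpy as np
import pytest

from btnscreen import allelecall as ac
from btnscreen import chimera as ch
from btnscreen import simcohort as sc
from btnscreen.errors import InputError


def genotype(freqs, ind="J161", locus="EF1a", tissue="hemolymph", seqs=None):
    alleles = []
    for i, (name, f) in enumerate(freqs.items()):
        seq = (seqs or {}).get(name, f"{name}_" * 5 + "X" * (30 - 2 * len(name) * 5 % 7))
        alleles.append(ac.AlleleCall(name, seq, 0, f, ac.COMMON))
    return ac.TissueGenotype(ind, locus, tissue, alleles)


def seq_table(names):
    # deterministic distinct sequences keyed by allele name
    return {n: (n * 40)[:30].ljust(30, "T") for n in names}


class TestExtraAlleles:
    def test_identical_genotypes_show_nothing(self):
        seqs = seq_table(["a", "b"])
        h = genotype({"a": 0.5, "b": 0.5}, seqs=seqs)
        f = genotype({"a": 0.5, "b": 0.5}, tissue="foot", seqs=seqs)
        assert ch.extra_alleles(h, f) == []

    def test_enrichment_with_printed_frequencies(self):
        # hemolymph D/G/H vs foot 6/7/G/H: G and H enriched, D hemolymph-only
        seqs = seq_table(["D", "G", "H", "6", "7"])
        h = genotype({"D": 0.33, "G": 0.39, "H": 0.28}, seqs=seqs)
        f = genotype(
            {"6": 0.31, "7": 0.25, "G": 0.12, "H": 0.06}, tissue="foot", seqs=seqs
        )
        extra = {a.allele_id for a in ch.extra_alleles(h, f)}
        assert extra == {"G", "H", "D"}

    def test_margin_absorbs_small_differences(self):
        seqs = seq_table(["a", "b"])
        h = genotype({"a": 0.55, "b": 0.45}, seqs=seqs)
        f = genotype({"a": 0.5, "b": 0.5}, tissue="foot", seqs=seqs)
        assert ch.extra_alleles(h, f, margin=0.1) == []
        assert len(ch.extra_alleles(h, f, margin=0.0)) == 1

    def test_missing_tissue_rejected(self):
        h = genotype({"a": 1.0})
        with pytest.raises(InputError):
            ch.extra_alleles(h, None)


class TestSharedCancerAlleles:
    def test_survey_fixture_yields_nuclear_pair(self, table1_genotypes):
        dn = [ch.detect_chimerism(table1_genotypes[i])
              for i in ("J54", "J111", "J161", "J181")]
        cancer = ch.shared_cancer_alleles(dn, "EF1a")
        names = {a.name for a in cancer.alleles["EF1a"]}
        assert names == {"G", "H"}
        assert len(cancer.alleles["EF1a"]) == 2
        assert all(a.support == 4 for a in cancer.alleles["EF1a"])

    def test_disjoint_extras_share_nothing(self):
        seqs = seq_table(["a", "b", "x", "y"])
        r1 = ch.ChimerismResult(
            "i1", extra_alleles={"EF1a": [ac.AlleleCall("a", seqs["a"], 0, 0.5, "common")]}
        )
        r2 = ch.ChimerismResult(
            "i2", extra_alleles={"EF1a": [ac.AlleleCall("b", seqs["b"], 0, 0.5, "common")]}
        )
        with pytest.warns(UserWarning):
            cancer = ch.shared_cancer_alleles([r1, r2], "EF1a")
        assert cancer.empty

    def test_majority_rule_for_larger_series(self):
        assert ch.default_min_support(4) == 4
        assert ch.default_min_support(6) == 3
        assert ch.default_min_support(7) == 4


class TestCallBTN:
    def test_fixture_case_series_all_positive(self, table1_genotypes):
        dn = [ch.detect_chimerism(table1_genotypes[i])
              for i in ("J54", "J111", "J161", "J181")]
        cancer = ch.build_cancer_genotype(dn)
        calls = [ch.call_btn(r, cancer) for r in dn]
        assert sum(c.positive for c in calls) == 4

    def test_non_chimeric_individual_is_negative(self):
        cancer = ch.CancerGenotype(
            alleles={"EF1a": [ch.SharedAllele("G", "A" * 30, 4)]}
        )
        res = ch.ChimerismResult("ctrl", extra_alleles={"EF1a": []})
        call = ch.call_btn(res, cancer)
        assert not call.positive
        assert call.annotation is None

    def test_novel_extras_annotated_as_possible_new_lineage(self):
        cancer = ch.CancerGenotype(
            alleles={"EF1a": [ch.SharedAllele("G", "A" * 30, 4)]}
        )
        res = ch.ChimerismResult(
            "new", extra_alleles={"EF1a": [ac.AlleleCall("z", "C" * 30, 0, 0.5, "common")]}
        )
        call = ch.call_btn(res, cancer)
        assert not call.positive
        assert call.annotation == "possible-new-lineage"


class TestMitoSex:
    def _cohort(self, n=60, seed=9):
        return sc.generate_cohort(
            sc.SimulationConfig(seed=seed, n_specimens=n, prevalence=0.05)
        )

    def test_f_only_mantle_is_female(self, panel):
        m_refs = [e.sequence for e in panel.entries
                  if e.lineage == "host_M" and e.locus == "16S"]
        f_refs = [e.sequence for e in panel.entries
                  if e.lineage == "host_F" and e.locus == "16S"]
        gt = ac.TissueGenotype(
            "x", "16S", "mantle",
            [ac.AlleleCall("f", f_refs[0], 0, 1.0, ac.COMMON)],
        )
        assert ch.mito_sex(gt, m_refs, f_refs) == "female"

    def test_f_plus_m_mantle_is_male(self, panel):
        m_refs = [e.sequence for e in panel.entries
                  if e.lineage == "host_M" and e.locus == "16S"]
        f_refs = [e.sequence for e in panel.entries
                  if e.lineage == "host_F" and e.locus == "16S"]
        gt = ac.TissueGenotype(
            "x", "16S", "mantle",
            [
                ac.AlleleCall("f", f_refs[0], 0, 0.5, ac.COMMON),
                ac.AlleleCall("m", m_refs[0], 0, 0.5, ac.COMMON),
            ],
        )
        assert ch.mito_sex(gt, m_refs, f_refs) == "male"

    def test_cohort_sexing_matches_truth(self, panel):
        cohort = self._cohort()
        m_refs = [e.sequence for e in panel.entries
                  if e.lineage == "host_M" and e.locus == "16S"]
        f_refs = [e.sequence for e in panel.entries
                  if e.lineage == "host_F" and e.locus == "16S"]
        for sp in cohort.specimens:
            inferred = ch.mito_sex(sp.tissues["mantle"]["16S"], m_refs, f_refs)
            assert inferred == sp.dui_sex_truth


class TestCohortProperties:
    def _truth_chimerism(self, cohort, sid):
        sp = next(s for s in cohort.specimens if s.id == sid)
        per = {
            locus: {
                "hemolymph": sp.tissues["hemolymph"][locus],
                "foot": sp.tissues["foot"][locus],
            }
            for locus in ("EF1a", "COI", "CR")
        }
        return ch.detect_chimerism(per)

    def test_clone_genotype_recovered_from_truth(self):
        cfg = sc.SimulationConfig(
            seed=21, n_specimens=30, n_clones=1,
            fixed_neoplastic_fractions=[0.25, 0.44, 0.8, 0.91],
        )
        cohort = sc.generate_cohort(cfg)
        infected = cohort.truth[cohort.truth.infected].id.tolist()
        dn = [self._truth_chimerism(cohort, i) for i in infected]
        cancer = ch.shared_cancer_alleles(dn, "EF1a")
        assert {a.sequence for a in cancer.alleles["EF1a"]} == set(
            cohort.clones[0].ef1a_alleles
        )

    def test_two_clone_structure_separates_mito_groups(self):
        # one nuclear genotype, two mito haplotype groups
        cfg = sc.SimulationConfig(
            seed=22, n_specimens=30, n_clones=2,
            fixed_neoplastic_fractions=[0.3, 0.5, 0.7, 0.9],
        )
        cohort = sc.generate_cohort(cfg)
        infected = cohort.truth[cohort.truth.infected].id.tolist()
        dn = [self._truth_chimerism(cohort, i) for i in infected]
        cancer = ch.build_cancer_genotype(dn)
        assert {a.sequence for a in cancer.alleles["EF1a"]} == set(
            cohort.clones[0].ef1a_alleles
        )
        groups = ch.mito_haplotype_groups(dn)
        assert len(groups["COI"]) == 2
        assert len(groups["CR"]) == 2
        # groups are consistent between the two mito loci
        assert sorted(map(tuple, groups["COI"].values())) == sorted(
            map(tuple, groups["CR"].values())
        )

    def test_uninfected_cohorts_yield_no_btn_positive(self):
        # zero false positives across seeds, with cloning noise included
        for seed in range(5):
            cfg = sc.SimulationConfig(seed=seed, n_specimens=8, prevalence=0.0)
            cohort = sc.generate_cohort(cfg)
            rng = np.random.default_rng(1000 + seed)
            cancer = ch.CancerGenotype(
                alleles={"EF1a": [
                    ch.SharedAllele("G", s, 4)
                    for s in sc.make_cancer_clones(cfg)[0].ef1a_alleles
                ]}
            )
            for sp in cohort.specimens:
                per = {}
                for locus in ("EF1a", "CR"):
                    cs_h = sc.simulate_cloning(
                        sp.tissues["hemolymph"][locus], 16, 0.15, rng
                    )
                    cs_f = sc.simulate_cloning(
                        sp.tissues["foot"][locus], 16, 0.15, rng,
                        avoid={s for _, s in cs_h.colonies},
                    )
                    per[locus] = {
                        "hemolymph": ac.call_alleles(cs_h, cross_reference=[cs_f]),
                        "foot": ac.call_alleles(cs_f, cross_reference=[cs_h]),
                    }
                res = ch.detect_chimerism(per)
                assert not ch.call_btn(res, cancer).positive

    def test_sensitivity_at_moderate_fraction(self):
        # BTN recall with 16-colony cloning at p = 0.25; also measure (not
        # assert) recall at p = 0.1
        recalls = {}
        for p in (0.25, 0.1):
            hits = 0
            n_rep = 200
            rng = np.random.default_rng(31)
            for rep in range(n_rep):
                cfg = sc.SimulationConfig(
                    seed=50_000 + rep, n_specimens=8, n_clones=1,
                    fixed_neoplastic_fractions=[p] * 4,
                )
                cohort = sc.generate_cohort(cfg)
                clone = cohort.clones[0]
                cancer = ch.CancerGenotype(
                    alleles={
                        "EF1a": [ch.SharedAllele("n", s, 4)
                                 for s in clone.ef1a_alleles],
                        "COI": [ch.SharedAllele("c", clone.mito_haplotypes[0]["coi"], 4)],
                        "CR": [ch.SharedAllele("r", clone.mito_haplotypes[0]["cr"], 4)],
                    }
                )
                sid = cohort.truth[cohort.truth.infected].id.iloc[0]
                sp = next(s for s in cohort.specimens if s.id == sid)
                per = {}
                seen = set()
                for locus in ("EF1a", "CR", "COI"):
                    cs_h = sc.simulate_cloning(
                        sp.tissues["hemolymph"][locus], 16, 0.15, rng, avoid=seen
                    )
                    seen |= {s for _, s in cs_h.colonies}
                    cs_f = sc.simulate_cloning(
                        sp.tissues["foot"][locus], 16, 0.15, rng, avoid=seen
                    )
                    seen |= {s for _, s in cs_f.colonies}
                    per[locus] = {
                        "hemolymph": ac.call_alleles(cs_h, cross_reference=[cs_f]),
                        "foot": ac.call_alleles(cs_f, cross_reference=[cs_h]),
                    }
                res = ch.detect_chimerism(per)
                hits += ch.call_btn(res, cancer).positive
            recalls[p] = hits / n_rep
        assert recalls[0.25] >= 0.95
        assert 0.0 <= recalls[0.1] <= 1.0  # reported, not asserted
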