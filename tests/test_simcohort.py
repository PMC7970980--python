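"""Synthetic cohort generator: sequence ops, DUI structure, measurement sims."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from btnscreen import simcohort as sc
from btnscreen._seqs import hamming, random_sequence
from btnscreen.allelecall import resolve_piggyback
from btnscreen.errors import AlignmentError, InputError, ParameterError


class TestMutateSequence:
    def test_zero_mutations_is_identity(self, rng):
        anc = "ACGT" * 10
        assert sc.mutate_sequence(anc, 0, rng) == anc

    def test_printed_coi_divergence(self, rng):
        anc = random_sequence(630, rng)
        mut = sc.mutate_sequence(anc, 6, rng)
        assert hamming(anc, mut) == 6
        assert round(100 * 6 / 630, 2) == 0.95

    @given(
        length=st.integers(10, 200),
        frac=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_distance_exactly_n(self, length, frac, seed):
        rng = np.random.default_rng(seed)
        anc = random_sequence(length, rng)
        n = int(frac * length)
        mut = sc.mutate_sequence(anc, n, rng)
        # independent position-by-position comparison
        assert sum(a != b for a, b in zip(anc, mut)) == n

    def test_too_many_substitutions_rejected(self, rng):
        with pytest.raises(ParameterError):
            sc.mutate_sequence("ACGT", 5, rng)

    def test_non_dna_rejected(self, rng):
        with pytest.raises(ParameterError):
            sc.mutate_sequence("ACGN", 1, rng)


class TestRecombinantCR:
    def test_full_replacement_returns_donor(self, rng):
        f, m = random_sequence(100, rng), random_sequence(100, rng)
        assert sc.make_recombinant_cr(f, m, (0, 100)) == m

    def test_empty_segment_returns_backbone(self, rng):
        f, m = random_sequence(100, rng), random_sequence(100, rng)
        assert sc.make_recombinant_cr(f, m, (40, 40)) == f

    def test_per_position_source(self, rng):
        f = random_sequence(622, rng)
        m = sc.mutate_sequence(f, 31, rng)  # ~5% divergent parents
        rec = sc.make_recombinant_cr(f, m, (200, 400))
        for i in range(622):
            expected = m[i] if 200 <= i < 400 else f[i]
            assert rec[i] == expected

    def test_unequal_lengths_rejected(self, rng):
        with pytest.raises(AlignmentError):
            sc.make_recombinant_cr("ACGT", "ACGTA", (0, 2))


class TestGenerateCohort:
    def test_zero_prevalence_carries_no_cancer_alleles(self):
        cfg = sc.SimulationConfig(seed=3, n_specimens=30, prevalence=0.0)
        cohort = sc.generate_cohort(cfg)
        assert not cohort.truth.infected.any()
        for sp in cohort.specimens:
            for loci in sp.tissues.values():
                for gt in loci.values():
                    assert all(not a.allele_id.startswith("cancer") for a in gt.alleles)

    def test_infected_count_is_floor_of_prevalence(self):
        cfg = sc.SimulationConfig(seed=1, n_specimens=226, prevalence=0.0442)
        cohort = sc.generate_cohort(cfg)
        assert int(cohort.truth.infected.sum()) == 9  # floor(9.99)

    def test_dui_invariant_large_cohort(self):
        # females never carry M-mtDNA anywhere; males only in the mantle
        cfg = sc.SimulationConfig(seed=7, n_specimens=1000, prevalence=0.05)
        cohort = sc.generate_cohort(cfg)
        for sp in cohort.specimens:
            for tissue, loci in sp.tissues.items():
                has_m = any(
                    a.allele_id == "m" for a in loci["16S"].retained()
                )
                if sp.dui_sex_truth == sc.FEMALE:
                    assert not has_m
                elif tissue != "mantle":
                    assert not has_m
        males = [sp for sp in cohort.specimens if sp.dui_sex_truth == sc.MALE]
        assert all(
            any(a.allele_id == "m" for a in sp.tissues["mantle"]["16S"].retained())
            for sp in males
        )

    def test_sexes_balanced(self):
        cfg = sc.SimulationConfig(seed=5, n_specimens=200, prevalence=0.0)
        cohort = sc.generate_cohort(cfg)
        assert (cohort.truth.sex == sc.FEMALE).sum() == 100

    def test_seed_determinism(self):
        cfg = dict(seed=11, n_specimens=40, prevalence=0.1)
        a = sc.generate_cohort(sc.SimulationConfig(**cfg))
        b = sc.generate_cohort(sc.SimulationConfig(**cfg))
        assert a.truth.equals(b.truth)
        for sa, sb in zip(a.specimens, b.specimens):
            for tissue in sc.TISSUES:
                for locus, ga in sa.tissues[tissue].items():
                    gb = sb.tissues[tissue][locus]
                    assert [(x.allele_id, x.sequence, x.frequency) for x in ga.alleles] \
                        == [(y.allele_id, y.sequence, y.frequency) for y in gb.alleles]


class TestInfect:
    @pytest.fixture
    def host(self):
        cfg = sc.SimulationConfig(seed=2, n_specimens=1, prevalence=0.0)
        return sc.generate_cohort(cfg)

    def test_p_zero_is_identity(self, host):
        sp = host.specimens[0]
        clone = sc.make_cancer_clones(host.config)[0]
        out = sc.infect(sp, clone, 0.0)
        for locus in ("EF1a", "COI", "CR"):
            assert out.tissues["hemolymph"][locus].freq_by_sequence() == \
                sp.tissues["hemolymph"][locus].freq_by_sequence()

    def test_mito_haplotype_frequency_equals_cell_fraction(self, host):
        sp = host.specimens[0]
        clone = sc.make_cancer_clones(host.config)[0]
        out = sc.infect(sp, clone, 0.91)
        coi = out.tissues["hemolymph"]["COI"].freq_by_sequence()
        assert coi[clone.mito_haplotypes[0]["coi"]] == pytest.approx(0.91)
        # foot untouched at default infiltration 0
        assert out.tissues["foot"]["COI"].freq_by_sequence() == \
            sp.tissues["foot"]["COI"].freq_by_sequence()

    def test_half_mixture_is_symmetric(self, host):
        sp = host.specimens[0]
        clone = sc.make_cancer_clones(host.config)[0]
        out = sc.infect(sp, clone, 0.5)
        coi = out.tissues["hemolymph"]["COI"].freq_by_sequence()
        assert sorted(coi.values()) == pytest.approx([0.5, 0.5])

    def test_mixture_mass_conserved(self, host):
        sp = host.specimens[0]
        clone = sc.make_cancer_clones(host.config)[0]
        for p in (0.12, 0.444, 0.98):
            out = sc.infect(sp, clone, p, foot_infiltration=0.1)
            for tissue in sc.TISSUES:
                for locus, gt in out.tissues[tissue].items():
                    assert sum(a.frequency for a in gt.retained()) == pytest.approx(1.0)


class TestSimulateCloning:
    def _single_allele_tissue(self, rng):
        cfg = sc.SimulationConfig(seed=4, n_specimens=1, prevalence=0.0)
        return sc.generate_cohort(cfg).specimens[0].tissues["hemolymph"]["COI"]

    def test_no_artifacts_single_allele(self, rng):
        tissue = self._single_allele_tissue(rng)
        cs = sc.simulate_cloning(tissue, 16, artifact_rate=0.0, rng=rng)
        assert len({seq for _, seq in cs.colonies}) == 1

    def test_artifacts_are_unique_singletons(self, rng):
        tissue = self._single_allele_tissue(rng)
        cs = sc.simulate_cloning(tissue, 16, artifact_rate=0.5, rng=rng)
        true_seq = tissue.retained()[0].sequence
        artifacts = [seq for _, seq in cs.colonies if seq != true_seq]
        assert artifacts  # at rate 0.5 over 16 colonies, some artifacts
        assert len(artifacts) == len(set(artifacts))

    def test_law_of_large_numbers(self, rng):
        from btnscreen.allelecall import AlleleCall, TissueGenotype, COMMON

        gt = TissueGenotype(
            individual_id="x", locus="EF1a", tissue="hemolymph",
            alleles=[
                AlleleCall("A", "ACGT" * 10, 0, 0.75, COMMON),
                AlleleCall("B", "TGCA" * 10, 0, 0.25, COMMON),
            ],
        )
        cs = sc.simulate_cloning(gt, 10_000, artifact_rate=0.0, rng=rng)
        freq_a = sum(seq == "ACGT" * 10 for _, seq in cs.colonies) / 10_000
        assert freq_a == pytest.approx(0.75, abs=0.02)

    def test_empty_genotype_rejected(self, rng):
        from btnscreen.allelecall import TissueGenotype

        gt = TissueGenotype("x", "EF1a", "hemolymph", alleles=[])
        with pytest.raises(InputError):
            sc.simulate_cloning(gt, 16, rng=rng)


class TestSimulateFlowEvents:
    def test_healthy_single_dominant_peak(self, rng):
        ev = sc.simulate_flow_events(0.0, 4.0, sc.FlowParams(), rng)
        mu = sc.FlowParams().diploid_mean
        near_diploid = np.abs(ev.intensities - mu) < 0.2 * mu
        assert near_diploid.mean() > 0.95

    def test_aneuploid_component_mean(self, rng):
        params = sc.FlowParams(n_events=50_000)
        ev = sc.simulate_flow_events(0.8, 5.2, params, rng)
        mu = params.diploid_mean
        aneu = ev.intensities[np.abs(ev.intensities - 2.6 * mu) < 3 * 0.05 * 2.6 * mu]
        assert aneu.mean() == pytest.approx(2.6 * mu, rel=0.01)

    def test_gate_counts_match_weights(self, rng):
        params = sc.FlowParams(n_events=10_000)
        p = 0.444
        ev = sc.simulate_flow_events(p, 5.2, params, rng)
        mu = params.diploid_mean
        tol = 3 / np.sqrt(params.n_events)
        for center, weight in [(mu, (1 - p) * 0.98), (2.6 * mu, p)]:
            gate = np.abs(ev.intensities - center) < 3 * 0.05 * center
            assert gate.mean() == pytest.approx(weight, abs=3 * tol)

    def test_invalid_ploidy_rejected(self, rng):
        with pytest.raises(ParameterError):
            sc.simulate_flow_events(0.5, 9.0, rng=rng)


class TestSimulateChromatogram:
    def test_identical_templates_have_no_mixed_sites(self, rng):
        seq = random_sequence(100, rng)
        assert all(not s.mixed for s in sc.simulate_chromatogram(seq, seq, 0.2))

    def test_mixed_site_count_equals_divergence(self, rng):
        a = random_sequence(630, rng)
        b = sc.mutate_sequence(a, 6, rng)
        calls = sc.simulate_chromatogram(a, b, 0.2)
        assert sum(s.mixed for s in calls) == 6

    def test_round_trip_through_piggyback_resolution(self, rng):
        host = random_sequence(630, rng)
        cancer = sc.mutate_sequence(host, 6, rng)
        calls = sc.simulate_chromatogram(cancer, host, 0.2)
        res = resolve_piggyback(calls, foot_allele=host)
        assert res.dominant == cancer
        assert res.minority == host
        assert res.attribution["dominant"] == "cancer-candidate"
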