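"""Synthetic mussel cohorts with the genetic and cytometric structure of a
BTN2-infected *Mytilus trossulus* population.

The generator emulates the latent structure the downstream analysis assumes:

* host nuclear diversity at EF1α and a single F-mtDNA haplotype per healthy
  somatic tissue (hosts are homoplasmic);
* doubly uniparental inheritance (DUI): females carry F-mtDNA only; males
  additionally carry an M-mtDNA 16S haplotype in the mantle (gonad) but not
  in somatic hemolymph or foot;
* a diploid cancer clone marked by two divergent EF1α alleles (21
  substitutions apart by default) shared by every infected specimen, and one
  or two cancer mitochondrial haplotypes whose control regions are
  recombinant — an M-derived segment inserted into an F backbone;
* hemolymph of infected specimens as a host/cancer cell mixture with
  neoplastic fraction p, the foot essentially uninvaded;
* molecular-cloning noise (multinomial colony sampling plus unique PCR
  artifact sequences) and 1-D DNA-fluorescence event mixtures.

Every latent variable is recorded in a truth table so downstream stages can
be scored against it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable

import numpy as np
import pandas as pd

from ._seqs import (
    hamming,
    is_strict_dna,
    random_sequence,
    stable_rng,
    substitute,
)
from .allelecall import AlleleCall, CloneSet, COMMON, SiteCall, TissueGenotype
from .errors import AlignmentError, InputError, ParameterError
from .flowploidy import FlowEventSet

FEMALE = "female"
MALE = "male"

TISSUES = ("hemolymph", "foot", "mantle")

DEFAULT_LOCUS_LENGTHS = {"EF1a": 450, "COI": 630, "CR": 622, "16S": 500}


# ---------------------------------------------------------------------------
# Elementary sequence operations


def mutate_sequence(ancestor: str, n_subs: int, rng: np.random.Generator) -> str:
    """Introduce exactly ``n_subs`` substitutions at distinct positions.

    The result is at Hamming distance exactly ``n_subs`` from ``ancestor``
    (each chosen position receives a different base).
    """
    if not is_strict_dna(ancestor):
        raise ParameterError("ancestor must contain only A/C/G/T")
    if n_subs < 0 or n_subs > len(ancestor):
        raise ParameterError(
            f"n_subs={n_subs} outside [0, {len(ancestor)}]"
        )
    if n_subs == 0:
        return ancestor
    positions = rng.choice(len(ancestor), size=n_subs, replace=False)
    return substitute(ancestor, positions, rng)


def make_recombinant_cr(
    f_backbone: str, m_donor: str, breakpoints: tuple[int, int]
) -> str:
    """Insert the M-mtDNA segment [b1, b2) of ``m_donor`` into ``f_backbone``.

    The result equals the F backbone outside the half-open interval and the
    M donor inside it — the mosaic ("masculinized") control-region structure
    of BTN2 mitogenomes.
    """
    if len(f_backbone) != len(m_donor):
        raise AlignmentError("parent sequences differ in length")
    b1, b2 = breakpoints
    if not 0 <= b1 <= b2 <= len(f_backbone):
        raise ParameterError(f"invalid breakpoints {breakpoints}")
    return f_backbone[:b1] + m_donor[b1:b2] + f_backbone[b2:]


# ---------------------------------------------------------------------------
# Configuration and cohort types


@dataclass
class FlowParams:
    """Flow-cytometry simulation settings."""

    n_events: int = 10_000
    cv: float = 0.05
    tetraploid_fraction_healthy: float = 0.02
    diploid_mean: float = 50.0

    def __post_init__(self):
        if self.n_events < 1:
            raise ParameterError("n_events must be >= 1")
        if not 0 < self.cv < 1:
            raise ParameterError("cv must be in (0, 1)")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the screening study the pipeline models: 226 specimens
    screened with ~4.4 % disease prevalence, neoplastic fractions between
    12 % and 98 %, relative ploidies 3.7–5.2 n, 16-colony cloning
    experiments, 10,000 flow events per specimen, and a cancer clone whose
    two EF1α alleles differ by 21 substitutions.
    """

    seed: int = 0
    n_specimens: int = 226
    prevalence: float = 10 / 226
    locus_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LOCUS_LENGTHS)
    )
    host_divergence: float = 4.0
    cancer_nuclear_divergence: int = 21
    cr_breakpoints: tuple[int, int] = (200, 400)
    neoplastic_fraction_range: tuple[float, float] = (0.12, 0.98)
    relative_ploidy_range: tuple[float, float] = (3.7, 5.2)
    foot_infiltration: float = 0.0
    n_colonies: int = 16
    artifact_rate: float = 0.15
    n_clones: int = 2
    flow_params: FlowParams = field(default_factory=FlowParams)
    fixed_neoplastic_fractions: list[float] | None = None
    site: str = "SIM"

    def __post_init__(self):
        if isinstance(self.flow_params, dict):
            self.flow_params = FlowParams(**self.flow_params)
        for name, val in [
            ("prevalence", self.prevalence),
            ("foot_infiltration", self.foot_infiltration),
            ("artifact_rate", self.artifact_rate),
        ]:
            if not 0 <= val <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")
        lo, hi = self.neoplastic_fraction_range
        if not 0 <= lo <= hi <= 1:
            raise ParameterError("neoplastic_fraction_range must be within [0, 1]")
        b1, b2 = self.cr_breakpoints
        if not 0 <= b1 < b2 <= self.locus_lengths["CR"]:
            raise ParameterError("cr_breakpoints must satisfy 0 <= b1 < b2 <= CR length")
        if self.n_specimens < 1 or self.n_colonies < 1:
            raise ParameterError("counts must be positive")
        if self.n_clones not in (1, 2):
            raise ParameterError("n_clones must be 1 or 2")


@dataclass
class CancerClone:
    """A transmissible cancer genotype."""

    id: str
    ef1a_alleles: tuple[str, str]
    mito_haplotypes: list[dict[str, str]]  # each {"coi": ..., "cr": ...}
    heteroplasmic: bool = False

    def __post_init__(self):
        if len(self.ef1a_alleles) != 2:
            raise ParameterError("a diploid clone carries exactly 2 nuclear alleles")
        if not self.mito_haplotypes:
            raise ParameterError("a clone carries at least one mito haplotype")


@dataclass
class Specimen:
    id: str
    site: str
    sex: str
    dui_sex_truth: str
    tissues: dict[str, dict[str, TissueGenotype]]  # tissue -> locus -> genotype
    flow_truth: dict[str, float]
    infected: bool = False
    clone_id: str | None = None

    def genotype(self, tissue: str, locus: str) -> TissueGenotype:
        return self.tissues[tissue][locus]


@dataclass
class Cohort:
    specimens: list[Specimen]
    clones: list[CancerClone]
    truth: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Fixed ancestral and reference sequences
#
# Ancestors are pinned by a label-keyed RNG so that the bundled synthetic
# reference panel stays valid for every simulated cohort regardless of seed.


def ancestral_sequence(locus: str, length: int | None = None) -> str:
    length = length or DEFAULT_LOCUS_LENGTHS[locus]
    seq = random_sequence(length, stable_rng(f"ancestor/{locus}"))
    if locus == "EF1a" and length >= 320:
        # embed a 9 bp poly-A tract (a known slippage-prone homopolymer)
        seq = seq[:299] + "T" + "A" * 9 + "G" + seq[310:]
    return seq


def m_type_sequence(locus: str, length: int | None = None) -> str:
    """M-mtDNA counterpart of the F-type ancestor (~8 % divergent)."""
    anc = ancestral_sequence(locus, length)
    n = max(1, round(0.08 * len(anc)))
    return mutate_sequence(anc, n, stable_rng(f"m-ancestor/{locus}"))


@dataclass(frozen=True)
class PanelEntry:
    lineage: str
    locus: str
    allele_name: str
    sequence: str


def synthetic_reference_panel(
    cr_breakpoints: tuple[int, int] = (200, 400)
) -> list[PanelEntry]:
    """Deterministic synthetic stand-in for the BTN reference allele panel.

    Real BTN1/BTN2 reference sequences live in GenBank (see the bundled
    accession manifest); this panel reproduces their *structure* — a BTN2
    nuclear pair 21 substitutions apart, a BTN2 COI reference, recombinant
    BTN2 control regions, a divergent BTN1 branch, and host F/M references —
    on synthetic ancestors, so the pipeline is fully testable offline.
    """
    ef = ancestral_sequence("EF1a")
    coi_f = ancestral_sequence("COI")
    cr_f = ancestral_sequence("CR")
    cr_m = m_type_sequence("CR")
    s16_f = ancestral_sequence("16S")
    s16_m = m_type_sequence("16S")

    g = mutate_sequence(ef, 12, stable_rng("panel/EF1a/G"))
    h = mutate_sequence(g, 21, stable_rng("panel/EF1a/H"))
    btn1_ef = mutate_sequence(ef, 30, stable_rng("panel/EF1a/BTN1"))

    coi_b = mutate_sequence(coi_f, 5, stable_rng("panel/COI/B"))
    btn1_coi = mutate_sequence(coi_f, 25, stable_rng("panel/COI/BTN1"))

    cr_d = make_recombinant_cr(
        mutate_sequence(cr_f, 3, stable_rng("panel/CR/D-backbone")),
        cr_m,
        cr_breakpoints,
    )
    cr_c = make_recombinant_cr(
        mutate_sequence(cr_f, 4, stable_rng("panel/CR/C-backbone")),
        mutate_sequence(cr_m, 4, stable_rng("panel/CR/C-donor")),
        cr_breakpoints,
    )

    return [
        PanelEntry("host_F", "EF1a", "anc", ef),
        PanelEntry("host_F", "COI", "F", coi_f),
        PanelEntry("host_F", "CR", "F", cr_f),
        PanelEntry("host_F", "16S", "F", s16_f),
        PanelEntry("host_M", "CR", "M", cr_m),
        PanelEntry("host_M", "16S", "M", s16_m),
        PanelEntry("BTN2", "EF1a", "G", g),
        PanelEntry("BTN2", "EF1a", "H", h),
        PanelEntry("BTN2", "COI", "B", coi_b),
        PanelEntry("BTN2", "CR", "D", cr_d),
        PanelEntry("BTN2", "CR", "C", cr_c),
        PanelEntry("BTN1", "EF1a", "A1", btn1_ef),
        PanelEntry("BTN1", "COI", "A", btn1_coi),
    ]


# ---------------------------------------------------------------------------
# Cohort generation


def _genotype(individual_id, locus, tissue, weighted: list[tuple[str, str, float]]):
    """Truth genotype from (allele_id, sequence, frequency) triples."""
    alleles = [
        AlleleCall(allele_id=a, sequence=s, colony_count=0, frequency=f, status=COMMON)
        for a, s, f in weighted
        if f > 0
    ]
    return TissueGenotype(
        individual_id=individual_id,
        locus=locus,
        tissue=tissue,
        alleles=alleles,
        heteroplasmic=(locus in ("COI", "CR", "16S") and len(alleles) > 1),
    )


def _poisson_mutant(ancestor: str, lam: float, rng) -> str:
    n = min(int(rng.poisson(lam)), len(ancestor))
    return mutate_sequence(ancestor, n, rng)


def make_cancer_clones(config: SimulationConfig) -> list[CancerClone]:
    """Build the cancer clone(s) from the synthetic reference panel.

    Both clones share the nuclear EF1α pair (lineage marker); they differ in
    their mitochondrial haplotype — a COI allele a few substitutions from
    the panel reference and a control region built as a fresh F/M
    recombinant with the configured breakpoints.
    """
    panel = {(e.lineage, e.locus, e.allele_name): e.sequence
             for e in synthetic_reference_panel(config.cr_breakpoints)}
    g = panel[("BTN2", "EF1a", "G")]
    h0 = panel[("BTN2", "EF1a", "H")]
    # enforce the configured nuclear divergence exactly
    rng = stable_rng("clone/nuclear", config.cancer_nuclear_divergence)
    h = mutate_sequence(g, config.cancer_nuclear_divergence, rng) \
        if config.cancer_nuclear_divergence != hamming(g, h0) else h0
    coi_b = panel[("BTN2", "COI", "B")]
    cr_f = panel[("host_F", "CR", "F")]
    cr_m = panel[("host_M", "CR", "M")]

    clones = []
    for k, (coi_subs, tag) in enumerate([(6, "1"), (8, "2")][: config.n_clones]):
        coi = mutate_sequence(coi_b, coi_subs, stable_rng(f"clone/coi/{tag}"))
        cr = make_recombinant_cr(
            mutate_sequence(cr_f, 3 + k, stable_rng(f"clone/cr-backbone/{tag}")),
            mutate_sequence(cr_m, 2 + k, stable_rng(f"clone/cr-donor/{tag}")),
            config.cr_breakpoints,
        )
        clones.append(
            CancerClone(
                id=f"BTN2-SIM{tag}",
                ef1a_alleles=(g, h),
                mito_haplotypes=[{"coi": coi, "cr": cr}],
            )
        )
    return clones


def _host_specimen(idx: int, config: SimulationConfig, sex: str, rng) -> Specimen:
    sid = f"{config.site}{idx + 1:03d}"
    lam = config.host_divergence / 2.0
    ef_anc = ancestral_sequence("EF1a", config.locus_lengths["EF1a"])
    ef1 = _poisson_mutant(ef_anc, lam, rng)
    ef2 = _poisson_mutant(ef_anc, lam, rng)
    f_haps = {
        locus: _poisson_mutant(
            ancestral_sequence(locus, config.locus_lengths[locus]), lam, rng
        )
        for locus in ("COI", "CR", "16S")
    }
    tissues: dict[str, dict[str, TissueGenotype]] = {}
    for tissue in TISSUES:
        loci: dict[str, TissueGenotype] = {}
        if ef1 == ef2:
            ef_weights = [("h1", ef1, 1.0)]
        else:
            ef_weights = [("h1", ef1, 0.5), ("h2", ef2, 0.5)]
        loci["EF1a"] = _genotype(sid, "EF1a", tissue, ef_weights)
        for locus in ("COI", "CR"):
            loci[locus] = _genotype(sid, locus, tissue, [("f", f_haps[locus], 1.0)])
        if tissue == "mantle" and sex == MALE:
            m16 = _poisson_mutant(
                m_type_sequence("16S", config.locus_lengths["16S"]), lam, rng
            )
            loci["16S"] = _genotype(
                sid, "16S", tissue, [("f", f_haps["16S"], 0.5), ("m", m16, 0.5)]
            )
        else:
            loci["16S"] = _genotype(sid, "16S", tissue, [("f", f_haps["16S"], 1.0)])
        tissues[tissue] = loci
    return Specimen(
        id=sid,
        site=config.site,
        sex=sex,
        dui_sex_truth=sex,
        tissues=tissues,
        flow_truth={"neoplastic_fraction": 0.0, "relative_ploidy": float("nan")},
    )


def infect(
    specimen: Specimen,
    clone: CancerClone,
    p: float,
    foot_infiltration: float = 0.0,
) -> Specimen:
    """Mix cancer alleles into a specimen's tissues at cell fraction ``p``.

    Neoplastic cells are modeled at one genome equivalent per cell, so
    allele weight equals cell fraction: hemolymph receives the cancer
    alleles at total weight p (host scaled to 1 - p); the foot mixes at
    ``foot_infiltration`` (0 by default — no infiltration); the mantle is
    untouched.  Each nuclear allele of the diploid clone gets p/2; each of
    the clone's mito haplotypes gets an equal share of p.
    """
    if not 0 <= p <= 1:
        raise ParameterError("neoplastic fraction must be in [0, 1]")
    new_tissues = {t: dict(loci) for t, loci in specimen.tissues.items()}
    for tissue, weight in (("hemolymph", p), ("foot", foot_infiltration)):
        if weight <= 0:
            continue
        for locus in ("EF1a", "COI", "CR"):
            host = specimen.tissues[tissue][locus]
            mixed: list[tuple[str, str, float]] = []
            if locus == "EF1a":
                for j, seq in enumerate(clone.ef1a_alleles):
                    mixed.append((f"cancer_n{j + 1}", seq, weight / 2))
            else:
                share = weight / len(clone.mito_haplotypes)
                key = "coi" if locus == "COI" else "cr"
                for j, hap in enumerate(clone.mito_haplotypes):
                    mixed.append((f"cancer_m{j + 1}", hap[key], share))
            # fold identical sequences together (host may coincide by chance)
            acc: dict[str, float] = {}
            names: dict[str, str] = {}
            for a in host.retained():
                acc[a.sequence] = acc.get(a.sequence, 0.0) + a.frequency * (1 - weight)
                names.setdefault(a.sequence, a.allele_id)
            for name, seq, w in mixed:
                acc[seq] = acc.get(seq, 0.0) + w
                names.setdefault(seq, name)
            new_tissues[tissue][locus] = _genotype(
                specimen.id, locus, tissue,
                [(names[s], s, f) for s, f in acc.items()],
            )
    out = dc_replace(specimen, tissues=new_tissues)
    out.infected = p > 0
    out.clone_id = clone.id if p > 0 else None
    out.flow_truth = dict(specimen.flow_truth)
    out.flow_truth["neoplastic_fraction"] = p
    return out


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full synthetic cohort.

    ``floor(prevalence * n_specimens)`` specimens are infected (unless
    ``fixed_neoplastic_fractions`` pins the infected count and their
    neoplastic fractions); sexes are assigned 1:1; every latent variable is
    recorded in the truth table.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_specimens
    sexes = np.array([FEMALE, MALE] * ((n + 1) // 2))[:n]
    rng.shuffle(sexes)

    if config.fixed_neoplastic_fractions is not None:
        fractions = list(config.fixed_neoplastic_fractions)
        n_infected = len(fractions)
        if n_infected > n:
            raise ParameterError("more fixed fractions than specimens")
    else:
        n_infected = math.floor(config.prevalence * n)
        lo, hi = config.neoplastic_fraction_range
        fractions = list(rng.uniform(lo, hi, size=n_infected))

    infected_idx = set(rng.choice(n, size=n_infected, replace=False).tolist())
    clones = make_cancer_clones(config) if n_infected else []

    specimens: list[Specimen] = []
    truth_rows = []
    j = 0
    for i in range(n):
        sp = _host_specimen(i, config, str(sexes[i]), rng)
        if i in infected_idx:
            clone = clones[j % len(clones)]
            p = fractions[j]
            sp = infect(sp, clone, p, config.foot_infiltration)
            rp_lo, rp_hi = config.relative_ploidy_range
            sp.flow_truth["relative_ploidy"] = float(rng.uniform(rp_lo, rp_hi))
            j += 1
        specimens.append(sp)
        truth_rows.append(
            {
                "id": sp.id,
                "site": sp.site,
                "sex": sp.sex,
                "infected": sp.infected,
                "clone_id": sp.clone_id if sp.clone_id else ".",
                "neoplastic_fraction": sp.flow_truth["neoplastic_fraction"],
                "relative_ploidy": sp.flow_truth["relative_ploidy"],
            }
        )
    truth = pd.DataFrame(truth_rows)
    return Cohort(specimens=specimens, clones=clones, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Measurement simulators


def simulate_cloning(
    tissue: TissueGenotype,
    n_colonies: int = 16,
    artifact_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    avoid: Iterable[str] = (),
) -> CloneSet:
    """Draw a molecular-cloning colony set from a tissue genotype.

    Colonies are drawn multinomially from the allele frequencies; each
    colony independently becomes a PCR/cloning artifact with probability
    ``artifact_rate``, replacing its sequence with a 1–2 substitution mutant
    guaranteed unique within the experiment (and distinct from every real
    allele and every sequence in ``avoid``), so artifacts are always
    single-colony singletons.
    """
    if rng is None:
        rng = np.random.default_rng()
    alleles = tissue.retained()
    if not alleles:
        raise InputError("empty genotype")
    freqs = np.array([a.frequency for a in alleles], dtype=float)
    total = freqs.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise InputError(f"allele frequencies sum to {total}, expected 1")
    freqs = freqs / total
    picks = rng.choice(len(alleles), size=n_colonies, p=freqs)
    forbidden = {a.sequence for a in alleles} | set(avoid)
    colonies: list[tuple[str, str]] = []
    for c, k in enumerate(picks):
        seq = alleles[k].sequence
        if rng.random() < artifact_rate:
            while True:
                mutant = mutate_sequence(seq, int(rng.integers(1, 3)), rng)
                if mutant not in forbidden:
                    break
            forbidden.add(mutant)
            seq = mutant
        colonies.append((f"c{c + 1:02d}", seq))
    return CloneSet(
        individual_id=tissue.individual_id,
        locus=tissue.locus,
        tissue=tissue.tissue,
        colonies=colonies,
    )


def simulate_flow_events(
    p_aneu: float,
    relative_ploidy: float,
    flow_params: FlowParams | None = None,
    rng: np.random.Generator | None = None,
    specimen_id: str = "sim",
) -> FlowEventSet:
    """Simulate a 1-D DNA-fluorescence event list.

    Events are a mixture of normal components: diploid at mean μ,
    tetraploid at 2 μ (the healthy proliferating admixture), and — with
    weight ``p_aneu`` — an aneuploid component at (relative_ploidy / 2) μ.
    All components share the configured coefficient of variation; negative
    draws are truncated to zero.
    """
    if flow_params is None:
        flow_params = FlowParams()
    if not 0 <= p_aneu <= 1:
        raise ParameterError("p_aneu must be in [0, 1]")
    if p_aneu > 0 and not 1.0 < relative_ploidy <= 8.0:
        raise ParameterError("relative_ploidy must be in (1, 8]")
    if rng is None:
        rng = np.random.default_rng()
    mu = flow_params.diploid_mean
    w_tetra = flow_params.tetraploid_fraction_healthy * (1.0 - p_aneu)
    w_dip = 1.0 - p_aneu - w_tetra
    means = np.array([mu, 2.0 * mu, (relative_ploidy / 2.0) * mu if p_aneu else mu])
    weights = np.array([w_dip, w_tetra, p_aneu])
    comp = rng.choice(3, size=flow_params.n_events, p=weights / weights.sum())
    intensities = rng.normal(means[comp], flow_params.cv * means[comp])
    np.clip(intensities, 0.0, None, out=intensities)
    return FlowEventSet(specimen_id=specimen_id, intensities=intensities)


def simulate_chromatogram(
    major: str, minor: str, ratio: float
) -> list[SiteCall]:
    """Per-site base calls for a two-template Sanger read.

    Where the templates agree there is a single call; where they differ the
    dominant template's base is the major call and the minority template's
    base appears as an overlapping minor peak with relative height
    ``ratio`` (< 0.5 — piggyback peaks).
    """
    if len(major) != len(minor):
        raise AlignmentError("template sequences differ in length")
    if not 0 < ratio < 0.5:
        raise ParameterError("minor/major ratio must be in (0, 0.5)")
    calls = []
    for a, b in zip(major, minor):
        if a == b:
            calls.append(SiteCall(major=a))
        else:
            calls.append(SiteCall(major=a, minor=b, ratio=ratio))
    return calls
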