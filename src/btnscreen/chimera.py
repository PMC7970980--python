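"""Genetic chimerism detection, cancer-genotype inference and BTN calling.

A transmissible cancer announces itself twice: an infected individual is a
genetic chimera (its hemolymph is dominated by alleles its own foot tissue
lacks or carries at lower frequency), and the "extra" hemolymph alleles are
identical across unrelated diseased individuals (the clonal genotype).  A
BTN call requires both kinds of evidence.  Mitochondrial sexing exploits
doubly uniparental inheritance: males carry an M-mtDNA 16S haplotype in the
mantle, females do not.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .allelecall import AlleleCall, TissueGenotype
from .errors import ConfigurationError, InputError
from .lineage import p_distance


@dataclass
class ChimerismResult:
    """Hemolymph-vs-foot comparison for one individual."""

    individual_id: str
    extra_alleles: dict[str, list[AlleleCall]] = field(default_factory=dict)
    host_alleles: dict[str, list[AlleleCall]] = field(default_factory=dict)

    @property
    def chimeric(self) -> bool:
        return any(self.extra_alleles.values())

    def extra_sequences(self, locus: str | None = None) -> set[str]:
        loci = [locus] if locus else list(self.extra_alleles)
        return {
            a.sequence for lc in loci for a in self.extra_alleles.get(lc, [])
        }


@dataclass(frozen=True)
class SharedAllele:
    name: str
    sequence: str
    support: int


@dataclass
class CancerGenotype:
    """Alleles shared across diseased individuals' hemolymph enrichments."""

    alleles: dict[str, list[SharedAllele]] = field(default_factory=dict)

    def sequences(self, locus: str | None = None) -> set[str]:
        loci = [locus] if locus else list(self.alleles)
        return {a.sequence for lc in loci for a in self.alleles.get(lc, [])}

    @property
    def empty(self) -> bool:
        return not any(self.alleles.values())

    def nuclear_violations(self) -> list[str]:
        """Loci where a diploid clone's expected <= 2 alleles is exceeded."""
        return [
            locus
            for locus, shared in self.alleles.items()
            if locus == "EF1a" and len(shared) > 2
        ]


@dataclass
class BTNCall:
    individual_id: str
    positive: bool
    evidence: dict
    annotation: str | None = None


def extra_alleles(
    hemolymph: TissueGenotype,
    foot: TissueGenotype,
    margin: float = 0.0,
) -> list[AlleleCall]:
    """Alleles strictly more frequent in hemolymph than in foot.

    An allele absent from the foot counts as frequency 0 there.  The
    default margin 0 means strict inequality; a positive margin absorbs
    colony-sampling noise at the cost of sensitivity.
    """
    if hemolymph is None or foot is None:
        raise InputError("both hemolymph and foot genotypes are required")
    if (hemolymph.individual_id, hemolymph.locus) != (foot.individual_id, foot.locus):
        raise InputError("tissues must come from the same individual and locus")
    foot_freq = foot.freq_by_sequence()
    return [
        a
        for a in hemolymph.retained()
        if a.frequency - foot_freq.get(a.sequence, 0.0) > margin
    ]


def detect_chimerism(
    genotypes: dict[str, dict[str, TissueGenotype]],
    margin: float = 0.0,
) -> ChimerismResult:
    """Chimerism across all loci with both hemolymph and foot genotypes.

    ``genotypes`` maps locus -> tissue -> genotype for one individual.
    Host alleles are the complement: the foot-dominant set.
    """
    individual_id = None
    extras: dict[str, list[AlleleCall]] = {}
    hosts: dict[str, list[AlleleCall]] = {}
    for locus, tissues in genotypes.items():
        hemo = tissues.get("hemolymph")
        foot = tissues.get("foot")
        if hemo is None or foot is None:
            continue
        individual_id = hemo.individual_id
        ex = extra_alleles(hemo, foot, margin=margin)
        extras[locus] = ex
        ex_seqs = {a.sequence for a in ex}
        hosts[locus] = [a for a in foot.retained() if a.sequence not in ex_seqs]
    if individual_id is None:
        raise InputError("no locus has both hemolymph and foot genotypes")
    return ChimerismResult(
        individual_id=individual_id, extra_alleles=extras, host_alleles=hosts
    )


def default_min_support(n_individuals: int) -> int:
    """All individuals for small case series; ceil(N/2) from N = 6 up."""
    if n_individuals >= 6:
        return math.ceil(n_individuals / 2)
    return n_individuals


def shared_cancer_alleles(
    dn_results: list[ChimerismResult],
    locus: str,
    min_support: int | None = None,
) -> CancerGenotype:
    """Extra alleles recurring (identical sequence) across diseased individuals.

    The clonal genotype is what every diseased individual's hemolymph is
    enriched for; ``min_support`` defaults to all individuals (relaxed to a
    majority rule for larger case series).
    """
    if len(dn_results) < 2:
        raise InputError("need at least two diseased individuals")
    if min_support is None:
        min_support = default_min_support(len(dn_results))
    support: dict[str, int] = {}
    names: dict[str, str] = {}
    for res in dn_results:
        for a in res.extra_alleles.get(locus, []):
            support[a.sequence] = support.get(a.sequence, 0) + 1
            names.setdefault(a.sequence, a.allele_id)
    shared = [
        SharedAllele(name=names[s], sequence=s, support=c)
        for s, c in support.items()
        if c >= min_support
    ]
    shared.sort(key=lambda a: (-a.support, a.name))
    if not shared:
        warnings.warn(f"no shared cancer allele at {locus}", stacklevel=2)
    return CancerGenotype(alleles={locus: shared})


def build_cancer_genotype(
    dn_results: list[ChimerismResult],
    loci: list[str] | None = None,
    min_support: int | None = None,
) -> CancerGenotype:
    """Shared cancer genotype over several loci (evidence pooled, reported
    per locus)."""
    if loci is None:
        loci = sorted({lc for r in dn_results for lc in r.extra_alleles})
    combined = CancerGenotype()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for locus in loci:
            combined.alleles[locus] = shared_cancer_alleles(
                dn_results, locus, min_support=min_support
            ).alleles[locus]
    if combined.empty:
        warnings.warn("no shared cancer allele at any locus", stacklevel=2)
    return combined


def call_btn(
    individual: ChimerismResult,
    cancer: CancerGenotype,
    match_min: int = 1,
) -> BTNCall:
    """Two-evidence BTN call: chimerism plus identity of extra alleles.

    Positive iff the individual is chimeric AND its extra alleles intersect
    the shared cancer genotype at >= ``match_min`` loci.  A chimeric
    individual with only novel extras is negative but annotated as a
    possible new lineage.
    """
    if cancer.empty:
        raise InputError("cancer genotype is empty")
    matched_loci = 0
    for locus, shared in cancer.alleles.items():
        cancer_seqs = {a.sequence for a in shared}
        if cancer_seqs & individual.extra_sequences(locus):
            matched_loci += 1
    positive = individual.chimeric and matched_loci >= match_min
    annotation = None
    if individual.chimeric and matched_loci < match_min:
        annotation = "possible-new-lineage"
    return BTNCall(
        individual_id=individual.individual_id,
        positive=positive,
        evidence={
            "chimeric": individual.chimeric,
            "shared_alleles_matched": matched_loci,
        },
        annotation=annotation,
    )


def mito_haplotype_groups(
    dn_results: list[ChimerismResult],
    loci: tuple[str, ...] = ("COI", "CR"),
) -> dict[str, dict[str, list[str]]]:
    """Group diseased individuals by their mitochondrial extra alleles.

    Returns locus -> allele name -> sorted individual ids; two groups at a
    mito locus with a single shared nuclear genotype is the signature of a
    lineage carrying two mitochondrial haplotypes across the case series.
    """
    out: dict[str, dict[str, list[str]]] = {}
    for locus in loci:
        by_seq: dict[str, list[str]] = {}
        names: dict[str, str] = {}
        for res in dn_results:
            for a in res.extra_alleles.get(locus, []):
                by_seq.setdefault(a.sequence, []).append(res.individual_id)
                names.setdefault(a.sequence, a.allele_id)
        groups: dict[str, list[str]] = {}
        for seq, members in by_seq.items():
            key = names[seq]
            while key in groups:  # same display name, different haplotype
                key += "*"
            groups[key] = sorted(set(members))
        out[locus] = groups
    return out


def mito_sex(
    mantle_genotype: TissueGenotype,
    m_references: list[str],
    f_references: list[str] | None = None,
    max_m_distance: float | None = None,
) -> str:
    """Mitochondrial sexing from the mantle 16S genotype.

    Male iff any mantle allele is attributable to M-mtDNA: within
    ``max_m_distance`` (p-distance) of an M reference when a threshold is
    given, otherwise by nearest-reference classification against the
    combined F/M reference sets.
    """
    alleles = mantle_genotype.retained()
    if not alleles:
        raise InputError("empty mantle genotype")
    if not m_references:
        raise ConfigurationError("no M-mtDNA references supplied")
    if max_m_distance is None and not f_references:
        raise ConfigurationError(
            "nearest-reference sexing needs F references; "
            "alternatively pass max_m_distance"
        )
    for a in alleles:
        d_m = min(p_distance(a.sequence, m)[1] for m in m_references)
        if max_m_distance is not None:
            if d_m <= max_m_distance:
                return "male"
        else:
            d_f = min(p_distance(a.sequence, f)[1] for f in f_references)
            if d_m < d_f:
                return "male"
    return "female"
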