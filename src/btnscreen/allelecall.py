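"""Allele calling from molecular-cloning colony sequences and mixed signals.

Molecular cloning of a PCR product yields a set of colony sequences per
(individual, locus, tissue) experiment.  Colonies carrying the same sequence
are grouped into allele candidates; sequences seen in only one colony are the
classic signature of polymerase error or template switching during cloning
and are excluded as artifacts — unless the identical sequence recurs in
another experiment of the study, in which case a real low-frequency template
(e.g. a minority host allele beneath a dominant cancer allele) is the more
parsimonious reading and the singleton is rescued.

Frequencies are always computed over retained ("major-sequence") colonies.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from ._seqs import homopolymer_runs
from .errors import (
    InputError,
    NoAlleleError,
    UnresolvableMixtureError,
)

COMMON = "common"
RARE = "rare"
ARTIFACT_EXCLUDED = "artifact_excluded"

#: loci treated as mitochondrial for heteroplasmy bookkeeping
MITO_LOCI = frozenset({"COI", "CR", "16S"})


@dataclass(frozen=True)
class AlleleCall:
    """One allele candidate in one cloning experiment."""

    allele_id: str
    sequence: str
    colony_count: int
    frequency: float
    status: str = COMMON


@dataclass
class CloneSet:
    """Colony sequences from one cloning experiment."""

    individual_id: str
    locus: str
    tissue: str
    colonies: list[tuple[str, str]]  # (colony_id, sequence)

    def __post_init__(self):
        if not self.colonies:
            raise InputError(
                f"empty clone set for {self.individual_id}/{self.locus}/{self.tissue}"
            )

    @property
    def n_colonies(self) -> int:
        return len(self.colonies)

    def sequences(self) -> list[str]:
        return [seq for _, seq in self.colonies]


@dataclass
class TissueGenotype:
    """Per-locus allele set with frequencies for one tissue of one individual."""

    individual_id: str
    locus: str
    tissue: str
    alleles: list[AlleleCall] = field(default_factory=list)
    heteroplasmic: bool = False

    def retained(self) -> list[AlleleCall]:
        return [a for a in self.alleles if a.status != ARTIFACT_EXCLUDED]

    def freq_by_sequence(self) -> dict[str, float]:
        return {a.sequence: a.frequency for a in self.retained()}

    def frequency_of(self, sequence: str) -> float:
        return self.freq_by_sequence().get(sequence, 0.0)


class AlleleNamer:
    """Assigns names to allele sequences per locus.

    Sequences matching a registered reference inherit its name; novel
    sequences get sequential numeric ids — the letters-vs-numerals
    convention of the BTN genotyping literature.
    """

    def __init__(self, references: Mapping[tuple[str, str], str] | None = None):
        # (locus, sequence) -> name
        self._names: dict[tuple[str, str], str] = dict(references or {})
        self._counters: dict[str, itertools.count] = {}

    def name(self, locus: str, sequence: str) -> str:
        key = (locus, sequence)
        if key not in self._names:
            counter = self._counters.setdefault(locus, itertools.count(1))
            existing = set(self._names.values())
            nm = str(next(counter))
            while nm in existing:
                nm = str(next(counter))
            self._names[key] = nm
        return self._names[key]


def call_alleles(
    clone_set: CloneSet,
    cross_reference: Iterable[CloneSet] | None = None,
    min_colonies: int = 2,
    namer: AlleleNamer | None = None,
    singleton_rescue: bool = True,
) -> TissueGenotype:
    """Group colony sequences into allele calls with artifact exclusion.

    Parameters
    ----------
    clone_set
        The experiment to call.
    cross_reference
        Other cloning experiments of the same study.  A sequence below
        ``min_colonies`` support is rescued (status ``rare``) when the
        identical sequence occurs in any of these; otherwise it is excluded
        as a presumed PCR/cloning artifact.
    min_colonies
        Minimum colony support for an unconditional (``common``) call.
    namer
        Optional :class:`AlleleNamer`; defaults to per-locus numeric ids.
    singleton_rescue
        Switch for the cross-reference rescue rule.
    """
    if namer is None:
        namer = AlleleNamer()
    counts: dict[str, int] = {}
    for _, seq in clone_set.colonies:
        counts[seq] = counts.get(seq, 0) + 1

    cross_seqs: set[str] = set()
    if singleton_rescue and cross_reference is not None:
        for other in cross_reference:
            if other is clone_set:
                continue
            cross_seqs.update(other.sequences())

    statuses: dict[str, str] = {}
    for seq, n in counts.items():
        if n >= min_colonies:
            statuses[seq] = COMMON
        elif seq in cross_seqs:
            statuses[seq] = RARE
        else:
            statuses[seq] = ARTIFACT_EXCLUDED

    total_retained = sum(
        n for seq, n in counts.items() if statuses[seq] != ARTIFACT_EXCLUDED
    )
    if total_retained == 0:
        raise NoAlleleError(
            f"all {clone_set.n_colonies} colonies excluded in "
            f"{clone_set.individual_id}/{clone_set.locus}/{clone_set.tissue}"
        )

    alleles = []
    for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        status = statuses[seq]
        freq = n / total_retained if status != ARTIFACT_EXCLUDED else 0.0
        alleles.append(
            AlleleCall(
                allele_id=namer.name(clone_set.locus, seq),
                sequence=seq,
                colony_count=n,
                frequency=freq,
                status=status,
            )
        )
    retained = [a for a in alleles if a.status != ARTIFACT_EXCLUDED]
    return TissueGenotype(
        individual_id=clone_set.individual_id,
        locus=clone_set.locus,
        tissue=clone_set.tissue,
        alleles=alleles,
        heteroplasmic=(clone_set.locus in MITO_LOCI and len(retained) > 1),
    )


def _mergeable(a: str, b: str, min_run: int) -> bool:
    """True when *a* and *b* differ only at sites inside or adjacent to a
    homopolymer run of length >= min_run in either sequence."""
    if len(a) != len(b):
        return False
    diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    if not diffs:
        return False
    shadow: set[int] = set()
    for seq in (a, b):
        for start, end in homopolymer_runs(seq, min_run):
            shadow.update(range(max(0, start - 1), min(len(seq), end + 1)))
    return all(i in shadow for i in diffs)


def merge_homopolymer_variants(
    genotype: TissueGenotype, enabled: bool = True, min_run: int = 6
) -> TissueGenotype:
    """Merge allele pairs that differ only at homopolymer-adjacent sites.

    Slipped-strand mispairing during PCR generates spurious variants at
    long single-base runs; such pairs are collapsed into the higher-count
    allele and frequencies renormalized.  No-op when ``enabled`` is False.
    """
    if not enabled:
        return genotype
    retained = list(genotype.retained())
    excluded = [a for a in genotype.alleles if a.status == ARTIFACT_EXCLUDED]
    merged = True
    while merged:
        merged = False
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                if _mergeable(retained[i].sequence, retained[j].sequence, min_run):
                    keep, drop = retained[i], retained[j]
                    if drop.colony_count > keep.colony_count:
                        keep, drop = drop, keep
                    keep = replace(keep, colony_count=keep.colony_count + drop.colony_count)
                    retained = [a for k, a in enumerate(retained) if k not in (i, j)]
                    retained.append(keep)
                    merged = True
                    break
            if merged:
                break
    total = sum(a.colony_count for a in retained)
    retained = [replace(a, frequency=a.colony_count / total) for a in retained]
    retained.sort(key=lambda a: (-a.colony_count, a.allele_id))
    return TissueGenotype(
        individual_id=genotype.individual_id,
        locus=genotype.locus,
        tissue=genotype.tissue,
        alleles=retained + excluded,
        heteroplasmic=(genotype.locus in MITO_LOCI and len(retained) > 1),
    )


# ---------------------------------------------------------------------------
# Mixed chromatogram ("piggyback" peaks) resolution


@dataclass(frozen=True)
class SiteCall:
    """Base calls at one chromatogram position: the dominant peak and, at
    mixed sites, the minor overlapping peak with its relative height."""

    major: str
    minor: str | None = None
    ratio: float | None = None

    @property
    def mixed(self) -> bool:
        return self.minor is not None and self.minor != self.major


@dataclass
class PiggybackResolution:
    dominant: str
    minority: str
    attribution: dict[str, str]
    n_mixed: int


def resolve_piggyback(
    site_calls: Sequence[SiteCall],
    foot_allele: str | None = None,
    context: str = "hemolymph",
    max_mixed_fraction: float = 0.3,
) -> PiggybackResolution:
    """Decompose a mixed Sanger signal into dominant and minority sequences.

    In a hemolymph read of a diseased animal the dominant peaks are
    attributed to the presumptive cancer allele and the minor peaks to the
    host — but only when the reconstructed minority sequence equals the
    allele observed in the same individual's foot tissue; otherwise both
    sequences are left unattributed.
    """
    if not site_calls:
        raise InputError("empty site-call list")
    mixed_sites = [i for i, s in enumerate(site_calls) if s.mixed]
    if len(mixed_sites) > max_mixed_fraction * len(site_calls):
        raise UnresolvableMixtureError(
            f"{len(mixed_sites)}/{len(site_calls)} mixed sites exceed the "
            f"{max_mixed_fraction:.0%} resolvability threshold"
        )
    dominant = "".join(s.major for s in site_calls)
    minority = "".join(
        (s.minor if s.mixed else s.major) for s in site_calls
    )
    attribution: dict[str, str] = {}
    if mixed_sites and foot_allele is not None:
        if minority == foot_allele:
            if context == "hemolymph":
                attribution = {"dominant": "cancer-candidate", "minority": "host-candidate"}
            else:
                attribution = {"dominant": "host-candidate", "minority": "unattributed"}
        else:
            attribution = {"dominant": "unattributed", "minority": "unattributed"}
    return PiggybackResolution(
        dominant=dominant,
        minority=minority,
        attribution=attribution,
        n_mixed=len(mixed_sites),
    )


# ---------------------------------------------------------------------------
# Microsatellite fragment-profile comparison


@dataclass
class FragmentProfile:
    """Capillary-electrophoresis fragment profile: size (bp) -> peak height."""

    heights: dict[int, float]

    def shares(self) -> dict[int, float]:
        total = sum(self.heights.values())
        if total <= 0:
            raise InputError("fragment profile has no signal")
        return {size: h / total for size, h in self.heights.items()}


@dataclass
class FragmentEnrichment:
    sizes: list[int]
    grade: str = "inconclusive-evidence"


def compare_fragment_profiles(
    hemolymph: FragmentProfile,
    foot: FragmentProfile,
    enrichment_ratio: float = 2.0,
) -> FragmentEnrichment:
    """Fragment sizes over-represented in hemolymph relative to foot.

    Microsatellite enrichment is graded inconclusive on its own: the same
    fragments may segregate in healthy hosts, so it corroborates but never
    establishes a chimerism call.
    """
    if not hemolymph.heights or not foot.heights:
        raise InputError("empty fragment profile")
    h_shares = hemolymph.shares()
    f_shares = foot.shares()
    enriched = []
    for size in sorted(set(h_shares) | set(f_shares)):
        h = h_shares.get(size, 0.0)
        f = f_shares.get(size, 0.0)
        if h <= 0:
            continue
        if f == 0.0 or h / f >= enrichment_ratio:
            enriched.append(size)
    return FragmentEnrichment(sizes=enriched)
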