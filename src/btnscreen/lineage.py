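"""Cancer-lineage assignment, haplotype networks and recombination scanning.

Lineage identity of a transmissible cancer rests on allele identity or
proximity: a query allele is assigned to the reference lineage (BTN1, BTN2,
host F/M) of its nearest panel sequence by uncorrected p-distance with
pairwise deletion of missing data.  Haplotype relationships are drawn as a
minimum spanning network (the union of all minimum spanning trees over
Hamming distances, with multi-step edges expanded through inferred median
nodes) — a parsimony-style approximation of the TCS statistical-parsimony
network.  Recombinant control regions are dissected with a sliding-window
parent-assignment scan whose candidate breakpoints are refined by
maximizing a 2x2 chi-square of (left/right x matches-parent-A/B) over
informative sites.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from ._seqs import MISSING
from .errors import AlignmentError, ConfigurationError, InputError, ParameterError


# ---------------------------------------------------------------------------
# Distances


def p_distance(
    a: str, b: str, gap_policy: str = "pairwise_deletion"
) -> tuple[int, float]:
    """Uncorrected p-distance between two aligned sequences.

    Returns ``(n_diff, proportion)`` where ``n_diff`` counts mismatching
    columns in which both sequences carry a base and ``proportion`` divides
    by the number of such compared columns (gaps/ambiguity treated as
    missing data under pairwise deletion).
    """
    if gap_policy != "pairwise_deletion":
        raise ParameterError(f"unsupported gap policy: {gap_policy}")
    if len(a) != len(b):
        raise AlignmentError("aligned sequences differ in length")
    compared = 0
    n_diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in MISSING or y in MISSING:
            continue
        compared += 1
        if x != y:
            n_diff += 1
    if compared == 0:
        return 0, 0.0
    return n_diff, n_diff / compared


# ---------------------------------------------------------------------------
# Reference panel and lineage assignment


@dataclass(frozen=True)
class PanelEntry:
    lineage: str
    locus: str
    allele_name: str
    sequence: str


@dataclass
class ReferencePanel:
    entries: list[PanelEntry]
    provenance: str = ""

    def for_locus(self, locus: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.locus == locus]


@dataclass
class LineageCall:
    allele_name: str
    best_lineage: str | None
    best_reference: str | None
    n_diff: int
    p_dist: float
    novel: bool
    ambiguous: bool = False
    tied_lineages: list[str] = field(default_factory=list)


def assign_lineage(
    allele: str,
    panel: ReferencePanel,
    locus: str,
    novel_threshold: float = 0.03,
    allele_name: str = "query",
) -> LineageCall:
    """Assign an allele to the lineage of its nearest panel reference.

    A tie between references from *different* lineages is reported as
    ambiguous rather than broken arbitrarily; the allele is flagged novel
    when even the nearest reference is more than ``novel_threshold``
    p-distance away.
    """
    entries = panel.for_locus(locus)
    if not entries:
        raise ConfigurationError(f"reference panel has no entries for locus {locus}")
    dists = [(p_distance(allele, e.sequence), e) for e in entries]
    (best_nd, best_pd), best = min(dists, key=lambda t: t[0][1])
    tied = sorted({e.lineage for (nd, pd), e in dists if np.isclose(pd, best_pd)})
    ambiguous = len(tied) > 1
    return LineageCall(
        allele_name=allele_name,
        best_lineage=None if ambiguous else best.lineage,
        best_reference=None if ambiguous else best.allele_name,
        n_diff=best_nd,
        p_dist=best_pd,
        novel=best_pd > novel_threshold,
        ambiguous=ambiguous,
        tied_lineages=tied if ambiguous else [best.lineage],
    )


# ---------------------------------------------------------------------------
# Haplotype network (minimum spanning network with median nodes)


@dataclass
class Haplotype:
    id: str
    sequence: str
    frequency: int = 1
    group_counts: dict[str, int] = field(default_factory=dict)


def _hamming_cols(a: str, b: str) -> int:
    # network distances ignore missing data columns, like p_distance
    return p_distance(a, b)[0]


def minimum_spanning_network_edges(
    ids: Sequence[str], dist: Mapping[tuple[str, str], int]
) -> set[tuple[str, str]]:
    """Union of all minimum spanning trees (Kruskal level-set construction).

    Processing distances in ascending order, every edge at the current
    distance level that joins two components *as they stood before the
    level* belongs to some MST and is kept.
    """
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges_by_d: dict[int, list[tuple[str, str]]] = {}
    for (u, v), d in dist.items():
        edges_by_d.setdefault(d, []).append((u, v))

    kept: set[tuple[str, str]] = set()
    for d in sorted(edges_by_d):
        level = [
            (u, v) for u, v in edges_by_d[d] if find(u) != find(v)
        ]
        kept.update(level)
        for u, v in level:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    return kept


def build_haplotype_network(
    haplotypes: Sequence[Haplotype],
    max_connection_steps: int | None = None,
) -> nx.Graph:
    """Minimum spanning network over haplotypes with median-node expansion.

    Every kept edge of k > 1 mutational steps is expanded into k unit edges
    through k - 1 inferred (hypothetical) median nodes, so each drawn edge
    is exactly one substitution.  ``max_connection_steps`` optionally drops
    connections longer than the given limit (an ad-hoc analogue of the
    statistical-parsimony connection limit); by default the network is
    connected.
    """
    if not haplotypes:
        raise InputError("no haplotypes")
    lengths = {len(h.sequence) for h in haplotypes}
    if len(lengths) > 1:
        raise AlignmentError("haplotypes must share an aligned length")
    g = nx.Graph()
    for h in haplotypes:
        g.add_node(
            h.id,
            frequency=h.frequency,
            median=False,
            **{f"group_{k}": v for k, v in h.group_counts.items()},
        )
    if len(haplotypes) == 1:
        return g
    dist: dict[tuple[str, str], int] = {}
    by_id = {h.id: h for h in haplotypes}
    ids = [h.id for h in haplotypes]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dist[(ids[i], ids[j])] = _hamming_cols(
                by_id[ids[i]].sequence, by_id[ids[j]].sequence
            )
    edges = minimum_spanning_network_edges(ids, dist)
    counter = 0
    for u, v in sorted(edges):
        d = dist[(u, v)] if (u, v) in dist else dist[(v, u)]
        if max_connection_steps is not None and d > max_connection_steps:
            continue
        if d <= 1:
            g.add_edge(u, v, steps=1)
            continue
        prev = u
        for k in range(d - 1):
            counter += 1
            med = f"median_{counter}"
            g.add_node(med, frequency=0, median=True)
            g.add_edge(prev, med, steps=1)
            prev = med
        g.add_edge(prev, v, steps=1)
    return g


# ---------------------------------------------------------------------------
# Recombination breakpoint scanning


@dataclass
class RecombinationReport:
    query_name: str
    breakpoints: list[int]
    segments: list[tuple[tuple[int, int], str]]  # ((start, end), parent)
    window_trace: list[tuple[int, int, int]]  # (window_start, mm_a, mm_b)

    @property
    def recombinant(self) -> bool:
        return bool(self.breakpoints)


def _chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square of a 2x2 table [[a, b], [c, d]] (no correction)."""
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def scan_recombination(
    query: str,
    parent_a: str,
    parent_b: str,
    window: int = 50,
    step: int = 10,
    query_name: str = "query",
    parent_names: tuple[str, str] = ("parent_a", "parent_b"),
) -> RecombinationReport:
    """Max-chi-square style recombination scan of a query against two parents.

    A sliding window assigns each stretch of the alignment to the parent
    the query matches better; candidate breakpoints are placed where the
    assignment flips and refined by maximizing the 2x2 chi-square of
    (left/right of the cut x query-matches-A/query-matches-B) computed over
    informative sites (sites where the parents differ and the query matches
    one of them).  When one parent wins everywhere, no breakpoints are
    reported.
    """
    L = len(query)
    if len(parent_a) != L or len(parent_b) != L:
        raise AlignmentError("query and parents must share an aligned length")
    if window < 20:
        raise ParameterError("window must be >= 20")
    if step < 1:
        raise ParameterError("step must be >= 1")
    if window > L:
        raise ParameterError("window exceeds alignment length")

    mm_a = np.fromiter((q != p for q, p in zip(query, parent_a)), bool, L)
    mm_b = np.fromiter((q != p for q, p in zip(query, parent_b)), bool, L)

    trace = []
    assignments = []  # (window_start, winner) with winner in {0, 1, -1}
    for start in range(0, L - window + 1, step):
        wa = int(mm_a[start : start + window].sum())
        wb = int(mm_b[start : start + window].sum())
        trace.append((start, wa, wb))
        winner = 0 if wa < wb else 1 if wb < wa else -1
        assignments.append((start, winner))

    # carry ties forward; leading ties take the first decided winner
    decided = [w for _, w in assignments if w != -1]
    if not decided:
        return RecombinationReport(query_name, [], [((0, L), "undecided")], trace)
    filled = []
    prev = decided[0]
    for start, w in assignments:
        if w == -1:
            w = prev
        filled.append((start, w))
        prev = w

    flips = [
        (filled[k][0], filled[k + 1][0], filled[k + 1][1])
        for k in range(len(filled) - 1)
        if filled[k][1] != filled[k + 1][1]
    ]

    # informative sites: parents differ and the query matches exactly one
    informative = np.flatnonzero(
        (mm_a != mm_b)
        & np.fromiter((a != b for a, b in zip(parent_a, parent_b)), bool, L)
    )
    matches_a = ~mm_a

    breakpoints = []
    for left_start, right_start, _ in flips:
        lo = left_start
        hi = min(L, right_start + window)
        local = informative[(informative >= lo) & (informative < hi)]
        if local.size == 0:
            breakpoints.append((left_start + right_start + window) // 2)
            continue
        best_chi = -1.0
        best_cuts: list[int] = []
        # candidate cuts: one per interval between consecutive informative
        # sites in the region (the statistic is constant on each interval)
        cuts = np.unique(np.concatenate([[lo], local + 1, [hi]]))
        for cut in cuts:
            left = informative[informative < cut]
            right = informative[informative >= cut]
            a_ = int(matches_a[left].sum())
            b_ = left.size - a_
            c_ = int(matches_a[right].sum())
            d_ = right.size - c_
            chi = _chi2_2x2(a_, b_, c_, d_)
            if chi > best_chi + 1e-12:
                best_chi = chi
                best_cuts = [int(cut)]
            elif abs(chi - best_chi) <= 1e-12:
                best_cuts.append(int(cut))
        # each maximizing cut stands for the whole interval of positions
        # between its flanking informative sites; report the centre of the
        # union of maximizing intervals
        plateau_lo = None
        plateau_hi = None
        for cut in best_cuts:
            below = informative[informative < cut]
            at_or_above = informative[informative >= cut]
            start = int(below[-1]) + 1 if below.size else lo
            end = int(at_or_above[0]) if at_or_above.size else hi
            plateau_lo = start if plateau_lo is None else min(plateau_lo, start)
            plateau_hi = end if plateau_hi is None else max(plateau_hi, end)
        breakpoints.append(int(round(0.5 * (plateau_lo + plateau_hi))))

    # deduplicate and order
    breakpoints = sorted(set(breakpoints))

    segments = []
    bounds = [0] + breakpoints + [L]
    seg_parents = []
    for k in range(len(bounds) - 1):
        s, e = bounds[k], bounds[k + 1]
        wa = int(mm_a[s:e].sum())
        wb = int(mm_b[s:e].sum())
        seg_parents.append(parent_names[0] if wa <= wb else parent_names[1])
    # merge adjacent segments assigned to the same parent
    merged_bounds = [0]
    merged_parents = []
    for k in range(len(seg_parents)):
        if merged_parents and seg_parents[k] == merged_parents[-1]:
            merged_bounds[-1] = bounds[k + 1]
        else:
            merged_parents.append(seg_parents[k])
            merged_bounds.append(bounds[k + 1])
    segments = [
        ((merged_bounds[k], merged_bounds[k + 1]), merged_parents[k])
        for k in range(len(merged_parents))
    ]
    breakpoints = merged_bounds[1:-1]
    return RecombinationReport(
        query_name=query_name,
        breakpoints=breakpoints,
        segments=segments,
        window_trace=trace,
    )
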