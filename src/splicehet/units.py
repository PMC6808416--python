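"""Grouping of splice junctions into intronic splicing units.

An intronic splicing unit is a set of splicing events that share a splice
site — donor or acceptor — within one intronic region. Junctions are nodes
of a graph whose edges connect junctions sharing either endpoint coordinate
on the same chromosome and strand class; the connected components of that
graph are the units. The components partition the junction set, so a
junction sharing its donor with one neighbour and its acceptor with another
lands in exactly one unit.

Strand classes ``+``, ``-`` and ``.`` (unknown) never merge: antisense
overlapping genes can share coordinates without sharing splicing events.

For a pairwise comparison the units are built on the union of both samples'
junctions, so both samples see the same unit list over the same intronic
regions; a junction absent from one sample enters that sample's count
vector as 0 (to be pseudo-counted downstream).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from .junction_io import JunctionKey, JunctionProfile

__all__ = [
    "SplicingUnit",
    "HarmonizedUnitPair",
    "group_junctions",
    "harmonize_units",
    "filter_units",
    "DROP_TOO_FEW_MEMBERS",
    "DROP_ABSENT_IN_ONE_SAMPLE",
]

DROP_TOO_FEW_MEMBERS = "too_few_members"
DROP_ABSENT_IN_ONE_SAMPLE = "absent_in_one_sample"


@dataclass(frozen=True)
class SplicingUnit:
    """A connected group of junctions sharing splice sites.

    ``members`` are canonically ordered by (start, end); ``site_set`` is the
    set of splice-site coordinates the members touch. The unit id encodes
    the intronic region: ``chrom:minsite-maxsite(strand)``.
    """

    unit_id: str
    chrom: str
    strand: str
    members: tuple[JunctionKey, ...]
    site_set: frozenset[int]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class HarmonizedUnitPair:
    """One unit over the union of two samples, with both count vectors.

    ``counts_p[i]`` and ``counts_q[i]`` support ``unit.members[i]``; entries
    are 0 where that sample did not observe the junction (pseudo-counting
    happens later, in the divergence layer).
    """

    unit: SplicingUnit
    counts_p: np.ndarray
    counts_q: np.ndarray


def _make_unit(chrom: str, strand: str, members: Iterable[JunctionKey]) -> SplicingUnit:
    ordered = tuple(sorted(members, key=lambda k: (k[1], k[2])))
    sites = frozenset(s for k in ordered for s in (k[1], k[2]))
    unit_id = f"{chrom}:{min(sites)}-{max(sites)}({strand})"
    return SplicingUnit(unit_id, chrom, strand, ordered, sites)


def group_junctions(junction_keys: Iterable[JunctionKey]) -> list[SplicingUnit]:
    """Partition junctions into splicing units (connected components).

    Returns units in deterministic genomic order:
    (chrom, min site, max site, strand).
    """
    keys = set(junction_keys)
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(keys)
    buckets: dict[tuple[str, str, int], list[JunctionKey]] = defaultdict(list)
    for key in keys:
        chrom, start, end, strand = key
        buckets[(chrom, strand, start)].append(key)
        buckets[(chrom, strand, end)].append(key)
    for bucket in buckets.values():
        anchor = bucket[0]
        for other in bucket[1:]:
            graph.add_edge(anchor, other)
    units = []
    for component in nx.connected_components(graph):
        chrom, _, _, strand = next(iter(component))
        units.append(_make_unit(chrom, strand, component))
    units.sort(key=lambda u: (u.chrom, min(u.site_set), max(u.site_set), u.strand))
    return units


def harmonize_units(
    p: JunctionProfile, q: JunctionProfile
) -> list[HarmonizedUnitPair]:
    """Build units on the union of both samples' junctions.

    Symmetric up to swapping the count vectors: ``harmonize_units(q, p)``
    yields the same units with ``counts_p`` and ``counts_q`` exchanged.
    """
    union = set(p.junctions) | set(q.junctions)
    pairs = []
    for unit in group_junctions(union):
        counts_p = np.array([p.count(k) for k in unit.members], dtype=float)
        counts_q = np.array([q.count(k) for k in unit.members], dtype=float)
        pairs.append(HarmonizedUnitPair(unit, counts_p, counts_q))
    return pairs


def filter_units(
    pairs: Iterable[HarmonizedUnitPair],
    min_members: int = 2,
    min_reads: float = 1.0,
) -> tuple[list[HarmonizedUnitPair], Counter]:
    """Drop degenerate units, tallying the reasons.

    A unit is dropped when it has fewer than ``min_members`` member
    junctions in the union (a singleton has a one-point usage distribution
    whose divergence is identically 0), or when either sample's total
    observed count in the unit is below ``min_reads`` (default 1: a unit
    wholly unobserved in one sample has no usage distribution there, and
    its pseudo-count — a fraction of the unit total — would be 0).
    """
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    kept: list[HarmonizedUnitPair] = []
    drop_log: Counter = Counter()
    for pair in pairs:
        if len(pair.unit) < min_members:
            drop_log[DROP_TOO_FEW_MEMBERS] += 1
        elif pair.counts_p.sum() < min_reads or pair.counts_q.sum() < min_reads:
            drop_log[DROP_ABSENT_IN_ONE_SAMPLE] += 1
        else:
            kept.append(pair)
    return kept, drop_log
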