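"""The sITH score: per-unit Jensen-Shannon divergence of splice-site usage.

For the k-th splicing unit with N_k alternative junctions, the usage
distribution of a sample is the fraction vector

    P_k(i) = CNT_k(i) / sum_j CNT_k(j),

where CNT_k(i) is the number of reads supporting the i-th alternative
junction. The divergence between two samples' usage in one unit is the
Jensen-Shannon divergence with base-2 logarithms,

    JSD(P_k, Q_k) = 1/2 * ( KLD(P_k || M_k) + KLD(Q_k || M_k) ),
    M_k = (P_k + Q_k) / 2,
    KLD(P || M) = sum_i P(i) * log2( P(i) / M(i) ),

which is symmetric and bounded in [0, 1]: 0 means identical splice-site
usage, 1 means completely disjoint usage. The spliceomic intratumor
heterogeneity of sample P relative to an origin sample Q (a tumor against
a normal reference) is the mean over the L usable units:

    sITH(P, Q) = (1/L) * sum_k JSD(P_k, Q_k).

When the two samples support different splice-site sets within a unit, the
entry that is 0 in one sample is replaced by a pseudo-count equal to 1/100
of that sample's total read count in the unit (the denominator is
configurable); usage distributions are renormalized afterwards, so both
samples have full support and the KLD terms stay finite.

With one or more normal references, the sITH of a tumor is the arithmetic
mean of its pairwise sITH against each reference.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .junction_io import JunctionProfile
from .units import filter_units, harmonize_units

__all__ = [
    "SithConfig",
    "UnitDivergence",
    "SithResult",
    "usage_distribution",
    "apply_pseudocounts",
    "intermediate_distribution",
    "kld",
    "jsd",
    "sith_pair",
    "sith_multi_ref",
]


@dataclass(frozen=True)
class SithConfig:
    """Pipeline knobs for unit filtering and pseudo-counting.

    min_members: smallest union member count for a unit to enter L
        (default 2; singletons have JSD identically 0 and only dilute the
        mean).
    min_reads: smallest per-sample unit total; below it the unit is
        dropped as effectively absent in that sample (default 1 read).
    pseudocount_denominator: the unit total is divided by this to obtain
        the pseudo-count for an unobserved splice site (default 100).
    """

    min_members: int = 2
    min_reads: float = 1.0
    pseudocount_denominator: float = 100.0

    def __post_init__(self) -> None:
        if self.pseudocount_denominator <= 0:
            raise ValueError("pseudocount_denominator must be > 0")


@dataclass(frozen=True)
class UnitDivergence:
    unit_id: str
    jsd: float


@dataclass
class SithResult:
    """Per-unit JSDs plus their mean, with bookkeeping of dropped units.

    ``sith`` is ``None`` — explicitly undefined, never silently 0 — when no
    unit survived filtering.
    """

    sample_p: str
    sample_q: str
    unit_divergences: list[UnitDivergence]
    drop_log: Counter = field(default_factory=Counter)
    sith: float | None = None

    @property
    def L(self) -> int:
        """Number of splicing units entering the mean."""
        return len(self.unit_divergences)

    @property
    def is_defined(self) -> bool:
        return self.sith is not None


def usage_distribution(counts: Sequence[float] | np.ndarray) -> np.ndarray:
    """Normalize a unit's count vector into the usage distribution (sums to 1)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("degenerate input: all counts are zero")
    return counts / total


def apply_pseudocounts(
    counts_p: Sequence[float] | np.ndarray,
    counts_q: Sequence[float] | np.ndarray,
    denominator: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Patch splice sites unobserved in exactly one sample.

    Where one vector is 0 and the other positive, the zero entry becomes
    (that vector's own unit total) / ``denominator``. Entries positive in
    both samples are untouched. Returns modified copies.
    """
    cp = np.array(counts_p, dtype=float)
    cq = np.array(counts_q, dtype=float)
    if cp.shape != cq.shape:
        raise ValueError("count vectors must have equal length")
    if np.any((cp == 0) & (cq == 0)):
        raise ValueError(
            "splice site unobserved in both samples: unit members must come "
            "from the union of observed junctions"
        )
    cp[cp == 0] = cp.sum() / denominator
    cq[cq == 0] = cq.sum() / denominator
    return cp, cq


def intermediate_distribution(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """The midpoint distribution M = (P + Q) / 2."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    return (p + q) / 2.0


def kld(p: np.ndarray, m: np.ndarray) -> float:
    """Kullback-Leibler divergence sum_i p(i) log2(p(i)/m(i)), in bits.

    Uses the 0*log(0)=0 convention. Raises if p has mass where m has none
    (infinite divergence; with the midpoint M of the JSD this cannot occur
    and signals a pseudo-counting bug upstream).
    """
    p = np.asarray(p, dtype=float)
    m = np.asarray(m, dtype=float)
    if p.shape != m.shape:
        raise ValueError("distributions must have equal length")
    support = p > 0
    if np.any(m[support] == 0):
        raise ValueError("p has mass where m is zero: divergence is infinite")
    return float(np.sum(p[support] * np.log2(p[support] / m[support])))


def jsd(p: Sequence[float] | np.ndarray, q: Sequence[float] | np.ndarray) -> float:
    """Jensen-Shannon divergence in bits; symmetric, in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = intermediate_distribution(p, q)
    value = 0.5 * (kld(p, m) + kld(q, m))
    # clamp the tiny negative round-off that can arise when p == q
    return min(max(value, 0.0), 1.0)


def sith_pair(
    p: JunctionProfile, q: JunctionProfile, config: SithConfig | None = None
) -> SithResult:
    """Compute sITH(P, Q): mean per-unit JSD over the harmonized unit set.

    Units are built on the union of both samples' junctions, filtered,
    pseudo-counted and normalized; the score is symmetric in P and Q.
    """
    cfg = config or SithConfig()
    pairs = harmonize_units(p, q)
    kept, drop_log = filter_units(pairs, cfg.min_members, cfg.min_reads)
    divergences: list[UnitDivergence] = []
    for pair in kept:
        cp, cq = apply_pseudocounts(
            pair.counts_p, pair.counts_q, cfg.pseudocount_denominator
        )
        divergences.append(
            UnitDivergence(
                pair.unit.unit_id, jsd(usage_distribution(cp), usage_distribution(cq))
            )
        )
    sith = (
        float(np.mean([d.jsd for d in divergences])) if divergences else None
    )
    return SithResult(p.sample_id, q.sample_id, divergences, drop_log, sith)


def sith_multi_ref(
    tumor: JunctionProfile,
    refs: Iterable[JunctionProfile],
    config: SithConfig | None = None,
) -> tuple[float | None, list[SithResult]]:
    """Average sITH of a tumor over several normal references.

    Returns the arithmetic mean of the defined pairwise scores together
    with every per-reference result; the mean is ``None`` if no pair
    yielded a defined score.
    """
    results = [sith_pair(tumor, ref, config) for ref in refs]
    if not results:
        raise ValueError("refs must be non-empty")
    defined = [r.sith for r in results if r.sith is not None]
    mean = float(np.mean(defined)) if defined else None
    return mean, results
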