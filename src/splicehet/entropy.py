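"""Shannon-entropy heterogeneity measures used to validate the intron-local view.

Two single-sample measures of transcriptomic heterogeneity:

* whole-transcript ITH — the mean, over genes, of the Shannon entropy of
  each gene's isoform abundance fractions:

      ITH_transcript = -(1/G) * sum_g sum_i P_gi * log2(P_gi),

  where P_gi is the fraction of the i-th isoform of gene g;

* intronic ITH — the mean, over splicing units, of the Shannon entropy of
  each unit's splice-site usage distribution:

      ITH_intron = -(1/L) * sum_k sum_i P_ki * log2(P_ki),

  where P_ki is the usage fraction of the i-th junction of unit k and L is
  the number of units.

If the intron-local measure tracks the whole-transcript measure across
samples, splice-site usage within intronic units is a valid, annotation-free
proxy for isoform-level heterogeneity. Logarithms are base 2 throughout,
matching the divergence core; correlation readouts are base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np

from .divergence import SithConfig
from .junction_io import JunctionProfile
from .units import group_junctions

__all__ = [
    "GeneIsoformSet",
    "transcript_entropy",
    "intron_entropy",
    "read_isoform_fractions_tsv",
]


@dataclass(frozen=True)
class GeneIsoformSet:
    """One gene's isoform abundance fractions (must sum to 1)."""

    gene_id: str
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.fractions, dtype=float)
        if arr.size == 0 or np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("fractions must be non-empty with entries in [0, 1]")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {arr.sum()}")


def _entropy_bits(fractions: np.ndarray) -> float:
    positive = fractions[fractions > 0]
    return float(-np.sum(positive * np.log2(positive)))


def transcript_entropy(genes: Sequence[GeneIsoformSet]) -> float:
    """Mean per-gene Shannon entropy of isoform fractions, in bits."""
    if not genes:
        raise ValueError("genes must be non-empty")
    return float(
        np.mean([_entropy_bits(np.asarray(g.fractions, dtype=float)) for g in genes])
    )


def intron_entropy(
    profile: JunctionProfile, config: SithConfig | None = None
) -> float | None:
    """Mean per-unit Shannon entropy of junction usage, in bits.

    Uses the same unit grouping and filtering configuration as the sITH
    core (so the two measures see identical unit sets); returns ``None``
    when no unit survives filtering.
    """
    cfg = config or SithConfig()
    entropies = []
    for unit in group_junctions(profile.junctions):
        if len(unit) < cfg.min_members:
            continue
        counts = np.array([profile.count(k) for k in unit.members], dtype=float)
        total = counts.sum()
        if total < cfg.min_reads or total <= 0:
            continue
        entropies.append(_entropy_bits(counts / total))
    if not entropies:
        return None
    return float(np.mean(entropies))


def read_isoform_fractions_tsv(stream: IO[str] | Iterable[str]) -> list[GeneIsoformSet]:
    """Read gene isoform fractions from a ``gene_id<TAB>isoform_id<TAB>fraction`` TSV."""
    lines = iter(stream)
    header = next(lines, None)
    if header is None or tuple(header.rstrip("\n").split("\t")) != (
        "gene_id",
        "isoform_id",
        "fraction",
    ):
        raise ValueError("expected header 'gene_id\\tisoform_id\\tfraction'")
    per_gene: dict[str, list[float]] = {}
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        gene_id, _isoform_id, fraction = line.split("\t")
        per_gene.setdefault(gene_id, []).append(float(fraction))
    return [GeneIsoformSet(g, tuple(fr)) for g, fr in per_gene.items()]
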