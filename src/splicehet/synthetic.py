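"""Synthetic junction profiles, in-silico mixtures, and experiment drivers.

This module provides desk-scale, download-free analogs of the validation
experiments the sITH score was designed for:

* a generator of "normal tissue" junction profiles with many independent
  splicing units, each carrying a Dirichlet-drawn splice-site usage
  distribution and Poisson read depth;
* a perturbation operator that derives "cancer cell" profiles whose usage
  distributions are pulled toward independently resampled targets — a
  stand-in for clones with shifted splice-site usage;
* the mixture model that blends i single cells into a normal profile at 1%
  per cell,

      MIX(i, j) = NT(j) * (1 - i/100) + sum_{l=1..i} SC(l, j) / 100,

  where j indexes junctions, NT is the normal-tissue count and SC(l) the
  l-th cell's count (counts stay fractional: the model is defined on the
  arithmetic, not on resampled reads);
* the mixture experiment driver (by default 39 mixing levels x 10
  replicates = 390 mixtures) whose readout is the Spearman rank
  correlation between the designed mixing level and the measured sITH;
* a paired-entropy experiment that derives junction counts from randomized
  isoform mixtures over fixed gene structures and compares the
  whole-transcript and intronic entropy measures.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import SithConfig, sith_pair
from .entropy import GeneIsoformSet, intron_entropy, transcript_entropy
from .junction_io import JunctionKey, JunctionProfile
from .units import group_junctions

__all__ = [
    "GeneratorParams",
    "MixtureSpec",
    "GeneModel",
    "generate_normal_profile",
    "perturb_profile",
    "synthesize_mixture",
    "run_mixture_experiment",
    "spearman",
    "generate_gene_models",
    "sample_isoform_fractions",
    "junction_profile_from_fractions",
    "run_entropy_experiment",
]

# Units are laid out on a synthetic genome with one shared donor site and
# alternative acceptor sites per unit, spaced so that no two units share a
# coordinate and grouping recovers the layout exactly.
_UNIT_SPACING = 10_000
_ACCEPTOR_OFFSET = 100
_ACCEPTOR_STEP = 10


@dataclass(frozen=True)
class GeneratorParams:
    """Conditions of the synthetic normal tissue and its derived cells.

    n_units: number of independent splicing units (default 300).
    members_range: inclusive range of alternative junctions per unit
        (default 2-4, the shared-donor pattern with a few acceptors).
    depth: mean read depth per unit (default 200 reads).
    dirichlet_concentration: symmetric Dirichlet concentration of the
        drawn usage distributions (default 1.0, uniform over the simplex).
    perturbation_strength: mixing weight pulling a cell's usage toward its
        resampled target, in (0, 1] (default 0.8 — clones with strongly
        shifted splice-site usage).
    seed: master seed; everything downstream is deterministic given it.
    """

    n_units: int = 300
    members_range: tuple[int, int] = (2, 4)
    depth: float = 200.0
    dirichlet_concentration: float = 1.0
    perturbation_strength: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        lo, hi = self.members_range
        if not (1 <= lo <= hi):
            raise ValueError("members_range must satisfy 1 <= lo <= hi")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        if not (0 < self.perturbation_strength <= 1):
            raise ValueError("perturbation_strength must be in (0, 1]")


@dataclass(frozen=True)
class MixtureSpec:
    """One in-silico mixture: ``level`` cells blended into ``normal`` at 1% each."""

    normal: JunctionProfile
    cells: tuple[JunctionProfile, ...]
    level: int
    replicate: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level < 0 or self.level > len(self.cells):
            raise ValueError(
                f"level must be in [0, {len(self.cells)}], got {self.level}"
            )


def generate_normal_profile(
    params: GeneratorParams,
    sample_id: str = "normal",
    return_usage: bool = False,
) -> JunctionProfile | tuple[JunctionProfile, list[np.ndarray]]:
    """Draw a synthetic normal-tissue junction profile.

    Each unit gets a member count from ``members_range``, a usage
    distribution from a symmetric Dirichlet, a Poisson total read count at
    the configured mean depth, and multinomial integer counts; every member
    is guaranteed at least one read so all units pass the default filters.
    With ``return_usage`` the drawn (pre-sampling) usage distributions are
    returned as well, in unit order.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.members_range
    junctions: dict[JunctionKey, float] = {}
    usages: list[np.ndarray] = []
    for k in range(params.n_units):
        m = int(rng.integers(lo, hi + 1))
        usage = rng.dirichlet(np.full(m, params.dirichlet_concentration))
        usages.append(usage)
        total = int(rng.poisson(params.depth))
        counts = np.ones(m) + rng.multinomial(max(total - m, 0), usage)
        donor = 1 + k * _UNIT_SPACING
        strand = "+" if k % 2 == 0 else "-"
        for i in range(m):
            acceptor = donor + _ACCEPTOR_OFFSET + i * _ACCEPTOR_STEP
            junctions[("chr1", donor, acceptor, strand)] = float(counts[i])
    profile = JunctionProfile(sample_id, junctions)
    return (profile, usages) if return_usage else profile


def perturb_profile(
    normal: JunctionProfile,
    strength: float,
    seed: int,
    concentration: float = 1.0,
    sample_id: str = "cell",
) -> JunctionProfile:
    """Derive a "cell" profile with splice-site usage shifted away from normal.

    For each unit the cell's usage is the convex combination
    ``(1 - strength) * normal_usage + strength * target`` with a fresh
    symmetric-Dirichlet target per unit; counts are the expected counts at
    the unit's normal total (fractional, no resampling noise), so the
    ``strength -> 0`` limit reproduces the normal usage exactly and the
    divergence from normal grows monotonically with ``strength``.
    """
    if not (0 <= strength <= 1):
        raise ValueError("strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    junctions: dict[JunctionKey, float] = {}
    for unit in group_junctions(normal.junctions):
        counts = np.array([normal.count(k) for k in unit.members], dtype=float)
        total = counts.sum()
        target = rng.dirichlet(np.full(len(unit), concentration))
        usage = (1.0 - strength) * (counts / total) + strength * target
        for key, c in zip(unit.members, usage * total):
            if c > 0:
                junctions[key] = float(c)
    return JunctionProfile(sample_id, junctions)


def synthesize_mixture(spec: MixtureSpec, sample_id: str | None = None) -> JunctionProfile:
    """Blend ``spec.level`` cells into the normal profile at 1% per cell.

    The junction universe is the union over the normal and the mixed
    cells; absent junctions contribute count 0. Counts are exactly the
    affine combination MIX(i, j) above, fractional values included.
    """
    i = spec.level
    mixed = spec.cells[:i]
    universe: set[JunctionKey] = set(spec.normal.junctions)
    for cell in mixed:
        universe.update(cell.junctions)
    junctions: dict[JunctionKey, float] = {}
    for key in universe:
        count = spec.normal.count(key) * (1.0 - i / 100.0)
        count += sum(cell.count(key) for cell in mixed) / 100.0
        if count > 0:
            junctions[key] = count
    if sample_id is None:
        sample_id = f"mix_level{i}_rep{spec.replicate}"
    return JunctionProfile(sample_id, junctions)


def run_mixture_experiment(
    params: GeneratorParams,
    n_cells: int = 39,
    n_levels: int = 39,
    replicates: int = 10,
    config: SithConfig | None = None,
) -> pd.DataFrame:
    """Run the full mixture experiment; returns rows (level, replicate, sith).

    One normal profile and ``n_cells`` distinct cell profiles are generated
    from the master seed; for each mixing level i = 1..n_levels and each
    replicate, i cells are drawn without replacement, mixed into the normal
    at 1% per cell, and scored with sITH against the normal. Deterministic
    given ``params.seed``.
    """
    if n_levels > n_cells:
        raise ValueError("n_levels must be <= n_cells")
    rng = np.random.default_rng(params.seed)
    normal = generate_normal_profile(params)
    cell_seeds = rng.integers(0, 2**31 - 1, size=n_cells)
    cells = tuple(
        perturb_profile(
            normal,
            params.perturbation_strength,
            int(s),
            params.dirichlet_concentration,
            sample_id=f"cell{l}",
        )
        for l, s in enumerate(cell_seeds)
    )
    rows = []
    for level in range(1, n_levels + 1):
        for rep in range(replicates):
            chosen = tuple(cells[i] for i in rng.choice(n_cells, level, replace=False))
            mixture = synthesize_mixture(
                MixtureSpec(normal, chosen, level, replicate=rep)
            )
            result = sith_pair(mixture, normal, config)
            rows.append((level, rep, result.sith))
    return pd.DataFrame(rows, columns=["level", "replicate", "sith"])


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# Paired-entropy experiment: isoform mixtures -> junction counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """Fixed intron structure of one synthetic gene.

    ``regions[r]`` assigns each of the gene's isoforms to one of the
    region's alternative junctions (isoforms sharing an acceptor share a
    junction; a region where all isoforms agree yields a single
    constitutive junction). ``offset`` places the gene's coordinates.
    """

    gene_id: str
    n_isoforms: int
    regions: tuple[tuple[int, ...], ...]
    offset: int


def generate_gene_models(
    n_genes: int = 10,
    isoform_range: tuple[int, int] = (2, 5),
    regions_per_gene: int = 8,
    seed: int = 0,
) -> list[GeneModel]:
    """Draw fixed gene structures: per intronic region, a random assignment
    of isoforms to alternative splice junctions."""
    rng = np.random.default_rng(seed)
    lo, hi = isoform_range
    genes = []
    for g in range(n_genes):
        n_iso = int(rng.integers(lo, hi + 1))
        regions = []
        for _ in range(regions_per_gene):
            n_groups = int(rng.integers(1, n_iso + 1))
            regions.append(tuple(int(v) for v in rng.integers(0, n_groups, n_iso)))
        genes.append(
            GeneModel(f"gene{g}", n_iso, tuple(regions), offset=1 + g * 1_000_000)
        )
    return genes


def sample_isoform_fractions(
    genes: Sequence[GeneModel], heterogeneity: float, rng: np.random.Generator
) -> list[GeneIsoformSet]:
    """Assign isoform fractions for one sample at a given heterogeneity level.

    The representative (first) isoform keeps weight ``1 - heterogeneity``;
    the remaining isoforms share ``heterogeneity`` in random proportions.
    """
    if not (0 <= heterogeneity <= 1):
        raise ValueError("heterogeneity must be in [0, 1]")
    out = []
    for gene in genes:
        rest = rng.dirichlet(np.ones(gene.n_isoforms - 1)) * heterogeneity
        fractions = np.concatenate([[1.0 - heterogeneity], rest])
        fractions /= fractions.sum()
        out.append(GeneIsoformSet(gene.gene_id, tuple(float(f) for f in fractions)))
    return out


def junction_profile_from_fractions(
    genes: Sequence[GeneModel],
    fractions: Sequence[GeneIsoformSet],
    depth: float,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> JunctionProfile:
    """Translate isoform fractions into junction read counts.

    Each region's junction receives Poisson reads at rate ``depth`` times
    the summed fraction of the isoforms using it — the sequencing-coverage
    consequence of the isoform mixture on that gene structure.
    """
    junctions: dict[JunctionKey, float] = {}
    for gene, iso in zip(genes, fractions):
        frac = np.asarray(iso.fractions, dtype=float)
        for r, assignment in enumerate(gene.regions):
            donor = gene.offset + r * _UNIT_SPACING
            assignment = np.asarray(assignment)
            for group in np.unique(assignment):
                rate = depth * frac[assignment == group].sum()
                count = int(rng.poisson(rate))
                if count > 0:
                    acceptor = donor + _ACCEPTOR_OFFSET + int(group) * _ACCEPTOR_STEP
                    junctions[("chr1", donor, acceptor, "+")] = float(count)
    return JunctionProfile(sample_id, junctions)


def run_entropy_experiment(
    n_samples: int = 200,
    n_genes: int = 10,
    n_pools: int = 10,
    isoform_range: tuple[int, int] = (2, 5),
    regions_per_gene: int = 8,
    depth: float = 100.0,
    seed: int = 0,
    config: SithConfig | None = None,
) -> pd.DataFrame:
    """Paired whole-transcript vs intronic entropy over randomized mixtures.

    Samples are split evenly over ``n_pools`` independently drawn gene
    pools of ``n_genes`` genes each; every sample gets a fresh
    heterogeneity level in [0, 1) and randomized isoform fractions, from
    which both a gene-level fraction table and a junction profile are
    derived. Returns rows (pool, sample, ith_transcript, ith_intron);
    ``ith_intron`` is NaN for the rare sample with no usable unit.
    """
    if n_samples < n_pools:
        raise ValueError("n_samples must be >= n_pools")
    rng = np.random.default_rng(seed)
    rows = []
    sample_idx = 0
    per_pool = n_samples // n_pools
    extra = n_samples % n_pools
    for pool in range(n_pools):
        genes = generate_gene_models(
            n_genes, isoform_range, regions_per_gene, seed=int(rng.integers(2**31 - 1))
        )
        pool_samples = per_pool + (1 if pool < extra else 0)
        for _ in range(pool_samples):
            h = float(rng.uniform(0.0, 1.0))
            fractions = sample_isoform_fractions(genes, h, rng)
            profile = junction_profile_from_fractions(
                genes, fractions, depth, rng, sample_id=f"s{sample_idx}"
            )
            ith_t = transcript_entropy(fractions)
            ith_i = intron_entropy(profile, config)
            rows.append(
                (pool, sample_idx, ith_t, np.nan if ith_i is None else ith_i)
            )
            sample_idx += 1
    return pd.DataFrame(
        rows, columns=["pool", "sample", "ith_transcript", "ith_intron"]
    )
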