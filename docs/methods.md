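# Methods

## Model

`splicehet` quantifies how far a tumor sample's splice-site usage has
drifted from a normal reference, junction table in, one number out.

**Splicing units.** Junctions are grouped by connected components of the
"shares a splice-site coordinate (either endpoint) on the same chromosome
and strand" relation. Components — not donor-only groups — are required so
that a junction sharing its donor with one neighbour and its acceptor with
another lands in exactly one unit: the units partition the junction set.
Strand classes `+`, `-` and `.` (unknown; spliced aligners emit it for
noncanonical junctions) never merge, because antisense overlapping genes
can share coordinates without sharing splicing events. Units are purely
coordinate-derived; no annotation is consulted.

**Harmonization.** For a pairwise score the units are built on the union
of both samples' junctions, so both samples see the same unit over the
same intronic region; a junction unobserved in one sample enters that
sample's count vector as 0.

**Filtering.** Two rules, both configurable (`SithConfig`):

* `min_members` (default 2): a singleton unit has a one-point usage
  distribution whose JSD is identically 0; keeping singletons only dilutes
  the mean. Setting `min_members=1` restores them.
* `min_reads` (default 1): a unit with fewer total reads than this in
  either sample is dropped as effectively absent there. A unit wholly
  unobserved in one sample cannot be pseudo-counted at all — the
  pseudo-count is a fraction of that sample's unit total, which is 0.

Dropped units are tallied by reason and reported.

**Pseudo-counts.** Where exactly one sample has count 0, that entry
becomes (that sample's own unit total) / `pseudocount_denominator`
(default 100). The observed sample's entries are not perturbed.
Renormalization happens after patching. The alternative reading — using
the *other* sample's unit total — changes little in practice but is not
what "the corresponding splicing unit" most plausibly means, since the
patch must be on the scale of the sample being patched.

**Divergence.** Per unit, the base-2 Jensen–Shannon divergence
`½·(KLD(P‖M) + KLD(Q‖M))` with midpoint `M = (P+Q)/2`, using the standard
non-negative KLD `Σ p·log2(p/m)` and the `0·log 0 = 0` convention. Base 2
makes the per-unit value live in [0, 1]; the implementation clamps the
~1e-16 negative round-off that arises at `P = Q`. The sITH is the
arithmetic mean over kept units; with zero kept units it is an explicit
`None`, never a silent 0. With several normal references the tumor's score
is the mean of the defined pairwise scores.

**Entropy measures.** The whole-transcript measure is the mean per-gene
Shannon entropy of isoform fractions; the intron-local measure is the mean
per-unit entropy of junction usage, computed with the same unit grouping
and filtering as the divergence core so both measures see identical unit
sets. The log base is 2 throughout for consistency; correlation readouts
between the two measures are base-invariant.

## Synthetic data generator

The generator emulates the statistical structure the score assumes, not
any particular dataset:

* **Normal tissue** (`generate_normal_profile`): `n_units` (default 300)
  independent units laid out on a synthetic genome (one shared donor, 2–4
  alternative acceptors, units spaced so no coordinates collide and
  grouping recovers the layout exactly). Per unit, usage is drawn from a
  symmetric Dirichlet (concentration 1.0 — no preferred sharpness), the
  total read count from a Poisson at mean `depth` (default 200 reads per
  unit, a deeply covered unit in bulk RNA-seq), and integer member counts
  from a multinomial, with one read guaranteed per member so every unit
  passes the default filters.
* **Cancer cells** (`perturb_profile`): per unit, a cell's usage is
  `(1−s)·normal + s·target` with a fresh Dirichlet target and mixing
  weight `s = perturbation_strength` (default 0.8: clones whose
  splice-site usage differs strongly from normal, as expected for
  distinct subclones). Cell counts are the expected counts at the unit's
  normal total — fractional, without resampling noise — so the `s → 0`
  limit reproduces normal usage exactly and divergence grows
  monotonically in `s`.
* **Mixtures** (`synthesize_mixture`): the count of junction *j* at mixing
  level *i* is exactly `NT(j)·(1−i/100) + Σ_{l≤i} SC(l,j)/100`. Counts stay
  fractional: the mixture model is defined on the arithmetic, not on
  resampled reads. The experiment driver generates one normal and 39
  distinct cells, then for each level 1..39 and each of 10 replicates
  draws the level's cells without replacement and scores the mixture
  against the normal; the readout is the Spearman correlation between
  level and sITH over all 390 rows.
* **Paired-entropy experiment** (`run_entropy_experiment`): 10 gene pools
  of 10 genes, each gene with 2–5 isoforms and 8 intronic regions whose
  random isoform-to-junction assignments are fixed per pool. Each of 200
  samples draws a heterogeneity level `h ∈ [0,1)`; the representative
  isoform keeps weight `1−h` and the rest share `h` in random proportions.
  Junction counts are Poisson at `depth × (summed fraction of the
  isoforms using the junction)` with default depth 100, mimicking the
  coverage consequence of the isoform mixture. Both entropy measures are
  computed per sample and correlated (Pearson); the rare sample with no
  usable unit (an extremely low `h` can zero out every alternative
  junction) is recorded as NaN and excluded.

Everything is a pure function of its seed; the experiment drivers derive
per-cell and per-pool seeds from the master seed.

**What passing these experiments does and does not show.** The generator
produces independent, well-covered units with union-identical junction
universes; real tumors add transcript-level coupling between junctions,
coverage that varies by orders of magnitude across units, novel junctions
absent from normals (available via the generator's novel-junction-free
design only as a strength-shift), single-cell dropout, and library-level
noise. Passing the synthetic experiments shows the score's arithmetic and
its monotone response to designed heterogeneity — not calibration on any
real cohort.

## Numerical choices

* Coordinates are 1-based, both-ends-inclusive intron positions (the STAR
  `SJ.out.tab` convention) everywhere internally; the only conversion is at
  parse time for strand codes.
* Counts default to uniquely-mapping reads; multimappers are opt-in, since
  they inflate noise junctions.
* Per-unit JSD is clamped to [0, 1] against float round-off.
* `kld` raises (rather than returns infinity) when `p` has mass where `m`
  has none: with the JSD midpoint this is unreachable and indicates a
  pseudo-counting bug upstream.
* Unit member order is canonical (by start, then end); unit ids encode the
  region as `chrom:minsite-maxsite(strand)`, making outputs byte-stable
  across runs.
* Undefined scores (`sITH`, intronic entropy with no usable units) are
  explicit `None`/`NA`/exit-code-3 states.

## Problem sizes

The default experiment sizes — 300 units at depth 200 with 39 cells × 10
replicates, and 200 entropy samples over 10 gene pools — are desk-scale
analogs of the validation experiments: large enough that the correlation
readouts are stable (the mixture experiment's Spearman changes by < 0.001
across seeds) while running in seconds.

## Known limitations

* No dropout model for the synthetic "single cells"; real single-cell
  junction capture is far sparser.
* Units are coordinate-chained: two genes whose introns happen to share a
  coordinate on the same strand would fuse into one unit; no splitting
  heuristic is applied.
* Whether singleton units should count toward `L` is a genuine modeling
  choice; both behaviors are supported via `min_members`, with the
  divergence-diluting singletons excluded by default.
* The score compares junction usage only; intron retention and other
  events invisible to junction counts are out of scope, as are read-level
  simulation, alignment and isoform-abundance estimation.
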