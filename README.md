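# splicehet

Spliceomic intratumor heterogeneity (sITH) from splice-junction counts.

Intratumor heterogeneity (ITH) — the diversity of cell subpopulations
within one tumor — is usually estimated from genomic data (subclone
reconstruction from somatic variants), which is expensive and
annotation-heavy. Aberrant splicing is pervasive in cancer, and the mix of
subclones in a bulk tumor leaves a signature in how splice sites are used.
`splicehet` scores that signature directly from the splice-junction counts
a spliced aligner already produces (e.g. STAR's `SJ.out.tab`), with no gene
or transcript annotation: it is aimed at anyone with bulk RNA-seq of a
tumor and one or more normal reference samples who wants a cheap,
annotation-free ITH proxy.

## The score

Splice junctions sharing a splice-site coordinate (donor or acceptor) on
the same chromosome and strand are grouped into **intronic splicing
units** — the connected components of the shares-a-site relation. Within
unit *k*, a sample's **usage distribution** is

    P_k(i) = CNT_k(i) / Σ_j CNT_k(j),

the fraction of reads supporting the *i*-th alternative junction. The
divergence of splice-site usage between samples *P* and *Q* in one unit is
the Jensen–Shannon divergence with base-2 logarithms,

    JSD(P_k, Q_k) = ½ [ KLD(P_k ‖ M_k) + KLD(Q_k ‖ M_k) ],
    M_k = (P_k + Q_k) / 2,

which is symmetric and bounded in [0, 1] (0 = identical usage, 1 =
disjoint usage). The score of a tumor *P* against a normal origin *Q* is
the mean over the *L* usable units:

    sITH(P, Q) = (1/L) Σ_k JSD(P_k, Q_k).

Using a normal reference subtracts the splicing heterogeneity normal
tissue already has, leaving the perturbation accumulated during cancer
progression. A splice site observed in only one sample receives a
pseudo-count of 1/100 of that sample's total reads in the unit before
normalization. With several normal references, the tumor's score is the
mean of its pairwise scores.

The package also implements two single-sample Shannon-entropy measures
used to validate the intron-local view (mean per-gene isoform entropy and
mean per-unit usage entropy), a synthetic junction-profile generator, and
the in-silico mixture model `MIX(i,j) = NT(j)·(1−i/100) + Σ_l SC(l,j)/100`
that blends *i* single-cell profiles into a normal profile at 1% per cell.

## Worked example

Two samples sharing two splicing units: a three-way shared-donor unit on
chr1 (the normal sample misses the middle junction) and a two-way unit on
chr2 with identical usage in both samples.

```python
from splicehet import JunctionProfile, sith_pair

tumor = JunctionProfile("tumor", {
    ("chr1", 100, 200, "+"): 5.0,
    ("chr1", 100, 300, "+"): 3.0,
    ("chr1", 100, 400, "+"): 2.0,
    ("chr2", 50, 99, "+"): 10.0,
    ("chr2", 50, 120, "+"): 10.0,
})
normal = JunctionProfile("normal", {
    ("chr1", 100, 200, "+"): 4.0,
    ("chr1", 100, 400, "+"): 6.0,
    ("chr2", 50, 99, "+"): 10.0,
    ("chr2", 50, 120, "+"): 10.0,
})

result = sith_pair(tumor, normal)
print(f"sITH = {result.sith:.6f} over L = {result.L} units")
for ud in result.unit_divergences:
    print(f"  {ud.unit_id}  JSD = {ud.jsd:.6f}")
```

prints

```
sITH = 0.100723 over L = 2 units
  chr1:100-400(+)  JSD = 0.201446
  chr2:50-120(+)  JSD = 0.000000
```

The chr1 unit compares tumor usage (0.5, 0.3, 0.2) with normal counts
(4, 0, 6): the unobserved middle junction gets the pseudo-count
10/100 = 0.1, giving normal usage ≈ (0.396, 0.0099, 0.594) and a JSD of
0.201. The chr2 unit has identical usage, JSD 0. The sITH is their mean.

The same workflows are available from the shell:

```sh
splicehet sith tumor.tsv --ref normal1.tsv --ref normal2.tsv --per-unit --out report.tsv
splicehet entropy --fractions isoforms.tsv --junctions sample.tsv
splicehet simulate --seed 1 --out mixtures.tsv --stats stats.tsv
```

`sith` accepts STAR `SJ.out.tab` tables with `--format star-sj` (counting
uniquely-mapping reads by default; add `--include-multimappers` to count
column 8 as well).

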