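# rgene-atlas

Genome-wide analysis of the NBS-LRR (NLR) disease-resistance gene landscape
of a plant genome: domain-architecture classification, physical gene-cluster
detection, Monte-Carlo significance of clustering, and the summary
accounting a resistance-gene survey reports.

It is a library for bioinformaticians who already have a genome annotation
(GFF3) and per-gene domain evidence (hmmscan-style NB-ARC/TIR/RPW8/LRR hits,
Paircoil-style coiled-coil p-scores, optional similarity hits) and want the
downstream landscape analysis to be reproducible and testable. A
synthetic-data generator produces whole annotations with known ground truth,
so every stage can be validated without any downloads.

## What it computes

**Architecture classification.** Each gene's evidence is reduced to a letter
code over its domains — T (TIR), C (coiled-coil), N (NBS/NB-ARC), L (LRR):
`TNL, TN, N_TIR, NL_TIR` (TNL-type family), `CNL, CN, N_CC, NL_CC`
(CNL-type), and `P` for partial genes lacking an intact NB-ARC. A gene has a
*full* NBS when its best NB-ARC hit passes E ≤ 0.01 **and** covers ≥ 90% of
the reference domain length; coiled-coils call at Paircoil p-score ≤ 0.03.
Bare-NBS genes are typed TIR- vs CC-side by a clade label or by the
diagnostic residue right after the kinase-2 motif (D → TIR-type,
W → CC-type), with the mechanism recorded per gene.

**Cluster detection.** A cluster is a maximal chain of ≥ 2 NBS-LRR genes in
which every consecutive pair lies < 200 kb apart with ≤ 8 intervening
non-NBS genes (chaining is transitive, so spans can exceed 200 kb).
Clusters are labelled homogeneous/heterogeneous by family and by clade.

**Clustering null.** Significance of cluster-size frequencies comes from
re-running the detector on 1000 random gene samples of the observed size
drawn from the annotation, with add-one empirical p-values
`p(s) = (1 + #{iterations with count(s) ≥ observed(s)}) / (n_iter + 1)`.

**Summary accounting.** Letter-code counts, CNL:TNL ratio, exon-count means
per group, mapped (chromosome-anchored) fractions, per-chromosome class
breakdowns, and expressed fractions (FPKM > 1 in any sample).

## Worked example

`examples/landscape_summary.py` generates the default synthetic study
conditions (30,666 genes on 18 chromosomes, 327 NBS-LRR genes with the
reference class mix) and prints:

```
NBS-LRR genes: 327 total = 228 full-length + 99 partial
families: 181 CNL-type, 47 TNL-type (ratio 3.85)
mapped to chromosomes: 205 (63%)
mean exons: all genes 6.15, full-length NBS 3.36, CNL 2.81, TNL 5.49
single-exon CNL-type genes: 35%
expressed (FPKM > 1): 72% of full-length, 77% of partial genes
```

i.e. the CNL subfamily dominates roughly 3.8:1, full-length NBS genes carry
about half as many exons as the genome average, and about a third of
NBS-LRR genes sit on unanchored scaffolds. `examples/cluster_significance_null.py`
shows the null in action — clusters planted at sizes 4–5 come out with
p ≈ 0.001 while sizes 2–3 occur at background rates (p = 1):

```
 size  observed  null_mean  null_sd  empirical_p
    2         0     10.558 2.938583     1.000000
    3         0      0.636 0.828366     1.000000
    4         2      0.035 0.183872     0.000999
    5         2      0.002 0.044699     0.000999
```

The other examples cover classification (`classify_synthetic_genome.py`)
and cluster detection with homogeneity labels (`find_gene_clusters.py`).

## Command line

A thin CLI wraps the same functions:

```sh
rgene-atlas synth --outdir synth --seed 1
rgene-atlas classify --gff synth/genes.gff3 --domains synth/domains.tsv \
    --cc synth/cc.tsv --chromosomes chr1,chr2 --out calls.tsv
rgene-atlas cluster --gff synth/genes.gff3 --focal calls.tsv \
    --max-gap 200000 --max-intervening 8 --out-prefix clusters
rgene-atlas null --gff synth/genes.gff3 --n-sample 205 --iterations 1000 \
    --seed 42 --out null.json
rgene-atlas run-all --config cfg.yaml
```

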