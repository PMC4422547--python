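# Methods

## The problem and the model

Plant NBS-LRR (NLR) resistance genes are recognised by their domain
architecture — a central nucleotide-binding NB-ARC domain, C-terminal
leucine-rich repeats, and an N-terminal TIR, coiled-coil (CC) or RPW8
domain — and by their strong tendency to occur in physical clusters that
arise from tandem duplication. This package implements the standard survey
of such a landscape as a deterministic, testable pipeline over four
operations: per-gene architecture classification, physical cluster
detection, a random-gene-sample significance null, and summary accounting.

## Classification cascade

Evidence per gene: NB-ARC/TIR/RPW8/LRR domain hits (E-value, alignment
coordinates, fraction of the reference domain covered), a coiled-coil
p-score, an optional similarity hit against known full-length NLRs, and an
optional kinase-2 diagnostic residue.

NBS status is `full` when the best NB-ARC hit has E ≤ `pass_evalue` (0.01)
and coverage ≥ `nbs_full_coverage_min` (0.90); `partial` when the E-value
passes but coverage does not; `absent` otherwise. The stricter
`hq_evalue` (1e-20) marks the high-confidence tier of the two-pass
profile-search protocol the thresholds mirror; the searches themselves are
upstream of this package, which consumes their tabular output. Genes
without an intact NB-ARC are `P` (family *partial*) when a truncated
NB-ARC hit or a similarity hit still ties them to the family — the spec of
record defines only the "partial + similarity" and "absent + nothing"
corners; we treat a sub-coverage NB-ARC hit alone as sufficient for P so
the letter-code function is total. Genes with neither are not NLRs.

Accessory domains call at `accessory_evalue` (1e-4), a conventional
Pfam-style cutoff exposed in config since no published threshold exists for
them. Coiled-coils call at p-score ≤ 0.03. N-terminal precedence on
conflicting evidence is RPW8 > TIR > CC (logged, flagged); RPW8 genes are
counted inside the CNL-type family with an `rpw8` flag, matching the usual
tabulation that has no separate RPW8 row.

Bare-NBS genes (no N-terminal domain evidence) are typed by a fallback
chain: explicit clade label first, then the kinase-2 diagnostic residue
(D → TIR-side, W → CC-side), else they default to the majority CNL-type
family with `nterm_type = unknown`. Both mechanisms are plausible routes to
the published N_CC/N_TIR split; the per-gene `nterm_type_source` records
which fired. `phylogeny_eligible` marks genes whose NB-ARC passed the
coverage bar — the set a 250-aa post-p-loop alignment window would accept.

## Cluster rule

Two consecutive focal genes chain when (i) their distance is **strictly**
under `max_gap_bp` (200 kb) and (ii) at most `max_intervening` (8,
**inclusive**) non-focal genes lie between them. Distance defaults to
nearest-edge (downstream start − upstream end, floored at 0 for overlapping
models); midpoint and start-to-start anchors are switchable because the
rule's literature source does not state the anchor. Intervening genes are
counted by rank in the per-sequence (start, end, gene_id) total order —
unambiguous even for nested or overlapping gene models. Chaining is
transitive: the rule binds consecutive pairs only, so a 10-member cluster
may span far more than 200 kb. Strand is ignored. Focal genes on
unanchored scaffolds are reported `unmapped` and never cluster. A
"supercluster" merge within a configurable window (default 1 Mb) exists as
a descriptive convenience only and is clearly not part of the rule.

## Significance null

Each of `n_iter` (1000) iterations draws `n_sample` (205) genes uniformly
without replacement and re-runs the detector. Sampling defaults to
anchored genes only: the observed focal set is the anchored NBS genes, and
sampling unanchored genes would deflate clustering by construction
(`all_genes` mode exists for sensitivity checks). Empirical p-values use
the add-one estimator, conservative and never zero, per exact size by
default with a tail-aggregated (≥ s) mode. Every iteration must satisfy
Σ size·count + singletons + unmapped = n_sample; this is asserted on every
run. The RNG is numpy PCG64 seeded explicitly; identical configs give
bit-identical distributions.

## Summary accounting

Letter-code counts partition into family totals (CNL-type =
CNL+CN+N_CC+NL_CC, analogously TNL-type; full-length = their sum; total
adds partials). The CNL:TNL ratio is kept unrounded; rendered values round
half-up (integers for percentages, one decimal for ratios, two for means).
"Expressed" means FPKM **strictly** greater than the threshold (default 1)
in at least one selected sample. The mapped percentage is
100·anchored/total over NBS-family genes, partials included.

## Synthetic study conditions

The generator's defaults are the study conditions: 30,666 genes on 18
chromosomes of 30 Mb; 327 NBS genes in the reference class mix
(117 CNL, 11 CN, 10 N_CC, 43 NL_CC, 29 TNL, 5 TN, 4 N_TIR, 9 NL_TIR, 99 P,
allocated by largest remainder so the composition is exact); 122/327 of
the NBS genes unanchored (the published mapped count, 205, and the "37%
unmapped" statement disagree by one gene; we pin the explicit count 205);
39 planted clusters totalling 143 genes with sizes 2–10 (the published
size range; the exact spectrum is not published, so a fixed composition —
two 10s down to fourteen 2s — was chosen once); exon counts from shifted
Poisson distributions (1 + Poisson(mean−1)) matched to group means 6.17
(background), 2.82 (CNL-type, with exactly 35% planted single-exon and the
multi-exon mean adjusted to keep the group mean), 5.48 (TNL-type);
expression planted deterministically so exactly round(0.72·n_full) and
round(0.77·n_partial) genes exceed FPKM 1.

Placement puts each cluster or singleton in an isolated block: within a
cluster, consecutive members sit `gap_bp` (20 kb) apart with exactly
`intervening` (2) background genes inside each gap; blocks are separated by
≥ 260 kb, which breaks the distance condition outright regardless of
intervening counts. Remaining background genes fill the inter-block space
evenly with bounded jitter (uniform density, guaranteed non-overlap). A
post-hoc checker in the test suite validates these margins from raw
coordinates, independently of the cluster finder under test.

What the generator does **not** emulate: real gene-density heterogeneity
along chromosomes (background is uniform), sequence content (no
nucleotides or proteins beyond the kinase-2 residue column), evidence noise
structure (hits are drawn from clean score ranges on the correct side of
every threshold), or mis-annotation. Passing tests therefore demonstrate
the correctness of the pipeline's logic under its stated rules, not
robustness to noisy real-world evidence.

## Numerical and design choices

- Coordinates are 1-based inclusive internally (GFF3 dialect); BED export
  converts to 0-based half-open at the boundary only.
- Gene order ties break by (start, end, gene_id) — a total order is needed
  for reproducible intervening-gene counts.
- Genes with no linkable exon features get `exon_count = 1` with a warning.
- The "manual curation" removal step is modelled as an explicit exclusion
  list, not reproduced algorithmically.
- The kinase-2 residue travels in its own optional `kinase2.tsv` table
  (gene_id, residue), since none of the standard evidence tables carries it.
- Empirical problem sizes used by the test suite — 1,000 random genomes for
  the cluster-rule oracle, 2,000 null iterations for the dual-route
  Monte-Carlo comparison, a 30,000-gene uniform universe for the null's
  property checks — were chosen to make sampling error small relative to
  the asserted tolerances (3 combined standard errors for means).

## Known limitations

- The classifier trusts the supplied coverage fraction; it does not compute
  NB-ARC reference lengths.
- The null is spatially uniform per draw; scan statistics or density-aware
  nulls are out of scope.
- Tree inference, motif discovery, read alignment and differential
  expression are upstream/downstream of this package and are consumed or
  ignored as inputs, never re-implemented.
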