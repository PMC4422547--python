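"""Synthetic genome annotations with known NBS-LRR ground truth.

The generator emulates the study system: a multi-chromosome annotation of
~30.7k protein-coding genes of which 327 are NBS-LRR candidates with the
cassava-like class mix (181 CNL-type, 47 TNL-type, 99 partial), ~37% of the
NBS genes on unanchored scaffolds, physical clusters planted with explicit
margins around the cluster rule, exon counts drawn from shifted-Poisson
distributions matched to the observed group means, and a deterministic
share of constitutively expressed genes.

Every emitted file uses the formats ``annotation_io`` reads, and a
``truth.json`` records per-gene codes, planted cluster memberships and the
expected summary values, so each downstream stage can be checked against
construction rather than against itself.

Placement layout: NBS genes are laid out as isolated "blocks" (one block per
planted cluster or singleton) separated by at least ``isolation_bp`` — more
than the rule's distance cap, so no two blocks can ever link.  Within a
cluster block, consecutive members sit ``gap_bp`` apart with exactly
``intervening`` background genes evenly spaced inside each gap.  Remaining
background genes fill the inter-block space evenly with bounded jitter,
which keeps density uniform without overlapping gene models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation_io import (
    DomainEvidence,
    DomainHit,
    GeneModel,
    GenomeAnnotation,
    SimilarityHit,
    write_domain_evidence,
    write_gene_models,
)
from .architecture_classifier import (
    ArchitectureCall,
    CNL_TYPE_CODES,
    TNL_TYPE_CODES,
)
from .cluster_finder import ClusterRule

# Reference class mix (cassava-like landscape): letter code -> gene count.
TABLE1_CLASS_COUNTS: dict[str, int] = {
    "CNL": 117, "CN": 11, "N_CC": 10, "NL_CC": 43,
    "TNL": 29, "TN": 5, "N_TIR": 4, "NL_TIR": 9,
    "P": 99,
}

# Default planted layout: 39 clusters totalling 143 genes, sizes 2-10,
# mirroring the observed cluster-size range.
DEFAULT_PLANTED_SIZES: tuple[int, ...] = (
    10, 10, 9, 6, 6, 5, 5, 5, 5,
    4, 4, 4, 4, 4, 4,
    3, 3, 3, 3, 3, 3, 3, 3, 3, 3,
    2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2,
)


@dataclass(frozen=True)
class PlantedCluster:
    size: int
    gap_bp: int = 20_000       # edge gap between consecutive members
    intervening: int = 2       # background genes inside each gap

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("planted cluster size must be >= 2")


def _default_planted() -> list[PlantedCluster]:
    return [PlantedCluster(size=s) for s in DEFAULT_PLANTED_SIZES]


def scaled_planted(
    n_anchored_nbs: int,
    frac_clustered: float = 143 / 205,
) -> list[PlantedCluster]:
    """Planted layout scaled to a smaller genome.

    Greedily keeps the default size spectrum while the clustered-gene total
    stays within ``frac_clustered`` of the anchored NBS budget (the observed
    clustered share is ~70%).
    """
    target = int(n_anchored_nbs * frac_clustered)
    out: list[PlantedCluster] = []
    total = 0
    for s in DEFAULT_PLANTED_SIZES:
        if total + s <= target:
            out.append(PlantedCluster(size=s))
            total += s
    return out


def _default_proportions() -> dict[str, float]:
    total = sum(TABLE1_CLASS_COUNTS.values())
    return {k: v / total for k, v in TABLE1_CLASS_COUNTS.items()}


@dataclass(frozen=True)
class ExonMeans:
    all_genes: float = 6.17
    cnl: float = 2.82
    tnl: float = 5.48
    frac_cnl_single_exon: float = 0.35


@dataclass(frozen=True)
class ExpressionFracs:
    full: float = 0.72
    partial: float = 0.77


@dataclass(frozen=True)
class SynthConfig:
    n_chromosomes: int = 18
    chromosome_length_bp: int = 30_000_000
    n_genes_total: int = 30_666
    n_nbs: int = 327
    class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    planted_clusters: list[PlantedCluster] = field(default_factory=_default_planted)
    # 122/327: pins the anchored NBS count at 205 under the defaults
    frac_unanchored: float = 122 / 327
    exon_means: ExonMeans = field(default_factory=ExonMeans)
    expression_fracs: ExpressionFracs = field(default_factory=ExpressionFracs)
    seed: int = 0
    gene_length_bp: int = 2_000
    rule: ClusterRule = field(default_factory=ClusterRule)
    isolation_bp: int = 260_000  # > rule.max_gap_bp: blocks can never link

    def __post_init__(self) -> None:
        s = sum(self.class_proportions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {s}, not 1")
        if not 0.0 <= self.frac_unanchored <= 1.0:
            raise ValueError("frac_unanchored outside [0, 1]")
        if self.isolation_bp <= self.rule.max_gap_bp:
            raise ValueError("isolation_bp must exceed the rule's max_gap_bp")
        if sum(p.size for p in self.planted_clusters) > self.n_nbs:
            raise ValueError("planted cluster sizes exceed n_nbs")


@dataclass(slots=True)
class SynthPaths:
    gff: Path
    domains: Path
    cc: Path
    similarity: Path
    kinase2: Path
    clades: Path
    expression: Path
    truth: Path


def largest_remainder(proportions: dict[str, float], total: int) -> dict[str, int]:
    """Integer allocation of *total* across categories (deterministic)."""
    keys = sorted(proportions)
    raw = {k: proportions[k] * total for k in keys}
    counts = {k: int(raw[k]) for k in keys}
    leftover = total - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:leftover]:
        counts[k] += 1
    return counts


def _shifted_poisson(rng: np.random.Generator, mean: float, n: int,
                     floor: int = 1) -> np.ndarray:
    """floor + Poisson(mean - floor); degenerate at the floor for small means."""
    lam = max(0.0, mean - floor)
    return floor + rng.poisson(lam, size=n)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _place_chromosome(
    rng: np.random.Generator,
    blocks: list[PlantedCluster | None],  # None = singleton NBS block
    n_background: int,
    length: int,
    cfg: SynthConfig,
) -> tuple[list[tuple[int, int]], list[list[int]], list[int]]:
    """Lay out one chromosome.

    Returns (background_starts_and_ends, focal_positions_per_cluster_block,
    singleton_positions); all positions are gene start coordinates.
    """
    L = cfg.gene_length_bp
    cursor = 100_000
    cluster_focal: list[list[int]] = []
    singleton_pos: list[int] = []
    background: list[tuple[int, int]] = []  # (start, end) of bg genes
    spans: list[tuple[int, int]] = []       # block extents, to keep bg out

    for blk in blocks:
        start = cursor + int(rng.integers(0, 100_000))
        if blk is None:
            singleton_pos.append(start)
            block_end = start + L - 1
        else:
            positions = []
            pos = start
            for i in range(blk.size):
                positions.append(pos)
                if i < blk.size - 1:
                    gap_start = pos + L  # first bp after this gene
                    # intervening background genes evenly inside the gap
                    step = blk.gap_bp / (blk.intervening + 1)
                    if step < 2 * L and blk.intervening > 0:
                        raise ValueError(
                            f"planted gap {blk.gap_bp} too small for "
                            f"{blk.intervening} intervening genes of {L} bp")
                    for j in range(blk.intervening):
                        b_start = int(gap_start + (j + 1) * step - L)
                        background.append((b_start, b_start + L - 1))
                    pos = pos + L + blk.gap_bp
            cluster_focal.append(positions)
            block_end = positions[-1] + L - 1
        spans.append((start, block_end))
        cursor = block_end + cfg.isolation_bp

    if cursor > length - 100_000:
        raise ValueError(
            f"infeasible packing: {len(blocks)} NBS blocks need ~{cursor} bp "
            f"but the chromosome is {length} bp")

    # background fill in the free intervals between/around blocks
    free: list[tuple[int, int]] = []
    prev = 10_000
    for s, e in spans:
        if s - 1_000 > prev:
            free.append((prev, s - 1_000))
        prev = e + 1_000
    if length - 10_000 > prev:
        free.append((prev, length - 10_000))
    total_free = sum(e - s for s, e in free)
    if n_background > 0 and total_free < n_background * 2 * L:
        raise ValueError("infeasible packing: background genes exceed free space")
    alloc = largest_remainder(
        {str(i): (e - s) / total_free for i, (s, e) in enumerate(free)},
        n_background) if free else {}
    for i, (s, e) in enumerate(free):
        n = alloc.get(str(i), 0)
        if n == 0:
            continue
        spacing = (e - s) / (n + 1)
        jitter_max = max(0.0, 0.25 * (spacing - L))
        for j in range(n):
            b = int(s + (j + 1) * spacing - L / 2
                    + rng.uniform(-jitter_max, jitter_max))
            background.append((b, b + L - 1))
    return background, cluster_focal, singleton_pos


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

def _evidence_for_code(
    gene_id: str, code: str, rng: np.random.Generator, alt_partial: bool,
) -> DomainEvidence:
    """Emit evidence the classifier must map back to *code*."""
    ev = DomainEvidence(gene_id=gene_id)
    tir_side = code in TNL_TYPE_CODES

    def nbarc(e_value: float, coverage: float) -> None:
        ev.domain_hits.append(DomainHit("NBARC", "PF00931", e_value, 10,
                                        10 + int(280 * coverage), coverage))

    if code == "P":
        if alt_partial:
            # truncated NB-ARC: passes E-value, fails the coverage bar
            nbarc(float(rng.uniform(1e-8, 1e-5)), float(rng.uniform(0.2, 0.6)))
        ev.similarity_hit = SimilarityHit("REF_NLR_%03d" % rng.integers(1, 200),
                                          float(rng.uniform(70, 98)))
        ev.cc_pscore = float(rng.uniform(0.2, 0.9))
        return ev

    nbarc(float(10.0 ** rng.uniform(-60, -25)), float(rng.uniform(0.92, 1.0)))
    has_nterm = code in ("CNL", "CN", "TNL", "TN")
    has_lrr = code in ("CNL", "NL_CC", "TNL", "NL_TIR")
    if has_nterm and tir_side:
        ev.domain_hits.append(DomainHit("TIR", "PF01582",
                                        float(10.0 ** rng.uniform(-30, -8)),
                                        1, 150, float(rng.uniform(0.8, 1.0))))
    if has_lrr:
        ev.domain_hits.append(DomainHit("LRR", "PF00560",
                                        float(10.0 ** rng.uniform(-15, -5)),
                                        600, 850, float(rng.uniform(0.6, 1.0))))
    if has_nterm and not tir_side:
        ev.cc_pscore = float(rng.uniform(0.001, 0.025))
    else:
        ev.cc_pscore = float(rng.uniform(0.2, 0.9))
    ev.kinase2_next_residue = "D" if tir_side else "W"
    return ev


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate(cfg: SynthConfig, outdir: str | Path) -> tuple[SynthPaths, dict]:
    """Write the synthetic annotation + evidence tables; return paths and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    class_counts = largest_remainder(cfg.class_proportions, cfg.n_nbs)
    n_unanchored = int(round(cfg.frac_unanchored * cfg.n_nbs))
    n_anchored = cfg.n_nbs - n_unanchored
    n_planted = sum(p.size for p in cfg.planted_clusters)
    if n_planted > n_anchored:
        raise ValueError(
            f"planted clusters need {n_planted} anchored NBS genes but only "
            f"{n_anchored} are anchored under frac_unanchored={cfg.frac_unanchored}")
    n_singletons = n_anchored - n_planted

    # distribute blocks round-robin over chromosomes (largest blocks first,
    # so no chromosome gets all the big clusters)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    blocks_per_chrom: list[list[PlantedCluster | None]] = [[] for _ in chroms]
    ordered = sorted(cfg.planted_clusters, key=lambda p: -p.size)
    for i, blk in enumerate(ordered):
        blocks_per_chrom[i % cfg.n_chromosomes].append(blk)
    for i in range(n_singletons):
        blocks_per_chrom[(i + len(ordered)) % cfg.n_chromosomes].append(None)

    n_bg_total = cfg.n_genes_total - cfg.n_nbs
    intervening_bg = sum(p.intervening * (p.size - 1) for p in cfg.planted_clusters)
    n_bg_fill = n_bg_total - intervening_bg
    if n_bg_fill < 0:
        raise ValueError("not enough background genes for the planted intervening slots")
    bg_alloc = largest_remainder(
        {c: 1.0 / cfg.n_chromosomes for c in chroms}, n_bg_fill)

    genes: list[GeneModel] = []
    cluster_truth: list[dict] = []
    singleton_ids: list[str] = []
    nbs_ids: list[str] = []
    bg_counter = 0
    nbs_counter = 0
    L = cfg.gene_length_bp

    def new_bg(seq_id: str, start: int, end: int) -> GeneModel:
        nonlocal bg_counter
        bg_counter += 1
        return GeneModel(f"BG{bg_counter:05d}", seq_id, start, end,
                         strand="+" if rng.random() < 0.5 else "-",
                         anchored=True)

    def new_nbs(seq_id: str, start: int, anchored: bool) -> GeneModel:
        nonlocal nbs_counter
        nbs_counter += 1
        gid = f"NBS{nbs_counter:04d}"
        nbs_ids.append(gid)
        return GeneModel(gid, seq_id, start, start + L - 1,
                         strand="+" if rng.random() < 0.5 else "-",
                         anchored=anchored)

    for ci, seq_id in enumerate(chroms):
        background, cluster_focal, singleton_pos = _place_chromosome(
            rng, blocks_per_chrom[ci], bg_alloc[seq_id],
            cfg.chromosome_length_bp, cfg)
        for s, e in background:
            genes.append(new_bg(seq_id, s, e))
        for positions in cluster_focal:
            members = []
            for pos in positions:
                g = new_nbs(seq_id, pos, anchored=True)
                genes.append(g)
                members.append(g.gene_id)
            cluster_truth.append({
                "seq_id": seq_id,
                "members": members,
                "span_start": positions[0],
                "span_end": positions[-1] + L - 1,
            })
        for pos in singleton_pos:
            g = new_nbs(seq_id, pos, anchored=True)
            genes.append(g)
            singleton_ids.append(g.gene_id)

    unanchored_ids: list[str] = []
    for i in range(n_unanchored):
        g = new_nbs(f"scaffold_{i + 1:05d}", 5_000, anchored=False)
        genes.append(g)
        unanchored_ids.append(g.gene_id)

    cluster_truth.sort(key=lambda c: (c["seq_id"], c["span_start"]))
    for i, c in enumerate(cluster_truth, start=1):
        c["cluster_id"] = f"T{i:03d}"

    # --- class codes: random assignment of the fixed composition ----------
    code_pool: list[str] = []
    for code in sorted(class_counts):
        code_pool.extend([code] * class_counts[code])
    code_pool = [code_pool[i] for i in rng.permutation(len(code_pool))]
    codes = dict(zip(nbs_ids, code_pool))

    # --- evidence, clades, kinase-2 ---------------------------------------
    evidence: dict[str, DomainEvidence] = {}
    clades: dict[str, str] = {}
    cc_clades = ("CC-1a", "CC-1b", "CC-2")
    for i, gid in enumerate(nbs_ids):
        code = codes[gid]
        evidence[gid] = _evidence_for_code(gid, code, rng, alt_partial=i % 2 == 0)
        if code in TNL_TYPE_CODES:
            clades[gid] = "TIR"
        elif code in CNL_TYPE_CODES:
            clades[gid] = cc_clades[int(rng.integers(0, len(cc_clades)))]
        # bare-NBS genes keep their clade only half the time, so both the
        # clade and the kinase-2 fallback paths see traffic
        if code in ("N_CC", "NL_CC", "N_TIR", "NL_TIR") and i % 2 == 1:
            clades.pop(gid, None)

    # --- exon counts -------------------------------------------------------
    exon_counts: dict[str, int] = {}
    bg_ids = [g.gene_id for g in genes if g.gene_id.startswith("BG")]
    for gid, n in zip(bg_ids, _shifted_poisson(rng, cfg.exon_means.all_genes,
                                               len(bg_ids))):
        exon_counts[gid] = int(n)
    cnl_ids = [gid for gid in nbs_ids if codes[gid] in CNL_TYPE_CODES]
    tnl_ids = [gid for gid in nbs_ids if codes[gid] in TNL_TYPE_CODES]
    partial_ids = [gid for gid in nbs_ids if codes[gid] == "P"]
    n_single = int(round(cfg.exon_means.frac_cnl_single_exon * len(cnl_ids)))
    cnl_perm = [cnl_ids[i] for i in rng.permutation(len(cnl_ids))]
    for gid in cnl_perm[:n_single]:
        exon_counts[gid] = 1
    multi = cnl_perm[n_single:]
    # conditional mean for multi-exon CNLs keeps the group mean on target
    f1 = cfg.exon_means.frac_cnl_single_exon
    multi_mean = (cfg.exon_means.cnl - f1) / (1 - f1) if f1 < 1 else 2.0
    for gid, n in zip(multi, _shifted_poisson(rng, multi_mean, len(multi), floor=2)):
        exon_counts[gid] = int(n)
    for gid, n in zip(tnl_ids, _shifted_poisson(rng, cfg.exon_means.tnl,
                                                len(tnl_ids))):
        exon_counts[gid] = int(n)
    for gid, n in zip(partial_ids, _shifted_poisson(rng, cfg.exon_means.all_genes,
                                                    len(partial_ids))):
        exon_counts[gid] = int(n)

    genes = [GeneModel(g.gene_id, g.seq_id, g.start, g.end, g.strand,
                       exon_counts.get(g.gene_id, 1), g.anchored)
             for g in genes]

    # --- expression (deterministic planting) -------------------------------
    full_ids = cnl_ids + tnl_ids
    n_full_expr = int(round(cfg.expression_fracs.full * len(full_ids)))
    n_part_expr = int(round(cfg.expression_fracs.partial * len(partial_ids)))
    full_perm = [full_ids[i] for i in rng.permutation(len(full_ids))]
    part_perm = [partial_ids[i] for i in rng.permutation(len(partial_ids))]
    expressed = set(full_perm[:n_full_expr]) | set(part_perm[:n_part_expr])
    expr_rows = []
    for gid in sorted(nbs_ids):
        fpkm = (float(rng.uniform(1.5, 60.0)) if gid in expressed
                else float(rng.uniform(0.0, 0.9)))
        expr_rows.append((gid, "leaf", fpkm))

    # --- write files --------------------------------------------------------
    chrom_lengths = {c: cfg.chromosome_length_bp for c in chroms}
    for i in range(n_unanchored):
        chrom_lengths[f"scaffold_{i + 1:05d}"] = 10_000
    annotation = GenomeAnnotation(genes, chrom_lengths)
    paths = SynthPaths(
        gff=outdir / "genes.gff3",
        domains=outdir / "domains.tsv",
        cc=outdir / "cc.tsv",
        similarity=outdir / "similarity.tsv",
        kinase2=outdir / "kinase2.tsv",
        clades=outdir / "clades.tsv",
        expression=outdir / "expression.tsv",
        truth=outdir / "truth.json",
    )
    write_gene_models(annotation, paths.gff)
    write_domain_evidence(evidence, paths.domains, paths.cc,
                          paths.similarity, paths.kinase2)
    with open(paths.clades, "w") as fh:
        fh.write("gene_id\tclade_label\n")
        for gid in sorted(clades):
            fh.write(f"{gid}\t{clades[gid]}\n")
    with open(paths.expression, "w") as fh:
        fh.write("gene_id\tsample\tfpkm\n")
        for gid, sample, fpkm in expr_rows:
            fh.write(f"{gid}\t{sample}\t{fpkm!r}\n")

    code_to_family = {**{c: "CNL_type" for c in CNL_TYPE_CODES},
                      **{c: "TNL_type" for c in TNL_TYPE_CODES},
                      "P": "partial"}
    truth = {
        "seed": cfg.seed,
        "chromosomes": chroms,
        "class_counts": class_counts,
        "codes": codes,
        "families": {gid: code_to_family[codes[gid]] for gid in nbs_ids},
        "clusters": cluster_truth,
        "singleton_ids": sorted(singleton_ids),
        "unanchored_ids": sorted(unanchored_ids),
        "n_anchored_nbs": n_anchored,
        "n_nbs": cfg.n_nbs,
        "n_genes_total": cfg.n_genes_total,
        "expression": {
            "n_full_expressed": n_full_expr,
            "n_partial_expressed": n_part_expr,
            "frac_full": n_full_expr / len(full_ids) if full_ids else None,
            "frac_partial": n_part_expr / len(partial_ids) if partial_ids else None,
        },
        "expressed_ids": sorted(expressed),
    }
    paths.truth.write_text(json.dumps(truth, indent=2))
    return paths, truth


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def table1_fixture() -> list[ArchitectureCall]:
    """Synthetic call list with the reference class composition (327 genes)."""
    code_to_family = {**{c: "CNL_type" for c in CNL_TYPE_CODES},
                      **{c: "TNL_type" for c in TNL_TYPE_CODES},
                      "P": "partial"}
    calls = []
    i = 0
    for code in ("CNL", "CN", "N_CC", "NL_CC", "TNL", "TN", "N_TIR", "NL_TIR", "P"):
        for _ in range(TABLE1_CLASS_COUNTS[code]):
            i += 1
            calls.append(ArchitectureCall(
                gene_id=f"NB{i:04d}",
                nbs_status="partial" if code == "P" else "full",
                letter_code=code,
                family=code_to_family[code],
                phylogeny_eligible=code != "P",
            ))
    return calls


def table1_annotation(
    calls: Sequence[ArchitectureCall],
    n_anchored: int = 205,
    spacing_bp: int = 1_000_000,
) -> GenomeAnnotation:
    """Minimal annotation for the fixture: first *n_anchored* calls on a
    chromosome (spaced too far apart to cluster), the rest on scaffolds."""
    genes = []
    for i, call in enumerate(calls):
        if i < n_anchored:
            start = 1 + i * spacing_bp
            genes.append(GeneModel(call.gene_id, "chr1", start, start + 1999,
                                   anchored=True))
        else:
            genes.append(GeneModel(call.gene_id, f"scaffold_{i:05d}", 1, 2000,
                                   anchored=False))
    return GenomeAnnotation(genes)
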