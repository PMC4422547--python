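"""Readers, writers and the shared genome model.

Everything downstream of this module works on :class:`GenomeAnnotation`, an
ordered collection of gene models, plus per-gene :class:`DomainEvidence`
assembled from external domain-scan tables (hmmscan-style domain hits,
Paircoil-style coiled-coil p-scores, optional sequence-similarity hits and an
optional kinase-2 diagnostic residue).

Coordinate conventions: the in-memory model is 1-based inclusive (the GFF3
dialect); BED export converts to 0-based half-open at the boundary and
nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

log = logging.getLogger(__name__)

DOMAIN_CLASSES = ("NBARC", "TIR", "RPW8", "LRR")


class AnnotationError(ValueError):
    """Raised for malformed annotation or evidence input."""


@dataclass(frozen=True, slots=True)
class GeneModel:
    """One annotated gene: coordinates are 1-based inclusive bp."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "."
    exon_count: int = 1
    anchored: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"gene {self.gene_id}: bad coordinates {self.start}..{self.end}"
            )
        if self.exon_count < 1:
            raise AnnotationError(f"gene {self.gene_id}: exon_count must be >= 1")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True, slots=True)
class DomainHit:
    domain_class: str  # one of DOMAIN_CLASSES
    accession: str
    e_value: float
    ali_start: int
    ali_end: int
    coverage_fraction: float

    def __post_init__(self) -> None:
        if self.domain_class not in DOMAIN_CLASSES:
            raise AnnotationError(f"unknown domain_class token {self.domain_class!r}")
        if self.e_value <= 0:
            raise AnnotationError(f"e_value must be > 0, got {self.e_value}")
        if self.ali_end < self.ali_start:
            raise AnnotationError("ali_end < ali_start")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise AnnotationError("coverage_fraction outside [0, 1]")


@dataclass(frozen=True, slots=True)
class SimilarityHit:
    subject_id: str
    percent_identity: float


@dataclass(slots=True)
class DomainEvidence:
    """All external observations for one gene (may be entirely empty)."""

    gene_id: str
    domain_hits: list[DomainHit] = field(default_factory=list)
    cc_pscore: float | None = None
    similarity_hit: SimilarityHit | None = None
    kinase2_next_residue: str | None = None

    def best_hit(self, domain_class: str) -> DomainHit | None:
        hits = [h for h in self.domain_hits if h.domain_class == domain_class]
        return min(hits, key=lambda h: h.e_value) if hits else None


class GenomeAnnotation:
    """Ordered set of gene models shared by all pipeline stages.

    The per-sequence ordering sorts by ``(start, end, gene_id)``; ranks in
    that total order drive the intervening-gene counts of the cluster rule.
    """

    def __init__(
        self,
        genes: Iterable[GeneModel],
        chromosome_lengths: Mapping[str, int] | None = None,
    ) -> None:
        genes = list(genes)
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
        self.chromosome_lengths: dict[str, int] = dict(chromosome_lengths or {})
        for g in genes:
            length = self.chromosome_lengths.get(g.seq_id)
            if length is not None and g.end > length:
                raise AnnotationError(
                    f"gene {g.gene_id} ends at {g.end} beyond {g.seq_id} "
                    f"length {length}"
                )
        self._by_seq: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_seq.setdefault(g.seq_id, []).append(g)
        for seq_genes in self._by_seq.values():
            seq_genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        self._by_id: dict[str, GeneModel] = {g.gene_id: g for g in genes}
        self._rank: dict[str, int] = {}
        for seq_genes in self._by_seq.values():
            for i, g in enumerate(seq_genes):
                self._rank[g.gene_id] = i

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __iter__(self):
        for seq_id in self.seq_ids():
            yield from self._by_seq[seq_id]

    def seq_ids(self) -> list[str]:
        return sorted(self._by_seq)

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self]

    def genes_on(self, seq_id: str) -> list[GeneModel]:
        """Genes on one sequence in (start, end, gene_id) order."""
        return self._by_seq.get(seq_id, [])

    def rank(self, gene_id: str) -> int:
        """0-based position of the gene within its sequence's total order."""
        return self._rank[gene_id]

    def anchored_ids(self) -> list[str]:
        return [g.gene_id for g in self if g.anchored]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gene_models(
    path: str | Path,
    chromosome_names: Sequence[str],
    chromosome_lengths: Mapping[str, int] | None = None,
) -> GenomeAnnotation:
    """Read gene features (with exon children) from a GFF3 file.

    ``anchored`` is set iff a gene's seq_id appears in *chromosome_names*.
    Exon counts come from ``exon`` features whose Parent resolves to the gene,
    directly or through one mRNA level; genes with no linkable exons get
    exon_count 1 with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise AnnotationError(f"malformed GFF3 {path}: {exc}") from exc

    chrom_set = set(chromosome_names)
    genes_raw: dict[str, gffutils.Feature] = {}
    parent_of: dict[str, str] = {}  # transcript id -> gene id
    exon_counts: dict[str, int] = {}
    errors: list[str] = []

    for feat in db.all_features():
        if feat.featuretype == "gene":
            gid = feat.attributes.get("ID", [feat.id])[0]
            if gid in genes_raw:
                raise AnnotationError(f"duplicate gene_id {gid!r} in {path}")
            genes_raw[gid] = feat
        elif feat.featuretype in ("mRNA", "transcript"):
            tid = feat.attributes.get("ID", [feat.id])[0]
            parents = feat.attributes.get("Parent", [])
            if parents:
                parent_of[tid] = parents[0]

    for feat in db.features_of_type("exon"):
        for parent in feat.attributes.get("Parent", []):
            gid = parent if parent in genes_raw else parent_of.get(parent)
            if gid is not None:
                exon_counts[gid] = exon_counts.get(gid, 0) + 1

    genes: list[GeneModel] = []
    for gid, feat in genes_raw.items():
        if feat.end < feat.start:
            errors.append(f"gene {gid}: end {feat.end} < start {feat.start}")
            continue
        n_exons = exon_counts.get(gid)
        if n_exons is None:
            log.warning("gene %s has no linkable exons; exon_count set to 1", gid)
            n_exons = 1
        genes.append(
            GeneModel(
                gene_id=gid,
                seq_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else ".",
                exon_count=n_exons,
                anchored=feat.seqid in chrom_set,
            )
        )
    if errors:
        raise AnnotationError(
            "malformed gene records:\n  " + "\n  ".join(errors)
        )
    return GenomeAnnotation(genes, chromosome_lengths)


def write_gene_models(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write the annotation as GFF3: gene features plus synthetic exon rows.

    Exons are emitted as equal-width placeholder intervals purely to carry the
    exon count through the round trip; they are not biological exon models.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seq_id in annotation.seq_ids():
            length = annotation.chromosome_lengths.get(seq_id)
            if length is not None:
                fh.write(f"##sequence-region {seq_id} 1 {length}\n")
        for g in annotation:
            fh.write(
                f"{g.seq_id}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            span = g.end - g.start + 1
            width = max(1, span // (2 * g.exon_count))
            for k in range(g.exon_count):
                # lay exons left to right inside the gene, never past the end
                ex_start = min(g.start + k * 2 * width, g.end)
                ex_end = min(ex_start + width - 1, g.end)
                fh.write(
                    f"{g.seq_id}\t.\texon\t{ex_start}\t{ex_end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{k + 1};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Evidence tables (TSV)
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(columns) - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_domain_evidence(
    domains_path: str | Path,
    cc_path: str | Path | None = None,
    similarity_path: str | Path | None = None,
    kinase2_path: str | Path | None = None,
) -> dict[str, DomainEvidence]:
    """Merge the external evidence tables into per-gene DomainEvidence.

    Expected columns: domains.tsv ``gene_id domain_class accession e_value
    ali_start ali_end coverage_fraction``; cc.tsv ``gene_id cc_pscore``;
    similarity.tsv ``gene_id subject_id percent_identity``; kinase2.tsv
    ``gene_id residue`` (the amino acid right after the kinase-2 motif).
    """
    evidence: dict[str, DomainEvidence] = {}

    def ev(gene_id: str) -> DomainEvidence:
        if gene_id not in evidence:
            evidence[gene_id] = DomainEvidence(gene_id=gene_id)
        return evidence[gene_id]

    errors: list[str] = []

    df = _read_tsv(
        domains_path,
        ["gene_id", "domain_class", "accession", "e_value", "ali_start",
         "ali_end", "coverage_fraction"],
    )
    for row in df.itertuples(index=False):
        try:
            hit = DomainHit(
                domain_class=row.domain_class,
                accession=row.accession,
                e_value=float(row.e_value),
                ali_start=int(row.ali_start),
                ali_end=int(row.ali_end),
                coverage_fraction=float(row.coverage_fraction),
            )
        except (TypeError, ValueError, AnnotationError) as exc:
            errors.append(f"domains row for {row.gene_id}: {exc}")
            continue
        ev(row.gene_id).domain_hits.append(hit)

    if cc_path is not None:
        for row in _read_tsv(cc_path, ["gene_id", "cc_pscore"]).itertuples(index=False):
            try:
                score = float(row.cc_pscore)
            except (TypeError, ValueError):
                errors.append(f"cc row for {row.gene_id}: non-numeric p-score "
                              f"{row.cc_pscore!r}")
                continue
            if not 0.0 <= score <= 1.0:
                errors.append(f"cc row for {row.gene_id}: p-score {score} outside [0,1]")
                continue
            ev(row.gene_id).cc_pscore = score

    if similarity_path is not None:
        sim = _read_tsv(similarity_path, ["gene_id", "subject_id", "percent_identity"])
        for row in sim.itertuples(index=False):
            try:
                pid = float(row.percent_identity)
            except (TypeError, ValueError):
                errors.append(f"similarity row for {row.gene_id}: non-numeric identity")
                continue
            ev(row.gene_id).similarity_hit = SimilarityHit(row.subject_id, pid)

    if kinase2_path is not None:
        for row in _read_tsv(kinase2_path, ["gene_id", "residue"]).itertuples(index=False):
            residue = str(row.residue).strip().upper()
            if len(residue) != 1 or not residue.isalpha():
                errors.append(f"kinase2 row for {row.gene_id}: bad residue {row.residue!r}")
                continue
            ev(row.gene_id).kinase2_next_residue = residue

    if errors:
        raise AnnotationError("bad evidence records:\n  " + "\n  ".join(errors))
    return evidence


def write_domain_evidence(
    evidence: Mapping[str, DomainEvidence],
    domains_path: str | Path,
    cc_path: str | Path,
    similarity_path: str | Path,
    kinase2_path: str | Path,
) -> None:
    dom_rows, cc_rows, sim_rows, k2_rows = [], [], [], []
    for gid in sorted(evidence):
        e = evidence[gid]
        for h in e.domain_hits:
            dom_rows.append((gid, h.domain_class, h.accession, repr(h.e_value),
                             h.ali_start, h.ali_end, repr(h.coverage_fraction)))
        if e.cc_pscore is not None:
            cc_rows.append((gid, repr(e.cc_pscore)))
        if e.similarity_hit is not None:
            sim_rows.append((gid, e.similarity_hit.subject_id,
                             repr(e.similarity_hit.percent_identity)))
        if e.kinase2_next_residue is not None:
            k2_rows.append((gid, e.kinase2_next_residue))
    pd.DataFrame(dom_rows, columns=["gene_id", "domain_class", "accession", "e_value",
                                    "ali_start", "ali_end", "coverage_fraction"]
                 ).to_csv(domains_path, sep="\t", index=False)
    pd.DataFrame(cc_rows, columns=["gene_id", "cc_pscore"]).to_csv(
        cc_path, sep="\t", index=False)
    pd.DataFrame(sim_rows, columns=["gene_id", "subject_id", "percent_identity"]
                 ).to_csv(similarity_path, sep="\t", index=False)
    pd.DataFrame(k2_rows, columns=["gene_id", "residue"]).to_csv(
        kinase2_path, sep="\t", index=False)


def read_simple_map(path: str | Path, value_column: str) -> dict[str, str]:
    """Read a two-column gene_id -> value TSV (clade labels and the like)."""
    df = _read_tsv(path, ["gene_id", value_column])
    return dict(zip(df["gene_id"], df[value_column]))


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read expression.tsv with columns gene_id, sample, fpkm."""
    df = _read_tsv(path, ["gene_id", "sample", "fpkm"])
    try:
        df["fpkm"] = df["fpkm"].astype(float)
    except ValueError as exc:
        raise AnnotationError(f"{path}: non-numeric fpkm: {exc}") from exc
    return df


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------

def write_cluster_bed(clusters: Sequence, path: str | Path) -> None:
    """Write clusters as BED6 (0-based half-open), name=id, score=size."""
    rows = []
    for c in clusters:
        if c.seq_id is None or c.span_start is None or c.span_end is None:
            raise AnnotationError(f"cluster {c.cluster_id} has no mapped span")
        rows.append((c.seq_id, c.span_start - 1, c.span_end, c.cluster_id, c.size, "."))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
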