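"""Domain-architecture classification of NBS-LRR (NLR) candidates.

Each gene's evidence — NB-ARC domain hits, N-terminal domain hits (TIR,
RPW8), a coiled-coil p-score, an optional similarity hit and an optional
kinase-2 diagnostic residue — is reduced to a letter code describing the
domain architecture:

====  ==========================================
CNL   CC + NBS + LRR          (CNL-type family)
CN    CC + NBS
N_CC  NBS only, CC-type
NL_CC NBS + LRR, CC-type
TNL   TIR + NBS + LRR         (TNL-type family)
TN    TIR + NBS
N_TIR NBS only, TIR-type
NL_TIR NBS + LRR, TIR-type
P     partial gene (no intact NB-ARC domain)
====  ==========================================

A gene has a *full* NBS when its best NB-ARC hit passes both the E-value
threshold and the minimum coverage of the reference NB-ARC length; an
E-value pass without coverage is a *partial* NBS.  Genes without an
N-terminal domain hit are typed TIR- vs CC- by a fallback chain: an
explicit clade label, then the diagnostic residue immediately after the
kinase-2 motif (D for TIR-type, W for CC-type), and the mechanism used is
recorded per gene.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .annotation_io import DomainEvidence, GenomeAnnotation

log = logging.getLogger(__name__)

LETTER_CODES = ("CNL", "CN", "N_CC", "NL_CC", "TNL", "TN", "N_TIR", "NL_TIR",
                "P", "unclassified")
FULL_LENGTH_CODES = ("CNL", "CN", "N_CC", "NL_CC", "TNL", "TN", "N_TIR", "NL_TIR")
CNL_TYPE_CODES = ("CNL", "CN", "N_CC", "NL_CC")
TNL_TYPE_CODES = ("TNL", "TN", "N_TIR", "NL_TIR")
FAMILIES = ("TNL_type", "CNL_type", "partial", "none")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the classification cascade.

    hq_evalue marks the high-confidence NB-ARC set; pass_evalue is the
    inclusive species-specific pass; accessory_evalue gates TIR/RPW8/LRR
    hits; cc_pscore_max is the Paircoil-style coiled-coil cutoff;
    nbs_full_coverage_min is the minimum fraction of the reference NB-ARC
    length for a *full* call (also the eligibility bar for phylogeny, whose
    alignment window is phylo_window_aa residues after the p-loop).
    """

    hq_evalue: float = 1e-20
    pass_evalue: float = 0.01
    accessory_evalue: float = 1e-4
    cc_pscore_max: float = 0.03
    nbs_full_coverage_min: float = 0.90
    phylo_window_aa: int = 250
    tir_diag_residues: frozenset[str] = frozenset({"D"})
    cc_diag_residues: frozenset[str] = frozenset({"W"})

    def __post_init__(self) -> None:
        for name in ("hq_evalue", "pass_evalue", "accessory_evalue", "cc_pscore_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.nbs_full_coverage_min <= 1:
            raise ValueError("nbs_full_coverage_min must be in (0, 1]")
        if set(self.tir_diag_residues) & set(self.cc_diag_residues):
            raise ValueError("tir_diag_residues and cc_diag_residues must be disjoint")

    @classmethod
    def from_file(cls, path: str | Path) -> "ClassifierConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})

    @classmethod
    def from_dict(cls, data: Mapping) -> "ClassifierConfig":
        kwargs = dict(data)
        for key in ("tir_diag_residues", "cc_diag_residues"):
            if key in kwargs:
                kwargs[key] = frozenset(kwargs[key])
        valid = {f.name for f in fields(cls)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(f"unknown classifier config keys {sorted(unknown)}")
        return cls(**kwargs)


@dataclass(slots=True)
class ArchitectureCall:
    """Per-gene classification result."""

    gene_id: str
    nbs_status: str  # full | partial | absent
    has_TIR: bool = False
    has_CC: bool = False
    has_RPW8: bool = False
    has_LRR: bool = False
    nterm_type: str = "unknown"  # TIR | CC | RPW8 | unknown
    nterm_type_source: str = "none"  # domain | clade | kinase2 | none
    letter_code: str = "unclassified"
    family: str = "none"  # TNL_type | CNL_type | partial | none
    rpw8: bool = False
    phylogeny_eligible: bool = False
    conflict: bool = False  # both TIR and CC evidence present


def call_nbs_status(evidence: DomainEvidence, cfg: ClassifierConfig) -> str:
    """full / partial / absent from the best NB-ARC hit.

    full: E-value <= pass_evalue and coverage >= nbs_full_coverage_min;
    partial: E-value passes but coverage does not; absent otherwise.
    """
    best = evidence.best_hit("NBARC")
    if best is None or best.e_value > cfg.pass_evalue:
        return "absent"
    if best.coverage_fraction >= cfg.nbs_full_coverage_min:
        return "full"
    return "partial"


def kinase2_diagnostic(residue: str | None, cfg: ClassifierConfig) -> str:
    """Type a bare-NBS gene from the residue right after the kinase-2 motif."""
    if residue is None:
        return "indeterminate"
    residue = residue.upper()
    if residue in cfg.tir_diag_residues:
        return "TIR-type"
    if residue in cfg.cc_diag_residues:
        return "CC-type"
    return "indeterminate"


def _clade_nterm(clade: str | None) -> str | None:
    """Map a clade label to an N-terminal type (TIR vs CC-side)."""
    if clade is None:
        return None
    label = clade.upper()
    if label.startswith("TIR") or label.startswith("TNL"):
        return "TIR"
    if label.startswith("CC") or label.startswith("CNL") or label.startswith("RPW8"):
        return "CC"
    return None


def classify_gene(
    evidence: DomainEvidence,
    clade: str | None,
    cfg: ClassifierConfig,
) -> ArchitectureCall:
    """Classify one gene from its evidence (total function, deterministic).

    N-terminal precedence on conflicting evidence is RPW8 > TIR > CC, with
    the conflict flagged.  Genes lacking an intact NB-ARC are partial (P)
    when any partial NB-ARC hit or similarity hit ties them to the family,
    else unclassified.
    """
    status = call_nbs_status(evidence, cfg)

    def passes(domain_class: str) -> bool:
        best = evidence.best_hit(domain_class)
        return best is not None and best.e_value <= cfg.accessory_evalue

    call = ArchitectureCall(gene_id=evidence.gene_id, nbs_status=status)
    call.has_TIR = passes("TIR")
    call.has_RPW8 = passes("RPW8")
    call.has_LRR = passes("LRR")
    call.has_CC = (evidence.cc_pscore is not None
                   and evidence.cc_pscore <= cfg.cc_pscore_max)
    call.conflict = call.has_TIR and (call.has_CC or call.has_RPW8)
    if call.conflict:
        log.warning("gene %s: conflicting N-terminal evidence "
                    "(TIR together with CC/RPW8); using precedence RPW8 > TIR > CC",
                    evidence.gene_id)

    if status != "full":
        # No intact NB-ARC: partial when anything still ties the gene to the
        # family (a sub-threshold-coverage NB-ARC hit, or sequence similarity
        # to a full-length NLR), otherwise not an NLR at all.
        if status == "partial" or evidence.similarity_hit is not None:
            call.letter_code, call.family = "P", "partial"
        return call

    # full NBS: establish the N-terminal type
    if call.has_RPW8:
        call.nterm_type, call.nterm_type_source = "RPW8", "domain"
        call.rpw8 = True
    elif call.has_TIR:
        call.nterm_type, call.nterm_type_source = "TIR", "domain"
    elif call.has_CC:
        call.nterm_type, call.nterm_type_source = "CC", "domain"
    else:
        by_clade = _clade_nterm(clade)
        if by_clade is not None:
            call.nterm_type, call.nterm_type_source = by_clade, "clade"
        else:
            diag = kinase2_diagnostic(evidence.kinase2_next_residue, cfg)
            if diag == "TIR-type":
                call.nterm_type, call.nterm_type_source = "TIR", "kinase2"
            elif diag == "CC-type":
                call.nterm_type, call.nterm_type_source = "CC", "kinase2"
            # else left unknown; the gene defaults to the majority
            # (CNL-type) family below.

    tir_side = call.nterm_type == "TIR"
    nterm_domain_present = call.has_TIR or call.has_CC or call.has_RPW8
    if nterm_domain_present:
        call.letter_code = (("TNL" if tir_side else "CNL") if call.has_LRR
                            else ("TN" if tir_side else "CN"))
    else:
        call.letter_code = (("NL_TIR" if tir_side else "NL_CC") if call.has_LRR
                            else ("N_TIR" if tir_side else "N_CC"))
    call.family = "TNL_type" if tir_side else "CNL_type"
    call.phylogeny_eligible = True  # full NBS implies the coverage bar passed
    return call


def classify_all(
    annotation: GenomeAnnotation,
    evidence_map: Mapping[str, DomainEvidence],
    clade_map: Mapping[str, str] | None = None,
    cfg: ClassifierConfig | None = None,
    exclude: Iterable[str] = (),
) -> list[ArchitectureCall]:
    """One ArchitectureCall per annotated gene, in annotation order.

    *exclude* lists curated removals (e.g. kinase-only hits); excluded genes
    are classified as if they had no evidence.
    """
    cfg = cfg or ClassifierConfig()
    unknown = [gid for gid in evidence_map if gid not in annotation]
    if unknown:
        raise KeyError(f"evidence for unknown gene ids: {sorted(unknown)[:10]}"
                       f"{'...' if len(unknown) > 10 else ''}")
    excluded = set(exclude)
    clade_map = clade_map or {}
    calls = []
    for gene in annotation:
        gid = gene.gene_id
        if gid in excluded or gid not in evidence_map:
            ev = DomainEvidence(gene_id=gid)
        else:
            ev = evidence_map[gid]
        calls.append(classify_gene(ev, clade_map.get(gid), cfg))
    return calls


def calls_to_frame(calls: Sequence[ArchitectureCall]) -> pd.DataFrame:
    cols = ["gene_id", "letter_code", "family", "nterm_type", "nterm_type_source",
            "nbs_status", "rpw8", "phylogeny_eligible"]
    return pd.DataFrame([[getattr(c, col) for col in cols] for c in calls],
                        columns=cols)


def write_calls_tsv(calls: Sequence[ArchitectureCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def phylogeny_eligible_ids(calls: Sequence[ArchitectureCall]) -> list[str]:
    """Genes whose NB-ARC region qualifies for tree building (full-coverage NBS)."""
    return [c.gene_id for c in calls if c.phylogeny_eligible]
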