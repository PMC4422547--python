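"""Summary accounting over classified NBS-LRR genes.

Covers the landscape bookkeeping: letter-code counts and family totals, the
CNL:TNL ratio, exon-count statistics per group, mapped/unmapped fractions,
per-chromosome class breakdowns and constitutive-expression fractions
(FPKM strictly greater than a threshold, default 1, in any sample).

Raw unrounded values are always kept; rendered percentages/ratios round
half-up to the printed precision (integers for percentages, one decimal for
ratios and means).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotation_io import GenomeAnnotation
from .architecture_classifier import (
    ArchitectureCall,
    CNL_TYPE_CODES,
    FULL_LENGTH_CODES,
    LETTER_CODES,
    TNL_TYPE_CODES,
)


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def render_percent(fraction: float) -> int:
    """0.6269 -> 63 (half-up on the percentage scale)."""
    return int(round_half_up(100.0 * fraction))


@dataclass(slots=True)
class FamilyTotals:
    n_TNL_type: int
    n_CNL_type: int
    n_partial: int

    @property
    def n_full_length(self) -> int:
        return self.n_TNL_type + self.n_CNL_type

    @property
    def n_total(self) -> int:
        return self.n_full_length + self.n_partial


def tabulate(calls: Sequence[ArchitectureCall]) -> tuple[dict[str, int], FamilyTotals]:
    """Letter-code counts plus family totals over classified genes."""
    counts = {code: 0 for code in LETTER_CODES}
    for c in calls:
        counts[c.letter_code] += 1
    totals = FamilyTotals(
        n_TNL_type=sum(counts[c] for c in TNL_TYPE_CODES),
        n_CNL_type=sum(counts[c] for c in CNL_TYPE_CODES),
        n_partial=counts["P"],
    )
    assert totals.n_full_length == sum(counts[c] for c in FULL_LENGTH_CODES)
    return counts, totals


def family_ratio(totals: FamilyTotals) -> float | None:
    """CNL-type over TNL-type gene count; None (undefined) without TNLs."""
    if totals.n_TNL_type == 0:
        return None
    return totals.n_CNL_type / totals.n_TNL_type


def exon_stats(
    calls: Sequence[ArchitectureCall],
    annotation: GenomeAnnotation,
) -> dict[str, float | None]:
    """Mean exon counts per group and the CNL-type single-exon fraction.

    Groups: all annotated genes; full-length NBS genes; CNL-type; TNL-type.
    Empty groups yield None.
    """
    exons = {g.gene_id: g.exon_count for g in annotation}

    def mean_of(ids: list[str]) -> float | None:
        return sum(exons[i] for i in ids) / len(ids) if ids else None

    cnl = [c.gene_id for c in calls if c.family == "CNL_type"]
    tnl = [c.gene_id for c in calls if c.family == "TNL_type"]
    full = cnl + tnl
    single = sum(exons[i] == 1 for i in cnl)
    return {
        "mean_all_genes": mean_of(list(exons)),
        "mean_full_length": mean_of(full),
        "mean_CNL": mean_of(cnl),
        "mean_TNL": mean_of(tnl),
        "frac_CNL_single_exon": single / len(cnl) if cnl else None,
    }


def mapping_stats(
    calls: Sequence[ArchitectureCall],
    annotation: GenomeAnnotation,
) -> dict[str, float | int]:
    """Mapped (anchored) fraction of the NBS-LRR gene set (incl. partials)."""
    nbs = [c.gene_id for c in calls if c.family in ("TNL_type", "CNL_type", "partial")]
    mapped = [gid for gid in nbs if annotation.gene(gid).anchored]
    n_total = len(nbs)
    frac = len(mapped) / n_total if n_total else 0.0
    return {
        "n_mapped": len(mapped),
        "n_unmapped": n_total - len(mapped),
        "n_total": n_total,
        "frac_mapped": frac,
        "pct_mapped": render_percent(frac),
    }


def per_chromosome_classes(
    calls: Sequence[ArchitectureCall],
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """CNL-type / TNL-type / partial counts per anchored chromosome."""
    rows: dict[str, dict[str, int]] = {}
    by_id = {c.gene_id: c for c in calls}
    for g in annotation:
        if not g.anchored:
            continue
        call = by_id.get(g.gene_id)
        if call is None or call.family not in ("TNL_type", "CNL_type", "partial"):
            continue
        r = rows.setdefault(g.seq_id, {"CNL_type": 0, "TNL_type": 0, "partial": 0})
        r[call.family] += 1
    table = pd.DataFrame(
        [{"seq_id": s, "n_CNL_type": v["CNL_type"], "n_TNL_type": v["TNL_type"],
          "n_partial": v["partial"],
          "n_total": v["CNL_type"] + v["TNL_type"] + v["partial"]}
         for s, v in sorted(rows.items())],
        columns=["seq_id", "n_CNL_type", "n_TNL_type", "n_partial", "n_total"],
    )
    return table


def expression_fractions(
    expression: pd.DataFrame | None,
    calls: Sequence[ArchitectureCall],
    threshold: float = 1.0,
    samples: Sequence[str] | None = None,
) -> dict[str, float | None]:
    """Fraction of full-length and of partial genes expressed anywhere.

    A gene counts as expressed iff FPKM > threshold (strict) in at least one
    (selected) sample.  Expression rows for unknown genes are ignored with a
    warning.  With no table the fractions are undefined.
    """
    out: dict[str, float | None] = {
        "fpkm_threshold": threshold,
        "frac_full_expressed": None,
        "frac_partial_expressed": None,
    }
    if expression is None or expression.empty:
        return out
    df = expression
    if samples is not None:
        df = df[df["sample"].isin(set(samples))]
    known = {c.gene_id for c in calls}
    stray = set(df["gene_id"]) - known
    if stray:
        import logging
        logging.getLogger(__name__).warning(
            "expression rows for %d unknown gene ids ignored", len(stray))
        df = df[df["gene_id"].isin(known)]
    expressed = set(df.loc[df["fpkm"] > threshold, "gene_id"])
    full = [c.gene_id for c in calls if c.family in ("TNL_type", "CNL_type")]
    partial = [c.gene_id for c in calls if c.family == "partial"]
    if full:
        out["frac_full_expressed"] = sum(g in expressed for g in full) / len(full)
    if partial:
        out["frac_partial_expressed"] = sum(g in expressed for g in partial) / len(partial)
    return out


@dataclass(slots=True)
class SummaryReport:
    counts_by_code: dict[str, int]
    family_totals: dict[str, int]
    cnl_tnl_ratio: float | None
    exon_stats: dict[str, float | None]
    mapping: dict[str, float | int]
    per_chromosome: list[dict]
    expression: dict[str, float | None]

    def validate(self) -> None:
        ft = self.family_totals
        assert ft["n_full_length"] == ft["n_TNL_type"] + ft["n_CNL_type"]
        assert ft["n_total"] == ft["n_full_length"] + ft["n_partial"]
        assert sum(self.counts_by_code[c] for c in FULL_LENGTH_CODES) == ft["n_full_length"]
        for key in ("frac_mapped",):
            assert 0.0 <= self.mapping[key] <= 1.0
        for key in ("frac_full_expressed", "frac_partial_expressed"):
            v = self.expression.get(key)
            assert v is None or 0.0 <= v <= 1.0

    def rendered(self) -> dict:
        """Values rounded the way the report prints them (raw kept alongside)."""
        r = {
            "cnl_tnl_ratio": (None if self.cnl_tnl_ratio is None
                              else round_half_up(self.cnl_tnl_ratio, 1)),
            "pct_mapped": self.mapping["pct_mapped"],
        }
        for key in ("mean_all_genes", "mean_full_length", "mean_CNL", "mean_TNL"):
            v = self.exon_stats[key]
            r[key] = None if v is None else round_half_up(v, 2)
        fcse = self.exon_stats["frac_CNL_single_exon"]
        r["pct_CNL_single_exon"] = None if fcse is None else render_percent(fcse)
        for key in ("frac_full_expressed", "frac_partial_expressed"):
            v = self.expression.get(key)
            r["pct_" + key.removeprefix("frac_")] = (
                None if v is None else render_percent(v))
        return r

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["rendered"] = self.rendered()
        Path(path).write_text(json.dumps(payload, indent=2))


def summarize(
    calls: Sequence[ArchitectureCall],
    annotation: GenomeAnnotation,
    expression: pd.DataFrame | None = None,
    fpkm_threshold: float = 1.0,
) -> SummaryReport:
    """Build the full summary report (validated before return)."""
    counts, totals = tabulate(calls)
    report = SummaryReport(
        counts_by_code=counts,
        family_totals={
            "n_TNL_type": totals.n_TNL_type,
            "n_CNL_type": totals.n_CNL_type,
            "n_partial": totals.n_partial,
            "n_full_length": totals.n_full_length,
            "n_total": totals.n_total,
        },
        cnl_tnl_ratio=family_ratio(totals),
        exon_stats=exon_stats(calls, annotation),
        mapping=mapping_stats(calls, annotation),
        per_chromosome=per_chromosome_classes(calls, annotation).to_dict("records"),
        expression=expression_fractions(expression, calls, fpkm_threshold),
    )
    report.validate()
    return report
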