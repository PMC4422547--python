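"""End-to-end orchestration: classify -> cluster -> null -> summarize.

A run is described by a YAML/JSON config (see :class:`PipelineConfig`).
Inputs are either real files or, with ``synthesize: true``, generated by the
synthetic-data module first.  All reports are written into a staging
directory and moved into place only when the whole run succeeds, so a failed
run never leaves partial reports.  A manifest records the config snapshot,
input checksums, seed and output paths.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .annotation_io import (
    AnnotationError,
    read_domain_evidence,
    read_expression,
    read_gene_models,
    read_simple_map,
    write_cluster_bed,
)
from .architecture_classifier import ClassifierConfig, classify_all, write_calls_tsv
from .cluster_finder import (
    ClusterRule,
    chromosome_summary,
    clusters_to_frame,
    find_clusters,
    label_homogeneity,
)
from .cluster_null import NullConfig, attach_observed, simulate_null
from .summary_stats import summarize
from .synthetic_data import PlantedCluster, SynthConfig, generate

log = logging.getLogger(__name__)

EXIT_BAD_INPUT = 2
EXIT_INVARIANT = 3


class PipelineInputError(Exception):
    """Missing or malformed input (exit status 2)."""


@dataclass
class PipelineConfig:
    outdir: Path = Path("rgene_atlas_run")
    seed: int = 0
    synthesize: bool = False
    synth: dict = field(default_factory=dict)
    chromosomes: list[str] = field(default_factory=list)
    inputs: dict = field(default_factory=dict)  # gff/domains/cc/similarity/...
    classifier: dict = field(default_factory=dict)
    cluster_rule: dict = field(default_factory=dict)
    null: dict = field(default_factory=dict)
    fpkm_threshold: float = 1.0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text)) or {}
        cfg = cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineInputError(f"unknown config keys {sorted(unknown)}")
        cfg.outdir = Path(cfg.outdir)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _build_synth_config(cfg: PipelineConfig) -> SynthConfig:
    kwargs = dict(cfg.synth)
    kwargs.setdefault("seed", cfg.seed)
    if "planted_clusters" in kwargs:
        kwargs["planted_clusters"] = [
            PlantedCluster(**p) if isinstance(p, Mapping) else PlantedCluster(p)
            for p in kwargs["planted_clusters"]]
    if "rule" in kwargs:
        kwargs["rule"] = ClusterRule.from_dict(kwargs["rule"])
    if "planted_clusters" not in kwargs and "n_nbs" in kwargs:
        # default planted layout may not fit a scaled-down genome
        from .synthetic_data import scaled_planted

        frac_un = kwargs.get("frac_unanchored", SynthConfig().frac_unanchored)
        n_anchored = kwargs["n_nbs"] - int(round(frac_un * kwargs["n_nbs"]))
        default_total = sum(p.size for p in SynthConfig().planted_clusters)
        if default_total > n_anchored:
            kwargs["planted_clusters"] = scaled_planted(n_anchored)
    return SynthConfig(**kwargs)


def run_all(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute the whole pipeline; returns the manifest dictionary."""
    t0 = time.time()
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix="stage_", dir=cfg.outdir))
    timings: dict[str, float] = {}
    try:
        # --- inputs -------------------------------------------------------
        t = time.time()
        if cfg.synthesize:
            synth_cfg = _build_synth_config(cfg)
            paths, _truth = generate(synth_cfg, staging / "synth")
            inputs = {
                "gff": paths.gff, "domains": paths.domains, "cc": paths.cc,
                "similarity": paths.similarity, "kinase2": paths.kinase2,
                "clades": paths.clades, "expression": paths.expression,
            }
            chromosomes = [f"chr{i + 1}" for i in range(synth_cfg.n_chromosomes)]
        else:
            inputs = {k: Path(v) for k, v in cfg.inputs.items()}
            chromosomes = list(cfg.chromosomes)
            if "gff" not in inputs or "domains" not in inputs:
                raise PipelineInputError("config must provide inputs.gff and "
                                         "inputs.domains (or synthesize: true)")
            for name, p in inputs.items():
                if not p.exists():
                    raise PipelineInputError(f"input {name} not found: {p}")
        timings["inputs"] = time.time() - t

        # --- classify -----------------------------------------------------
        t = time.time()
        try:
            annotation = read_gene_models(inputs["gff"], chromosomes)
        except (AnnotationError, FileNotFoundError) as exc:
            raise PipelineInputError(str(exc)) from exc
        evidence = read_domain_evidence(
            inputs["domains"], inputs.get("cc"), inputs.get("similarity"),
            inputs.get("kinase2"))
        clade_map = (read_simple_map(inputs["clades"], "clade_label")
                     if inputs.get("clades") else None)
        clf_cfg = ClassifierConfig.from_dict(cfg.classifier)
        calls = classify_all(annotation, evidence, clade_map, clf_cfg)
        write_calls_tsv(calls, staging / "classification.tsv")
        timings["classify"] = time.time() - t

        # --- cluster ------------------------------------------------------
        t = time.time()
        rule = ClusterRule.from_dict(cfg.cluster_rule)
        focal = [c.gene_id for c in calls
                 if c.family in ("TNL_type", "CNL_type", "partial")]
        clusters, singletons, unmapped = find_clusters(annotation, focal, rule)
        call_map = {c.gene_id: c for c in calls}
        for c in clusters:
            label_homogeneity(c, call_map, clade_map)
        clusters_to_frame(clusters).to_csv(staging / "clusters.tsv",
                                           sep="\t", index=False)
        write_cluster_bed(clusters, staging / "clusters.bed")
        chromosome_summary(clusters, singletons, annotation).to_csv(
            staging / "chromosome_summary.tsv", sep="\t", index=False)
        timings["cluster"] = time.time() - t

        # --- null ---------------------------------------------------------
        t = time.time()
        null_kwargs = dict(cfg.null)
        null_kwargs.setdefault("seed", cfg.seed)
        null_kwargs.setdefault("n_sample", len(focal) - len(unmapped)
                               if len(focal) > len(unmapped) else 2)
        null_kwargs["rule"] = rule
        null_cfg = NullConfig(**null_kwargs)
        dist = simulate_null(annotation, null_cfg)
        attach_observed(dist, clusters)
        dist.to_json(staging / "null.json")
        dist.to_frame().to_csv(staging / "null.tsv", sep="\t", index=False)
        timings["null"] = time.time() - t

        # --- summarize ----------------------------------------------------
        t = time.time()
        expression = (read_expression(inputs["expression"])
                      if inputs.get("expression") else None)
        report = summarize(calls, annotation, expression, cfg.fpkm_threshold)
        report.to_json(staging / "summary.json")
        timings["summarize"] = time.time() - t

        manifest = {
            "tool_version": __version__,
            "seed": cfg.seed,
            "config": {k: (str(v) if isinstance(v, Path) else v)
                       for k, v in vars(cfg).items()},
            "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                       for name, p in inputs.items()},
            "outputs": ["classification.tsv", "clusters.tsv", "clusters.bed",
                        "chromosome_summary.tsv", "null.json", "null.tsv",
                        "summary.json"],
            "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
            "total_seconds": round(time.time() - t0, 3),
        }
        (staging / "manifest.json").write_text(json.dumps(manifest, indent=2))

        # atomic-ish publish: move every report into outdir at the end
        for name in manifest["outputs"] + ["manifest.json"]:
            shutil.move(str(staging / name), str(cfg.outdir / name))
        if cfg.synthesize:
            dest = cfg.outdir / "synth"
            if dest.exists():
                shutil.rmtree(dest)
            shutil.move(str(staging / "synth"), str(dest))
        return manifest
    finally:
        shutil.rmtree(staging, ignore_errors=True)
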