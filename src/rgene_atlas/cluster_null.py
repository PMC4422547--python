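"""Random-gene-sample null for cluster-size frequencies.

The significance question: do NBS-LRR genes cluster more than an arbitrary
set of genes of the same size would?  The null repeatedly draws gene sets of
the observed size uniformly without replacement from the annotation (by
default from anchored genes only, matching the mapped NBS-LRR universe),
re-runs the cluster detector on each draw, and records the frequency of each
cluster size.  Observed frequencies are then compared to the null via an
add-one empirical p-value:

    p(s) = (1 + #{iterations with count(s) >= observed(s)}) / (n_iter + 1)

which is conservative and never exactly zero.  By default counts are
compared per exact size; a tail-aggregated mode (counting clusters of size
>= s) is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import GenomeAnnotation
from .cluster_finder import ClusterRule, GeneCluster, find_clusters

SAMPLING_UNIVERSES = ("anchored_only", "all_genes")


@dataclass(frozen=True)
class NullConfig:
    n_sample: int = 205
    n_iter: int = 1000
    seed: int = 0
    rule: ClusterRule = field(default_factory=ClusterRule)
    sampling_universe: str = "anchored_only"
    tail_aggregate: bool = False

    def __post_init__(self) -> None:
        if self.n_sample < 2:
            raise ValueError("n_sample must be >= 2")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.sampling_universe not in SAMPLING_UNIVERSES:
            raise ValueError(f"sampling_universe must be one of {SAMPLING_UNIVERSES}")


@dataclass(slots=True)
class NullDistribution:
    """Cluster-size frequencies under the random-sample null.

    ``per_iteration_counts`` has one row per iteration and one column per
    cluster size (>= 2) observed in any iteration; ``singletons`` and
    ``unmapped`` record, per iteration, sampled genes in no cluster and
    sampled genes on unanchored sequences.
    """

    config: NullConfig
    per_iteration_counts: pd.DataFrame  # index: iteration; columns: int sizes
    singletons: np.ndarray
    unmapped: np.ndarray
    observed_frequency: dict[int, int] | None = None
    empirical_p: dict[int, float] | None = None

    @property
    def mean_frequency(self) -> dict[int, float]:
        return {int(s): float(m) for s, m in self.per_iteration_counts.mean().items()}

    @property
    def sd_frequency(self) -> dict[int, float]:
        return {int(s): float(m)
                for s, m in self.per_iteration_counts.std(ddof=1).items()}

    def check_conservation(self) -> None:
        """Every iteration's genes must add up to the sample size."""
        sizes = self.per_iteration_counts.columns.to_numpy(dtype=int)
        clustered = self.per_iteration_counts.to_numpy() @ sizes
        total = clustered + self.singletons + self.unmapped
        bad = np.nonzero(total != self.config.n_sample)[0]
        if bad.size:
            raise AssertionError(
                f"conservation violated at iterations {bad[:5].tolist()}: "
                f"totals {total[bad[:5]].tolist()} != n_sample {self.config.n_sample}"
            )

    def to_frame(self) -> pd.DataFrame:
        sizes = sorted(set(map(int, self.per_iteration_counts.columns))
                       | set(self.observed_frequency or {}))
        mean, sd = self.mean_frequency, self.sd_frequency
        rows = []
        for s in sizes:
            rows.append({
                "size": s,
                "observed": (self.observed_frequency or {}).get(s, 0)
                if self.observed_frequency is not None else None,
                "null_mean": mean.get(s, 0.0),
                "null_sd": sd.get(s, 0.0),
                "empirical_p": (self.empirical_p or {}).get(s)
                if self.empirical_p is not None else None,
            })
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {
                "n_sample": self.config.n_sample,
                "n_iter": self.config.n_iter,
                "seed": self.config.seed,
                "sampling_universe": self.config.sampling_universe,
                "tail_aggregate": self.config.tail_aggregate,
                "rule": {
                    "max_gap_bp": self.config.rule.max_gap_bp,
                    "max_intervening": self.config.rule.max_intervening,
                    "min_members": self.config.rule.min_members,
                    "distance_anchor": self.config.rule.distance_anchor,
                },
            },
            "mean_frequency": {str(k): v for k, v in self.mean_frequency.items()},
            "sd_frequency": {str(k): v for k, v in self.sd_frequency.items()},
            "observed_frequency": (None if self.observed_frequency is None else
                                   {str(k): v for k, v in self.observed_frequency.items()}),
            "empirical_p": (None if self.empirical_p is None else
                            {str(k): v for k, v in self.empirical_p.items()}),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def sampling_universe_ids(annotation: GenomeAnnotation, cfg: NullConfig) -> list[str]:
    if cfg.sampling_universe == "anchored_only":
        return annotation.anchored_ids()
    return annotation.gene_ids()


def simulate_null(annotation: GenomeAnnotation, cfg: NullConfig) -> NullDistribution:
    """Run the random-sample simulation; fully reproducible from cfg.seed."""
    universe = sampling_universe_ids(annotation, cfg)
    if len(universe) < cfg.n_sample:
        raise ValueError(
            f"sampling universe has {len(universe)} genes < n_sample {cfg.n_sample}"
        )
    rng = np.random.default_rng(cfg.seed)
    universe_arr = np.asarray(universe, dtype=object)

    counts_per_iter: list[dict[int, int]] = []
    singles = np.zeros(cfg.n_iter, dtype=int)
    unmapped_n = np.zeros(cfg.n_iter, dtype=int)
    all_sizes: set[int] = set()
    for it in range(cfg.n_iter):
        sample = rng.choice(universe_arr, size=cfg.n_sample, replace=False)
        clusters, singletons, unmapped = find_clusters(annotation, sample, cfg.rule)
        counts: dict[int, int] = {}
        for c in clusters:
            counts[c.size] = counts.get(c.size, 0) + 1
        counts_per_iter.append(counts)
        all_sizes.update(counts)
        singles[it] = len(singletons)
        unmapped_n[it] = len(unmapped)

    sizes = sorted(all_sizes) or [2]
    matrix = np.zeros((cfg.n_iter, len(sizes)), dtype=int)
    col = {s: j for j, s in enumerate(sizes)}
    for i, counts in enumerate(counts_per_iter):
        for s, n in counts.items():
            matrix[i, col[s]] = n
    dist = NullDistribution(
        config=cfg,
        per_iteration_counts=pd.DataFrame(matrix, columns=sizes),
        singletons=singles,
        unmapped=unmapped_n,
    )
    dist.check_conservation()
    return dist


def _counts_matrix(dist: NullDistribution, sizes: Sequence[int]) -> np.ndarray:
    """Per-iteration counts for the requested sizes (missing sizes are 0)."""
    out = np.zeros((dist.config.n_iter, len(sizes)), dtype=int)
    for j, s in enumerate(sizes):
        if s in dist.per_iteration_counts.columns:
            out[:, j] = dist.per_iteration_counts[s].to_numpy()
    return out


def attach_observed(
    dist: NullDistribution,
    observed_clusters: Sequence[GeneCluster],
) -> NullDistribution:
    """Attach observed cluster-size frequencies and add-one empirical p-values."""
    observed: dict[int, int] = {}
    for c in observed_clusters:
        observed[c.size] = observed.get(c.size, 0) + 1
    sizes = sorted(set(map(int, dist.per_iteration_counts.columns)) | set(observed))
    matrix = _counts_matrix(dist, sizes)
    if dist.config.tail_aggregate:
        # count clusters of size >= s, both observed and per iteration
        matrix = matrix[:, ::-1].cumsum(axis=1)[:, ::-1]
        obs_vec = np.array([sum(n for s2, n in observed.items() if s2 >= s)
                            for s in sizes])
    else:
        obs_vec = np.array([observed.get(s, 0) for s in sizes])
    n_iter = dist.config.n_iter
    p = (1 + (matrix >= obs_vec).sum(axis=0)) / (n_iter + 1)
    dist.observed_frequency = {int(s): int(observed.get(s, 0)) for s in sizes}
    dist.empirical_p = {int(s): float(pv) for s, pv in zip(sizes, p)}
    return dist
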