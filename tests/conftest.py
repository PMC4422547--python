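import numpy as np
import pytest

from rgene_atlas.annotation_io import (
    DomainEvidence,
    DomainHit,
    GeneModel,
    GenomeAnnotation,
    SimilarityHit,
)


def make_genes(positions, seq_id="chr1", length=2000, anchored=True, prefix="g"):
    """Gene models at the given start positions (1-based)."""
    return [
        GeneModel(f"{prefix}{i + 1}", seq_id, p, p + length - 1, anchored=anchored)
        for i, p in enumerate(positions)
    ]


def nbarc_hit(e_value=1e-30, coverage=0.95):
    return DomainHit("NBARC", "PF00931", e_value, 10, 290, coverage)


def evidence(gene_id="g1", nbs=True, nbs_e=1e-30, nbs_cov=0.95, tir=False,
             cc=False, lrr=False, rpw8=False, similarity=False, kinase2=None):
    """Compact evidence builder used across the classifier tests."""
    ev = DomainEvidence(gene_id=gene_id)
    if nbs:
        ev.domain_hits.append(nbarc_hit(nbs_e, nbs_cov))
    if tir:
        ev.domain_hits.append(DomainHit("TIR", "PF01582", 1e-10, 1, 150, 0.9))
    if rpw8:
        ev.domain_hits.append(DomainHit("RPW8", "PF05659", 1e-10, 1, 120, 0.9))
    if lrr:
        ev.domain_hits.append(DomainHit("LRR", "PF00560", 1e-8, 600, 850, 0.8))
    ev.cc_pscore = 0.01 if cc else 0.5
    if similarity:
        ev.similarity_hit = SimilarityHit("REF_NLR_001", 85.0)
    ev.kinase2_next_residue = kinase2
    return ev


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_synth(tmp_path_factory):
    """A small synthetic genome shared by IO/pipeline tests."""
    from rgene_atlas.synthetic_data import PlantedCluster, SynthConfig, generate

    cfg = SynthConfig(
        n_chromosomes=4,
        chromosome_length_bp=12_000_000,
        n_genes_total=2_000,
        n_nbs=60,
        planted_clusters=[PlantedCluster(5), PlantedCluster(3),
                          PlantedCluster(2), PlantedCluster(2)],
        frac_unanchored=0.2,
        seed=11,
    )
    outdir = tmp_path_factory.mktemp("synth_small")
    paths, truth = generate(cfg, outdir)
    return cfg, paths, truth
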