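"""End-to-end orchestration helpers tying the stage modules together."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .classify import KmerIndex, build_index, classify_group, redistribute_to_rank
from .simulate import BarcodeGroup, SimulationConfig, iter_barcode_groups
from .taxonomy import ReferenceSet
from .tda import (
    AbundanceVector,
    FilterThresholds,
    annotate,
    assemble_matrix,
    embed_cluster,
    filter_vectors,
    integrate_contigs,
    to_abundance_vector,
)

__all__ = ["groups_to_vectors", "DiscoveryRun", "run_discovery"]


def groups_to_vectors(
    groups: Iterable[BarcodeGroup],
    index: KmerIndex,
    rank: str = "genus",
) -> list[AbundanceVector]:
    """Classify each group and bin it into a rank abundance vector."""
    vectors = []
    for g in groups:
        counts = classify_group(g, index)
        ra = redistribute_to_rank(counts, index.taxonomy, rank)
        vectors.append(to_abundance_vector(ra, counts.total, batch=g.batch))
    return vectors


@dataclass(slots=True)
class DiscoveryRun:
    """Everything one reference-free clustering run produced."""

    vectors: list[AbundanceVector]
    retained: list[AbundanceVector]
    rejection_log: pd.DataFrame
    cluster_map: pd.DataFrame
    truth_hosts: dict[str, str] = field(default_factory=dict)


def run_discovery(
    refset: ReferenceSet,
    config: SimulationConfig,
    thresholds: Optional[FilterThresholds] = None,
    k: int = 21,
    rank: str = "genus",
    seed: int = 0,
    contig_groups: Optional[Sequence[BarcodeGroup]] = None,
    n_neighbors: int = 30,
    resolution: float = 1.0,
    compute_embedding: bool = True,
) -> DiscoveryRun:
    """Simulate, classify, filter, and cluster one synthetic community.

    When ``contig_groups`` are given their vectors are purity-filtered
    and co-clustered with the cells. Truth hosts are recorded per unit
    for benchmarking.
    """
    thresholds = thresholds or FilterThresholds()
    index = build_index(refset, k=k)
    truth_hosts: dict[str, str] = {}
    vectors: list[AbundanceVector] = []
    for g in iter_barcode_groups(refset, config, seed=seed):
        truth_hosts[g.barcode_id] = g.truth_host
        counts = classify_group(g, index)
        ra = redistribute_to_rank(counts, index.taxonomy, rank)
        vectors.append(to_abundance_vector(ra, counts.total, batch=g.batch))
    retained, log = filter_vectors(vectors, thresholds)
    if contig_groups:
        contig_vectors = []
        for g in contig_groups:
            truth_hosts[g.barcode_id] = g.truth_host
            counts = classify_group(g, index)
            ra = redistribute_to_rank(counts, index.taxonomy, rank)
            contig_vectors.append(to_abundance_vector(ra, counts.total, batch="contig"))
        vectors = vectors + contig_vectors
        matrix = integrate_contigs(
            retained, contig_vectors, contig_min_purity=thresholds.min_purity_contig
        )
    else:
        matrix = assemble_matrix(retained)
    cmap = embed_cluster(
        matrix,
        n_neighbors=n_neighbors,
        resolution=resolution,
        seed=seed,
        compute_embedding=compute_embedding,
    )
    cmap = annotate(cmap, vectors, refset.taxonomy)
    return DiscoveryRun(
        vectors=vectors,
        retained=retained,
        rejection_log=log,
        cluster_map=cmap,
        truth_hosts=truth_hosts,
    )
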