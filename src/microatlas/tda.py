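"""Taxonomic discovery: genus-vector construction, filtering, clustering.

Each barcode group (or pseudo-contig read group) becomes a relative
abundance vector over the taxa observed at a working rank, annotated
with its read count, classified fraction, and purity (the relative
abundance of its dominant taxon). Vectors are quality-filtered, stacked
into a units x taxa matrix, embedded with UMAP for display, and
clustered by Leiden communities on a shared-nearest-neighbour graph
built in the vector space (cosine metric) — the embedding is for the
eye, the graph does the clustering. Metagenomic contig vectors pass a
stricter purity filter and then co-cluster with the cells, and clusters
can be re-resolved at species rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import RankAbundance
from .taxonomy import Taxonomy

__all__ = [
    "AbundanceVector",
    "FilterThresholds",
    "VectorMatrix",
    "BenchmarkReport",
    "to_abundance_vector",
    "filter_vectors",
    "assemble_matrix",
    "embed_cluster",
    "annotate",
    "integrate_contigs",
    "subcluster",
    "evaluate_benchmark",
]


@dataclass(slots=True)
class AbundanceVector:
    unit_id: str
    batch: str
    rank: str
    abundances: dict[int, float]
    read_count: int
    classified_fraction: float
    purity: float


def to_abundance_vector(
    abund: RankAbundance, total_reads: int, batch: str = "single_cell"
) -> AbundanceVector:
    """Normalize rank counts to fractions of classified reads.

    Purity is the maximum relative abundance; classified fraction uses
    the group's total read count as denominator so partially classified
    groups are penalised by the separate classified-fraction filter, not
    by a deflated purity.
    """
    classified = abund.classified_at_rank
    if any(v < 0 for v in abund.counts.values()):
        raise ValueError("negative counts")
    if total_reads < 0 or (classified > 0 and total_reads < classified - 1e-9):
        raise ValueError("total_reads must be >= classified reads")
    if classified > 0:
        fracs = {t: v / classified for t, v in abund.counts.items() if v > 0}
        purity = max(fracs.values())
        cf = classified / total_reads if total_reads else 0.0
    else:
        fracs, purity, cf = {}, 0.0, 0.0
    return AbundanceVector(
        unit_id=abund.barcode_id,
        batch=batch,
        rank=abund.rank,
        abundances=fracs,
        read_count=total_reads,
        classified_fraction=cf,
        purity=purity,
    )


@dataclass(slots=True)
class FilterThresholds:
    """Quality gates applied per unit; boundaries are inclusive (a unit
    sitting exactly at a threshold is retained)."""

    min_reads: int = 1000
    min_classified_fraction: float = 0.5
    min_purity: float = 0.8
    min_purity_contig: float = 0.9

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        for v in (self.min_classified_fraction, self.min_purity, self.min_purity_contig):
            if not (0.0 <= v <= 1.0):
                raise ValueError("fractions must be in [0, 1]")


def filter_vectors(
    vectors: Iterable[AbundanceVector], thresholds: Optional[FilterThresholds] = None
) -> tuple[list[AbundanceVector], pd.DataFrame]:
    """Retain units passing all gates; the rejection log records the first
    failed test per rejected unit."""
    thresholds = thresholds or FilterThresholds()
    retained: list[AbundanceVector] = []
    log_rows = []
    for v in vectors:
        min_purity = (
            thresholds.min_purity_contig if v.batch == "contig" else thresholds.min_purity
        )
        if v.read_count < thresholds.min_reads:
            log_rows.append((v.unit_id, v.batch, "read_count"))
        elif v.classified_fraction < thresholds.min_classified_fraction:
            log_rows.append((v.unit_id, v.batch, "classified_fraction"))
        elif v.purity < min_purity:
            log_rows.append((v.unit_id, v.batch, "purity"))
        else:
            retained.append(v)
    log = pd.DataFrame(log_rows, columns=["unit_id", "batch", "failed"])
    return retained, log


@dataclass(slots=True)
class VectorMatrix:
    unit_ids: list[str]
    batches: list[str]
    taxids: list[int]
    X: np.ndarray
    rank: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, index=self.unit_ids, columns=self.taxids)
        df.insert(0, "batch", self.batches)
        return df


def assemble_matrix(vectors: Sequence[AbundanceVector]) -> VectorMatrix:
    """Stack vectors over the union taxon universe (missing taxa -> 0)."""
    if not vectors:
        raise ValueError("no vectors to assemble")
    ranks = {v.rank for v in vectors}
    if len(ranks) != 1:
        raise ValueError(f"vectors mix ranks {sorted(ranks)}")
    taxids = sorted({t for v in vectors for t in v.abundances})
    col = {t: j for j, t in enumerate(taxids)}
    X = np.zeros((len(vectors), len(taxids)))
    for i, v in enumerate(vectors):
        for t, a in v.abundances.items():
            X[i, col[t]] = a
    return VectorMatrix(
        unit_ids=[v.unit_id for v in vectors],
        batches=[v.batch for v in vectors],
        taxids=taxids,
        X=X,
        rank=ranks.pop(),
    )


# -- clustering ------------------------------------------------------------


def _snn_graph(X: np.ndarray, n_neighbors: int):
    """Shared-nearest-neighbour graph (Jaccard-weighted) on cosine kNN."""
    from sklearn.neighbors import NearestNeighbors

    n = X.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1, metric="cosine")
    nn.fit(X)
    _, idx = nn.kneighbors(X)
    neigh = [set(row.tolist()) for row in idx]  # includes self
    seen: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j == i:
                continue
            key = (i, j) if i < j else (j, i)
            if key in seen:
                continue
            shared = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = shared / union
            if w > 0:
                seen[key] = w
    edges = list(seen.keys())
    weights = [seen[e] for e in edges]
    return n, edges, weights


def _leiden_labels(n: int, edges, weights, resolution: float, seed: int) -> np.ndarray:
    import igraph as ig
    import leidenalg

    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights or None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def _umap_coords(X: np.ndarray, n_neighbors: int, min_dist: float, seed: int) -> np.ndarray:
    n = X.shape[0]
    if n < 6:
        # too few points for a manifold embedding; fall back to PCA-style coords
        Xc = X - X.mean(axis=0)
        if Xc.shape[1] == 0 or not np.any(Xc):
            return np.zeros((n, 2))
        u, s, _ = np.linalg.svd(Xc, full_matrices=False)
        coords = u[:, :2] * s[:2]
        if coords.shape[1] < 2:
            coords = np.column_stack([coords, np.zeros(n)])
        return coords
    import umap

    reducer = umap.UMAP(
        n_neighbors=min(n_neighbors, n - 1),
        min_dist=min_dist,
        metric="cosine",
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(X), dtype=float)


def embed_cluster(
    matrix: VectorMatrix,
    n_neighbors: int = 30,
    min_dist: float = 0.1,
    resolution: float = 1.0,
    seed: int = 0,
    compute_embedding: bool = True,
) -> pd.DataFrame:
    """2-D embedding plus Leiden cluster labels; deterministic per seed.

    Returns a frame with columns unit_id, batch, x, y, cluster. An
    all-identical matrix degenerates to a single cluster.
    """
    X = matrix.X
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units to cluster")
    if np.allclose(X, X[0]):
        labels = np.zeros(n, dtype=int)
        coords = np.zeros((n, 2))
    else:
        n_g, edges, weights = _snn_graph(X, n_neighbors)
        labels = _leiden_labels(n_g, edges, weights, resolution, seed)
        coords = (
            _umap_coords(X, n_neighbors, min_dist, seed)
            if compute_embedding
            else np.zeros((n, 2))
        )
    return pd.DataFrame(
        {
            "unit_id": matrix.unit_ids,
            "batch": matrix.batches,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "cluster": labels,
        }
    )


def annotate(
    cluster_map: pd.DataFrame,
    vectors: Sequence[AbundanceVector],
    taxonomy: Optional[Taxonomy] = None,
) -> pd.DataFrame:
    """Dominant-taxon annotation per unit and modal annotation per cluster.

    Abundance ties break lexicographically on the taxon label and are
    flagged in the ``tie`` column.
    """
    by_id = {v.unit_id: v for v in vectors}

    def label(taxid: int) -> str:
        if taxonomy is not None and taxid in taxonomy:
            return taxonomy.name(taxid)
        return str(taxid)

    annotations, ties = [], []
    for uid in cluster_map["unit_id"]:
        v = by_id.get(uid)
        if v is None or not v.abundances:
            annotations.append("unclassified")
            ties.append(False)
            continue
        best = max(v.abundances.values())
        winners = sorted(label(t) for t, a in v.abundances.items() if a == best)
        annotations.append(winners[0])
        ties.append(len(winners) > 1)
    out = cluster_map.copy()
    out["annotation"] = annotations
    out["tie"] = ties
    modal = (
        out.groupby("cluster")["annotation"]
        .agg(lambda s: sorted(s.mode())[0])
        .to_dict()
    )
    out["cluster_annotation"] = out["cluster"].map(modal)
    return out


def integrate_contigs(
    cell_vectors: Sequence[AbundanceVector],
    contig_vectors: Sequence[AbundanceVector],
    contig_min_purity: float = 0.9,
) -> VectorMatrix:
    """Purity-filter contig vectors, then stack them with the cells for a
    joint embedding (batch column preserved)."""
    ranks = {v.rank for v in cell_vectors} | {v.rank for v in contig_vectors}
    if len(ranks) > 1:
        raise ValueError(f"cell and contig vectors mix ranks {sorted(ranks)}")
    kept = [
        replace(v, batch="contig")
        for v in contig_vectors
        if v.purity >= contig_min_purity
    ]
    return assemble_matrix(list(cell_vectors) + kept)


def subcluster(
    unit_ids: Sequence[str],
    species_vectors: Sequence[AbundanceVector],
    n_neighbors: int = 30,
    resolution: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-cluster one (genus) cluster's units using species-rank vectors."""
    chosen = [v for v in species_vectors if v.unit_id in set(unit_ids)]
    if len(chosen) < 2:
        raise ValueError("subcluster needs at least 2 units")
    matrix = assemble_matrix(chosen)
    return embed_cluster(
        matrix, n_neighbors=n_neighbors, resolution=resolution, seed=seed
    )


@dataclass(slots=True)
class BenchmarkReport:
    identification_accuracy: float
    mean_after_filter_purity: float
    retained_units: int
    retention_curve: pd.DataFrame = field(repr=False, default=None)


def evaluate_benchmark(
    cluster_map: pd.DataFrame,
    vectors: Sequence[AbundanceVector],
    truth: Mapping[str, str],
    threshold_grid: Sequence[float] = tuple(np.arange(0.50, 1.00, 0.01)),
) -> BenchmarkReport:
    """Score an annotated run against truth labels.

    ``truth`` maps unit_id to the true taxon label (same labelling as
    :func:`annotate` produced). Identification accuracy is the fraction
    of units whose dominant-taxon annotation equals truth; the retention
    curve counts units passing each purity threshold and their mean
    purity after filtering.
    """
    if "annotation" not in cluster_map.columns:
        raise ValueError("cluster_map must be annotated first")
    missing = [u for u in cluster_map["unit_id"] if u not in truth]
    if missing:
        raise KeyError(f"truth missing for units {missing[:3]}...")
    correct = sum(
        1
        for uid, ann in zip(cluster_map["unit_id"], cluster_map["annotation"])
        if truth[uid] == ann
    )
    accuracy = correct / len(cluster_map)
    purities = np.array([v.purity for v in vectors])
    rows = []
    for thr in threshold_grid:
        mask = purities >= thr
        rows.append(
            (
                float(thr),
                int(mask.sum()),
                float(purities[mask].mean()) if mask.any() else float("nan"),
            )
        )
    curve = pd.DataFrame(rows, columns=["threshold", "retained", "mean_purity"])
    retained_ids = set(cluster_map["unit_id"])
    after = [v.purity for v in vectors if v.unit_id in retained_ids]
    return BenchmarkReport(
        identification_accuracy=accuracy,
        mean_after_filter_purity=float(np.mean(after)) if after else float("nan"),
        retained_units=len(cluster_map),
        retention_curve=curve,
    )
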