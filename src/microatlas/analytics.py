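"""Cluster-level post-processing and assay arithmetic.

Once barcode groups are clustered, their reads are pooled per cluster
(for external assembly), coverage and rarefaction are computed against
a reference, a cluster error rate measures reads not attributable to
the cluster's taxon, gene presence/absence matrices are filtered and
subclustered, feature hits (e.g. antibiotic-resistance genes) are
counted as MAPQ-filtered, deduplicated reads per million, and droplet
occupancy probabilities are computed for the gel-loading arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import BarcodeGroup, ReadPair

__all__ = [
    "ClusterSummary",
    "OccupancyProfile",
    "pool_cluster",
    "write_pooled_fastq",
    "coverage_stats",
    "rarefaction",
    "cluster_error_rate",
    "filter_gene_matrix",
    "subcluster_genes",
    "count_feature_hits",
    "droplet_occupancy",
]


@dataclass(slots=True)
class ClusterSummary:
    cluster: str
    pooled_reads: int
    covered_fraction: float
    mean_depth: float
    error_rate: float


# -- read pooling ----------------------------------------------------------


def pool_cluster(
    groups: Mapping[str, BarcodeGroup] | Iterable[BarcodeGroup],
    labels: Mapping[str, object],
) -> dict[object, list[ReadPair]]:
    """Concatenate reads per cluster, ordered by (barcode, serial).

    Every barcode must be labelled; read counts are conserved exactly.
    """
    if not isinstance(groups, Mapping):
        groups = {g.barcode_id: g for g in groups}
    pools: dict[object, list[ReadPair]] = {}
    for bc in sorted(groups):
        if bc not in labels:
            raise KeyError(f"barcode {bc!r} has no cluster label")
        pools.setdefault(labels[bc], []).extend(groups[bc].read_pairs)
    return pools


def write_pooled_fastq(
    pools: Mapping[object, list[ReadPair]], out_dir: str | Path
) -> dict[object, tuple[Path, Path]]:
    """One FASTQ pair per cluster, for handing to an external assembler."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for cluster, reads in pools.items():
        r1 = out / f"cluster_{cluster}_R1.fastq"
        r2 = out / f"cluster_{cluster}_R2.fastq"
        with open(r1, "w") as f1, open(r2, "w") as f2:
            for rp in reads:
                f1.write(f"@{rp.read_id}/1\n{rp.seq1}\n+\n{rp.qual1}\n")
                f2.write(f"@{rp.read_id}/2\n{rp.seq2}\n+\n{rp.qual2}\n")
        paths[cluster] = (r1, r2)
    return paths


# -- coverage --------------------------------------------------------------


def coverage_stats(
    placements: Iterable[tuple[int, int]], genome_length: int
) -> tuple[float, float]:
    """Covered-base fraction and mean depth from (start, length) intervals.

    Intervals are half-open, 0-based; a placement beyond the genome end
    is an error.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    delta = np.zeros(genome_length + 1, dtype=np.int64)
    total = 0
    for start, length in placements:
        if start < 0 or length < 0 or start + length > genome_length:
            raise ValueError(f"placement ({start}, {length}) outside genome")
        delta[start] += 1
        delta[start + length] -= 1
        total += length
    depth = np.cumsum(delta[:-1])
    covered = int((depth > 0).sum())
    return covered / genome_length, total / genome_length


def rarefaction(
    placements: Sequence[tuple[int, int]],
    genome_length: int,
    n_total: int = 10000,
    n_points: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Coverage saturation curve by cumulative subsampling without
    replacement (capped at the group size); evaluated at ``n_points``
    evenly spaced depths, ending at ``n_total``."""
    rng = np.random.default_rng(seed)
    n_total = min(n_total, len(placements))
    order = rng.permutation(len(placements))[:n_total]
    checkpoints = np.unique(
        np.linspace(0, n_total, n_points + 1).round().astype(int)[1:]
    )
    rows = []
    for m in checkpoints:
        chosen = [placements[i] for i in order[:m]]
        frac, _ = coverage_stats(chosen, genome_length)
        rows.append((int(m), frac))
    return pd.DataFrame(rows, columns=["reads_sampled", "covered_fraction"])


def cluster_error_rate(sources: Sequence[object], allowed: Iterable[object]) -> float:
    """Fraction of reads whose source is not in the cluster's allowed set
    (truth mode), or equivalently the unaligned fraction when ``sources``
    are alignment statuses and ``allowed`` the aligned markers."""
    sources = list(sources)
    if not sources:
        return 0.0
    allowed = set(allowed)
    bad = sum(1 for s in sources if s not in allowed)
    return bad / len(sources)


# -- gene matrices ---------------------------------------------------------


def filter_gene_matrix(
    matrix: pd.DataFrame, min_cells_per_gene: int = 10, min_genes_per_cell: int = 10
) -> pd.DataFrame:
    """Drop genes present in too few cells, then cells with too few genes
    (one pass, in that order). Presence means a positive entry."""
    present = matrix > 0
    genes_ok = present.sum(axis=0) >= min_cells_per_gene
    out = matrix.loc[:, genes_ok]
    cells_ok = (out > 0).sum(axis=1) >= min_genes_per_cell
    return out.loc[cells_ok]


def subcluster_genes(
    matrix: pd.DataFrame,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
) -> pd.Series:
    """Leiden communities on the Jaccard kNN graph of the binary matrix.

    Returns one integer label per cell (row); an all-identical matrix
    collapses to a single cluster.
    """
    from .tda import _leiden_labels

    X = (matrix.to_numpy() > 0)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    if (X == X[0]).all():
        return pd.Series(np.zeros(n, dtype=int), index=matrix.index, name="cluster")
    inter = (X.astype(int) @ X.T.astype(int))
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = np.where(union > 0, inter / union, 1.0)
    k = min(n_neighbors, n - 1)
    seen: dict[tuple[int, int], float] = {}
    for i in range(n):
        sim = jac[i].copy()
        sim[i] = -1
        for j in np.argsort(-sim, kind="stable")[:k]:
            j = int(j)
            a, b = min(i, j), max(i, j)
            if jac[a, b] > 0:
                seen[(a, b)] = float(jac[a, b])
    edges = list(seen.keys())
    weights = [seen[e] for e in edges]
    labels = _leiden_labels(n, edges, weights, resolution, seed)
    return pd.Series(labels, index=matrix.index, name="cluster")


# -- feature counting ------------------------------------------------------


def count_feature_hits(
    alignments: pd.DataFrame,
    total_reads: int,
    mapq_min: int = 42,
) -> pd.DataFrame:
    """Unique feature hits per million total reads.

    ``alignments`` needs columns read_id, feature_id, mapq, position.
    Records below ``mapq_min`` are discarded; identical
    (feature_id, position) records count once (duplicate removal).
    Result is order-invariant.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    required = {"read_id", "feature_id", "mapq", "position"}
    missing = required - set(alignments.columns)
    if missing:
        raise ValueError(f"alignments missing columns {sorted(missing)}")
    kept = alignments[alignments["mapq"] >= mapq_min]
    uniq = kept.drop_duplicates(subset=["feature_id", "position"])
    counts = uniq.groupby("feature_id").size().sort_index()
    out = counts.rename("unique_hits").to_frame()
    out["rpm"] = out["unique_hits"] * 1_000_000 / total_reads
    return out.reset_index()


# -- droplet occupancy -----------------------------------------------------


@dataclass(slots=True)
class OccupancyProfile:
    load_rate: float
    gels_per_droplet: int
    model: str
    p_zero: float
    p_one: float
    p_multi: float
    pmf: np.ndarray

    @property
    def p_any(self) -> float:
        return self.p_one + self.p_multi


def droplet_occupancy(
    load_rate: float = 0.02,
    gels_per_droplet: int = 5,
    model: str = "binomial",
) -> OccupancyProfile:
    """Cells-per-droplet distribution for gel loading.

    With n gels per droplet each occupied with probability p, the
    binomial model gives P(k) = C(n,k) p^k (1-p)^(n-k); the Poisson
    model uses rate lambda = n*p. Defaults (p=0.02, n=5) give the
    roughly-10%-occupied / 90%-empty operating point of dilute loading.
    """
    if not (0.0 <= load_rate <= 1.0):
        raise ValueError("load_rate must be in [0, 1]")
    if gels_per_droplet < 0:
        raise ValueError("gels_per_droplet must be >= 0")
    if model == "binomial":
        k = np.arange(gels_per_droplet + 1)
        pmf = stats.binom.pmf(k, gels_per_droplet, load_rate)
    elif model == "poisson":
        lam = gels_per_droplet * load_rate
        cap = max(20, int(lam + 12 * np.sqrt(lam + 1)))
        pmf = stats.poisson.pmf(np.arange(cap + 1), lam)
    else:
        raise ValueError("model must be 'binomial' or 'poisson'")
    p0 = float(pmf[0]) if pmf.size else 1.0
    p1 = float(pmf[1]) if pmf.size > 1 else 0.0
    return OccupancyProfile(
        load_rate=load_rate,
        gels_per_droplet=gels_per_droplet,
        model=model,
        p_zero=p0,
        p_one=p1,
        p_multi=max(0.0, 1.0 - p0 - p1),
        pmf=pmf,
    )
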