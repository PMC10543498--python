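"""Self-contained k-mer LCA read classification and rank redistribution.

The classifier follows the canonical k-mer/LCA design of Kraken-style
tools: every k-mer of every reference genome is indexed under the
lowest common ancestor of the genomes containing it; a read (pair) is
classified by pooling its k-mer hits and scoring every root-to-leaf
path by the total hit count on its nodes, returning the leaf-most node
of the best path (ties resolved to the LCA of the tied terminals).
Counts assigned above a working rank (typically genus) are then
redistributed down to that rank proportionally to the counts already
lifted from below — the proportionality at the heart of Bracken's
re-estimation. Reports written by real Kraken2/Bracken runs can be
imported in place of the internal classifier.

No minimizers, spaced seeds, or confidence thresholds: the contract is
the same input/output shape as the external tools, at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seq import kmer_codes, seq_to_array
from .simulate import BarcodeGroup, ReadPair
from .taxonomy import RANK_INDEX, ReferenceSet, Taxonomy, TaxonomyError

__all__ = [
    "KmerIndex",
    "TaxonCounts",
    "RankAbundance",
    "build_index",
    "classify_read_pair",
    "classify_group",
    "redistribute_to_rank",
    "import_external_report",
]


class KmerIndex:
    """Sorted canonical k-mer code array mapping to LCA taxids."""

    def __init__(self, k: int, codes: np.ndarray, taxids: np.ndarray, taxonomy: Taxonomy):
        self.k = k
        self.codes = codes  # sorted uint64
        self.taxids = taxids  # parallel int64
        self.taxonomy = taxonomy
        # root-to-self ancestor sets for path scoring
        self._anc: dict[int, frozenset[int]] = {}

    def __len__(self) -> int:
        return self.codes.size

    def lookup(self, query: np.ndarray) -> np.ndarray:
        """Taxid per query code, -1 for misses."""
        idx = np.searchsorted(self.codes, query)
        idx_c = np.minimum(idx, self.codes.size - 1) if self.codes.size else idx
        if self.codes.size == 0:
            return np.full(query.size, -1, dtype=np.int64)
        hit = self.codes[idx_c] == query
        hit &= idx < self.codes.size
        out = np.where(hit, self.taxids[idx_c], -1)
        return out

    def lookup_kmer(self, kmer: str) -> Optional[int]:
        """Taxid for one k-mer string (canonicalized), or None."""
        arr = seq_to_array(kmer)
        if arr.size != self.k:
            raise ValueError(f"expected a {self.k}-mer")
        codes, valid = kmer_codes(arr, self.k)
        if not valid[0]:
            return None
        t = int(self.lookup(codes[:1])[0])
        return None if t < 0 else t

    def ancestor_set(self, taxid: int) -> frozenset[int]:
        s = self._anc.get(taxid)
        if s is None:
            s = frozenset(self.taxonomy.ancestors(taxid))
            self._anc[taxid] = s
        return s


def build_index(refset: ReferenceSet, k: int = 21) -> KmerIndex:
    """Index every genome k-mer under the LCA of the genomes containing it."""
    if k % 2 == 0 or not (11 <= k <= 31):
        raise ValueError("k must be odd and in [11, 31]")
    tax = refset.taxonomy
    code_chunks: list[np.ndarray] = []
    taxid_chunks: list[np.ndarray] = []
    for genome in refset:
        per_genome: list[np.ndarray] = []
        for seq in genome.sequences:
            codes, valid = kmer_codes(seq_to_array(seq), k)
            per_genome.append(codes[valid])
        if not per_genome:
            continue
        uniq = np.unique(np.concatenate(per_genome))
        code_chunks.append(uniq)
        taxid_chunks.append(np.full(uniq.size, genome.taxid, dtype=np.int64))
    if not code_chunks:
        return KmerIndex(k, np.empty(0, np.uint64), np.empty(0, np.int64), tax)
    codes = np.concatenate(code_chunks)
    taxids = np.concatenate(taxid_chunks)
    order = np.argsort(codes, kind="stable")
    codes, taxids = codes[order], taxids[order]
    # collapse duplicate codes to the LCA of their source taxids
    boundary = np.empty(codes.size, dtype=bool)
    boundary[0] = True
    boundary[1:] = codes[1:] != codes[:-1]
    starts = np.flatnonzero(boundary)
    ends = np.append(starts[1:], codes.size)
    out_codes = codes[starts]
    out_taxids = taxids[starts].copy()
    multi = np.flatnonzero(ends - starts > 1)
    for i in multi:
        t = int(taxids[starts[i]])
        for j in range(starts[i] + 1, ends[i]):
            t = tax.lca(t, int(taxids[j]))
        out_taxids[i] = t
    return KmerIndex(k, out_codes, out_taxids, tax)


@dataclass(slots=True)
class TaxonCounts:
    """Per-barcode direct classification counts at assignment nodes."""

    barcode_id: str
    counts: dict[int, int] = field(default_factory=dict)
    unclassified: int = 0
    total: int = 0

    @property
    def classified(self) -> int:
        return sum(self.counts.values())


@dataclass(slots=True)
class RankAbundance:
    """Read counts redistributed onto nodes of one rank."""

    barcode_id: str
    rank: str
    counts: dict[int, float] = field(default_factory=dict)

    @property
    def classified_at_rank(self) -> float:
        return sum(self.counts.values())


# -- classification --------------------------------------------------------


def _score_hits(hits: Sequence[int], index: KmerIndex) -> Optional[int]:
    """Kraken-style path scoring over the multiset of hit taxids."""
    if not isinstance(hits, dict):
        counts: dict[int, int] = {}
        for t in hits:
            counts[t] = counts.get(t, 0) + 1
    else:
        counts = hits
    if not counts:
        return None
    if len(counts) == 1:
        return next(iter(counts))
    best_score = -1
    best: list[int] = []
    for cand in counts:
        anc = index.ancestor_set(cand)
        score = sum(c for t, c in counts.items() if t in anc)
        if score > best_score:
            best_score, best = score, [cand]
        elif score == best_score:
            best.append(cand)
    if len(best) == 1:
        return best[0]
    tax = index.taxonomy
    t = best[0]
    for other in best[1:]:
        t = tax.lca(t, other)
    return t


def _encode_reads(seqs: Sequence[str], k: int) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Concatenate reads (k-spacer-separated) and compute one code array.

    Returns (codes, valid, spans) where spans[i] slices the windows of
    read i out of the shared arrays.
    """
    spacer = "N" * k
    buf = spacer.join(seqs)
    arr = seq_to_array(buf)
    codes, valid = kmer_codes(arr, k)
    spans = []
    pos = 0
    for s in seqs:
        n_win = max(0, len(s) - k + 1)
        spans.append((pos, pos + n_win))
        pos += len(s) + k
    return codes, valid, spans


def classify_group(group: BarcodeGroup, index: KmerIndex) -> TaxonCounts:
    """Classify every read pair of a barcode group (mates pooled)."""
    out = TaxonCounts(barcode_id=group.barcode_id, total=len(group.read_pairs))
    if not group.read_pairs:
        return out
    seqs: list[str] = []
    for rp in group.read_pairs:
        seqs.append(rp.seq1)
        seqs.append(rp.seq2)
    codes, valid, spans = _encode_reads(seqs, index.k)
    taxids = index.lookup(codes)
    taxids[~valid] = -1
    # window -> read-pair index (both mates of pair i share index i)
    n_pairs = len(group.read_pairs)
    window_pair = np.full(taxids.size, -1, dtype=np.int64)
    for s, (a0, a1) in enumerate(spans):
        window_pair[a0:a1] = s // 2
    found = (taxids >= 0) & (window_pair >= 0)
    r = window_pair[found]
    t = taxids[found]
    # per (pair, taxid) hit counts via one unique pass
    big = np.int64(int(taxids.max()) + 1) if t.size else np.int64(1)
    keys, kcounts = np.unique(r * big + t, return_counts=True)
    kr = (keys // big).astype(np.int64)
    kt = (keys % big).astype(np.int64)
    classified = np.zeros(n_pairs, dtype=bool)
    boundaries = np.flatnonzero(np.diff(kr, prepend=-1))
    ends = np.append(boundaries[1:], kr.size)
    for b0, b1 in zip(boundaries, ends):
        pair = int(kr[b0])
        classified[pair] = True
        if b1 - b0 == 1:
            assigned = int(kt[b0])
        else:
            counts = {int(kt[j]): int(kcounts[j]) for j in range(b0, b1)}
            assigned = _score_hits(counts, index)
        out.counts[assigned] = out.counts.get(assigned, 0) + 1
    out.unclassified = int(n_pairs - classified.sum())
    return out


def classify_read_pair(pair: ReadPair, index: KmerIndex) -> Optional[int]:
    """Taxid for one read pair, or None when no k-mer is indexed."""
    if min(len(pair.seq1), len(pair.seq2)) < index.k:
        raise ValueError("mates shorter than k")
    codes, valid, spans = _encode_reads([pair.seq1, pair.seq2], index.k)
    taxids = index.lookup(codes)
    taxids[~valid] = -1
    hits = [int(t) for t in taxids if t >= 0]
    return _score_hits(hits, index)


# -- rank redistribution ---------------------------------------------------


def redistribute_to_rank(
    counts: TaxonCounts, taxonomy: Taxonomy, rank: str = "genus"
) -> RankAbundance:
    """Lift below-rank counts to their rank ancestor; split above-rank
    counts among rank descendants proportionally to the lifted counts
    (uniformly when all are zero). Paths with no node at ``rank`` drop
    out of the profile.
    """
    if rank not in RANK_INDEX:
        raise TaxonomyError(f"unknown rank {rank!r}")
    target_idx = RANK_INDEX[rank]
    lifted: dict[int, float] = {}
    above: dict[int, int] = {}
    for taxid, n in counts.counts.items():
        if n < 0:
            raise ValueError("negative count")
        node_rank = taxonomy.nodes[taxid].rank
        if RANK_INDEX[node_rank] >= target_idx:
            anc = taxonomy.ancestor_at_rank(taxid, rank)
            if anc is not None:
                lifted[anc] = lifted.get(anc, 0.0) + n
            # else: path skips the rank -> dropped
        else:
            above[taxid] = above.get(taxid, 0) + n
    out = dict(lifted)
    for taxid, n in above.items():
        descendants = taxonomy.descendants_at_rank(taxid, rank)
        if not descendants:
            continue  # nothing at the rank below this node -> dropped
        weights = np.array([lifted.get(d, 0.0) for d in descendants])
        if weights.sum() == 0:
            weights = np.ones(len(descendants))
        weights = weights / weights.sum()
        for d, w in zip(descendants, weights):
            out[d] = out.get(d, 0.0) + n * float(w)
    return RankAbundance(barcode_id=counts.barcode_id, rank=rank, counts=out)


# -- external report import ------------------------------------------------

_KRAKEN_RANK_CODES = {
    "R": "root",
    "D": "superkingdom",
    "K": "superkingdom",
    "P": "phylum",
    "C": "class",
    "O": "order",
    "F": "family",
    "G": "genus",
    "S": "species",
}


def import_external_report(
    path: str | Path,
    format: str,
    rank: str = "genus",
    barcode_id: str = "",
) -> RankAbundance:
    """Parse a Kraken2 report or Bracken TSV into a :class:`RankAbundance`.

    Kraken2 reports are the 6-column dialect (percent, clade_reads,
    direct_reads, rank code, taxid, indented name); rows whose rank code
    matches ``rank`` contribute their clade read counts. Bracken TSVs
    contribute ``new_est_reads`` per taxon.
    """
    if format == "kraken2_report":
        counts: dict[int, float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 6:
                    raise ValueError(
                        f"{path}:{lineno}: expected 6 columns in Kraken2 report, "
                        f"got {len(parts)}"
                    )
                code = parts[3].strip()[:1]
                if _KRAKEN_RANK_CODES.get(code) != rank:
                    continue
                try:
                    taxid = int(parts[4])
                    clade_reads = float(parts[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
                counts[taxid] = counts.get(taxid, 0.0) + clade_reads
        return RankAbundance(barcode_id=barcode_id, rank=rank, counts=counts)
    if format == "bracken_tsv":
        counts = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            try:
                i_tax = header.index("taxonomy_id")
                i_est = header.index("new_est_reads")
            except ValueError as exc:
                raise ValueError(f"{path}:1: missing Bracken columns") from exc
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) <= max(i_tax, i_est):
                    raise ValueError(f"{path}:{lineno}: short Bracken row")
                try:
                    counts[int(parts[i_tax])] = counts.get(int(parts[i_tax]), 0.0) + float(
                        parts[i_est]
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
        return RankAbundance(barcode_id=barcode_id, rank=rank, counts=counts)
    raise ValueError(f"unknown report format {format!r}")
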