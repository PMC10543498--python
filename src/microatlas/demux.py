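"""Cell-barcode extraction, Hamming-1 correction, and demultiplexing.

Raw read 1 carries the cell barcode at a configurable offset. Observed
barcodes are matched to a whitelist: exact matches stand, a unique
whitelist entry at Hamming distance 1 corrects the observation, and
anything else (distance >= 2, or two candidates at distance 1) is
rejected so that sequencing errors cannot cross-contaminate groups.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import BarcodeGroup, ReadPair

__all__ = [
    "Whitelist",
    "BarcodeLayout",
    "AdapterSpec",
    "DemuxResult",
    "correct_barcode",
    "demultiplex",
    "filter_by_read_count",
    "random_whitelist",
]

_ALPHABET = "ACGT"


class Whitelist:
    """A set of equal-length barcodes over {A,C,G,T}."""

    def __init__(self, barcodes: Iterable[str]):
        barcodes = [b.upper() for b in barcodes]
        if not barcodes:
            raise ValueError("whitelist is empty")
        lengths = {len(b) for b in barcodes}
        if len(lengths) != 1:
            raise ValueError(f"whitelist barcodes have mixed lengths {sorted(lengths)}")
        bad = [b for b in barcodes if set(b) - set(_ALPHABET)]
        if bad:
            raise ValueError(f"non-ACGT barcode(s): {bad[:3]}")
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("whitelist contains duplicates")
        self.barcodes: frozenset[str] = frozenset(barcodes)
        self.length: int = lengths.pop()

    @classmethod
    def from_file(cls, path: str | Path) -> "Whitelist":
        with open(path) as fh:
            return cls([ln.strip() for ln in fh if ln.strip()])

    def __len__(self) -> int:
        return len(self.barcodes)

    def __contains__(self, bc: str) -> bool:
        return bc in self.barcodes


def random_whitelist(n: int, length: int = 9, seed: int = 0) -> Whitelist:
    """Random distinct barcodes, all at pairwise Hamming distance >= 3 not
    guaranteed — only distinctness is (as for real instrument whitelists,
    ambiguity at distance 1 is resolved by rejection)."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    while len(seen) < n:
        bc = "".join(_ALPHABET[i] for i in rng.integers(0, 4, size=length))
        seen.add(bc)
    return Whitelist(sorted(seen))


def correct_barcode(observed: str, whitelist: Whitelist) -> Optional[str]:
    """Exact match, else the unique whitelist entry at Hamming distance 1,
    else None (including ambiguous distance-1 ties)."""
    observed = observed.upper()
    if len(observed) != whitelist.length:
        raise ValueError(
            f"observed barcode length {len(observed)} != whitelist length "
            f"{whitelist.length}"
        )
    if observed in whitelist:
        return observed
    candidate = None
    for i, base in enumerate(observed):
        for alt in _ALPHABET:
            if alt == base:
                continue
            variant = observed[:i] + alt + observed[i + 1 :]
            if variant in whitelist:
                if candidate is not None:
                    return None  # ambiguous
                candidate = variant
    return candidate


@dataclass(slots=True)
class BarcodeLayout:
    """Where the barcode sits in read 1. ``length`` defaults to the
    whitelist length; combinatorial sub-blocks are modelled as one
    contiguous block of their concatenation."""

    offset: int = 0
    length: Optional[int] = None


@dataclass(slots=True)
class AdapterSpec:
    """Exact prefix/suffix adapter trimming with a small mismatch allowance."""

    r1_5p: Optional[str] = None
    r1_3p: Optional[str] = None
    r2_5p: Optional[str] = None
    r2_3p: Optional[str] = None
    max_mismatches: int = 1


@dataclass(slots=True)
class DemuxResult:
    groups: dict[str, BarcodeGroup] = field(default_factory=dict)
    rejected: int = 0

    @property
    def counts(self) -> dict[str, int]:
        return {bc: len(g) for bc, g in self.groups.items()}

    @property
    def assigned(self) -> int:
        return sum(len(g) for g in self.groups.values())

    @property
    def total(self) -> int:
        return self.assigned + self.rejected


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _trim(seq: str, qual: str, five: Optional[str], three: Optional[str], mm: int):
    if five and len(seq) >= len(five) and _mismatches(seq[: len(five)], five) <= mm:
        seq, qual = seq[len(five) :], qual[len(five) :]
    if three and len(seq) >= len(three) and _mismatches(seq[-len(three) :], three) <= mm:
        seq, qual = seq[: -len(three)], qual[: -len(three)]
    return seq, qual


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def demultiplex(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    whitelist: Whitelist,
    layout: Optional[BarcodeLayout] = None,
    trim: Optional[AdapterSpec] = None,
) -> DemuxResult:
    """Assign paired reads to corrected barcodes.

    Read 1 loses its barcode block (and any configured adapters); reads
    whose barcode cannot be corrected are counted as rejected. The
    conservation invariant assigned + rejected == input always holds.
    """
    layout = layout or BarcodeLayout()
    bc_len = layout.length or whitelist.length
    if bc_len != whitelist.length:
        raise ValueError("layout length disagrees with whitelist length")
    result = DemuxResult()
    with _open_text(fastq_r1) as f1, _open_text(fastq_r2) as f2:
        it1, it2 = FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                break
            if rec1 is None or rec2 is None:
                raise ValueError("paired FASTQ files are out of sync (unequal length)")
            (id1, seq1, q1), (id2, seq2, q2) = rec1, rec2
            if len(seq1) < layout.offset + bc_len:
                result.rejected += 1
                continue
            observed = seq1[layout.offset : layout.offset + bc_len]
            corrected = correct_barcode(observed, whitelist)
            if corrected is None:
                result.rejected += 1
                continue
            seq1t = seq1[: layout.offset] + seq1[layout.offset + bc_len :]
            q1t = q1[: layout.offset] + q1[layout.offset + bc_len :]
            if trim:
                seq1t, q1t = _trim(seq1t, q1t, trim.r1_5p, trim.r1_3p, trim.max_mismatches)
                seq2, q2 = _trim(seq2, q2, trim.r2_5p, trim.r2_3p, trim.max_mismatches)
            group = result.groups.get(corrected)
            if group is None:
                group = result.groups[corrected] = BarcodeGroup(barcode_id=corrected)
            group.read_pairs.append(ReadPair(id1.split()[0], seq1t, q1t, seq2, q2))
    return result


def filter_by_read_count(result: DemuxResult, min_reads: int = 1000) -> set[str]:
    """Barcodes with at least ``min_reads`` read pairs (boundary retained;
    groups with fewer are the "less than cutoff" rejects)."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    return {bc for bc, n in result.counts.items() if n >= min_reads}
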