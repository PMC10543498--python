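"""Strain resolution within a barcode group.

Closely related strains (~99% identity) share most of their genome, so
single reads rarely identify a strain on their own. Instead each genome
is treated as an "isoform": every read is aligned against the whole
panel, per-alignment likelihoods are computed from the mismatch count
under a per-base error rate epsilon,

    log L(read | strain) = m * log(epsilon / 3) + (L - m) * log(1 - epsilon),

and the per-barcode strain abundance vector theta is inferred with
mean-field variational Bayes under a Dirichlet(alpha) prior on the
mixture weights — the transcript-quantification model re-purposed for
genomes. A barcode is assigned to the most abundant strain when that
abundance reaches 15%; below that (or on a tie) it is called "mixed",
interpreted as a multiplet or unresolved cell.

Alignment is internal k-mer seed-and-extend (ungapped, mismatch-capped);
multi-mapping SAM records from a real aligner can be imported instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import digamma, gammaln, xlogy

from ._seq import forward_kmer_codes, revcomp, seq_to_array
from .simulate import BarcodeGroup
from .taxonomy import GenomeRecord

__all__ = [
    "StrainPanel",
    "AlignmentLikelihoods",
    "StrainPosterior",
    "align_reads_to_panel",
    "estimate_abundance_vb",
    "assign_strain",
    "likelihoods_from_sam",
]

MIXED = "mixed"


class StrainPanel:
    """An ordered panel of strain genomes with a shared k-mer seed index."""

    def __init__(self, genomes: Sequence[GenomeRecord], seed_k: int = 21):
        if len(genomes) < 2:
            raise ValueError("a strain panel needs at least 2 strains")
        ids = [g.genome_id for g in genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("strain ids must be unique")
        self.genomes = list(genomes)
        self.strain_ids = ids
        self.seed_k = seed_k
        self.arrays = [
            np.concatenate([seq_to_array(s) for s in g.sequences]) for g in genomes
        ]
        # forward-strand seed index: packed k-mer -> [(strain, pos), ...]
        self._seeds: dict[int, list[tuple[int, int]]] = {}
        for s, arr in enumerate(self.arrays):
            codes, valid = forward_kmer_codes(arr, seed_k)
            for pos in np.flatnonzero(valid):
                self._seeds.setdefault(int(codes[pos]), []).append((s, int(pos)))

    def __len__(self) -> int:
        return len(self.genomes)

    def seed_hits(self, code: int) -> list[tuple[int, int]]:
        return self._seeds.get(code, [])


@dataclass(slots=True)
class AlignmentLikelihoods:
    """reads x strains log-likelihood matrix; -inf marks "no alignment"."""

    barcode_id: str
    strain_ids: list[str]
    read_ids: list[str]
    loglik: np.ndarray  # (n_reads, n_strains)

    @property
    def n_reads(self) -> int:
        return self.loglik.shape[0]


def _best_mismatches(
    read_arr: np.ndarray,
    panel: StrainPanel,
    max_mismatches: int,
    seed_stride: int,
) -> np.ndarray:
    """Per-strain minimum mismatch count at any seeded placement; -1 if none."""
    L = read_arr.size
    k = panel.seed_k
    out = np.full(len(panel), -1, dtype=np.int64)
    if L < k:
        return out
    codes, valid = forward_kmer_codes(read_arr, k)
    offsets = list(range(0, L - k + 1, seed_stride))
    if offsets[-1] != L - k:
        offsets.append(L - k)
    candidates: set[tuple[int, int]] = set()
    for off in offsets:
        if not valid[off]:
            continue
        for strain, pos in panel.seed_hits(int(codes[off])):
            candidates.add((strain, pos - off))
    for strain, start in candidates:
        arr = panel.arrays[strain]
        if start < 0 or start + L > arr.size:
            continue
        m = int((arr[start : start + L] != read_arr).sum())
        if m <= max_mismatches and (out[strain] < 0 or m < out[strain]):
            out[strain] = m
    return out


def align_reads_to_panel(
    group: BarcodeGroup,
    panel: StrainPanel,
    epsilon: float = 0.01,
    max_mismatches: int = 5,
    seed_stride: int = 25,
) -> AlignmentLikelihoods:
    """Seed-and-extend every read pair against the panel.

    Both orientations of each mate are tried; mates contribute the sum
    of their best per-strain log-likelihoods when both align to a strain
    (the per-strain consistency rule), otherwise the aligned mate alone.
    Pairs aligning nowhere are dropped from the matrix.
    """
    if not (0.0 < epsilon < 0.25):
        raise ValueError("epsilon must be in (0, 0.25)")
    log_err = np.log(epsilon / 3.0)
    log_ok = np.log1p(-epsilon)
    S = len(panel)
    rows, read_ids = [], []
    for rp in group.read_pairs:
        per_mate = []
        for seq in (rp.seq1, rp.seq2):
            arr = seq_to_array(seq)
            m_f = _best_mismatches(arr, panel, max_mismatches, seed_stride)
            m_r = _best_mismatches(
                seq_to_array(revcomp(seq)), panel, max_mismatches, seed_stride
            )
            m = np.where(
                (m_f >= 0) & ((m_r < 0) | (m_f <= np.where(m_r < 0, np.iinfo(np.int64).max, m_r))),
                m_f,
                m_r,
            )
            L = arr.size
            ll = np.where(m >= 0, m * log_err + (L - m) * log_ok, -np.inf)
            per_mate.append(ll)
        ll1, ll2 = per_mate
        both = np.isfinite(ll1) & np.isfinite(ll2)
        if both.any():
            # likelihoods must be comparable across strains: once any
            # strain explains both mates, single-mate placements are
            # treated as non-alignments
            row = np.where(both, ll1 + ll2, -np.inf)
        elif np.isfinite(ll1).any():
            row = ll1
        else:
            row = ll2
        if np.isfinite(row).any():
            rows.append(row)
            read_ids.append(rp.read_id)
    loglik = np.array(rows) if rows else np.empty((0, S))
    return AlignmentLikelihoods(
        barcode_id=group.barcode_id,
        strain_ids=list(panel.strain_ids),
        read_ids=read_ids,
        loglik=loglik,
    )


@dataclass(slots=True)
class StrainPosterior:
    strain_ids: list[str]
    theta: np.ndarray
    elbo_trace: np.ndarray
    converged: bool
    n_reads: int
    n_informative_reads: int
    assignment: Optional[str] = None


def estimate_abundance_vb(
    lik: AlignmentLikelihoods,
    alpha: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> StrainPosterior:
    """Mean-field VB for the read-mixture model with a Dirichlet prior.

    Coordinate ascent alternates responsibilities
    ``r_is proportional to L_is * exp(E[log theta_s])`` with Dirichlet
    pseudo-count updates ``a_s = alpha + sum_i r_is`` until the
    posterior-mean theta moves less than ``tol``; the returned ELBO
    trace is monotone non-decreasing.
    """
    N, S = lik.loglik.shape
    if N == 0:
        raise ValueError("no reads with a finite likelihood")
    logL = lik.loglik
    row_max = logL.max(axis=1, keepdims=True)
    W = np.exp(logL - row_max)  # -inf -> 0
    logW = np.where(W > 0, logL - row_max, 0.0)
    alpha_vec = np.full(S, float(alpha))
    a = alpha_vec + N / S
    theta = a / a.sum()
    elbos = []
    converged = False
    log_b_prior = gammaln(alpha_vec).sum() - gammaln(alpha_vec.sum())
    shift = float(row_max.sum())
    for _ in range(max_iter):
        elog = digamma(a) - digamma(a.sum())
        R = W * np.exp(elog)[None, :]
        R /= R.sum(axis=1, keepdims=True)
        a = alpha_vec + R.sum(axis=0)
        theta_new = a / a.sum()
        log_b_post = gammaln(a).sum() - gammaln(a.sum())
        elbo = (
            float((R * logW).sum())
            - float(xlogy(R, R).sum())
            + log_b_post
            - log_b_prior
            + shift
        )
        elbos.append(elbo)
        if np.abs(theta_new - theta).max() < tol:
            theta = theta_new
            converged = True
            break
        theta = theta_new
    finite = np.isfinite(logL)
    uniform_rows = finite.all(axis=1) & (np.ptp(logL, axis=1) == 0)
    return StrainPosterior(
        strain_ids=list(lik.strain_ids),
        theta=theta,
        elbo_trace=np.array(elbos),
        converged=converged,
        n_reads=N,
        n_informative_reads=int(N - uniform_rows.sum()),
    )


def assign_strain(
    posterior: StrainPosterior, min_abundance: float = 0.15, tie_tol: float = 1e-9
) -> str:
    """Most abundant strain if its abundance reaches ``min_abundance``;
    "mixed" below the threshold or on an abundance tie."""
    theta = posterior.theta
    best = float(theta.max())
    if best < min_abundance:
        return MIXED
    winners = np.flatnonzero(theta >= best - tie_tol)
    if winners.size > 1:
        return MIXED
    return posterior.strain_ids[int(winners[0])]


def likelihoods_from_sam(
    path: str | Path,
    strain_ids: Sequence[str],
    epsilon: float = 0.01,
    barcode_id: str = "",
) -> AlignmentLikelihoods:
    """Build the likelihood matrix from multi-mapping SAM records.

    Expects an ``-a``-style alignment (all matches reported) with NM
    tags; reference names must match the panel's strain ids. Mates of a
    pair (same QNAME) contribute the sum of their per-strain best
    log-likelihoods.
    """
    import pysam

    idx = {sid: j for j, sid in enumerate(strain_ids)}
    log_err = np.log(epsilon / 3.0)
    log_ok = np.log1p(-epsilon)
    per_read: dict[str, dict[tuple[int, bool], float]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name not in idx:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            L = rec.query_length or (len(rec.query_sequence or ""))
            ll = nm * log_err + (L - nm) * log_ok
            key = (idx[rec.reference_name], rec.is_read2)
            best = per_read.setdefault(rec.query_name, {})
            if key not in best or ll > best[key]:
                best[key] = ll
    rows, read_ids = [], []
    S = len(strain_ids)
    for qname, hits in sorted(per_read.items()):
        row = np.full(S, -np.inf)
        for s in range(S):
            l1, l2 = hits.get((s, False)), hits.get((s, True))
            if l1 is not None and l2 is not None:
                row[s] = l1 + l2
            elif l1 is not None:
                row[s] = l1
            elif l2 is not None:
                row[s] = l2
        if np.isfinite(row).any():
            rows.append(row)
            read_ids.append(qname)
    loglik = np.array(rows) if rows else np.empty((0, S))
    return AlignmentLikelihoods(
        barcode_id=barcode_id,
        strain_ids=list(strain_ids),
        read_ids=read_ids,
        loglik=loglik,
    )
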