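"""Reference alignment shared by training-label construction and error-rate
evaluation.

Sequences are globally aligned to each reference with affine gap costs
(match +1, mismatch -1, gap open -2, gap extend -1).  Gaps at the ends
of the *query* row (unsequenced reference flanks) are free, so an
amplicon scores fairly against a longer reference; query overhangs are
penalized and counted as insertions.  Error events are substitutions,
inserted query bases and deleted reference bases.

Two fast paths avoid most dynamic programming on amplicon-scale data:
an exact-match lookup, and a Hamming scan for equal-length references.
When the minimum Hamming distance over the references is <= 2 the
optimal alignment provably contains no gaps under the scoring above
(an indel pair alone costs more than two substitutions), so the
mismatch positions are returned directly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align

from .contigs import _seq_to_u8

_HAMMING_FAST_PATH = 2  # optimality argument above holds up to 2 mismatches
_DP_CANDIDATES = 3  # references aligned in full when the fast path misses


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    # free end gaps in the query row: unsequenced reference flanks
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


@dataclass
class AlignmentErrors:
    """Error decomposition of one query against its best reference."""

    ref_id: str
    n_sub: int
    n_ins: int
    n_del: int
    query_errors: np.ndarray  # query positions labeled erroneous (sorted, unique)
    ref_positions: np.ndarray  # reference coordinate of every error event
    identity: float  # matching columns / query length

    @property
    def n_errors(self) -> int:
        return self.n_sub + self.n_ins + self.n_del


def _align_errors(aligner, query: str, ref: str):
    """(subs, ins, dels, query error positions, ref positions, matches)."""
    aln = aligner.align(ref, query)[0]
    t_blocks, q_blocks = aln.aligned
    qa = _seq_to_u8(query)
    ta = _seq_to_u8(ref)
    subs = ins = dels = matches = 0
    qerr: list[int] = []
    refpos: list[int] = []
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is None:
            if qs > 0:  # leading query overhang: insertions
                ins += qs
                qerr.extend(range(qs))
                refpos.extend([max(ts - 1, 0)] * qs)
            # leading reference flank: not an error
        else:
            dq, dt = qs - prev_q, ts - prev_t
            if dq:  # inserted query bases
                ins += dq
                qerr.extend(range(prev_q, qs))
                refpos.extend([prev_t - 1] * dq)
            if dt:  # deleted reference bases: label the query base left of the gap
                dels += dt
                qerr.append(prev_q - 1)
                refpos.extend(range(prev_t, ts))
        mism = np.flatnonzero(ta[ts:te] != qa[qs:qe])
        subs += mism.size
        matches += (te - ts) - mism.size
        qerr.extend((qs + mism).tolist())
        refpos.extend((ts + mism).tolist())
        prev_t, prev_q = te, qe
    if prev_q is not None and prev_q < len(query):  # trailing query overhang
        n_over = len(query) - prev_q
        ins += n_over
        qerr.extend(range(prev_q, len(query)))
        refpos.extend([min(prev_t, len(ref) - 1)] * n_over)
    return subs, ins, dels, qerr, refpos, matches


class ReferenceSet:
    """A set of reference sequences with cached best-alignment lookups."""

    def __init__(self, refs: Sequence[tuple[str, str]] | dict):
        if isinstance(refs, dict):
            refs = list(refs.items())
        if not refs:
            raise ValueError("reference set is empty")
        self.ids = [r[0] for r in refs]
        self.seqs = [r[1].upper() for r in refs]
        self._exact = {}
        for i, s in enumerate(self.seqs):
            self._exact.setdefault(s, i)
        # group equal-length references for the vectorized Hamming scan
        self._by_len: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for length in {len(s) for s in self.seqs}:
            idx = np.array([i for i, s in enumerate(self.seqs) if len(s) == length])
            mat = np.vstack([_seq_to_u8(self.seqs[i]) for i in idx])
            self._by_len[length] = (idx, mat)
        self._aligner = make_aligner()
        self._cache: dict[str, AlignmentErrors] = {}

    def __len__(self) -> int:
        return len(self.ids)

    def best(self, seq: str) -> AlignmentErrors:
        """Minimum-error alignment of ``seq`` over all references.

        Ties in error count are broken by reference input order.
        """
        hit = self._cache.get(seq)
        if hit is not None:
            return hit
        result = self._best_uncached(seq)
        self._cache[seq] = result
        return result

    def _best_uncached(self, seq: str) -> AlignmentErrors:
        empty = np.zeros(0, np.int64)
        i = self._exact.get(seq)
        if i is not None:
            return AlignmentErrors(self.ids[i], 0, 0, 0, empty, empty, 1.0)
        candidates = range(len(self.seqs))
        group = self._by_len.get(len(seq))
        if group is not None:
            idx, mat = group
            q = _seq_to_u8(seq)
            hams = np.count_nonzero(mat != q, axis=1)
            k = int(np.argmin(hams))
            if hams[k] <= _HAMMING_FAST_PATH:
                pos = np.flatnonzero(mat[k] != q).astype(np.int64)
                ident = 1.0 - hams[k] / len(seq)
                return AlignmentErrors(
                    self.ids[idx[k]], int(hams[k]), 0, 0, pos, pos.copy(), ident
                )
            if idx.size == len(self.seqs):
                # All references share the query's length: restrict the
                # dynamic programming to the closest few by Hamming
                # distance (point errors dominate; a farther reference
                # winning through indels would require a shifted repeat).
                order = np.argsort(hams, kind="stable")[:_DP_CANDIDATES]
                candidates = sorted(idx[order].tolist())
        best = None
        for i in candidates:
            ref = self.seqs[i]
            subs, ins, dels, qerr, refpos, matches = _align_errors(self._aligner, seq, ref)
            total = subs + ins + dels
            if best is None or total < best[0]:
                best = (total, i, subs, ins, dels, qerr, refpos, matches)
        _, i, subs, ins, dels, qerr, refpos, matches = best
        return AlignmentErrors(
            self.ids[i],
            subs,
            ins,
            dels,
            np.unique(np.asarray(qerr, np.int64)),
            np.asarray(refpos, np.int64),
            matches / max(len(seq), 1),
        )
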