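"""Abundance-sorted single-linkage preclustering with masked distances.

Rare sequences are merged into near-identical, strictly more abundant
ones when they differ by at most one base per 100 nt.  Positions
flagged as potential sequencing errors (on either sequence of a pair)
do not count toward the distance, which lets error-containing reads
reach the correct representative they came from.  Masks never mutate
sequence content: after clustering every emitted representative is
byte-identical to one of the input sequences.

Running with all-false masks reproduces the plain single-linkage
preclustering baseline exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contigs import UniqueSequence, _seq_to_u8

GAP = ord("-")


def masked_distance(seq_a: str, mask_a, seq_b: str, mask_b) -> int:
    """Number of differing positions, ignoring masked and gap-gap columns.

    ``mask_a``/``mask_b`` are boolean vectors (None means no mask); a
    mask on either sequence suppresses the difference at that column.
    Sequences must be equal length (same amplicon region, or aligned).
    """
    a = _seq_to_u8(seq_a)
    b = _seq_to_u8(seq_b)
    mask_a = np.zeros(a.size, bool) if mask_a is None else np.asarray(mask_a, bool)
    mask_b = np.zeros(b.size, bool) if mask_b is None else np.asarray(mask_b, bool)
    if not (a.size == b.size == mask_a.size == mask_b.size):
        raise ValueError("masked_distance requires equal-length sequences and masks")
    diff = (a != b) & ~((a == GAP) & (b == GAP))
    return int(np.count_nonzero(diff & ~mask_a & ~mask_b))


def allowed_diffs(seq_len: int) -> int:
    """Merge threshold for a given ungapped length: one difference per
    100 nt, i.e. floor(len/100), clamped to a minimum of 1."""
    if seq_len < 1:
        raise ValueError("sequence length must be >= 1")
    return max(1, seq_len // 100)


@dataclass
class MergeRecord:
    rare_id: str
    representative_id: str
    distance: int


@dataclass
class ClusterResult:
    """Outcome of one preclustering run.

    ``merge_map`` sends every input unique-sequence ID to the ID of the
    representative that absorbed it (itself if unmerged); chains are
    resolved, so every representative maps to itself.
    """

    merge_map: dict[str, str]
    table: list[UniqueSequence]
    records: list[MergeRecord] = field(default_factory=list)


def _ungapped_len(seq: str) -> int:
    return len(seq) - seq.count("-")


def precluster(uniques: Sequence[UniqueSequence], diffs="auto") -> ClusterResult:
    """Single-linkage precluster a table of unique sequences.

    Sequences are processed in abundance-descending order (ties broken
    lexicographically).  Each sequence is compared against every
    strictly more abundant current representative; among those within
    the allowed number of masked differences it merges into the nearest
    (ties: highest current abundance, then earliest-established
    representative), immediately transferring its abundance so that
    later sequences see post-merge abundances.

    ``diffs`` is an integer threshold, or "auto" to apply the 1-per-100-nt
    rule to each rare sequence's ungapped length.
    """
    if not uniques:
        return ClusterResult({}, [], [])
    length = len(uniques[0].seq)
    for u in uniques:
        if len(u.seq) != length:
            raise ValueError(
                "precluster requires equal-length sequences; align them first"
            )
    order = sorted(range(len(uniques)), key=lambda i: (-uniques[i].abundance, uniques[i].seq))
    seqs = np.vstack([_seq_to_u8(u.seq) for u in uniques]) if length else np.zeros((len(uniques), 0), np.uint8)
    masks = np.vstack([u.mask for u in uniques]) if length else np.zeros((len(uniques), 0), bool)

    abundance = [u.abundance for u in uniques]
    members: dict[int, list[str]] = {}
    rep_order: list[int] = []  # established representatives, earliest first
    absorbed_by: dict[int, int] = {}
    records: list[MergeRecord] = []

    for i in order:
        u = uniques[i]
        members[i] = list(u.member_ids)
        limit = allowed_diffs(_ungapped_len(u.seq)) if diffs == "auto" else int(diffs)
        best: tuple[int, int, int] | None = None  # (distance, -abundance, rep rank)
        best_rep = -1
        if rep_order:
            reps = np.array(rep_order)
            stronger = np.array([abundance[r] > u.abundance for r in rep_order])
            cand = reps[stronger]
            if cand.size:
                pair_diff = (seqs[cand] != seqs[i]) & ~(
                    (seqs[cand] == GAP) & (seqs[i] == GAP)
                )
                counted = pair_diff & ~masks[cand] & ~masks[i]
                dists = counted.sum(axis=1)
                for rank, (r, d) in enumerate(zip(cand.tolist(), dists.tolist())):
                    if d <= limit:
                        key = (d, -abundance[r], rank)
                        if best is None or key < best:
                            best = key
                            best_rep = r
        if best is None:
            rep_order.append(i)
        else:
            abundance[best_rep] += u.abundance
            members[best_rep].extend(u.member_ids)
            absorbed_by[i] = best_rep
            records.append(MergeRecord(u.id, uniques[best_rep].id, best[0]))

    merge_map = {
        uniques[i].id: uniques[absorbed_by.get(i, i)].id for i in range(len(uniques))
    }
    table = [
        UniqueSequence(
            id=uniques[r].id,
            seq=uniques[r].seq,
            abundance=abundance[r],
            member_ids=members[r],
            mask=uniques[r].mask.copy(),
        )
        for r in rep_order
    ]
    table.sort(key=lambda u: (-u.abundance, u.seq))
    return ClusterResult(merge_map, table, records)


def revert_and_emit(result: ClusterResult) -> list[UniqueSequence]:
    """Denoised table: representatives with their original sequences.

    Masking is only ever a distance bookkeeping device, so emitting the
    stored sequences *is* the reversion step; masks are cleared on the
    way out and abundances are the merged totals.
    """
    out = [
        UniqueSequence(
            id=u.id,
            seq=u.seq,
            abundance=u.abundance,
            member_ids=list(u.member_ids),
        )
        for u in result.table
    ]
    out.sort(key=lambda u: (-u.abundance, u.seq))
    return out


# ---------------------------------------------------------------------------
# Mask and merge-map files


def write_masks(masks: dict[str, np.ndarray] | Sequence[UniqueSequence], path) -> None:
    """Mask TSV: sequence ID -> comma-separated masked positions (0-based)."""
    if not isinstance(masks, dict):
        masks = {u.id: u.mask for u in masks}
    with open(path, "w") as fh:
        fh.write("sequence_id\tmasked_positions\n")
        for name, mask in masks.items():
            pos = ",".join(str(i) for i in np.flatnonzero(np.asarray(mask, bool)))
            fh.write(f"{name}\t{pos}\n")


def read_masks(path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    masks: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence_id"):
            raise ValueError(f"{path}: missing mask table header")
        for line in fh:
            if not line.strip():
                continue
            name, _, pos = line.rstrip("\n").partition("\t")
            if name not in lengths:
                raise ValueError(f"{path}: mask for unknown sequence {name!r}")
            mask = np.zeros(lengths[name], bool)
            if pos:
                mask[[int(p) for p in pos.split(",")]] = True
            masks[name] = mask
    return masks


def write_merge_map(result: ClusterResult, path) -> None:
    """Merge map TSV (rare_id, representative_id, masked distance)."""
    with open(path, "w") as fh:
        fh.write("rare_id\trepresentative_id\tdistance\n")
        for rec in result.records:
            fh.write(f"{rec.rare_id}\t{rec.representative_id}\t{rec.distance}\n")
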