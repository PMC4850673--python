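"""Paired-end contig assembly and dereplication.

Merges Illumina MiSeq paired-end amplicon reads into contigs with an
ungapped overlap scan and a Phred-difference consensus rule, keeping
per-position provenance (originating read coordinate, base and quality
for both mates, plus the overlap status of the position).  Provenance
is what the downstream per-position error classifier consumes.

Coordinates are 0-based and half-open throughout.  Reverse-read
coordinates refer to the reverse-complemented orientation of the
reverse read, i.e. the orientation in which it lies on the contig.
"""
from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

# Overlap status codes for contig positions.
NOT_OVERLAP, MATCH, CONFLICT, UNKNOWN = 0, 1, 2, 3
OVERLAP_NAMES = ("NOT_OVERLAP", "MATCH", "CONFLICT", "UNKNOWN")

_RC = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")
_N = ord("N")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.encode("ascii").translate(_RC)[::-1].decode("ascii")


def _seq_to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def _u8_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


@dataclass
class PairedRead:
    """One forward/reverse read pair with per-base Phred qualities.

    Both mates are stored in sequencing orientation; the reverse read is
    reverse-complemented only at merge time.
    """

    id: str
    fwd_seq: str
    fwd_qual: np.ndarray
    rev_seq: str
    rev_qual: np.ndarray

    def __post_init__(self) -> None:
        self.fwd_qual = np.asarray(self.fwd_qual, dtype=np.int16)
        self.rev_qual = np.asarray(self.rev_qual, dtype=np.int16)
        if len(self.fwd_seq) != self.fwd_qual.size:
            raise ValueError(f"{self.id}: forward sequence/quality length mismatch")
        if len(self.rev_seq) != self.rev_qual.size:
            raise ValueError(f"{self.id}: reverse sequence/quality length mismatch")
        for q in (self.fwd_qual, self.rev_qual):
            if q.size and (q.min() < 0 or q.max() > 93):
                raise ValueError(f"{self.id}: Phred quality outside [0, 93]")


@dataclass
class Contig:
    """Merged amplicon sequence with per-position provenance.

    Arrays are indexed by contig position.  ``fwd_pos``/``rev_pos`` hold
    the originating read coordinate (-1 where the read does not cover
    the position); ``rev_pos`` counts along the reverse-complemented
    reverse read.  ``fwd_base``/``rev_base`` are uint8 ASCII codes (0
    where absent), qualities are -1 where absent, and ``overlap`` holds
    one of the status codes above.
    """

    id: str
    seq: str
    fwd_pos: np.ndarray
    rev_pos: np.ndarray
    fwd_base: np.ndarray
    rev_base: np.ndarray
    fwd_qual: np.ndarray
    rev_qual: np.ndarray
    overlap: np.ndarray

    def __len__(self) -> int:
        return len(self.seq)

    def fwd_read_seq(self) -> str:
        """Forward-read bases in read order (contig order; merge is ungapped)."""
        return _u8_to_seq(self.fwd_base[self.fwd_pos >= 0])

    def rev_read_seq(self) -> str:
        """Reverse-complemented reverse-read bases in contig order."""
        return _u8_to_seq(self.rev_base[self.rev_pos >= 0])


@dataclass
class UniqueSequence:
    """A dereplicated sequence: the unit of preclustering.

    ``mask`` flags positions predicted to be sequencing errors; it is
    all-false on creation and filled in by the error classifier.
    """

    id: str
    seq: str
    abundance: int
    member_ids: list[str]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(len(self.seq), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.size != len(self.seq):
            raise ValueError(f"{self.id}: mask length != sequence length")
        if self.abundance != len(self.member_ids) or self.abundance < 1:
            raise ValueError(f"{self.id}: abundance must equal len(member_ids) >= 1")


# ---------------------------------------------------------------------------
# FASTQ input


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


_MATE_SUFFIX = re.compile(r"/[12]$")


def _canonical_id(record_id: str) -> str:
    return _MATE_SUFFIX.sub("", record_id)


def read_paired_fastq(fwd_path, rev_path) -> Iterator[PairedRead]:
    """Stream read pairs from two FASTQ files (Phred+33, plain or gzip).

    Records must appear in the same order in both files with matching
    identifiers up to a ``/1``-``/2`` or Illumina ``1:N:...``/``2:N:...``
    mate suffix.  Mismatched IDs or unequal record counts raise a
    ``ValueError`` naming the first offending record.
    """
    with _open_text(fwd_path) as fh, _open_text(rev_path) as rh:
        fwd_iter = SeqIO.parse(fh, "fastq")
        rev_iter = SeqIO.parse(rh, "fastq")
        for i, (f, r) in enumerate(zip_longest(fwd_iter, rev_iter)):
            if f is None or r is None:
                raise ValueError(
                    f"record count mismatch between {fwd_path} and {rev_path}: "
                    f"one file ended before record {i + 1}"
                )
            fid, rid = _canonical_id(f.id), _canonical_id(r.id)
            if fid != rid:
                raise ValueError(
                    f"read ID mismatch at record {i + 1}: {f.id!r} vs {r.id!r}"
                )
            yield PairedRead(
                fid,
                str(f.seq).upper(),
                np.asarray(f.letter_annotations["phred_quality"], np.int16),
                str(r.seq).upper(),
                np.asarray(r.letter_annotations["phred_quality"], np.int16),
            )


# ---------------------------------------------------------------------------
# Merging


def merge_pair(pair: PairedRead, min_overlap: int = 10, q_delta: int = 6) -> Contig | None:
    """Merge one read pair into a contig, or return None (pair rejected).

    The reverse read is reverse-complemented and slid along the forward
    read over every ungapped offset with at least ``min_overlap``
    overlapping bases; the offset maximizing matches minus mismatches
    over the overlap wins (ties go to the larger overlap).  Inside the overlap, agreeing bases
    are kept with the maximum of the two qualities; if either base is N
    the other base is used (status UNKNOWN); conflicting calls take the
    base of the higher-quality read when the Phred difference is at
    least ``q_delta`` and become N (quality 0) otherwise (status
    CONFLICT either way).  Outside the overlap the covering read
    provides base and quality.

    A pair whose reads are shorter than ``min_overlap`` cannot be
    merged and is rejected (None) rather than raising, mirroring the
    culling of improperly merged pairs in standard pre-processing.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if q_delta < 0:
        raise ValueError("q_delta must be >= 0")
    f = _seq_to_u8(pair.fwd_seq)
    fq = pair.fwd_qual
    r = _seq_to_u8(revcomp(pair.rev_seq))
    rq = pair.rev_qual[::-1].copy()
    lf, lr = f.size, r.size
    if min(lf, lr) < min_overlap:
        return None

    # Score per offset of the RC reverse read along the forward read,
    # via per-base cross-correlation.  The score is matches minus
    # mismatches over non-N overlap columns: a pure match count would
    # favour long spurious overlaps, whose chance matches (~25 % of the
    # columns) can outnumber the true short overlap.
    matches = np.zeros(lf + lr - 1)
    for b in b"ACGT":
        matches += np.correlate(
            (f == b).astype(np.float64), (r == b).astype(np.float64), mode="full"
        )
    non_n = np.correlate(
        (f != _N).astype(np.float64), (r != _N).astype(np.float64), mode="full"
    )
    max_off = lf - min_overlap
    scores = (2 * matches - non_n)[lr - 1 : lr + max_off]
    off = int(np.argmax(scores))  # first max == smallest offset == largest overlap

    clen = max(lf, off + lr)
    fwd_pos = np.full(clen, -1, np.int32)
    fwd_pos[:lf] = np.arange(lf)
    rev_pos = np.full(clen, -1, np.int32)
    rev_pos[off : off + lr] = np.arange(lr)
    fwd_base = np.zeros(clen, np.uint8)
    fwd_base[:lf] = f
    rev_base = np.zeros(clen, np.uint8)
    rev_base[off : off + lr] = r
    fwd_qual = np.full(clen, -1, np.int16)
    fwd_qual[:lf] = fq
    rev_qual = np.full(clen, -1, np.int16)
    rev_qual[off : off + lr] = rq

    seq = np.where(fwd_pos >= 0, fwd_base, rev_base).astype(np.uint8)
    overlap = np.zeros(clen, np.uint8)  # NOT_OVERLAP

    both = (fwd_pos >= 0) & (rev_pos >= 0)
    fb, rb = fwd_base[both], rev_base[both]
    fqo, rqo = fwd_qual[both], rev_qual[both]
    eq = (fb == rb) & (fb != _N)
    any_n = (fb == _N) | (rb == _N)
    conflict = ~eq & ~any_n

    cons = fb.copy()
    cons[any_n] = np.where(fb[any_n] == _N, rb[any_n], fb[any_n])
    fwd_wins = fqo >= rqo
    resolved = np.where(fwd_wins, fb, rb)
    cons[conflict] = np.where(
        (np.abs(fqo - rqo) >= q_delta)[conflict], resolved[conflict], _N
    )
    status = np.where(eq, MATCH, np.where(any_n, UNKNOWN, CONFLICT)).astype(np.uint8)

    seq[both] = cons
    overlap[both] = status
    return Contig(
        id=pair.id,
        seq=_u8_to_seq(seq),
        fwd_pos=fwd_pos,
        rev_pos=rev_pos,
        fwd_base=fwd_base,
        rev_base=rev_base,
        fwd_qual=fwd_qual,
        rev_qual=rev_qual,
        overlap=overlap,
    )


def merge_pairs(
    pairs: Iterable[PairedRead], min_overlap: int = 10, q_delta: int = 6
) -> tuple[list[Contig], int]:
    """Merge many pairs; returns (contigs, number of rejected pairs)."""
    contigs: list[Contig] = []
    rejected = 0
    for pair in pairs:
        contig = merge_pair(pair, min_overlap=min_overlap, q_delta=q_delta)
        if contig is None:
            rejected += 1
        else:
            contigs.append(contig)
    return contigs, rejected


# ---------------------------------------------------------------------------
# Dereplication


def dereplicate(contigs: Sequence[Contig]) -> tuple[list[UniqueSequence], int]:
    """Collapse identical contigs into unique sequences with abundances.

    Contigs containing an ambiguous base (N) are culled first; the
    second return value reports how many were removed.  The table is
    sorted by abundance descending, ties broken lexicographically by
    sequence.  The sum of abundances equals the number of surviving
    contigs.
    """
    if len(contigs) == 0:
        raise ValueError("dereplicate: no contigs supplied")
    groups: dict[str, list[str]] = {}
    culled = 0
    for c in contigs:
        if "N" in c.seq:
            culled += 1
            continue
        groups.setdefault(c.seq, []).append(c.id)
    if not groups:
        warnings.warn("dereplicate: every contig contained an ambiguous base")
        return [], culled
    uniques = [
        UniqueSequence(id=ids[0], seq=seq, abundance=len(ids), member_ids=ids)
        for seq, ids in groups.items()
    ]
    uniques.sort(key=lambda u: (-u.abundance, u.seq))
    return uniques, culled


# ---------------------------------------------------------------------------
# Output formats

COUNT_TABLE_HEADER = "Representative_Sequence\ttotal"


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_count_table(uniques: Sequence[UniqueSequence], path) -> None:
    """Two-column count table in the mothur count_table dialect."""
    with open(path, "w") as fh:
        fh.write(COUNT_TABLE_HEADER + "\n")
        for u in uniques:
            fh.write(f"{u.id}\t{u.abundance}\n")


def read_count_table(path) -> dict[str, int]:
    counts: dict[str, int] = {}
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.startswith("Representative_Sequence"):
            raise ValueError(f"{path}: missing count table header")
        for line in fh:
            if not line.strip():
                continue
            name, total = line.rstrip("\n").split("\t")[:2]
            counts[name] = int(total)
    return counts


def write_unique_table(uniques: Sequence[UniqueSequence], prefix) -> tuple[Path, Path]:
    """Write a unique-sequence FASTA plus count table; returns the two paths."""
    fasta = Path(f"{prefix}.fasta")
    count = Path(f"{prefix}.count_table")
    write_fasta(((u.id, u.seq) for u in uniques), fasta)
    write_count_table(uniques, count)
    return fasta, count


def read_unique_table(fasta_path, count_path) -> list[UniqueSequence]:
    counts = read_count_table(count_path)
    uniques = []
    for name, seq in read_fasta(fasta_path):
        if name not in counts:
            raise ValueError(f"{name} present in FASTA but not in count table")
        uniques.append(
            UniqueSequence(
                id=name, seq=seq, abundance=counts[name], member_ids=[name] * counts[name]
            )
        )
    return uniques


PROVENANCE_HEADER = (
    "contig_id\tpos\tbase\tfwd_pos\tfwd_base\tfwd_qual\trev_pos\trev_base\trev_qual\toverlap"
)


def write_provenance(contigs: Iterable[Contig], path) -> None:
    """Tab-separated per-position provenance sidecar (one row per position)."""
    with open(path, "w") as fh:
        fh.write(PROVENANCE_HEADER + "\n")
        for c in contigs:
            for i in range(len(c)):
                fb = chr(c.fwd_base[i]) if c.fwd_base[i] else "."
                rb = chr(c.rev_base[i]) if c.rev_base[i] else "."
                fh.write(
                    f"{c.id}\t{i}\t{c.seq[i]}\t{c.fwd_pos[i]}\t{fb}\t{c.fwd_qual[i]}"
                    f"\t{c.rev_pos[i]}\t{rb}\t{c.rev_qual[i]}\t{OVERLAP_NAMES[c.overlap[i]]}\n"
                )
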