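"""Per-position features for sequencing-error prediction.

For every contig position the extractor computes quality/context
features of the covering read(s): position in the read, Phred quality,
homopolymer status, presence of a GGC motif immediately upstream, the
homopolymer status and quality of the neighbouring read positions, and
the overlap status of the contig position (17 features in full mode).
The ``selected`` mode keeps the six features retained after
correlation-based feature selection: forward position, forward
homopolymer status, forward quality, reverse position, reverse quality
and overlap status.

Numeric features use the sentinel -1 where the read does not cover the
position (or at read ends for neighbour features).  The overlap feature
is stored as an integer category code (see ``iped.contigs``) and is
one-hot encoded inside the classifier.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .contigs import _N, Contig, _seq_to_u8

SELECTED_FEATURES = (
    "fwd_pos",
    "fwd_homopolymer",
    "fwd_qual",
    "rev_pos",
    "rev_qual",
    "overlap",
)

FULL_FEATURES = (
    "fwd_pos",
    "fwd_homopolymer",
    "fwd_qual",
    "fwd_ggc_before",
    "fwd_prev_homopolymer",
    "fwd_prev_qual",
    "fwd_next_homopolymer",
    "fwd_next_qual",
    "rev_pos",
    "rev_homopolymer",
    "rev_qual",
    "rev_ggc_before",
    "rev_prev_homopolymer",
    "rev_prev_qual",
    "rev_next_homopolymer",
    "rev_next_qual",
    "overlap",
)


def feature_names(mode: str = "selected") -> tuple[str, ...]:
    if mode == "selected":
        return SELECTED_FEATURES
    if mode == "full":
        return FULL_FEATURES
    raise ValueError(f"unknown feature mode {mode!r}")


# ---------------------------------------------------------------------------
# Elementary features


def _homopolymer_vector(arr: np.ndarray) -> np.ndarray:
    """Homopolymer status for every position of a uint8 sequence.

    0 when the maximal run containing the position is a singleton, the
    1-based index within the run for runs of length >= 2, and -1 for
    ambiguous (N) bases.
    """
    n = arr.size
    if n == 0:
        return np.zeros(0, np.int16)
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    lens = np.diff(np.concatenate((starts, [n])))
    run_start = np.repeat(starts, lens)
    run_len = np.repeat(lens, lens)
    idx_in_run = np.arange(n) - run_start + 1
    out = np.where(run_len >= 2, idx_in_run, 0).astype(np.int16)
    out[arr == _N] = -1
    return out


def homopolymer_status(seq: str, i: int) -> int:
    """Homopolymer status of position ``i`` of ``seq`` (see above)."""
    if not 0 <= i < len(seq):
        raise IndexError(f"position {i} out of range for sequence of length {len(seq)}")
    return int(_homopolymer_vector(_seq_to_u8(seq))[i])


def _ggc_vector(arr: np.ndarray) -> np.ndarray:
    out = np.zeros(arr.size, bool)
    if arr.size >= 4:
        motif = (arr[:-3] == ord("G")) & (arr[1:-2] == ord("G")) & (arr[2:-1] == ord("C"))
        out[3:] = motif
    return out


def ggc_before(seq: str, i: int) -> bool:
    """True iff the three bases immediately preceding ``i`` are GGC."""
    if not 0 <= i < len(seq):
        raise IndexError(f"position {i} out of range for sequence of length {len(seq)}")
    return i >= 3 and seq[i - 3 : i] == "GGC"


def overlap_status_feature(contig: Contig, i: int) -> str:
    """Overlap category recorded at merge time, as its name."""
    from .contigs import OVERLAP_NAMES

    if not 0 <= i < len(contig):
        raise IndexError(f"position {i} out of range for contig of length {len(contig)}")
    return OVERLAP_NAMES[contig.overlap[i]]


# ---------------------------------------------------------------------------
# Per-contig extraction


def _read_feature_columns(
    bases: np.ndarray, quals: np.ndarray, pos: np.ndarray, n: int, full: bool
) -> dict[str, np.ndarray]:
    """Feature columns for one mate, scattered onto contig coordinates."""
    covered = pos >= 0
    read_bases = bases[covered]  # in read order: the merge is ungapped
    read_quals = quals[covered].astype(np.float32)
    hp = _homopolymer_vector(read_bases).astype(np.float32)
    cols: dict[str, np.ndarray] = {}

    def scatter(values: np.ndarray) -> np.ndarray:
        out = np.full(n, -1.0, np.float32)
        out[covered] = values
        return out

    cols["pos"] = scatter(pos[covered].astype(np.float32))
    cols["homopolymer"] = scatter(hp)
    cols["qual"] = scatter(read_quals)
    if full:
        cols["ggc_before"] = scatter(_ggc_vector(read_bases).astype(np.float32))
        pad = np.float32(-1.0)
        cols["prev_homopolymer"] = scatter(np.concatenate(([pad], hp[:-1])))
        cols["prev_qual"] = scatter(np.concatenate(([pad], read_quals[:-1])))
        cols["next_homopolymer"] = scatter(np.concatenate((hp[1:], [pad])))
        cols["next_qual"] = scatter(np.concatenate((read_quals[1:], [pad])))
    return cols


def extract_features(contig: Contig, mode: str = "selected") -> np.ndarray:
    """Feature matrix (positions x features) for one contig.

    Row order follows contig positions; columns follow
    ``feature_names(mode)``.
    """
    if contig.fwd_pos is None or contig.rev_pos is None:
        raise ValueError("contig carries no provenance; run merge_pair with provenance enabled")
    names = feature_names(mode)
    n = len(contig)
    full = mode == "full"
    fwd = _read_feature_columns(contig.fwd_base, contig.fwd_qual, contig.fwd_pos, n, full)
    rev = _read_feature_columns(contig.rev_base, contig.rev_qual, contig.rev_pos, n, full)
    table = {f"fwd_{k}": v for k, v in fwd.items()}
    table.update({f"rev_{k}": v for k, v in rev.items()})
    table["overlap"] = contig.overlap.astype(np.float32)
    return np.column_stack([table[name] for name in names])


def extract_features_many(
    contigs, mode: str = "selected"
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked feature matrix for many contigs plus per-contig lengths."""
    blocks = [extract_features(c, mode) for c in contigs]
    lengths = np.array([b.shape[0] for b in blocks], dtype=np.int64)
    if not blocks:
        return np.zeros((0, len(feature_names(mode))), np.float32), lengths
    return np.vstack(blocks), lengths


def features_frame(contigs, mode: str = "selected") -> pd.DataFrame:
    """Feature matrix as a DataFrame with contig_id/pos index columns.

    This is the layout written by ``iped merge``/``iped predict`` when a
    tab-separated feature table is requested.
    """
    X, lengths = extract_features_many(contigs, mode)
    ids = np.repeat([c.id for c in contigs], lengths)
    pos = np.concatenate([np.arange(n) for n in lengths]) if len(lengths) else np.zeros(0, int)
    frame = pd.DataFrame(X, columns=list(feature_names(mode)))
    frame.insert(0, "pos", pos)
    frame.insert(0, "contig_id", ids)
    return frame
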