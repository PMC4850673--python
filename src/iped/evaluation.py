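"""Error-rate evaluation against mock-community references.

The error rate follows the seq.error convention: the ratio of the
number of deletions, insertions and substitutions over the total
number of bases, with every unique sequence aligned to its
minimum-error reference and counts weighted by abundance.  The module
also attributes errors to reference-anchored amplicon coordinates (for
position-wise error profiles) and produces the
raw / preclustered / masked-preclustered comparison used to judge the
denoiser end to end.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._align import ReferenceSet
from .classifier import VotingEnsemble, aggregate_masks, predict_contig_masks
from .contigs import Contig, UniqueSequence, dereplicate, merge_pairs, read_paired_fastq
from .precluster import precluster, revert_and_emit
from .simulate import load_sim


@dataclass
class ErrorReport:
    """Abundance-weighted error decomposition of a unique-sequence table."""

    per_sequence: pd.DataFrame  # id, ref_id, abundance, subs, ins, dels, bases
    total_errors: int
    total_bases: int
    error_rate: float
    n_skipped: int = 0


def error_rate(
    uniques: Sequence[UniqueSequence],
    refs: ReferenceSet | Sequence[tuple[str, str]],
) -> ErrorReport:
    """seq.error-style error rate of a dereplicated table.

    Every sequence is aligned (affine-gap global, free reference end
    gaps) to every reference and the minimum-error alignment is kept;
    substitution, insertion and deletion counts are weighted by
    abundance and the aggregate rate is total errors / total bases.
    """
    if not uniques:
        raise ValueError("error_rate: empty unique-sequence table")
    if not isinstance(refs, ReferenceSet):
        refs = ReferenceSet(refs)
    rows = []
    total_errors = 0
    total_bases = 0
    for u in uniques:
        best = refs.best(u.seq)
        bases = len(u.seq) * u.abundance
        errors = best.n_errors * u.abundance
        rows.append(
            (u.id, best.ref_id, u.abundance, best.n_sub, best.n_ins, best.n_del, bases)
        )
        total_errors += errors
        total_bases += bases
    frame = pd.DataFrame(
        rows, columns=["id", "ref_id", "abundance", "subs", "ins", "dels", "bases"]
    )
    return ErrorReport(frame, total_errors, total_bases, total_errors / total_bases)


def positionwise_error(
    uniques: Sequence[UniqueSequence],
    refs: ReferenceSet | Sequence[tuple[str, str]],
) -> np.ndarray:
    """Per-position error rate in reference-anchored amplicon coordinates.

    All references must share one length (one amplicon region); the
    result has that length.  Coverage-weighted sums of the vector give
    back the aggregate error count exactly.
    """
    if not isinstance(refs, ReferenceSet):
        refs = ReferenceSet(refs)
    lengths = {len(s) for s in refs.seqs}
    if len(lengths) != 1:
        raise ValueError("positionwise_error needs references of a single length")
    amplicon_len = lengths.pop()
    errors = np.zeros(amplicon_len, dtype=np.int64)
    coverage = np.zeros(amplicon_len, dtype=np.int64)
    for u in uniques:
        best = refs.best(u.seq)
        coverage += u.abundance  # global alignment: full amplicon covered
        if best.ref_positions.size:
            np.add.at(errors, best.ref_positions, u.abundance)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(coverage > 0, errors / np.maximum(coverage, 1), 0.0)
    return rate


# ---------------------------------------------------------------------------
# Pipeline comparison


def truth_contig_masks(
    contigs: Sequence[Contig],
    assignments: pd.DataFrame,
    refs: Sequence[tuple[str, str]],
    amplicon_len: int,
) -> dict[str, np.ndarray]:
    """Oracle masks: positions where the contig disagrees with its true
    source amplicon.  Upper-bounds what a perfect classifier could mark."""
    ref_seq = dict(refs)
    source = dict(zip(assignments["read_id"], zip(assignments["ref_id"], assignments["start"])))
    masks: dict[str, np.ndarray] = {}
    for c in contigs:
        ref_id, start = source[c.id]
        amplicon = ref_seq[ref_id][start : start + amplicon_len]
        mask = np.zeros(len(c), bool)
        n = min(len(c), len(amplicon))
        a = np.frombuffer(c.seq[:n].encode(), np.uint8)
        b = np.frombuffer(amplicon[:n].encode(), np.uint8)
        mask[:n] = a != b
        mask[n:] = True  # length disagreement: everything unexplained is suspect
        masks[c.id] = mask
    return masks


def filter_modal_length(
    uniques: Sequence[UniqueSequence],
) -> tuple[list[UniqueSequence], int]:
    """Keep only sequences of the most abundant length.

    A minimal stand-in for length screening: preclustering requires
    equal-length sequences, and pairs merged at a spurious offset
    produce rare off-length contigs.  Returns (kept, reads dropped).
    """
    weight: dict[int, int] = {}
    for u in uniques:
        weight[len(u.seq)] = weight.get(len(u.seq), 0) + u.abundance
    modal = max(weight, key=lambda k: (weight[k], k))
    kept = [u for u in uniques if len(u.seq) == modal]
    dropped = sum(u.abundance for u in uniques) - sum(u.abundance for u in kept)
    return kept, dropped


def _clone_with_masks(
    uniques: Sequence[UniqueSequence], masks: dict[str, np.ndarray] | None
) -> list[UniqueSequence]:
    clones = [
        UniqueSequence(
            id=u.id, seq=u.seq, abundance=u.abundance, member_ids=list(u.member_ids)
        )
        for u in uniques
    ]
    if masks is not None:
        aggregate_masks(clones, masks)
    return clones


def compare_tables(
    uniques: Sequence[UniqueSequence],
    refs: ReferenceSet,
    mask_sets: dict[str, dict[str, np.ndarray] | None],
    diffs="auto",
) -> tuple[pd.DataFrame, dict[str, list[UniqueSequence]]]:
    """Error-rate comparison across denoising variants of one table.

    ``mask_sets`` maps a variant name to per-contig masks (None = plain
    preclustering).  The raw table is always reported first.
    """
    raw_report = error_rate(uniques, refs)
    rows = [("raw", raw_report)]
    tables: dict[str, list[UniqueSequence]] = {"raw": list(uniques)}
    for name, masks in mask_sets.items():
        masked = _clone_with_masks(uniques, masks)
        result = precluster(masked, diffs=diffs)
        denoised = revert_and_emit(result)
        tables[name] = denoised
        rows.append((name, error_rate(denoised, refs)))
    raw_rate = raw_report.error_rate
    frame = pd.DataFrame(
        {
            "variant": [name for name, _ in rows],
            "error_rate": [r.error_rate for _, r in rows],
            "total_errors": [r.total_errors for _, r in rows],
            "total_bases": [r.total_bases for _, r in rows],
            "n_uniques": [len(tables[name]) for name, _ in rows],
            "reduction_vs_raw_pct": [
                float("nan") if raw_rate == 0 else 100.0 * (1 - r.error_rate / raw_rate)
                for _, r in rows
            ],
        }
    )
    return frame, tables


def compare_pipelines(
    sim_dir,
    model: VotingEnsemble | str | Path,
    threshold: float = 0.5,
    min_overlap: int = 10,
    q_delta: int = 6,
    diffs="auto",
    include_oracle: bool = False,
) -> pd.DataFrame:
    """Raw vs plain preclustering vs masked preclustering on one simulated
    dataset.

    Runs merge -> dereplicate -> {nothing | precluster | predicted-mask
    precluster [| truth-mask precluster]} -> error rate, and reports the
    rates plus relative reductions.  ``model`` may be a fitted ensemble
    or a model archive directory.
    """
    sim = load_sim(sim_dir)
    if not isinstance(model, VotingEnsemble):
        model_path = Path(model)
        if not model_path.exists():
            raise FileNotFoundError(f"model archive {model_path} not found")
        model = VotingEnsemble.load(model_path)
    pairs = read_paired_fastq(sim["r1"], sim["r2"])
    contigs, _rejected = merge_pairs(pairs, min_overlap=min_overlap, q_delta=q_delta)
    uniques, _culled = dereplicate(contigs)
    uniques, _off_length = filter_modal_length(uniques)
    refs = ReferenceSet(sim["refs"])

    kept = {u_id for u in uniques for u_id in u.member_ids}
    used_contigs = [c for c in contigs if c.id in kept]
    predicted = predict_contig_masks(model, used_contigs, threshold=threshold)
    mask_sets: dict[str, dict[str, np.ndarray] | None] = {
        "precluster": None,
        "iped": predicted,
    }
    if include_oracle:
        mask_sets["iped_oracle"] = truth_contig_masks(
            used_contigs, sim["assignments"], sim["refs"], sim["profile"].amplicon_len
        )
    frame, _tables = compare_tables(uniques, refs, mask_sets, diffs=diffs)
    return frame
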