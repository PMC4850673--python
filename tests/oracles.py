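"""Independent brute-force reference implementations used as test oracles.

Everything here is written naively (plain Python loops, recomputation at
every step) and shares no code with the package internals it checks.
"""
from __future__ import annotations

import math


def bf_masked_distance(seq_a, mask_a, seq_b, mask_b) -> int:
    assert len(seq_a) == len(seq_b) == len(mask_a) == len(mask_b)
    d = 0
    for i in range(len(seq_a)):
        if mask_a[i] or mask_b[i]:
            continue
        if seq_a[i] == "-" and seq_b[i] == "-":
            continue
        if seq_a[i] != seq_b[i]:
            d += 1
    return d


def bf_homopolymer(seq: str, i: int) -> int:
    if seq[i] == "N":
        return -1
    start = i
    while start > 0 and seq[start - 1] == seq[i]:
        start -= 1
    end = i
    while end + 1 < len(seq) and seq[end + 1] == seq[i]:
        end += 1
    if end == start:
        return 0
    return i - start + 1


def bf_mcc(pred, truth) -> float:
    tp = fp = tn = fn = 0
    for p, t in zip(pred, truth, strict=True):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def bf_precluster(rows, diffs):
    """Naive single-linkage preclustering over (id, seq, abundance, mask) rows.

    Recomputes every pairwise masked distance at every step.  Returns
    (merge_map, {rep_id: final_abundance}).
    """
    rows = sorted(rows, key=lambda r: (-r[2], r[1]))
    reps = []  # ids in establishment order
    state = {r[0]: {"seq": r[1], "ab": r[2], "mask": r[3]} for r in rows}
    merge_map = {}
    for rid, seq, ab, mask in rows:
        best = None
        best_rep = None
        for rank, rep in enumerate(reps):
            s = state[rep]
            if s["ab"] <= ab:
                continue
            d = bf_masked_distance(seq, mask, s["seq"], s["mask"])
            if d <= diffs:
                key = (d, -s["ab"], rank)
                if best is None or key < best:
                    best = key
                    best_rep = rep
        if best_rep is None:
            reps.append(rid)
            merge_map[rid] = rid
        else:
            state[best_rep]["ab"] += ab
            merge_map[rid] = best_rep
    return merge_map, {rep: state[rep]["ab"] for rep in reps}
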