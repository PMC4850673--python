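"""Mock-community paired-end read simulator with exact error truth.

Emulates the dominant error structure of Illumina MiSeq amplicon runs:
Phred quality decays along each read, reverse reads are systematically
worse, per-read quality varies between clusters, a GGC motif depresses
the quality of the following positions, and miscalls are biased toward
the fluorophore-confusable partner base (A<->C, G<->T).  Substitutions
are drawn independently per base with probability 10^(-Q/10) at the
*realized* quality Q, so emitted FASTQ qualities are calibrated by
construction.  Indels are off by default (MiSeq substitutions dominate)
but a small per-read indel rate can be enabled for robustness tests.

Every injected error is recorded, which gives downstream modules exact
per-position truth without external downloads.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .contigs import PairedRead, revcomp, write_fasta, _seq_to_u8, _u8_to_seq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate(b"ACGT")}

# Rows: true base A,C,G,T; columns: substituted base A,C,G,T.  0.6 of the
# miscall mass goes to the fluorophore-confusable partner.
DEFAULT_MISCALL = np.array(
    [
        [0.0, 0.6, 0.2, 0.2],  # A -> C confusable
        [0.6, 0.0, 0.2, 0.2],  # C -> A
        [0.2, 0.2, 0.0, 0.6],  # G -> T confusable
        [0.2, 0.2, 0.6, 0.0],  # T -> G
    ]
)


@dataclass
class ErrorProfile:
    """Quality/error model for one simulated run.

    ``q_start``/``q_end`` anchor a linear Phred decay along the read;
    ``rev_penalty`` is subtracted across the reverse read; ``read_q_sd``
    is the standard deviation of a per-read quality offset (cluster-
    to-cluster variability, the source of multi-error reads);
    ``ggc_drop`` is subtracted for ``ggc_span`` positions following a
    GGC motif; ``q_jitter`` adds uniform integer noise per position.
    Realized qualities are clamped to [q_min, q_max] (default [2, 40];
    raise ``q_max`` to model an idealized error-free run at Phred 93).
    """

    read_len: int = 250
    amplicon_len: int = 430
    q_start: int = 38
    q_end: int = 23
    rev_penalty: int = 6
    read_q_sd: float = 4.0
    ggc_drop: int = 6
    ggc_span: int = 5
    q_jitter: int = 2
    indel_rate: float = 0.0
    q_min: int = 2
    q_max: int = 40
    miscall: np.ndarray = field(default_factory=lambda: DEFAULT_MISCALL.copy())

    def __post_init__(self) -> None:
        self.miscall = np.asarray(self.miscall, float)
        if self.amplicon_len > 2 * self.read_len:
            raise ValueError("amplicon longer than twice the read length cannot overlap")
        if min(self.q_start, self.q_end, self.rev_penalty, self.ggc_drop, self.q_jitter) < 0:
            raise ValueError("Phred parameters must be >= 0")
        rows = self.miscall.sum(axis=1)
        if not np.allclose(rows, 1.0) or np.any(np.diag(self.miscall) != 0):
            raise ValueError("miscall rows must sum to 1 over the three alternative bases")

    @classmethod
    def uniform(cls, q: int, read_len: int = 250, amplicon_len: int = 430, **kwargs):
        """Flat quality profile: every position gets exactly Phred ``q``."""
        return cls(
            read_len=read_len,
            amplicon_len=amplicon_len,
            q_start=q,
            q_end=q,
            rev_penalty=0,
            read_q_sd=0.0,
            ggc_drop=0,
            q_jitter=0,
            **kwargs,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["miscall"] = self.miscall.tolist()
        return d


# Geometry presets mirroring the hypervariable-region designs commonly
# sequenced with the 2 x 250 bp protocol: full overlap (V4-like), 70 nt
# overlap (V34-like) and 125 nt overlap (V45-like).
PRESETS: dict[str, dict] = {
    "v4": {"read_len": 250, "amplicon_len": 250},
    "v34": {"read_len": 250, "amplicon_len": 430},
    "v45": {"read_len": 250, "amplicon_len": 375},
}


def profile_from_preset(name: str, **overrides) -> ErrorProfile:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return ErrorProfile(**params)


# ---------------------------------------------------------------------------
# Quality model


def _decay_curve(profile: ErrorProfile) -> np.ndarray:
    n = profile.read_len
    if n == 1:
        return np.array([float(profile.q_start)])
    return profile.q_start + (profile.q_end - profile.q_start) * np.arange(n) / (n - 1)


def _ggc_affected(read_seq_u8: np.ndarray, span: int) -> np.ndarray:
    """Positions within ``span`` bases after a GGC motif in the read."""
    n = read_seq_u8.size
    out = np.zeros(n, bool)
    if n < 4 or span < 1:
        return out
    motif_end = (
        (read_seq_u8[:-2] == ord("G"))
        & (read_seq_u8[1:-1] == ord("G"))
        & (read_seq_u8[2:] == ord("C"))
    )  # motif occupying e-2..e marks True at index e-2; affected: e+1 .. e+span
    ends = np.flatnonzero(motif_end) + 2
    for e in ends:
        out[e + 1 : e + 1 + span] = True
    return out


def expected_quality(read: str, position: int, profile: ErrorProfile, context: str) -> int:
    """Deterministic part of the quality model at one read position.

    ``read`` is "fwd" or "rev"; ``context`` is the true read sequence
    (used for the GGC drop).  Jitter and the per-read offset are not
    included; the result is clamped to [2, 40].
    """
    if not 0 <= position < profile.read_len:
        raise ValueError("position outside the read")
    q = _decay_curve(profile)[position]
    if read == "rev":
        q -= profile.rev_penalty
    if _ggc_affected(_seq_to_u8(context), profile.ggc_span)[position]:
        q -= profile.ggc_drop
    return int(np.clip(round(q), profile.q_min, profile.q_max))


# ---------------------------------------------------------------------------
# Reference generation


def synthetic_references(
    n_refs: int = 15,
    length: int = 430,
    divergence: tuple[float, float] = (0.03, 0.10),
    seed: int = 0,
) -> list[tuple[str, str]]:
    """16S-like reference set: mutated copies of one random ancestor.

    Each reference carries a substitution rate drawn from ``divergence``
    relative to the ancestor, giving roughly 90-97 % pairwise identity
    (OTU-style distinctness).
    """
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(_BASES, size=length)
    refs = []
    for k in range(n_refs):
        rate = rng.uniform(*divergence)
        seq = ancestor.copy()
        sites = np.flatnonzero(rng.random(length) < rate)
        for i in sites:
            choices = _BASES[_BASES != seq[i]]
            seq[i] = rng.choice(choices)
        refs.append((f"ref_{k:03d}", _u8_to_seq(seq)))
    return refs


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class SimResult:
    """Simulated pairs plus exact truth.

    ``truth`` has one row per injected error (read_id, mate, pos in
    sequencing orientation, op, true_base, obs_base); ``assignments``
    maps each read pair to its source reference and amplicon start.
    """

    pairs: list[PairedRead]
    truth: pd.DataFrame
    assignments: pd.DataFrame
    refs: list[tuple[str, str]]
    composition: pd.DataFrame
    profile: ErrorProfile
    seed: int


def _simulate_mate(
    true_reads: np.ndarray,
    mate: str,
    profile: ErrorProfile,
    read_offsets: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed bases, qualities and error mask for one mate of many reads.

    ``true_reads`` is (n_reads, read_len) uint8 in sequencing
    orientation; all rows must be identical (one source amplicon), so
    the deterministic quality curve is computed once.
    """
    n, m = true_reads.shape
    base_q = _decay_curve(profile).copy()
    if mate == "rev":
        base_q -= profile.rev_penalty
    ggc = _ggc_affected(true_reads[0], profile.ggc_span)
    base_q = base_q - profile.ggc_drop * ggc

    q = np.broadcast_to(base_q, (n, m)) + read_offsets[:, None]
    if profile.q_jitter:
        q = q + rng.integers(-profile.q_jitter, profile.q_jitter + 1, size=(n, m))
    q = np.clip(np.rint(q), profile.q_min, profile.q_max).astype(np.int16)

    p_err = 10.0 ** (-q / 10.0)
    err = rng.random((n, m)) < p_err
    obs = true_reads.copy()
    if err.any():
        rows, cols = np.nonzero(err)
        true_idx = np.searchsorted(_BASES, obs[rows, cols])
        cum = np.cumsum(profile.miscall, axis=1)
        draws = rng.random(rows.size)
        sub_idx = (draws[:, None] >= cum[true_idx][:, :-1]).sum(axis=1)
        obs[rows, cols] = _BASES[sub_idx]
    return obs, q, err


def _apply_indels(
    seq: np.ndarray, qual: np.ndarray, amplicon_ext: np.ndarray | None, rng
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, str]]]:
    """One random indel in one read (robustness-test helper).

    A deletion shifts the read left and extends it from the amplicon
    when more template is available (otherwise the read shortens); an
    insertion duplicates a base and trims the read end.
    """
    events: list[tuple[int, str]] = []
    pos = int(rng.integers(0, seq.size))
    if rng.random() < 0.5:  # deletion of the base at pos
        events.append((pos, "del"))
        seq = np.delete(seq, pos)
        qual = np.delete(qual, pos)
        if amplicon_ext is not None and amplicon_ext.size:
            seq = np.append(seq, amplicon_ext[0])
            qual = np.append(qual, qual[-1])
    else:  # insertion: duplicate the base at pos
        events.append((pos, "ins"))
        seq = np.insert(seq, pos, seq[pos])[: seq.size]
        qual = np.insert(qual, pos, qual[pos])[: qual.size]
    return seq, qual, events


def simulate_mock(
    refs: Sequence[tuple[str, str]],
    n_pairs: int,
    profile: ErrorProfile,
    seed: int = 0,
    composition: Sequence[float] | None = None,
) -> SimResult:
    """Simulate ``n_pairs`` paired-end reads from a mock community.

    References are sampled according to ``composition`` (default
    equimolar).  The forward read is the first ``read_len`` bases of the
    amplicon; the reverse read is the reverse complement of the last
    ``read_len`` bases.  Identical seeds give byte-identical output.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    refs = [(name, seq.upper()) for name, seq in refs]
    for name, seq in refs:
        if len(seq) < profile.amplicon_len:
            raise ValueError(
                f"reference {name!r} is shorter ({len(seq)}) than the amplicon length "
                f"({profile.amplicon_len})"
            )
    if composition is None:
        composition = np.full(len(refs), 1.0 / len(refs))
    else:
        composition = np.asarray(composition, float)
        if composition.size != len(refs) or composition.min() < 0:
            raise ValueError("composition must be a non-negative vector over the references")
        composition = composition / composition.sum()
    rng = np.random.default_rng(seed)

    ref_idx = rng.choice(len(refs), size=n_pairs, p=composition)
    starts = np.zeros(n_pairs, dtype=int)  # amplicons anchored at the reference start
    offsets = (
        rng.normal(0.0, profile.read_q_sd, size=(n_pairs, 2))
        if profile.read_q_sd > 0
        else np.zeros((n_pairs, 2))
    )

    pairs: list[PairedRead] = [None] * n_pairs  # type: ignore[list-item]
    truth_rows: list[tuple] = []
    rl = profile.read_len

    for k in np.unique(ref_idx):
        rows = np.flatnonzero(ref_idx == k)
        amplicon = refs[k][1][: profile.amplicon_len]
        fwd_true = np.tile(_seq_to_u8(amplicon[:rl]), (rows.size, 1))
        rev_true = np.tile(_seq_to_u8(revcomp(amplicon[-rl:])), (rows.size, 1))
        fwd_obs, fwd_q, fwd_err = _simulate_mate(fwd_true, "fwd", profile, offsets[rows, 0], rng)
        rev_obs, rev_q, rev_err = _simulate_mate(rev_true, "rev", profile, offsets[rows, 1], rng)
        for j, row in enumerate(rows):
            rid = f"read_{row:07d}"
            fs, fq = fwd_obs[j], fwd_q[j]
            rs, rq = rev_obs[j], rev_q[j]
            for pos in np.flatnonzero(fwd_err[j]):
                truth_rows.append(
                    (rid, "fwd", int(pos), "sub", chr(fwd_true[j, pos]), chr(fs[pos]))
                )
            for pos in np.flatnonzero(rev_err[j]):
                truth_rows.append(
                    (rid, "rev", int(pos), "sub", chr(rev_true[j, pos]), chr(rs[pos]))
                )
            if profile.indel_rate > 0 and rng.random() < profile.indel_rate:
                ext = _seq_to_u8(refs[k][1][rl : rl + 1])
                fs, fq, events = _apply_indels(fs.copy(), fq.copy(), ext, rng)
                for pos, op in events:
                    truth_rows.append((rid, "fwd", pos, op, ".", "."))
            pairs[row] = PairedRead(rid, _u8_to_seq(fs), fq, _u8_to_seq(rs), rq)

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "mate", "pos", "op", "true_base", "obs_base"]
    )
    assignments = pd.DataFrame(
        {
            "read_id": [f"read_{i:07d}" for i in range(n_pairs)],
            "ref_id": [refs[k][0] for k in ref_idx],
            "start": starts,
        }
    )
    comp = pd.DataFrame({"ref_id": [r[0] for r in refs], "fraction": composition})
    return SimResult(pairs, truth, assignments, refs, comp, profile, seed)


# ---------------------------------------------------------------------------
# On-disk layout


def _phred33(qual: np.ndarray) -> str:
    return "".join(chr(int(q) + 33) for q in qual)


def write_sim(sim: SimResult, outdir) -> Path:
    """Write R1/R2 FASTQ, reference FASTA, truth, assignments, composition
    and the profile (JSON) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "R1.fastq", "w") as r1, open(outdir / "R2.fastq", "w") as r2:
        for p in sim.pairs:
            r1.write(f"@{p.id}/1\n{p.fwd_seq}\n+\n{_phred33(p.fwd_qual)}\n")
            r2.write(f"@{p.id}/2\n{p.rev_seq}\n+\n{_phred33(p.rev_qual)}\n")
    write_fasta(sim.refs, outdir / "refs.fasta")
    sim.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    sim.assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    sim.composition.to_csv(outdir / "composition.tsv", sep="\t", index=False)
    meta = {"seed": sim.seed, "n_pairs": len(sim.pairs), "profile": sim.profile.to_dict()}
    (outdir / "profile.json").write_text(json.dumps(meta, indent=2))
    return outdir


def load_sim(simdir) -> dict:
    """Load the files written by :func:`write_sim` (reads stay on disk)."""
    simdir = Path(simdir)
    meta = json.loads((simdir / "profile.json").read_text())
    profile_dict = dict(meta["profile"])
    profile_dict["miscall"] = np.asarray(profile_dict["miscall"])
    from .contigs import read_fasta

    return {
        "r1": simdir / "R1.fastq",
        "r2": simdir / "R2.fastq",
        "refs": read_fasta(simdir / "refs.fasta"),
        "truth": pd.read_csv(simdir / "truth.tsv", sep="\t"),
        "assignments": pd.read_csv(simdir / "assignments.tsv", sep="\t"),
        "composition": pd.read_csv(simdir / "composition.tsv", sep="\t"),
        "profile": ErrorProfile(**profile_dict),
        "seed": meta["seed"],
    }
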