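"""End-to-end workflow: simulate -> merge -> label -> train -> predict ->
denoise -> evaluate.

``run_pipeline`` executes the stages in order inside one run directory,
writes every intermediate in its documented text format, logs
stage-level counts, and serializes the effective configuration so a run
can be reproduced (bit-identically for deterministic stages,
seed-identically for stochastic ones) or resumed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._align import ReferenceSet
from .classifier import (
    ClassifierConfig,
    VotingEnsemble,
    build_labeled_instances,
    build_training_bundle,
    predict_contig_masks,
    train_ensemble,
)
from .contigs import dereplicate, merge_pairs, read_paired_fastq, write_unique_table
from .evaluation import compare_tables, filter_modal_length, truth_contig_masks
from .features import SELECTED_FEATURES
from .precluster import write_masks
from .simulate import profile_from_preset, simulate_mock, synthetic_references, write_sim

log = logging.getLogger("iped")


@dataclass
class RunConfig:
    """Every knob of the workflow, with defaults.

    The effective config is serialized alongside each run's outputs.
    """

    preset: str = "v34"
    n_pairs: int = 20000
    n_train_pairs: int = 15000
    n_refs: int = 15
    seed: int = 7
    min_overlap: int = 10
    q_delta: int = 6
    ratio_a: str = "1:3"
    caps: tuple[int, int] = (5000, 15000)
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    min_identity: float = 0.9
    threshold: float = 0.5
    diffs: str = "auto"
    include_oracle: bool = False
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    profile_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifier"] = self.classifier.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["classifier"] = ClassifierConfig(**d.get("classifier", {}))
        d["caps"] = tuple(d.get("caps", (5000, 15000)))
        d["split"] = tuple(d.get("split", (0.6, 0.2, 0.2)))
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    if not log.handlers:
        log.addHandler(logging.StreamHandler(sys.stderr))
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(fh)


def run_pipeline(config: RunConfig, outdir, resume: bool = True) -> Path:
    """Execute the full workflow into ``outdir``; returns the directory.

    Completed stages (detected by their output files) are skipped when
    ``resume`` is true.  Any stage failure propagates with the stage
    named in the log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    profile = profile_from_preset(config.preset, **config.profile_overrides)

    # -- stage 1: simulation ------------------------------------------------
    refs = synthetic_references(
        n_refs=config.n_refs, length=profile.amplicon_len, seed=config.seed
    )
    eval_dir = outdir / "sim_eval"
    train_dir = outdir / "sim_train"
    if not resume or not (eval_dir / "profile.json").exists():
        log.info("stage simulate: %d eval + %d training pairs", config.n_pairs, config.n_train_pairs)
        write_sim(simulate_mock(refs, config.n_pairs, profile, seed=config.seed), eval_dir)
        write_sim(
            simulate_mock(refs, config.n_train_pairs, profile, seed=config.seed + 1),
            train_dir,
        )

    # -- stage 2: merge + dereplicate (training arm) ------------------------
    log.info("stage merge: training reads")
    train_pairs = read_paired_fastq(train_dir / "R1.fastq", train_dir / "R2.fastq")
    train_contigs, rejected = merge_pairs(
        train_pairs, min_overlap=config.min_overlap, q_delta=config.q_delta
    )
    log.info("  %d training contigs (%d pairs rejected)", len(train_contigs), rejected)

    # -- stage 3: label + train ---------------------------------------------
    model_dir = outdir / "model"
    if not resume or not (model_dir / "meta.json").exists():
        log.info("stage label: aligning training contigs to references")
        refset = ReferenceSet(refs)
        X, y, skipped = build_labeled_instances(
            train_contigs, refset, mode="selected", min_identity=config.min_identity
        )
        log.info(
            "  %d instances (%d errors), %d contigs skipped",
            len(y), int(np.sum(y == 1)), skipped,
        )
        bundle = build_training_bundle(
            X,
            y,
            ratio_a=config.ratio_a,
            split=config.split,
            seed=config.seed,
            caps=config.caps,
            names=SELECTED_FEATURES,
        )
        log.info("stage train: class counts %s", bundle.class_counts())
        model = train_ensemble(bundle, seed=config.seed, config=config.classifier)
        model.save(model_dir)
    else:
        model = VotingEnsemble.load(model_dir)

    # -- stage 4: merge + dereplicate (evaluation arm) ----------------------
    log.info("stage merge: evaluation reads")
    eval_pairs = read_paired_fastq(eval_dir / "R1.fastq", eval_dir / "R2.fastq")
    contigs, rejected = merge_pairs(
        eval_pairs, min_overlap=config.min_overlap, q_delta=config.q_delta
    )
    uniques, culled = dereplicate(contigs)
    uniques, off_length = filter_modal_length(uniques)
    log.info(
        "  %d contigs (%d rejected), %d culled for ambiguity, %d off-length reads, %d uniques",
        len(contigs), rejected, culled, off_length, len(uniques),
    )
    write_unique_table(uniques, outdir / "uniques")

    # -- stage 5: predict masks ---------------------------------------------
    log.info("stage predict: per-position error masks")
    kept = {m for u in uniques for m in u.member_ids}
    used_contigs = [c for c in contigs if c.id in kept]
    predicted = predict_contig_masks(model, used_contigs, threshold=config.threshold)
    write_masks({cid: m for cid, m in predicted.items()}, outdir / "contig_masks.tsv")
    n_masked = int(sum(int(m.sum()) for m in predicted.values()))
    log.info("  %d positions masked", n_masked)

    # -- stage 6: denoise + compare -----------------------------------------
    log.info("stage denoise: preclustering variants")
    from .simulate import load_sim

    sim = load_sim(eval_dir)
    mask_sets: dict = {"precluster": None, "iped": predicted}
    if config.include_oracle:
        mask_sets["iped_oracle"] = truth_contig_masks(
            used_contigs, sim["assignments"], sim["refs"], profile.amplicon_len
        )
    refset = ReferenceSet(refs)
    frame, tables = compare_tables(uniques, refset, mask_sets, diffs=config.diffs)
    write_unique_table(tables["iped"], outdir / "denoised")
    frame.to_csv(outdir / "comparison.tsv", sep="\t", index=False)
    log.info("stage evaluate:\n%s", frame.to_string(index=False))
    return outdir
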