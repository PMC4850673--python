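"""Per-position sequencing-error classifier.

A plurality-voting ensemble of a multilayer perceptron (one hidden
layer of 6 units, learning rate 0.3, momentum 0.2) and a random forest
of unpruned trees predicts, for every contig position, whether the
base call is a sequencing error.  Each member outputs class
confidences; the class carrying the single highest confidence across
all members wins (ties are resolved conservatively to CORRECT).

The module also builds labeled training data by aligning contigs to
mock-community reference sequences, balances and splits it into
learning/validation/test subsets, offers a correlation-based
feature-selection routine, and computes the evaluation metrics
(sensitivity, specificity, MCC, ROC/AUC).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from ._align import ReferenceSet
from .contigs import Contig, UniqueSequence
from .features import extract_features, feature_names

CORRECT, ERROR = 0, 1


# ---------------------------------------------------------------------------
# Labeling against references


def label_by_reference(
    contig: Contig | str,
    refs: ReferenceSet | Sequence[tuple[str, str]],
    min_identity: float = 0.9,
) -> np.ndarray | None:
    """Per-position ERROR/CORRECT labels for one contig, or None if skipped.

    The contig is globally aligned (affine gaps, free reference end
    gaps) to every reference and the minimum-error alignment wins.
    Positions at mismatch columns are labeled ERROR, as are inserted
    contig bases (at their own position) and the contig position
    immediately left of a deleted reference base.  Contigs below
    ``min_identity`` to every reference are skipped.
    """
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    if not isinstance(refs, ReferenceSet):
        refs = ReferenceSet(refs)
    seq = contig.seq if isinstance(contig, Contig) else contig
    best = refs.best(seq)
    if best.identity < min_identity:
        return None
    labels = np.zeros(len(seq), dtype=np.int8)
    labels[best.query_errors] = ERROR
    return labels


def build_labeled_instances(
    contigs: Sequence[Contig],
    refs: ReferenceSet | Sequence[tuple[str, str]],
    mode: str = "selected",
    min_identity: float = 0.9,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Feature matrix and label vector over many contigs.

    Returns (X, y, n_skipped); contigs under ``min_identity`` to every
    reference contribute no instances.
    """
    if not isinstance(refs, ReferenceSet):
        refs = ReferenceSet(refs)
    xs, ys = [], []
    skipped = 0
    for contig in contigs:
        labels = label_by_reference(contig, refs, min_identity=min_identity)
        if labels is None:
            skipped += 1
            continue
        xs.append(extract_features(contig, mode))
        ys.append(labels)
    if not xs:
        return (
            np.zeros((0, len(feature_names(mode))), np.float32),
            np.zeros(0, np.int8),
            skipped,
        )
    return np.vstack(xs), np.concatenate(ys), skipped


# ---------------------------------------------------------------------------
# Training bundle


@dataclass
class TrainingBundle:
    """Learning (a), validation (b) and test (c) splits of labeled instances.

    Instances are dereplicated before splitting; subset (a) is
    downsampled to the requested error:non-error ratio (capped at
    5,000/15,000 by default) and subset (b) is balanced 1:1.
    """

    X_a: np.ndarray
    y_a: np.ndarray
    X_b: np.ndarray
    y_b: np.ndarray
    X_c: np.ndarray
    y_c: np.ndarray
    ratio_a: tuple[int, int] = (1, 3)
    feature_names: tuple[str, ...] = ()

    def class_counts(self) -> dict[str, tuple[int, int]]:
        return {
            name: (int(np.sum(y == ERROR)), int(np.sum(y == CORRECT)))
            for name, y in (("a", self.y_a), ("b", self.y_b), ("c", self.y_c))
        }


def _parse_ratio(ratio) -> tuple[int, int]:
    if isinstance(ratio, str):
        err, cor = ratio.split(":")
        ratio = (int(err), int(cor))
    err, cor = ratio
    if err < 1 or cor < 1:
        raise ValueError("ratio parts must be positive")
    return err, cor


def dereplicate_instances(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical (features, label) rows, keeping one copy each."""
    stacked = np.column_stack([X, y.astype(X.dtype)])
    uniq = np.unique(stacked, axis=0)
    return uniq[:, :-1], uniq[:, -1].astype(np.int8)


def build_training_bundle(
    X: np.ndarray,
    y: np.ndarray,
    ratio_a="1:3",
    split: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    caps: tuple[int, int] = (5000, 15000),
    names: tuple[str, ...] = (),
) -> TrainingBundle:
    """Dereplicate, shuffle and split labeled instances.

    The a/b/c split preserves the original class ratio (stratified);
    subset (a) is then downsampled to ``ratio_a`` error:non-error, the
    error class capped at ``caps[0]`` and the non-error class at
    ``caps[1]``; subset (b) is downsampled to equal class counts.
    """
    err_w, cor_w = _parse_ratio(ratio_a)
    if not np.isclose(sum(split), 1.0):
        raise ValueError("split fractions must sum to 1")
    X, y = dereplicate_instances(np.asarray(X), np.asarray(y))
    n_err, n_cor = int(np.sum(y == ERROR)), int(np.sum(y == CORRECT))
    if n_err == 0 or n_cor == 0:
        raise ValueError("both classes must be present in the training instances")
    rng = np.random.default_rng(seed)

    parts: dict[str, list[np.ndarray]] = {"a": [], "b": [], "c": []}
    for cls in (ERROR, CORRECT):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n = idx.size
        n_a = int(round(split[0] * n))
        n_b = int(round(split[1] * n))
        parts["a"].append(idx[:n_a])
        parts["b"].append(idx[n_a : n_a + n_b])
        parts["c"].append(idx[n_a + n_b :])

    def take(indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        indices = rng.permutation(indices)
        return X[indices], y[indices]

    # subset a: enforce ratio_a with caps on both classes
    a_err, a_cor = parts["a"]
    cap_err, cap_cor = caps
    want_err = min(a_err.size, cap_err)
    want_cor = min(a_cor.size, cap_cor, want_err * cor_w // err_w)
    want_err = min(want_err, max(want_cor * err_w // cor_w, 1))
    if want_err < cap_err:
        warnings.warn(
            f"subset a: only {want_err} error instances available "
            f"(requested cap {cap_err}); proceeding at the achievable size"
        )
    X_a, y_a = take(
        np.concatenate([
            rng.choice(a_err, size=want_err, replace=False),
            rng.choice(a_cor, size=want_cor, replace=False),
        ])
    )
    # subset b: equal class counts
    b_err, b_cor = parts["b"]
    n_bal = min(b_err.size, b_cor.size)
    if n_bal == 0:
        raise ValueError("validation subset lost one class; supply more instances")
    X_b, y_b = take(
        np.concatenate([
            rng.choice(b_err, size=n_bal, replace=False),
            rng.choice(b_cor, size=n_bal, replace=False),
        ])
    )
    X_c, y_c = take(np.concatenate(parts["c"]))
    return TrainingBundle(X_a, y_a, X_b, y_b, X_c, y_c, (err_w, cor_w), tuple(names))


# ---------------------------------------------------------------------------
# Correlation-based feature selection


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0  # constant features carry no signal
    return float(abs(np.corrcoef(a, b)[0, 1]))


def _cfs_merit(subset: list[int], corr_fc: np.ndarray, corr_ff: np.ndarray) -> float:
    k = len(subset)
    r_cf = corr_fc[subset].mean()
    if k == 1:
        return r_cf
    pairs = [(i, j) for n, i in enumerate(subset) for j in subset[n + 1 :]]
    r_ff = float(np.mean([corr_ff[i, j] for i, j in pairs]))
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def _greedy_cfs(X: np.ndarray, y: np.ndarray) -> list[int]:
    p = X.shape[1]
    corr_fc = np.array([_abs_corr(X[:, j], y) for j in range(p)])
    # chance-level guard: with k uncorrelated features the merit still
    # grows like sqrt(k) * mean|r|, so pure-noise correlations (about
    # 1/sqrt(n)) must not enter the search at all
    usable = corr_fc > 2.0 / np.sqrt(max(X.shape[0], 4))
    corr_ff = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            corr_ff[i, j] = corr_ff[j, i] = _abs_corr(X[:, i], X[:, j])
    selected: list[int] = []
    best_merit = -np.inf
    while True:
        candidates = [j for j in range(p) if usable[j] and j not in selected]
        if not candidates:
            return selected
        merits = [(_cfs_merit(selected + [j], corr_fc, corr_ff), j) for j in candidates]
        merit, j = max(merits)
        if merit <= best_merit:
            return selected
        best_merit = merit
        selected.append(j)


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 3,
    seed: int = 0,
    names: Sequence[str] | None = None,
):
    """Correlation-based greedy forward feature selection under k-fold CV.

    For each fold's training split a subset maximizing the merit
    k*r_cf / sqrt(k + k(k-1)*r_ff) is grown greedily (r_cf: mean
    absolute feature-class correlation, r_ff: mean absolute
    feature-feature correlation); features chosen in a majority of
    folds are returned (indices, or names when ``names`` is given).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(seed)
    order = rng.permutation(X.shape[0])
    fold_of = np.arange(X.shape[0]) % folds
    votes = np.zeros(X.shape[1], dtype=int)
    for f in range(folds):
        train = order[fold_of != f]
        for j in _greedy_cfs(X[train], y[train]):
            votes[j] += 1
    chosen = [j for j in range(X.shape[1]) if votes[j] * 2 > folds]
    if names is not None:
        return [names[j] for j in chosen]
    return chosen


# ---------------------------------------------------------------------------
# Voting ensemble


@dataclass
class ClassifierConfig:
    """Hyperparameters of the ensemble members.

    The MLP geometry (one hidden layer of 6 logistic units), learning
    rate 0.3 and momentum 0.2, and the use of unpruned random-forest
    trees are fixed properties of the method; epoch count, batch size,
    forest size and split candidates are artifact choices recorded here.
    """

    mlp_epochs: int = 500
    mlp_batch_size: int = 200
    rf_trees: int = 100
    rf_max_features: str = "sqrt"

    def to_dict(self) -> dict:
        return {
            "mlp_epochs": self.mlp_epochs,
            "mlp_batch_size": self.mlp_batch_size,
            "rf_trees": self.rf_trees,
            "rf_max_features": self.rf_max_features,
        }


def _preprocessor(names: Sequence[str]) -> ColumnTransformer:
    names = list(names)
    cat_idx = [i for i, n in enumerate(names) if n == "overlap"]
    num_idx = [i for i in range(len(names)) if i not in cat_idx]
    transformers = [("num", StandardScaler(), num_idx)]
    if cat_idx:
        transformers.append(
            (
                "cat",
                OneHotEncoder(categories=[[0.0, 1.0, 2.0, 3.0]], handle_unknown="ignore"),
                cat_idx,
            )
        )
    return ColumnTransformer(transformers)


@dataclass
class VotingEnsemble:
    """Plurality-voting ensemble over fitted member classifiers.

    Every member outputs per-class confidences in [0, 1] summing to 1;
    the predicted class is the class of the single highest confidence
    among all members' outputs.  An exact tie between the best ERROR
    and best CORRECT confidence resolves to CORRECT (no masking).
    """

    members: list[tuple[str, Pipeline]]
    feature_names: tuple[str, ...]
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature width {X.shape[1] if X.ndim == 2 else X.shape} does not "
                f"match the {len(self.feature_names)} features this model was trained on"
            )
        return X

    def member_confidences(self, X: np.ndarray) -> np.ndarray:
        """Confidences, shape (members, instances, 2): CORRECT then ERROR."""
        X = self._check(X)
        out = np.zeros((len(self.members), X.shape[0], 2))
        for m, (_, clf) in enumerate(self.members):
            proba = clf.predict_proba(X)
            for local, cls in enumerate(clf.classes_):
                out[m, :, int(cls)] = proba[:, local]
        return out

    def confidences(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(best CORRECT confidence, best ERROR confidence) per instance."""
        conf = self.member_confidences(X)
        return conf[:, :, CORRECT].max(axis=0), conf[:, :, ERROR].max(axis=0)

    def error_confidence(self, X: np.ndarray) -> np.ndarray:
        """Score used for ROC sweeps: the best ERROR confidence."""
        return self.confidences(X)[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        cor, err = self.confidences(X)
        return (err > cor).astype(np.int8)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> Path:
        """Versioned model archive: meta.json plus one joblib per member."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "feature_names": list(self.feature_names),
            "members": [name for name, _ in self.members],
            "config": self.config.to_dict(),
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))
        for name, clf in self.members:
            joblib.dump(clf, directory / f"{name}.joblib")
        return directory

    @classmethod
    def load(cls, directory) -> "VotingEnsemble":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        if meta.get("format_version") != 1:
            raise ValueError(f"unsupported model archive version in {directory}")
        members = [
            (name, joblib.load(directory / f"{name}.joblib")) for name in meta["members"]
        ]
        return cls(
            members=members,
            feature_names=tuple(meta["feature_names"]),
            config=ClassifierConfig(**meta["config"]),
        )


def train_ensemble(
    bundle: TrainingBundle,
    seed: int = 0,
    config: ClassifierConfig | None = None,
) -> VotingEnsemble:
    """Train the MLP + random-forest plurality-voting ensemble on subset (a)."""
    config = config or ClassifierConfig()
    X, y = np.asarray(bundle.X_a, np.float64), np.asarray(bundle.y_a)
    if X.size == 0:
        raise ValueError("subset a is empty")
    if not np.isfinite(X).all():
        raise ValueError("training features contain non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("subset a must contain both classes")
    names = bundle.feature_names or tuple(f"f{i}" for i in range(X.shape[1]))

    mlp = Pipeline(
        [
            ("prep", _preprocessor(names)),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=(6,),
                    activation="logistic",
                    solver="sgd",
                    learning_rate_init=0.3,
                    momentum=0.2,
                    nesterovs_momentum=False,
                    batch_size=min(config.mlp_batch_size, X.shape[0]),
                    max_iter=config.mlp_epochs,
                    random_state=seed,
                ),
            ),
        ]
    )
    rf = Pipeline(
        [
            ("prep", _preprocessor(names)),
            (
                "rf",
                RandomForestClassifier(
                    n_estimators=config.rf_trees,
                    max_features=config.rf_max_features,
                    max_depth=None,  # unpruned trees
                    random_state=seed + 1,
                    n_jobs=1,
                ),
            ),
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(X, y)
    rf.fit(X, y)
    return VotingEnsemble(
        members=[("mlp", mlp), ("random_forest", rf)],
        feature_names=tuple(names),
        config=config,
    )


# ---------------------------------------------------------------------------
# Mask prediction


def predict_mask(
    model: VotingEnsemble, features: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Boolean error mask: plurality vote is ERROR and its confidence
    reaches ``threshold``."""
    cor, err = model.confidences(features)
    return (err > cor) & (err >= threshold)


def predict_contig_masks(
    model: VotingEnsemble,
    contigs: Sequence[Contig],
    threshold: float = 0.5,
    chunk_positions: int = 500_000,
) -> dict[str, np.ndarray]:
    """Per-contig error masks, predicting in bounded-size chunks."""
    mode = "selected" if len(model.feature_names) == 6 else "full"
    masks: dict[str, np.ndarray] = {}
    batch: list[Contig] = []
    batch_len = 0

    def flush() -> None:
        nonlocal batch, batch_len
        if not batch:
            return
        X = np.vstack([extract_features(c, mode) for c in batch])
        flat = predict_mask(model, X, threshold)
        start = 0
        for c in batch:
            masks[c.id] = flat[start : start + len(c)]
            start += len(c)
        batch, batch_len = [], 0

    for contig in contigs:
        batch.append(contig)
        batch_len += len(contig)
        if batch_len >= chunk_positions:
            flush()
    flush()
    return masks


def aggregate_masks(
    uniques: Sequence[UniqueSequence], contig_masks: dict[str, np.ndarray]
) -> None:
    """Reconcile per-read masks onto unique sequences (in place).

    A position is masked when predicted erroneous in more than half of
    the member reads; exact ties mask.
    """
    for u in uniques:
        votes = np.zeros(len(u.seq), dtype=np.int64)
        for member in u.member_ids:
            votes += contig_masks[member]
        u.mask = (votes * 2 >= u.abundance) & (votes > 0)


# ---------------------------------------------------------------------------
# Evaluation metrics


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    mcc: float


def confusion_metrics(predicted, truth) -> ConfusionMetrics:
    """Confusion counts plus sensitivity, specificity and MCC.

    An erroneous position predicted erroneous is a TP; sensitivity is
    TP/(TP+FN), specificity TN/(TN+FP), and
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined
    as 0 whenever a denominator factor is 0 (as is a 0/0 rate).
    """
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth labels differ in length")
    tp = int(np.sum(predicted & truth))
    fp = int(np.sum(predicted & ~truth))
    tn = int(np.sum(~predicted & ~truth))
    fn = int(np.sum(~predicted & truth))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return ConfusionMetrics(tp, fp, tn, fn, sens, spec, float(mcc))


def roc_curve(error_confidences, truth) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC points (one per distinct threshold) and trapezoidal AUC.

    Returns (fpr, tpr, thresholds, auc); raises when the truth labels
    contain a single class.
    """
    truth = np.asarray(truth).astype(int)
    if len(np.unique(truth)) < 2:
        raise ValueError("ROC requires both classes in the truth labels")
    fpr, tpr, thresholds = _sk_roc_curve(truth, np.asarray(error_confidences, float))
    return fpr, tpr, thresholds, float(_trapezoid_auc(fpr, tpr))
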