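"""SVM-ensemble identification of discriminative frame parameters.

Many linear support-vector classifiers are trained on disjoint balanced
frame samples to separate experimental from control sessions; the
best-validated subset is kept, and each parameter's hyperplane weights
across the kept classifiers are tested against zero (one-sample t-test,
Bonferroni-corrected) to find the parameters that discriminate the groups.

Because every classifier sees a disjoint set of frames, the kept weight
vectors are treated as independent samples of the discriminative
direction, which is what licenses the t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import FEATURE_NAMES


@dataclass
class EnsembleConfig:
    """Protocol parameters for the classifier ensemble.

    Defaults follow the full-scale experimental protocol: 90 classifiers
    of which the 30 best-validated are kept, 3,000 training and 30,000
    validation/test frames per class per classifier, all frame sets
    pairwise disjoint, significance at alpha = 1e-4 after a 17-way
    Bonferroni correction.
    """

    n_classifiers: int = 90
    n_keep: int = 30
    n_train_per_class: int = 3000
    n_val_per_class: int = 30000
    n_test_per_class: int = 30000
    C: float = 1.0
    alpha: float = 1e-4
    bonferroni_m: int = 17
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_keep > self.n_classifiers:
            raise ValueError("n_keep must not exceed n_classifiers")
        if min(self.n_train_per_class, self.n_val_per_class,
               self.n_test_per_class, self.n_classifiers, self.n_keep) <= 0:
            raise ValueError("all counts must be positive")


@dataclass
class EnsembleResult:
    weights: np.ndarray                 # (n_keep, n_features)
    val_accuracy: np.ndarray            # (n_keep,)
    test_accuracy: np.ndarray           # (n_keep,)
    p_values: np.ndarray                # (n_features,) raw
    significant: List[str]
    feature_names: List[str]
    kept_indices: np.ndarray
    frame_ledger: Dict[int, Dict[str, np.ndarray]]
    models: list = field(default_factory=list, repr=False)
    scalers: list = field(default_factory=list, repr=False)
    flags: List[str] = field(default_factory=list)


def _disjoint_partition(
    idx: np.ndarray, rng: np.random.Generator, sizes: Sequence[int],
    n_groups: int,
) -> Tuple[List[List[np.ndarray]], float]:
    """Split ``idx`` into ``n_groups`` x len(sizes) disjoint chunks.

    If not enough frames exist, all sizes are shrunk proportionally (a
    warning is the caller's responsibility). Returns the chunks and the
    shrink factor applied.
    """
    need = n_groups * sum(sizes)
    shrink = 1.0
    if need > len(idx):
        shrink = len(idx) / need
        sizes = [max(1, int(s * shrink)) for s in sizes]
    perm = rng.permutation(idx)
    chunks, pos = [], 0
    for _ in range(n_groups):
        group = []
        for s in sizes:
            group.append(perm[pos:pos + s])
            pos += s
        chunks.append(group)
    return chunks, shrink


def train_svm_ensemble(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: Optional[EnsembleConfig] = None,
    feature_names: Optional[List[str]] = None,
) -> EnsembleResult:
    """Train the ensemble and test per-parameter weight significance.

    ``features`` is (n_frames, n_features); ``labels`` holds exactly two
    classes (sorted order defines class 0/1; the hyperplane weight sign
    follows that orientation). Frames with NaNs are dropped up front.
    Features are z-scored on each classifier's training split so weight
    magnitudes are comparable across parameters.
    """
    from sklearn.svm import SVC
    from sklearn.preprocessing import StandardScaler

    cfg = cfg or EnsembleConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if feature_names is None:
        feature_names = (FEATURE_NAMES if x.shape[1] == len(FEATURE_NAMES)
                         else [f"f{i}" for i in range(x.shape[1])])
    ok = ~np.isnan(x).any(axis=1)
    x, y = x[ok], y[ok]
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    rng = np.random.default_rng(cfg.seed)
    flags: List[str] = []

    sizes = [cfg.n_train_per_class, cfg.n_val_per_class, cfg.n_test_per_class]
    chunks = {}
    for c in classes:
        idx = np.where(y == c)[0]
        chunks[c], shrink = _disjoint_partition(idx, rng, sizes,
                                                cfg.n_classifiers)
        if shrink < 1.0:
            flags.append(f"shrunk_{c}:{shrink:.3f}")
            warnings.warn(
                f"class {c!r}: not enough frames for disjoint sampling; "
                f"set sizes shrunk by {shrink:.3f}", stacklevel=2)

    n_feat = x.shape[1]
    weights = np.empty((cfg.n_classifiers, n_feat))
    val_acc = np.empty(cfg.n_classifiers)
    models, scalers, ledger = [], [], {}
    for i in range(cfg.n_classifiers):
        tr = np.concatenate([chunks[c][i][0] for c in classes])
        va = np.concatenate([chunks[c][i][1] for c in classes])
        te = np.concatenate([chunks[c][i][2] for c in classes])
        ledger[i] = {"train": tr, "val": va, "test": te}
        scaler = StandardScaler().fit(x[tr])
        if np.any(scaler.scale_ == 0):
            flags.append(f"constant_feature_clf{i}")
            warnings.warn("constant feature in a training split; its weight "
                          "is zero", stacklevel=2)
            scaler.scale_[scaler.scale_ == 0] = 1.0
        clf = SVC(kernel="linear", C=cfg.C).fit(scaler.transform(x[tr]),
                                                y[tr])
        w = clf.coef_.ravel().copy()
        models.append(clf)
        scalers.append(scaler)
        weights[i] = w
        val_acc[i] = float(
            (clf.predict(scaler.transform(x[va])) == y[va]).mean())

    # keep the best-validated classifiers; ties broken by classifier index
    order = np.lexsort((np.arange(cfg.n_classifiers), -val_acc))
    kept = np.sort(order[:cfg.n_keep])
    test_acc = np.array([
        float((models[i].predict(scalers[i].transform(x[ledger[i]["test"]]))
               == y[ledger[i]["test"]]).mean())
        for i in kept
    ])
    kept_w = weights[kept]
    p, significant, sig_flags = weight_significance(
        kept_w, alpha=cfg.alpha, m=cfg.bonferroni_m,
        feature_names=feature_names)
    return EnsembleResult(
        weights=kept_w, val_accuracy=val_acc[kept], test_accuracy=test_acc,
        p_values=p, significant=significant, feature_names=feature_names,
        kept_indices=kept, frame_ledger=ledger,
        models=[models[i] for i in kept],
        scalers=[scalers[i] for i in kept], flags=flags + sig_flags)


def weight_significance(
    weights: np.ndarray,
    alpha: float = 1e-4,
    m: int = 17,
    feature_names: Optional[List[str]] = None,
) -> Tuple[np.ndarray, List[str], List[str]]:
    """One-sample t-test of each weight column against zero.

    Returns (raw p-values, significant feature names under a Bonferroni
    correction of size ``m``, flags). A zero-variance column with nonzero
    mean is degenerate evidence (p -> 0) and is flagged; a zero-variance
    zero-mean column gets p = 1.
    """
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    if len(w) < 2:
        raise ValueError("need at least two kept classifiers")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(w.shape[1])]
    p = np.empty(w.shape[1])
    flags: List[str] = []
    for j in range(w.shape[1]):
        col = w[:, j]
        if col.std(ddof=1) == 0:
            if col.mean() == 0:
                p[j] = 1.0
            else:
                p[j] = 0.0
                flags.append(f"degenerate_t:{feature_names[j]}")
        else:
            p[j] = stats.ttest_1samp(col, 0.0).pvalue
    corrected = np.minimum(p * m, 1.0)
    significant = [feature_names[j] for j in range(w.shape[1])
                   if corrected[j] < alpha]
    return p, significant, flags


def audit_frame_ledger(ledger: Dict[int, Dict[str, np.ndarray]]) -> None:
    """Verify the disjointness guarantees of the sampling protocol.

    Raises ValueError if any two classifiers share training frames or if
    any classifier's train/val/test sets overlap.
    """
    for i, sets in ledger.items():
        tr, va, te = (set(sets[k].tolist()) for k in ("train", "val", "test"))
        if tr & va or tr & te or va & te:
            raise ValueError(f"classifier {i}: train/val/test sets overlap")
    ids = sorted(ledger)
    for a_pos, a in enumerate(ids):
        sa = set(ledger[a]["train"].tolist())
        for b in ids[a_pos + 1:]:
            if sa & set(ledger[b]["train"].tolist()):
                raise ValueError(
                    f"classifiers {a} and {b} share training frames")


def classify_frames(
    result: EnsembleResult,
    features: np.ndarray,
    labels: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, Optional[np.ndarray], int]:
    """Majority-vote predictions of the kept classifiers on new frames.

    Returns (majority predictions, per-classifier accuracy if ``labels``
    given, number of NaN frames skipped). NaN frames get a prediction of
    None (object array) and are excluded from accuracies.
    """
    x = np.asarray(features, dtype=float)
    ok = ~np.isnan(x).any(axis=1)
    n_skipped = int((~ok).sum())
    preds = np.empty((len(result.models), ok.sum()), dtype=object)
    for i, (clf, scaler) in enumerate(zip(result.models, result.scalers)):
        preds[i] = clf.predict(scaler.transform(x[ok]))
    majority = np.empty(len(x), dtype=object)
    majority[~ok] = None
    for col, j in enumerate(np.where(ok)[0]):
        vals, counts = np.unique(preds[:, col].astype(str),
                                 return_counts=True)
        majority[j] = vals[np.argmax(counts)]
    acc = None
    if labels is not None:
        yy = np.asarray(labels)[ok].astype(str)
        acc = np.array([(preds[i].astype(str) == yy).mean()
                        for i in range(len(result.models))])
    return majority, acc, n_skipped
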