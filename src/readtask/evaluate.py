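"""Feature assembly and the cross-validated classification harness.

Per-segment features from the speech modality (PIVD, AFVC), the head
movement channel (RHR, UHD) and the mouth-fluency embedding (RRF1-4) are
joined on (subject, segment) and evaluated with SVM and random-forest
classifiers under stratified 10-fold cross-validation repeated 5 times;
accuracy, specificity, sensitivity and AUC (all in percent) are averaged
over every fold of every repeat.

Folds group by subject by default so the four segments of one subject
never straddle a train/test boundary; the per-segment alternative
("paper mode") is optimistic and available via ``CVConfig``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SPEECH_FEATURES",
    "VIDEO_FEATURES",
    "FUSED_FEATURES",
    "FEATURE_SELECTIONS",
    "CVConfig",
    "EvalReport",
    "assemble_features",
    "compute_metrics",
    "cross_validate",
]

SPEECH_FEATURES = ["pivd", "afvc"]
VIDEO_FEATURES = ["rhr", "uhd", "rrf1", "rrf2", "rrf3", "rrf4"]
FUSED_FEATURES = SPEECH_FEATURES + VIDEO_FEATURES
FEATURE_SELECTIONS = {
    "speech": SPEECH_FEATURES,
    "video": VIDEO_FEATURES,
    "fused": FUSED_FEATURES,
}

_KEYS = ["subject", "segment"]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol parameters."""

    folds: int = 10
    repeats: int = 5
    stratified: bool = True
    seed: int = 0
    group_by_subject: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")
        if self.repeats < 1:
            raise ValueError(f"repeats must be >= 1, got {self.repeats}")


@dataclass
class EvalReport:
    """Per-fold metrics plus their means over repeats x folds."""

    classifier: str
    per_fold: pd.DataFrame = field(repr=False)

    @property
    def summary(self) -> dict[str, float]:
        return {
            k: float(self.per_fold[k].mean())
            for k in ("accuracy", "specificity", "sensitivity", "auc")
        }


def _key_check(frames: dict[str, pd.DataFrame]) -> None:
    keysets = {
        name: set(map(tuple, df[_KEYS].itertuples(index=False)))
        for name, df in frames.items()
    }
    union = set.union(*keysets.values())
    problems = []
    for name, keys in keysets.items():
        missing = union - keys
        if missing:
            shown = sorted(missing)[:5]
            problems.append(f"{name} is missing keys {shown}" +
                            (" ..." if len(missing) > 5 else ""))
    if problems:
        raise ValueError("feature tables do not align: " + "; ".join(problems))


def assemble_features(
    acoustic: pd.DataFrame,
    head: pd.DataFrame,
    rrf: pd.DataFrame | None = None,
    selection: str = "fused",
) -> pd.DataFrame:
    """Inner-join per-segment feature tables and select a modality subset.

    Every table must carry ``subject`` and ``segment`` columns; the label
    column is taken from whichever table provides it.  ``selection`` is one
    of ``speech`` (2 columns), ``video`` (6) or ``fused`` (8).  Key
    mismatches raise with the offending keys listed.
    """
    if selection not in FEATURE_SELECTIONS:
        raise ValueError(f"selection must be one of {sorted(FEATURE_SELECTIONS)}")
    wanted = FEATURE_SELECTIONS[selection]
    frames = {"acoustic": acoustic, "head": head}
    if rrf is not None:
        frames["rrf"] = rrf
    for name, df in frames.items():
        if not set(_KEYS) <= set(df.columns):
            raise ValueError(f"{name} table lacks key columns {_KEYS}")
    _key_check(frames)
    merged = acoustic.merge(head, on=_KEYS, suffixes=("", "_head"))
    if rrf is not None:
        merged = merged.merge(rrf, on=_KEYS, suffixes=("", "_rrf"))
    label_cols = [c for c in merged.columns if c == "label" or c.startswith("label_")]
    if not label_cols:
        raise ValueError("no table provides a 'label' column")
    missing = [c for c in wanted if c not in merged.columns]
    if missing:
        raise ValueError(f"selection {selection!r} needs absent columns {missing}")
    out = merged[_KEYS].copy()
    out["label"] = merged[label_cols[0]]
    for c in wanted:
        out[c] = merged[c]
    return out


def compute_metrics(
    labels: np.ndarray, predictions: np.ndarray, scores: np.ndarray
) -> dict[str, float]:
    """Accuracy, specificity, sensitivity and AUC in percent.

    Labels are binary with 1 = patient (positive) and 0 = control;
    specificity is the true-negative rate over controls and sensitivity the
    true-positive rate over patients.  AUC uses the continuous scores.
    Single-class ground truth makes AUC (and one of the rates) undefined
    and raises.
    """
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not (labels.shape == predictions.shape == scores.shape):
        raise ValueError("labels, predictions and scores must have equal length")
    if np.unique(labels).size < 2:
        raise ValueError("ground truth contains a single class; AUC undefined")
    pos, neg = labels == 1, labels == 0
    tp = int(np.sum(pos & (predictions == 1)))
    tn = int(np.sum(neg & (predictions == 0)))
    return {
        "accuracy": 100.0 * float(np.mean(predictions == labels)),
        "specificity": 100.0 * tn / int(neg.sum()),
        "sensitivity": 100.0 * tp / int(pos.sum()),
        "auc": 100.0 * float(roc_auc_score(labels, scores)),
    }


def _make_classifier(kind: str, seed: int):
    if kind == "svm":
        return SVC(kernel="rbf", C=1.0)
    if kind == "rf":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    raise ValueError(f"classifier must be 'svm' or 'rf', got {kind!r}")


def _scores(clf, x: np.ndarray) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        return clf.decision_function(x)
    return clf.predict_proba(x)[:, 1]


def cross_validate(
    table: pd.DataFrame,
    classifier: str = "svm",
    cfg: CVConfig | None = None,
    feature_cols: list[str] | None = None,
    rrf_extractor=None,
) -> EvalReport:
    """Repeated stratified k-fold evaluation of one feature selection.

    Feature standardization uses training-fold statistics only.  When
    ``rrf_extractor`` is given, the RRF columns are recomputed per fold with
    heads trained exclusively on that fold's training rows (no leakage);
    static ``rrf*`` columns in the table are ignored in that case.
    """
    cfg = cfg or CVConfig()
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c not in _KEYS + ["label"]]
    y = table["label"].to_numpy().astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cfg.folds:
        raise ValueError(
            f"each class needs >= {cfg.folds} rows, got counts {counts.tolist()}"
        )
    rrf_cols = [c for c in feature_cols if c.startswith("rrf")]
    base_cols = [c for c in feature_cols if not c.startswith("rrf")]
    use_extractor = rrf_extractor is not None and rrf_cols
    if not use_extractor:
        missing = [c for c in feature_cols if c not in table.columns]
        if missing:
            raise ValueError(f"table lacks feature columns {missing}")
    x_base = table[base_cols].to_numpy(dtype=float) if base_cols else None
    x_static = None
    if rrf_cols and not use_extractor:
        x_static = table[rrf_cols].to_numpy(dtype=float)

    groups = table["subject"].to_numpy() if cfg.group_by_subject else None
    rows = []
    for repeat in range(cfg.repeats):
        split_seed = cfg.seed + repeat
        if cfg.group_by_subject:
            splitter = StratifiedGroupKFold(
                n_splits=cfg.folds, shuffle=True, random_state=split_seed
            )
            splits = splitter.split(np.zeros(len(y)), y, groups=groups)
        else:
            splitter = StratifiedKFold(
                n_splits=cfg.folds, shuffle=True, random_state=split_seed
            )
            splits = splitter.split(np.zeros(len(y)), y)
        for fold, (train_idx, test_idx) in enumerate(splits):
            parts = []
            if x_base is not None:
                parts.append(x_base)
            if use_extractor:
                fold_seed = (cfg.seed * 1009 + repeat * 101 + fold) % (2**31 - 1)
                parts.append(rrf_extractor.features_for_fold(train_idx, fold_seed))
            elif x_static is not None:
                parts.append(x_static)
            x = np.hstack(parts)
            scaler = StandardScaler().fit(x[train_idx])
            xtr, xte = scaler.transform(x[train_idx]), scaler.transform(x[test_idx])
            clf_seed = (cfg.seed * 7919 + repeat * 211 + fold) % (2**31 - 1)
            clf = _make_classifier(classifier, clf_seed).fit(xtr, y[train_idx])
            metrics = compute_metrics(
                y[test_idx], clf.predict(xte), _scores(clf, xte)
            )
            rows.append({"repeat": repeat, "fold": fold, **metrics})
    return EvalReport(classifier=classifier, per_fold=pd.DataFrame(rows))
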