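"""SVM re-prediction of expression status from motif-count features.

Validates detected motifs by asking a second, unrelated classifier to
re-predict the expressed/low label from nothing but per-gene motif hit
counts (hits pre-filtered at q <= 0.1). An rbf-kernel SVM is fit on a
training split and scored on a held-out split with accuracy, precision,
recall and F1, expressed being the positive class. Running two motif
sets through the identical split yields the paired comparison table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

METRICS = ("accuracy", "precision", "recall", "f1")


@dataclass
class FeatureMatrix:
    counts: pd.DataFrame  # genes x motifs, non-negative ints
    source: str = "transformed"

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)


def feature_matrix(
    hits,
    genes: list[str],
    motif_names: list[str],
    source: str = "transformed",
) -> FeatureMatrix:
    """Per-(gene, motif) hit counts; genes without hits get zero rows."""
    counts = pd.DataFrame(
        0, index=list(genes), columns=list(motif_names), dtype=np.int64
    )
    for h in hits:
        if h.gene_id in counts.index and h.motif in counts.columns:
            counts.loc[h.gene_id, h.motif] += 1
    return FeatureMatrix(counts, source=source)


def svm_evaluate(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    split: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    C: float = 1.0,
    gamma: str | float = "scale",
) -> dict:
    """Fit the rbf SVM on the train split, report the four metrics on
    the held-out split (expressed = label 1 = positive class)."""
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    train_idx, test_idx = split
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("training split must contain both classes")
    degenerate = bool(np.all(Xv == 0))
    if degenerate:
        logger.warning("feature matrix is all zeros; metrics are degenerate")
    clf = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
    clf.fit(Xv[train_idx], y[train_idx])
    pred = clf.predict(Xv[test_idx])
    truth = y[test_idx]
    metrics = {
        "accuracy": float(accuracy_score(truth, pred)),
        "precision": float(precision_score(truth, pred, zero_division=0)),
        "recall": float(recall_score(truth, pred, zero_division=0)),
        "f1": float(f1_score(truth, pred, zero_division=0)),
        "degenerate_features": degenerate,
    }
    return metrics


def compare_motif_sets(
    feature_sets: dict[str, FeatureMatrix],
    y: np.ndarray,
    split: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    **svm_kwargs,
) -> pd.DataFrame:
    """Paired metric table: one row per motif set, identical split and
    seed throughout, so differences reflect the motif sets alone."""
    rows = []
    for tag, fm in feature_sets.items():
        m = svm_evaluate(fm, y, split, seed=seed, **svm_kwargs)
        rows.append({"motif_set": tag, **{k: m[k] for k in METRICS}})
    return pd.DataFrame(rows).set_index("motif_set")
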