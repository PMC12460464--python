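"""Classification metrics, latent-space divergence, and t-SNE export.

Accuracy is correct/total; per-class F1 follows
F1 = 2*Precision*Recall / (Precision+Recall) with the zero-division
convention F1 = 0 (flagged).  The headline F1 is the unweighted (macro)
mean over classes, which is robust to the class imbalance typical of
clinical cohorts; the support-weighted micro average is also emitted.

Latent-domain divergence is a Kullback-Leibler divergence between
diagonal Gaussians fitted by moments to two latent sample sets — a
deterministic closed form, asymmetric by construction.  t-SNE is
export-only: it returns 2-D coordinates (and can write them with group
labels); plotting is left to the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

__all__ = [
    "MetricsReport",
    "score",
    "gaussian_kl",
    "tsne_embed",
    "write_embedding",
    "cross_validate_accuracy",
]


@dataclass
class MetricsReport:
    accuracy: float
    per_class: dict          # label -> {"precision", "recall", "f1", "support"}
    macro_f1: float
    micro_f1: float
    confusion: np.ndarray    # rows = true, cols = predicted
    labels: list
    zero_division_flag: bool = False

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
            "per_class": self.per_class,
            "confusion": self.confusion.tolist(),
            "labels": list(self.labels),
            "zero_division_flag": self.zero_division_flag,
        }


def score(y_true, y_pred, labels=None) -> MetricsReport:
    """Accuracy, per-class precision/recall/F1, macro and micro F1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.dtype == object:
        y_true = y_true.astype(str)
    if y_pred.dtype == object:
        y_pred = y_pred.astype(str)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred have different lengths")
    if len(y_true) == 0:
        raise ValueError("empty input")
    if labels is None:
        labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    zero_div = bool(np.any((prec + rec) == 0))
    per_class = {
        str(lab): {
            "precision": float(p),
            "recall": float(r),
            "f1": float(f),
            "support": int(s),
        }
        for lab, p, r, f, s in zip(labels, prec, rec, f1, support)
    }
    conf = confusion_matrix(y_true, y_pred, labels=labels)
    micro = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="micro", zero_division=0
    )[2]
    return MetricsReport(
        accuracy=float(np.mean(y_true == y_pred)),
        per_class=per_class,
        macro_f1=float(f1.mean()),
        micro_f1=float(micro),
        confusion=conf,
        labels=list(labels),
        zero_division_flag=zero_div,
    )


def gaussian_kl(latent_a, latent_b, var_floor: float = 1e-8) -> float:
    """KL( N_a || N_b ) between diagonal Gaussians fitted by moments.

    Each set is summarized by per-dimension mean and (MLE) variance;
    the closed form sum_i [ log(s_b/s_a) + (s_a^2 + (m_a-m_b)^2) /
    (2 s_b^2) - 1/2 ] is returned.  Asymmetric in (a, b); >= 0.
    """
    a = np.asarray(latent_a, dtype=np.float64)
    b = np.asarray(latent_b, dtype=np.float64)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 samples per set")
    if a.shape[1] != b.shape[1]:
        raise ValueError("dimension mismatch")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0), b.var(axis=0)
    if np.any(va < var_floor) or np.any(vb < var_floor):
        warnings.warn(
            f"degenerate variance floored at {var_floor}", RuntimeWarning, stacklevel=2
        )
        va = np.maximum(va, var_floor)
        vb = np.maximum(vb, var_floor)
    kl = 0.5 * (np.log(vb / va) + (va + (ma - mb) ** 2) / vb - 1.0)
    return float(kl.sum())


def cross_validate_accuracy(
    make_classifier, X, y, domain=None, n_splits: int = 5, seed: int = 0
) -> dict:
    """Stratified k-fold accuracy of a fit/predict classifier, mean +/- sd.

    ``make_classifier()`` must return a fresh unfitted estimator whose
    ``fit`` accepts (X, y) — plus ``domain=`` when a domain array is
    given — and whose ``predict`` mirrors it.  Folds are stratified on
    the labels of the labeled rows only; unlabeled rows (label
    "unknown") ride along in every training fold and are never scored.
    """
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=object)
    labeled = np.flatnonzero(y != "unknown")
    unlabeled = np.flatnonzero(y == "unknown")
    folds = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs = []
    for tr, te in folds.split(X[labeled], y[labeled].astype(str)):
        fit_rows = np.concatenate([labeled[tr], unlabeled]).astype(int)
        test_rows = labeled[te]
        clf = make_classifier()
        if domain is None:
            clf.fit(X[fit_rows], y[fit_rows])
            pred = clf.predict(X[test_rows])
        else:
            dom = np.asarray(domain, dtype=object)
            clf.fit(X[fit_rows], y[fit_rows], domain=dom[fit_rows])
            pred = clf.predict(X[test_rows], domain=dom[test_rows])
        accs.append(float(np.mean(pred == y[test_rows])))
    return {
        "mean_accuracy": float(np.mean(accs)),
        "sd_accuracy": float(np.std(accs, ddof=1)),
        "fold_accuracies": accs,
        "n_splits": n_splits,
    }


def tsne_embed(features, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE embedding (Barnes-Hut, PCA init), deterministic per seed."""
    from sklearn.manifold import TSNE

    features = np.asarray(features, dtype=np.float64)
    n = len(features)
    if n <= 3 * perplexity:
        raise ValueError(
            f"n={n} too small for perplexity={perplexity} (need n > 3*perplexity)"
        )
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(features)
    if not np.all(np.isfinite(emb)):
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return emb


def write_embedding(path, embedding, subject_ids, domain, diagnosis) -> None:
    """Write an embedding TSV: subject_id, dim1, dim2, domain, diagnosis."""
    df = pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "dim1": np.asarray(embedding)[:, 0],
            "dim2": np.asarray(embedding)[:, 1],
            "domain": list(domain),
            "diagnosis": list(diagnosis),
        }
    )
    df.to_csv(path, sep="\t", index=False)
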