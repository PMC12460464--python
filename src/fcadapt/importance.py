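"""Weight-based feature importance with a permutation null and FDR.

The first encoding layer is the most interpretable part of the model:
the magnitude of the weights leaving input feature j measures how much
that FC feature contributes to the learned representation.  The score
of feature j is the mean absolute outgoing weight, averaged over
per-epoch training checkpoints.  Significance comes from a permutation
null: the input feature order is globally shuffled (one permutation
applied to all subjects), the model is retrained under an identical
configuration, and the scores are recorded; the per-feature p-value is

    P = 100 * #(null scores > observed) / n_permutations   (percent),

optionally with the add-one smoothing (count+1)/(n+1) that avoids exact
zeros.  Benjamini-Hochberg step-up at q = 0.05 controls the FDR, and
surviving features map back to ROI pairs through the documented
upper-triangle ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import index_to_pair, n_features_for_rois

__all__ = [
    "ImportanceResult",
    "feature_scores",
    "permutation_null",
    "p_values",
    "fdr_select",
    "map_to_roi_pairs",
    "write_edge_list",
]


@dataclass
class ImportanceResult:
    scores: np.ndarray          # observed score per input feature
    null: np.ndarray            # n_perm x n_features null scores
    p_percent: np.ndarray       # p-values in percent
    significant: np.ndarray     # FDR mask
    q: float
    p_policy: str


def feature_scores(checkpoints, input_dim: int | None = None,
                   aggregate: str = "mean_abs") -> np.ndarray:
    """Per-input-feature score from first-layer weight checkpoints.

    Each checkpoint is an (n_inputs, n_units) weight matrix (rows beyond
    ``input_dim`` — e.g. domain one-hot inputs — are ignored).  The
    score of feature j is the mean over checkpoints of the aggregate
    over hidden units of |w_{j,unit}| ("mean_abs", default) or the L2
    norm over units ("l2").
    """
    checkpoints = list(checkpoints)
    if not checkpoints:
        raise ValueError("need at least one checkpoint")
    shapes = {np.asarray(c).shape for c in checkpoints}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent checkpoint shapes: {shapes}")
    per_ckpt = []
    for c in checkpoints:
        w = np.asarray(c, dtype=np.float64)
        if input_dim is not None:
            w = w[:input_dim]
        if aggregate == "mean_abs":
            per_ckpt.append(np.abs(w).mean(axis=1))
        elif aggregate == "l2":
            per_ckpt.append(np.sqrt((w**2).sum(axis=1)))
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
    return np.mean(per_ckpt, axis=0)


def permutation_null(train_fn, X, n_perm: int, seed: int = 0,
                     max_retries: int = 3) -> np.ndarray:
    """Null score matrix from retraining on column-shuffled inputs.

    ``train_fn(X_shuffled, seed)`` must retrain the model under the
    identical configuration and return a score vector of length
    n_features.  One global permutation per run is applied to all
    subjects, so within a run every input position still sees a single
    coherent feature.  Returns an (n_perm, n_features) matrix; a failed
    training run is resampled up to ``max_retries`` times.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=np.float64)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_perm):
        for attempt in range(max_retries + 1):
            perm = rng.permutation(X.shape[1])
            try:
                scores = np.asarray(train_fn(X[:, perm], int(rng.integers(2**31))))
                break
            except Exception:
                if attempt == max_retries:
                    raise
        if scores.shape != (X.shape[1],):
            raise ValueError("train_fn returned a wrong-shaped score vector")
        rows.append(scores)
    return np.asarray(rows)


def p_values(observed, null, policy: str = "paper") -> np.ndarray:
    """Per-feature permutation p-values in percent.

    policy="paper": 100 * #(null > observed) / n_perm (strictly greater;
    can reach exactly 0).  policy="smoothed": the add-one variant
    100 * (#(null > observed) + 1) / (n_perm + 1).
    """
    observed = np.asarray(observed, dtype=np.float64)
    null = np.asarray(null, dtype=np.float64)
    if null.ndim != 2 or null.shape[1] != observed.shape[0]:
        raise ValueError("null must be (n_perm, n_features) matching observed")
    n_perm = null.shape[0]
    greater = (null > observed[None, :]).sum(axis=0)
    if policy == "paper":
        return 100.0 * greater / n_perm
    if policy == "smoothed":
        return 100.0 * (greater + 1) / (n_perm + 1)
    raise ValueError(f"unknown p-value policy {policy!r}")


def fdr_select(p_percent, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up on p-values given in percent.

    Returns the boolean mask of features surviving FDR control at
    level q: with sorted p_(1) <= ... <= p_(m), all features with
    p <= p_(k*) survive, where k* is the largest k with
    p_(k) <= k*q/m.
    """
    p = np.asarray(p_percent, dtype=np.float64) / 100.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 100] percent")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    passing = np.flatnonzero(p[order] <= thresh)
    mask = np.zeros(m, dtype=bool)
    if passing.size:
        k_star = passing[-1]
        mask[order[: k_star + 1]] = True
    return mask


def map_to_roi_pairs(scores, p_percent=None, significant=None,
                     r: int | None = None) -> pd.DataFrame:
    """Edge list (roi_i, roi_j, score[, p_percent, significant]).

    The inverse of the upper-triangle flat-index formula; the vector
    length must equal r(r-1)/2.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if r is None:
        from .features import infer_n_rois

        r = infer_n_rois(scores.size)
    elif scores.size != n_features_for_rois(r):
        raise ValueError(f"vector length {scores.size} inconsistent with r={r}")
    pairs = [index_to_pair(k, r) for k in range(scores.size)]
    df = pd.DataFrame(pairs, columns=["roi_i", "roi_j"])
    df["score"] = scores
    if p_percent is not None:
        df["p_percent"] = np.asarray(p_percent, dtype=np.float64)
    if significant is not None:
        df["significant"] = np.asarray(significant, dtype=bool)
    return df


def write_edge_list(path, df: pd.DataFrame) -> None:
    """Write an edge-list TSV with the ordering formula documented."""
    with open(path, "w") as fh:
        fh.write(
            "# 0-based ROI pairs, row-major upper triangle: "
            "flat index = i*R - i*(i+1)/2 + (j-i-1)\n"
        )
        df.to_csv(fh, sep="\t", index=False)
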