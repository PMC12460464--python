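"""Functional-connectivity feature extraction.

Turns ROI time series into the feature vectors the classifiers consume:
the Pearson correlation matrix between regional time series, vectorized
over the strict upper triangle (FC is non-directional, so the lower
triangle and unit diagonal carry no information).  For a parcellation
with R regions this yields R(R-1)/2 features — 19,900 for a 200-region
atlas.

Upper-triangle ordering is row-major over 0-based pairs (i, j) with
i < j; the flat index of pair (i, j) is ``i*R - i*(i+1)//2 + (j-i-1)``.
This ordering is fixed so that feature-importance scores map back to
ROI pairs unambiguously.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_fc",
    "vectorize_upper",
    "devectorize",
    "fisher_z",
    "inverse_fisher_z",
    "pair_to_index",
    "index_to_pair",
    "n_features_for_rois",
    "read_timeseries",
    "write_timeseries",
]


def n_features_for_rois(r: int) -> int:
    """Number of upper-triangle FC features for ``r`` regions."""
    return r * (r - 1) // 2


def compute_fc(ts: np.ndarray, on_constant: str = "fail") -> np.ndarray:
    """Pearson correlation matrix of a T x R time-series matrix.

    Parameters
    ----------
    ts : array of shape (T, R)
        One subject's regional time series, T time points by R regions.
    on_constant : {"fail", "zero"}
        Policy for constant (zero-variance) columns: raise (default) or
        set that region's off-diagonal correlations to 0 with a warning.

    Returns
    -------
    array of shape (R, R), symmetric with unit diagonal, entries in [-1, 1].
    """
    ts = np.asarray(ts, dtype=np.float64)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D (T x R) matrix")
    t, r = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    sd = ts.std(axis=0)
    constant = sd == 0
    if constant.any():
        bad = np.flatnonzero(constant)
        if on_constant == "fail":
            raise ValueError(f"constant time series in column(s) {bad.tolist()}")
        if on_constant != "zero":
            raise ValueError(f"unknown on_constant policy {on_constant!r}")
        import warnings

        warnings.warn(
            f"constant column(s) {bad.tolist()}: correlations set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        ts = ts.copy()
        ts[:, constant] = np.random.default_rng(0).standard_normal((t, constant.sum()))
        fcm = np.corrcoef(ts, rowvar=False)
        fcm[constant, :] = 0.0
        fcm[:, constant] = 0.0
        np.fill_diagonal(fcm, 1.0)
        return fcm
    fcm = np.corrcoef(ts, rowvar=False)
    fcm = np.clip(fcm, -1.0, 1.0)
    fcm = (fcm + fcm.T) / 2.0
    np.fill_diagonal(fcm, 1.0)
    return fcm


def vectorize_upper(fcm: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Flatten the strict upper triangle of a symmetric FC matrix.

    The inverse is :func:`devectorize`.  Raises on asymmetry beyond
    ``atol``.
    """
    fcm = np.asarray(fcm, dtype=np.float64)
    if fcm.ndim != 2 or fcm.shape[0] != fcm.shape[1]:
        raise ValueError("FC matrix must be square")
    if not np.allclose(fcm, fcm.T, atol=atol):
        raise ValueError("FC matrix is not symmetric within tolerance")
    r = fcm.shape[0]
    iu = np.triu_indices(r, k=1)
    return fcm[iu]


def devectorize(vec: np.ndarray, r: int | None = None) -> np.ndarray:
    """Rebuild a symmetric unit-diagonal matrix from an upper-triangle vector."""
    vec = np.asarray(vec, dtype=np.float64)
    if r is None:
        r = infer_n_rois(len(vec))
    if len(vec) != n_features_for_rois(r):
        raise ValueError(f"vector length {len(vec)} inconsistent with r={r}")
    out = np.eye(r)
    iu = np.triu_indices(r, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


def infer_n_rois(n_features: int) -> int:
    """Region count r with r(r-1)/2 == n_features, or raise."""
    r = int(round((1 + np.sqrt(1 + 8 * n_features)) / 2))
    if n_features_for_rois(r) != n_features:
        raise ValueError(f"{n_features} is not r(r-1)/2 for any integer r")
    return r


def pair_to_index(i: int, j: int, r: int) -> int:
    """Flat feature index of ROI pair (i, j), 0-based, i < j."""
    if not (0 <= i < j < r):
        raise ValueError(f"need 0 <= i < j < r, got ({i}, {j}) with r={r}")
    return i * r - i * (i + 1) // 2 + (j - i - 1)


def index_to_pair(idx: int, r: int) -> tuple[int, int]:
    """ROI pair (i, j) of a flat feature index; inverse of pair_to_index."""
    if not 0 <= idx < n_features_for_rois(r):
        raise ValueError(f"index {idx} out of range for r={r}")
    i = 0
    while idx >= r - i - 1:
        idx -= r - i - 1
        i += 1
    return i, i + 1 + idx


def fisher_z(r):
    """Fisher z-transform arctanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    return np.arctanh(r)


def inverse_fisher_z(z):
    """Inverse Fisher transform tanh(z); maps the real line into (-1, 1)."""
    return np.tanh(np.asarray(z, dtype=np.float64))


def read_timeseries(path) -> tuple[np.ndarray, list[str] | None]:
    """Read a T x R time-series TSV; returns (values, roi_labels or None).

    A header row of ROI labels is detected by non-numeric first line.
    """
    with open(path) as fh:
        first = fh.readline()
    tokens = first.rstrip("\n").split("\t")
    try:
        [float(t) for t in tokens]
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(path, sep="\t", header=header)
    labels = [str(c) for c in df.columns] if header == 0 else None
    return df.to_numpy(dtype=np.float64), labels


def write_timeseries(path, values: np.ndarray, roi_labels=None) -> None:
    df = pd.DataFrame(np.asarray(values, dtype=np.float64), columns=roi_labels)
    df.to_csv(path, sep="\t", index=False, header=roi_labels is not None)
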