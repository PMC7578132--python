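"""Simplex geometry for concentration data.

Concentration tables are compositional: each row carries relative, not
absolute, information, because the parts of a whole are constrained to a
constant sum once expressed in a common unit.  All downstream statistics in
this package are therefore built from log-ratios, which are invariant to the
closure operation.  This module provides the closure operator (mapping raw
amounts onto the simplex), subcompositions, the Aitchison distance, the
variation matrix of pairwise log-ratio variances, the induced-covariance
identity that makes raw covariances on closed data uninterpretable, and
multiplicative replacement of below-detection-limit values (log-ratios need
strictly positive data).

Natural logarithms and the sample (n-1) variance convention are used
throughout.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "closure",
    "subcomposition",
    "aitchison_distance",
    "aitchison_distance_matrix",
    "variation_matrix",
    "closure_covariance_residual",
    "replace_below_detection",
    "ClosureTransformer",
    "DEFAULT_K",
    "CLOSURE_RTOL",
    "ZeroReplacementError",
    "AlignmentError",
    "InsufficientDataError",
]

#: Closure constant for mg/kg data: parts per 10^6.
DEFAULT_K = 1e6

#: Relative tolerance for "rows sum to k" checks (double-precision round-trip).
CLOSURE_RTOL = 1e-9


class ZeroReplacementError(ValueError):
    """Nonpositive values reached a log-ratio operation.

    Raised with a pointer to :func:`replace_below_detection`, which is the
    supported way of making censored data strictly positive.
    """


class AlignmentError(ValueError):
    """Two objects that must share labels or shape do not."""


class InsufficientDataError(ValueError):
    """Fewer samples than the statistic requires."""


def _as_positive_1d(z, name: str = "z") -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if not np.all(np.isfinite(z)):
        raise ValueError(f"{name} contains non-finite values")
    if np.any(z <= 0):
        raise ZeroReplacementError(
            f"{name} contains nonpositive entries; log-ratio methods need "
            "strictly positive data — run replace_below_detection first"
        )
    return z


def closure(z, k: float = DEFAULT_K):
    """Close a vector of amounts to constant sum *k*.

    Parameters
    ----------
    z : array-like or pandas.Series
        Strictly positive component amounts (e.g. mg/kg), length >= 2.
    k : float
        Closure constant; ``1e6`` for mg/kg expressed as parts per million
        of the measured total.

    Returns
    -------
    Same type as the input, with parts ``k * z_i / sum(z)``.

    Notes
    -----
    Closure preserves every ratio ``z_i / z_j`` exactly, is idempotent and is
    invariant to rescaling of ``z`` — the defining properties of compositional
    equivalence classes.
    """
    if k <= 0:
        raise ValueError("closure constant k must be positive")
    labels = z.index if isinstance(z, pd.Series) else None
    arr = _as_positive_1d(z)
    if arr.size < 2:
        raise ValueError("a composition needs at least 2 parts")
    parts = k * arr / arr.sum()
    if labels is not None:
        return pd.Series(parts, index=labels)
    return parts


def closure_matrix(Z, k: float = DEFAULT_K):
    """Row-wise closure of a samples x elements matrix (DataFrame-aware)."""
    if isinstance(Z, pd.DataFrame):
        vals = Z.to_numpy(dtype=float)
        closed = _closure_rows(vals, k)
        return pd.DataFrame(closed, index=Z.index, columns=Z.columns)
    return _closure_rows(np.asarray(Z, dtype=float), k)


def _closure_rows(vals: np.ndarray, k: float) -> np.ndarray:
    if vals.ndim != 2:
        raise ValueError("expected a 2-D samples x elements matrix")
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise ZeroReplacementError(
            "matrix contains nonpositive or non-finite entries; run "
            "replace_below_detection first"
        )
    return k * vals / vals.sum(axis=1, keepdims=True)


def is_closed(X, k: float = DEFAULT_K, rtol: float = CLOSURE_RTOL) -> bool:
    """True if every row of *X* sums to *k* within relative tolerance."""
    vals = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    sums = vals.sum(axis=-1)
    return bool(np.allclose(sums, k, rtol=rtol, atol=0.0))


def subcomposition(x: pd.Series, keep: Sequence[str], k: float | None = None) -> pd.Series:
    """Closure of a subset of parts, preserving within-subset ratios.

    Parameters
    ----------
    x : pandas.Series
        A composition (or raw amounts) indexed by part labels.
    keep : sequence of labels
        At least two distinct labels of ``x`` to retain.
    k : float, optional
        Closure constant of the result; defaults to ``sum(x)`` so a closed
        input keeps its constant.
    """
    keep = list(keep)
    if len(set(keep)) != len(keep):
        raise ValueError("keep labels must be distinct")
    if len(keep) < 2:
        raise ValueError("a subcomposition needs at least 2 parts")
    missing = [lbl for lbl in keep if lbl not in x.index]
    if missing:
        raise KeyError(f"unknown part labels: {missing}")
    if k is None:
        k = float(np.asarray(x, dtype=float).sum())
    return closure(x.loc[keep], k=k)


def aitchison_distance(x, y) -> float:
    """Aitchison distance between two compositions.

    ``d_A(x, y) = sqrt( sum_i ( ln(x_i/g(x)) - ln(y_i/g(y)) )^2 )`` with
    ``g`` the geometric mean — the Euclidean distance between centred
    log-ratio representations, and the natural metric on the simplex.  It is
    zero iff the two vectors are proportional and does not depend on whether
    the inputs are closed.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if list(x.index) != list(y.index):
            raise AlignmentError("compositions do not share part labels")
    xa = _as_positive_1d(x, "x")
    ya = _as_positive_1d(y, "y")
    if xa.shape != ya.shape:
        raise AlignmentError("compositions differ in length")
    lx = np.log(xa)
    ly = np.log(ya)
    diff = (lx - lx.mean()) - (ly - ly.mean())
    return float(np.sqrt(np.sum(diff**2)))


def aitchison_distance_matrix(X) -> pd.DataFrame | np.ndarray:
    """All pairwise Aitchison distances between the rows of *X*."""
    labels = X.index if isinstance(X, pd.DataFrame) else None
    vals = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if np.any(vals <= 0):
        raise ZeroReplacementError(
            "matrix contains nonpositive entries; run replace_below_detection first"
        )
    clr = np.log(vals)
    clr -= clr.mean(axis=1, keepdims=True)
    sq = np.sum(clr**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * clr @ clr.T
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.maximum(d2, 0.0))
    if labels is not None:
        return pd.DataFrame(d, index=labels, columns=labels)
    return d


def variation_matrix(X) -> pd.DataFrame | np.ndarray:
    """Variation matrix T: ``t_jl = var(ln(x_j / x_l))`` over samples.

    Small ``t_jl`` means the two parts are nearly proportional across
    samples (positive covariability); large values indicate opposing trends.
    Sample variance (n-1 divisor).  The result is identical for raw and
    closed data, since per-sample scale cancels in the ratio.
    """
    labels = X.columns if isinstance(X, pd.DataFrame) else None
    vals = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if vals.ndim != 2:
        raise ValueError("expected a samples x elements matrix")
    if vals.shape[0] < 3:
        raise InsufficientDataError("variation matrix needs at least 3 samples")
    if np.any(vals <= 0):
        raise ZeroReplacementError(
            "matrix contains nonpositive entries; run replace_below_detection first"
        )
    logs = np.log(vals)
    # var(ln x_j - ln x_l) = var_j + var_l - 2 cov_jl, computed in one pass
    cov = np.cov(logs, rowvar=False, ddof=1)
    var = np.diag(cov)
    t = var[:, None] + var[None, :] - 2.0 * cov
    t = np.maximum((t + t.T) / 2.0, 0.0)
    np.fill_diagonal(t, 0.0)
    if labels is not None:
        return pd.DataFrame(t, index=labels, columns=labels)
    return t


def closure_covariance_residual(X, j, k: float = DEFAULT_K) -> float:
    """Sum of covariances of part *j* with every part (itself included).

    On closed data the row sums are constant, so
    ``sum_l cov(x_j, x_l) = 0`` identically — equivalently the covariances
    of a part with the others are forced to sum to minus its own variance.
    This is the algebraic reason raw covariances (and Pearson correlations)
    of closed data carry spurious structure.

    Raises a precondition error when the input rows do not sum to *k*.
    """
    labels = X.columns if isinstance(X, pd.DataFrame) else None
    vals = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if vals.shape[0] < 3:
        raise InsufficientDataError("covariance needs at least 3 samples")
    if not is_closed(vals, k=k):
        raise ValueError(
            f"input is not closed to k={k!r}; apply closure() first"
        )
    if labels is not None:
        j = labels.get_loc(j) if not isinstance(j, (int, np.integer)) else int(j)
    cov = np.cov(vals, rowvar=False, ddof=1)
    return float(cov[j, :].sum())


def replace_below_detection(
    Z: pd.DataFrame,
    detection_limits: pd.Series | None = None,
    fraction: float = 0.65,
    nondetect: pd.DataFrame | None = None,
):
    """Multiplicative replacement of censored (below-detection) values.

    Each flagged cell is replaced by ``fraction * detection_limit`` for its
    element; detected values are untouched.  Returns the positive matrix and
    a replacement log (DataFrame with sample, element, substituted value).

    Parameters
    ----------
    Z : DataFrame
        Raw concentrations; censored cells are NaN (or flagged via
        ``nondetect``).
    detection_limits : Series indexed by element
        Per-element detection limits; required if any cell is censored.
    fraction : float in (0, 1)
        Fraction of the detection limit substituted (default 0.65).
    nondetect : boolean DataFrame, optional
        Explicit censoring mask; defaults to ``Z.isna()``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    mask = Z.isna() if nondetect is None else nondetect.astype(bool)
    if not mask.to_numpy().any():
        bad = Z.to_numpy(dtype=float) <= 0
        if bad.any():
            raise ZeroReplacementError(
                "nonpositive detected values present but not flagged as "
                "nondetects; flag them or supply a nondetect mask"
            )
        return Z.copy(), pd.DataFrame(columns=["sample_id", "element", "replacement"])
    if detection_limits is None:
        raise ZeroReplacementError(
            "censored values present but no detection limits supplied"
        )
    records = []
    out = Z.copy().astype(float)
    for element in Z.columns:
        col_mask = mask[element]
        if not col_mask.any():
            continue
        if col_mask.all():
            raise ZeroReplacementError(
                f"element {element!r} is censored in every sample; the column "
                "carries no information and cannot be replaced"
            )
        if element not in detection_limits.index or not np.isfinite(
            detection_limits[element]
        ):
            raise ZeroReplacementError(
                f"nondetects in element {element!r} but no detection limit given"
            )
        value = fraction * float(detection_limits[element])
        out.loc[col_mask, element] = value
        records.extend(
            {"sample_id": idx, "element": element, "replacement": value}
            for idx in Z.index[col_mask]
        )
    log = pd.DataFrame.from_records(
        records, columns=["sample_id", "element", "replacement"]
    )
    return out, log


class ClosureTransformer(TransformerMixin, BaseEstimator):
    """Row-wise closure as a scikit-learn transformer.

    Maps raw amounts (samples x elements, strictly positive) onto the
    simplex of constant row sum ``k``; stateless apart from recording the
    input dimensionality, so it composes with pipelines and grid search.

    Parameters
    ----------
    k : float, default 1e6
        Closure constant (parts per million for mg/kg input).
    """

    def __init__(self, k: float = DEFAULT_K):
        self.k = k

    def fit(self, X, y=None):
        vals = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        if vals.ndim != 2:
            raise ValueError("expected a 2-D samples x elements matrix")
        if self.k <= 0:
            raise ValueError("closure constant k must be positive")
        self.n_features_in_ = vals.shape[1]
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X):
        if not hasattr(self, "n_features_in_"):
            self.fit(X)
        return closure_matrix(X, k=self.k)
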