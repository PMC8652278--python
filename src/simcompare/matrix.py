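"""Labelled (dis)similarity matrices and the feature-matrix preprocessing that feeds them.

Feature data are held as :class:`pandas.DataFrame` objects with subjects on the
index and features on the columns.  Similarity matrices get a thin wrapper,
:class:`SimilarityMatrix`, that carries the subject labels, whether the matrix
is a similarity or a dissimilarity, and how the diagonal has been treated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SimilarityMatrix",
    "euclidean_dissimilarity",
    "covariance_similarity",
    "standardize_features",
    "remove_diagonal",
]

#: relative tolerance for the symmetry check on construction
SYMMETRY_RTOL = 1e-10


def _check_labels(labels: list[str]) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"subject labels are not unique: {dupes}")
    return labels


@dataclass
class SimilarityMatrix:
    """A labelled d x d symmetric non-negative matrix over a set of subjects.

    Parameters
    ----------
    values
        Square array of pairwise (dis)similarities.
    labels
        Unique subject identifiers, one per row/column.
    kind
        ``"similarity"`` (close pairs have large entries) or
        ``"dissimilarity"`` (close pairs have small entries, e.g. distances).
    diagonal_policy
        ``"raw"`` for untouched input, ``"next_extreme"`` after
        :func:`remove_diagonal`, ``"fitted"`` when a diagonal model supplied it.
    """

    values: np.ndarray
    labels: list[str]
    kind: Literal["similarity", "dissimilarity"] = "dissimilarity"
    diagonal_policy: Literal["raw", "next_extreme", "fitted"] = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = _check_labels(list(self.labels))
        d = len(self.labels)
        if self.values.shape != (d, d):
            raise ValueError(
                f"matrix is not square with one row per subject: shape "
                f"{self.values.shape} for {d} labels"
            )
        if d < 2:
            raise ValueError("at least two subjects are required")
        if self.kind not in ("similarity", "dissimilarity"):
            raise ValueError(f"unknown kind {self.kind!r}")
        scale = max(1.0, float(np.max(np.abs(self.values))))
        asym = float(np.max(np.abs(self.values - self.values.T)))
        if asym > SYMMETRY_RTOL * scale:
            raise ValueError(
                f"matrix is not symmetric (max asymmetry {asym:.3g} "
                f"exceeds relative tolerance {SYMMETRY_RTOL})"
            )
        if self.values.min() < 0 and not self.metadata.get("allow_negative", False):
            raise ValueError(
                "matrix has negative entries; pass allow_negative metadata to "
                "accept them"
            )

    # -- conveniences -------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        kind: str = "dissimilarity",
        **kwargs,
    ) -> "SimilarityMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValueError("row and column labels of a square matrix must agree")
        return cls(frame.to_numpy(dtype=float), list(frame.index), kind=kind, **kwargs)

    def reordered(self, labels: list[str]) -> "SimilarityMatrix":
        """Return a copy with subjects permuted into the given label order."""
        if set(labels) != set(self.labels):
            missing = sorted(set(labels) - set(self.labels))
            extra = sorted(set(self.labels) - set(labels))
            raise ValueError(
                f"label sets differ: missing {missing}, unexpected {extra}"
            )
        idx = [self.labels.index(l) for l in labels]
        return SimilarityMatrix(
            self.values[np.ix_(idx, idx)],
            list(labels),
            kind=self.kind,
            diagonal_policy=self.diagonal_policy,
            metadata=dict(self.metadata),
        )


def _require_complete(data: pd.DataFrame) -> np.ndarray:
    x = data.to_numpy(dtype=float)
    bad = np.isnan(x).any(axis=1)
    if bad.any():
        names = [str(s) for s in data.index[bad]]
        raise ValueError(
            "feature matrix has missing values for subjects: "
            + ", ".join(names[:10])
            + ("..." if len(names) > 10 else "")
        )
    return x


def euclidean_dissimilarity(data: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise Euclidean distances between subject rows of a feature matrix."""
    x = _require_complete(data)
    values = squareform(pdist(x, metric="euclidean"))
    return SimilarityMatrix(values, list(data.index), kind="dissimilarity")


def covariance_similarity(
    data: pd.DataFrame,
    center: bool = False,
    allow_negative: bool = False,
) -> SimilarityMatrix:
    """Subject-by-subject covariance-style similarity.

    Entry (i, j) is ``(1/L) * sum_l (x_il - c_i)(x_jl - c_j)`` with ``c`` the
    per-subject mean when ``center`` is set and zero otherwise.  Centring is
    off by default: a difference in subject means is usually part of the
    signal being compared, so removing it is an explicit modelling decision.
    Negative entries violate the non-negativity required of a (dis)similarity
    and are rejected unless ``allow_negative`` is set (recorded in metadata).
    """
    x = _require_complete(data)
    if x.shape[1] < 2:
        raise ValueError("covariance similarity needs at least two features")
    if center:
        x = x - x.mean(axis=1, keepdims=True)
    values = (x @ x.T) / x.shape[1]
    values = (values + values.T) / 2.0
    return SimilarityMatrix(
        values,
        list(data.index),
        kind="similarity",
        metadata={"allow_negative": bool(allow_negative), "centered": bool(center)},
    )


def standardize_features(
    data: pd.DataFrame,
    max_missing_frac: float = 0.4,
    cap_sd: float = 10.0,
    impute: bool = True,
) -> pd.DataFrame:
    """Drop high-missingness features, scale to unit variance, cap outliers, impute.

    Features with a missing fraction at or above ``max_missing_frac`` are
    removed.  The remaining features are scaled to unit standard deviation
    (without centring, which is a separate decision), values further than
    ``cap_sd`` standard deviations from the feature mean are clamped, and
    missing values are replaced by the feature mean (computed before capping).
    Constant features cannot be scaled and are dropped as well.
    """
    frac = data.isna().mean(axis=0)
    kept = data.loc[:, frac < max_missing_frac]
    x = kept.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0)
    nonconst = sd > 0
    kept = kept.loc[:, nonconst]
    if kept.shape[1] == 0:
        raise ValueError(
            "no features remain after the missingness/variance filters"
        )
    x, mean, sd = x[:, nonconst], mean[nonconst], sd[nonconst]
    if impute:
        x = np.where(np.isnan(x), mean, x)
    x = x / sd
    mean_std = mean / sd
    x = np.clip(x, mean_std - cap_sd, mean_std + cap_sd)
    return pd.DataFrame(x, index=kept.index, columns=kept.columns)


def remove_diagonal(y: SimilarityMatrix) -> SimilarityMatrix:
    """Replace each self-(dis)similarity by the row's next most extreme value.

    A subject's raw self-similarity typically carries excess similarity unique
    to that subject.  For a similarity each diagonal entry becomes the largest
    off-diagonal entry of its row; for a dissimilarity, the smallest.  The
    result is re-symmetrised by averaging with its transpose; off-diagonal
    entries are never changed.
    """
    v = y.values.copy()
    d = v.shape[0]
    off = v.copy()
    np.fill_diagonal(off, np.nan)
    if y.kind == "similarity":
        extreme = np.nanmax(off, axis=1)
    else:
        extreme = np.nanmin(off, axis=1)
    np.fill_diagonal(v, extreme)
    v = (v + v.T) / 2.0
    return SimilarityMatrix(
        v,
        list(y.labels),
        kind=y.kind,
        diagonal_policy="next_extreme",
        metadata=dict(y.metadata),
    )
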