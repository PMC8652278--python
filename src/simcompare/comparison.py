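"""Predicting a target matrix from a reference structure and summarising residuals.

The comparison keeps the reference structure A_k at every complexity k and
refits only the relationship, X2^(k) = A_k+ Y2 (A_k+)^T, so differences in
overall scale or in the strength of relationships are absorbed while genuine
structural differences are not.  What remains is the residual matrix
R2^(k) = Y2 - A_k X2^(k) A_k^T and its row sums of squares, the *residual
persistence* P_ik: subjects whose persistence stays high across many k carry
structure in the target that the reference does not explain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import SimilarityMatrix
from .model import StructureScan, fit_relationship

__all__ = [
    "ComparisonResults",
    "predict_target",
    "persistence_matrix",
    "excess_persistence",
    "group_residual_summary",
]


@dataclass
class ComparisonResults:
    """Residuals and persistences of a target predicted from a reference scan."""

    scan: StructureScan
    y2: np.ndarray
    labels: list[str]
    k_values: list[int]
    X2: dict[int, np.ndarray]
    persistence: pd.DataFrame  # d x k_max, columns are complexities
    total_loss: np.ndarray
    D2: dict[int, np.ndarray] | None = None
    _residuals: dict[int, np.ndarray] | None = None
    info: dict = field(default_factory=dict)

    @property
    def k_max(self) -> int:
        return max(self.k_values)

    def residual(self, k: int) -> np.ndarray:
        """The residual matrix R2^(k) (recomputed if not stored)."""
        if self._residuals is not None and k in self._residuals:
            return self._residuals[k]
        a = self.scan.A[k]
        r = self.y2 - a @ self.X2[k] @ a.T
        if self.D2 is not None:
            r = r - np.diag(self.D2[k])
        return r

    def excess_persistence(self, group) -> pd.Series:
        return excess_persistence(self.persistence, group)

    def group_residual_summary(self, partition) -> dict[int, pd.DataFrame]:
        return group_residual_summary(self, partition)

    def plot_persistence(self, path=None, pvalues=None, alpha: float = 0.05, **kw):
        from .plotting import render_persistence_chart

        return render_persistence_chart(
            self.persistence, pvals=pvalues, alpha=alpha, path=path, **kw
        )

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "total_loss": self.total_loss,
                "reference_loss": self.scan.fit_loss,
            }
        ).set_index("k")

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.persistence.to_csv(directory / "persistence.csv")
        self.summary().to_csv(directory / "total_loss.csv")
        manifest = {
            "labels": self.labels,
            "k_values": self.k_values,
            "method": self.scan.method,
            "diagonal_model": self.D2 is not None,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return directory


def _refit_diagonal(a, y2, svd: bool, tol=1e-10, max_outer=50):
    """Alternate the target relationship and a free target diagonal."""
    d = y2.shape[0]
    dvec = np.zeros(d)
    ap = a.T if svd else np.linalg.pinv(a)
    prev = np.inf
    for _ in range(max_outer):
        x2 = ap @ (y2 - np.diag(dvec)) @ ap.T
        approx = a @ x2 @ a.T
        dvec = np.diag(y2 - approx).copy()
        loss = float(np.linalg.norm(y2 - approx - np.diag(dvec), "fro"))
        if abs(prev - loss) <= tol * max(prev, 1e-300):
            break
        prev = loss
    return x2, dvec


def predict_target(
    scan: StructureScan, y2, store_residuals: bool = True
) -> ComparisonResults:
    """Predict a target matrix at every complexity of a reference scan.

    The target is reordered to the scan's subject labels when needed; a
    disjoint label set is rejected.  For orthonormal (svd) structures the
    relationship refit reduces to ``X2 = A^T Y2 A``; otherwise the
    pseudo-inverse form is used.  If the scan carries a diagonal model, a
    target diagonal is refit the same way and persistence is computed on the
    off-diagonal residuals which are all the model is asked to explain.

    Set ``store_residuals=False`` to avoid holding all d x d residual
    matrices in memory (they can be recomputed per k on demand).
    """
    if isinstance(y2, pd.DataFrame):
        y2 = SimilarityMatrix.from_frame(y2)
    if isinstance(y2, SimilarityMatrix):
        y2 = y2.reordered(scan.labels)
        y2v = y2.values
    else:
        y2v = np.asarray(y2, dtype=float)
        if y2v.shape != (scan.n_subjects, scan.n_subjects):
            raise ValueError(
                f"target shape {y2v.shape} does not match the scan "
                f"({scan.n_subjects} subjects)"
            )
    if np.max(np.abs(y2v - y2v.T)) > 1e-8 * max(1.0, np.max(np.abs(y2v))):
        warnings.warn(
            "target matrix is asymmetric beyond tolerance; residuals are "
            "reported as computed",
            RuntimeWarning,
            stacklevel=2,
        )

    with_diag = scan.diagonal is not None
    X2, D2 = {}, ({} if with_diag else None)
    residuals = {} if store_residuals else None
    pers = np.empty((scan.n_subjects, len(scan.k_values)))
    total = np.empty(len(scan.k_values))
    for j, k in enumerate(scan.k_values):
        a = scan.A[k]
        if with_diag:
            x2, dvec = _refit_diagonal(a, y2v, svd=scan.method == "svd")
            D2[k] = dvec
            r = y2v - a @ x2 @ a.T - np.diag(dvec)
            r_for_p = r.copy()
            np.fill_diagonal(r_for_p, 0.0)
        else:
            if scan.method == "svd":
                x2 = a.T @ y2v @ a
            else:
                x2 = fit_relationship(a, y2v)
            r = y2v - a @ x2 @ a.T
            r_for_p = r
        X2[k] = x2
        if store_residuals:
            residuals[k] = r
        pers[:, j] = (r_for_p**2).sum(axis=1)
        total[j] = np.sqrt(pers[:, j].sum())
    return ComparisonResults(
        scan=scan,
        y2=y2v,
        labels=list(scan.labels),
        k_values=list(scan.k_values),
        X2=X2,
        persistence=pd.DataFrame(pers, index=scan.labels, columns=scan.k_values),
        total_loss=total,
        D2=D2,
        _residuals=residuals,
    )


def persistence_matrix(c: ComparisonResults) -> pd.DataFrame:
    """The d x k_max residual persistence matrix P, P_ik = sum_j R2^(k)_ij^2."""
    return c.persistence


def excess_persistence(P: pd.DataFrame, group) -> pd.Series:
    """Mean persistence of a subject group minus the mean over its complement.

    Positive values at a complexity k mean the group is systematically worse
    predicted than the remaining subjects at that k.
    """
    group = [str(g) for g in group]
    labels = [str(l) for l in P.index]
    unknown = sorted(set(group) - set(labels))
    if unknown:
        raise ValueError(f"group members not among subjects: {unknown}")
    if len(group) == 0:
        raise ValueError("group is empty")
    if len(set(group)) == len(labels):
        raise ValueError("group must be a proper subset of the subjects")
    mask = np.array([l in set(group) for l in labels])
    return P.loc[mask].mean(axis=0) - P.loc[~mask].mean(axis=0)


def group_residual_summary(
    c: ComparisonResults, partition: dict[str, list[str]]
) -> dict[int, pd.DataFrame]:
    """Per-complexity sums of squared residuals between subject groups.

    ``partition`` maps group names to disjoint label lists covering all
    subjects.  Entry (g, h) of the returned frame at complexity k is
    ``sum_{i in g, j in h} R2^(k)_ij^2``.
    """
    labels = list(c.labels)
    seen: set[str] = set()
    for name, members in partition.items():
        members = [str(m) for m in members]
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"groups overlap on subjects: {sorted(overlap)}")
        seen |= set(members)
    missing = set(labels) - seen
    if missing:
        raise ValueError(f"partition does not cover subjects: {sorted(missing)}")
    names = list(partition)
    idx = {
        name: [labels.index(str(m)) for m in members]
        for name, members in partition.items()
    }
    out = {}
    for k in c.k_values:
        r2 = c.residual(k) ** 2
        mat = np.array(
            [[r2[np.ix_(idx[g], idx[h])].sum() for h in names] for g in names]
        )
        out[k] = pd.DataFrame(mat, index=names, columns=names)
    return out
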