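"""Learning Structure and Relationship from a reference (dis)similarity matrix.

A d x d matrix Y is approximated at every complexity k by the quadratic
low-rank model

    Y ~ A_k X^(k) A_k^T,

where the *structure* A_k is d x k and the *relationship* X^(k) is k x k.
Two solvers are provided:

* ``svd`` -- the unconstrained optimum.  For symmetric Y this is computed by
  a symmetric eigendecomposition sorted by absolute eigenvalue, which is the
  SVD up to signs; by the Eckart-Young theorem the fit loss at complexity k
  is the root sum of squares of the discarded singular values.
* ``mixture`` -- rows of A are constrained to the probability simplex, so the
  columns act as latent clusters and row i gives subject i's mixture over
  them.  The solver alternates a multiplicative update of A (Lee-Seung style,
  adapted to the quadratic form) with an exact least-squares solve for X,
  renormalising the rows of A at every iteration.

The statsmodels-style entry point is :class:`StructuralModel`, whose ``fit``
returns a :class:`StructureScan` results object; ``StructureScan.predict``
performs the structural comparison against a target matrix (see
``simcompare.comparison``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import SimilarityMatrix

__all__ = [
    "StructuralModel",
    "StructureScan",
    "MixtureFit",
    "fit_relationship",
    "svd_scan",
    "mixture_fit",
    "mixture_scan",
    "diagonal_model_fit",
]

#: floor added to denominators of multiplicative updates
_MU_EPS = 1e-12


def _as_values(y) -> np.ndarray:
    if isinstance(y, SimilarityMatrix):
        return y.values
    return np.asarray(y, dtype=float)


def _labels_of(y, d: int) -> list[str]:
    if isinstance(y, SimilarityMatrix):
        return list(y.labels)
    return [f"s{i}" for i in range(d)]


def _rank_tolerance(a: np.ndarray) -> float:
    sv = np.linalg.svd(a, compute_uv=False)
    return max(a.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)


def fit_relationship(a: np.ndarray, y) -> np.ndarray:
    """Least-squares relationship X minimising ||Y - A X A^T||_F.

    For full column rank A the optimum is X = A+ Y (A+)^T with A+ the
    Moore-Penrose pseudo-inverse, equivalently A X A^T = P_A Y P_A with P_A
    the orthogonal projector onto the column space of A.  Rank-deficient A is
    handled by a tolerance-thresholded pseudo-inverse, with a warning.
    """
    a = np.asarray(a, dtype=float)
    yv = _as_values(y)
    if np.linalg.matrix_rank(a, tol=_rank_tolerance(a)) < a.shape[1]:
        warnings.warn(
            "structure matrix is rank deficient; relationship computed via a "
            "tolerance-thresholded pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
    ap = np.linalg.pinv(a)
    return ap @ yv @ ap.T


# ---------------------------------------------------------------------------
# results container


@dataclass
class StructureScan:
    """Per-complexity structures, relationships and fit losses for a reference.

    Attributes
    ----------
    method
        ``"svd"`` or ``"mixture"``.
    k_values
        Ascending complexities scanned.
    A, X
        Mappings ``k -> structure`` (d x k) and ``k -> relationship`` (k x k).
    fit_loss
        Frobenius norm of ``Y1 - A_k X^(k) A_k^T`` per k.
    diagonal
        Optional mapping ``k -> length-d diagonal vector`` when the
        self-similarity diagonal was modelled explicitly.
    eigenvalues
        Eigenvalues of the reference (svd method only), descending by
        absolute value; useful for eigengap diagnostics.
    """

    method: str
    labels: list[str]
    k_values: list[int]
    A: dict[int, np.ndarray]
    X: dict[int, np.ndarray]
    fit_loss: np.ndarray
    y1: np.ndarray
    kind: str = "dissimilarity"
    diagonal: dict[int, np.ndarray] | None = None
    eigenvalues: np.ndarray | None = None
    info: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.labels)

    @property
    def k_max(self) -> int:
        return max(self.k_values)

    def predict(self, y2, store_residuals: bool = True):
        """Structural comparison: predict a target matrix with this structure."""
        from .comparison import predict_target

        return predict_target(self, y2, store_residuals=store_residuals)

    def summary(self) -> pd.DataFrame:
        """Per-complexity fit summary table."""
        rows = {"k": self.k_values, "fit_loss": self.fit_loss}
        if self.method == "svd" and self.eigenvalues is not None:
            lam = self.eigenvalues
            rows["eigenvalue"] = [lam[k - 1] for k in self.k_values]
            rows["eigengap"] = [
                lam[k - 1] - lam[k] if k < lam.size else np.nan
                for k in self.k_values
            ]
        if self.info.get("statuses"):
            rows["status"] = [
                self.info["statuses"].get(k, "") for k in self.k_values
            ]
        return pd.DataFrame(rows).set_index("k")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"StructureScan(method={self.method}, d={self.n_subjects}, "
            f"k={self.k_values[0]}..{self.k_max})"
        )

    # -- serialization ------------------------------------------------------
    def save(self, directory) -> Path:
        """Write the scan as one CSV per k for A and X plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for k in self.k_values:
            pd.DataFrame(self.A[k], index=self.labels).to_csv(
                directory / f"A_{k}.csv"
            )
            pd.DataFrame(self.X[k]).to_csv(directory / f"X_{k}.csv", index=False)
            if self.diagonal is not None:
                pd.DataFrame(
                    {"diagonal": self.diagonal[k]}, index=self.labels
                ).to_csv(directory / f"D_{k}.csv")
        pd.DataFrame(self.y1, index=self.labels, columns=self.labels).to_csv(
            directory / "reference.csv"
        )
        manifest = {
            "method": self.method,
            "kind": self.kind,
            "labels": self.labels,
            "k_values": self.k_values,
            "fit_loss": [float(x) for x in self.fit_loss],
            "has_diagonal": self.diagonal is not None,
            "eigenvalues": None
            if self.eigenvalues is None
            else [float(x) for x in self.eigenvalues],
            "info": {
                key: val
                for key, val in self.info.items()
                if isinstance(val, (int, float, str, bool, list, dict))
            },
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return directory

    @classmethod
    def load(cls, directory) -> "StructureScan":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        labels = [str(x) for x in manifest["labels"]]
        k_values = [int(k) for k in manifest["k_values"]]
        A = {
            k: pd.read_csv(directory / f"A_{k}.csv", index_col=0).to_numpy()
            for k in k_values
        }
        X = {
            k: pd.read_csv(directory / f"X_{k}.csv").to_numpy() for k in k_values
        }
        diagonal = None
        if manifest.get("has_diagonal"):
            diagonal = {
                k: pd.read_csv(directory / f"D_{k}.csv", index_col=0)[
                    "diagonal"
                ].to_numpy()
                for k in k_values
            }
        y1 = pd.read_csv(directory / "reference.csv", index_col=0).to_numpy()
        eig = manifest.get("eigenvalues")
        return cls(
            method=manifest["method"],
            labels=labels,
            k_values=k_values,
            A=A,
            X=X,
            fit_loss=np.asarray(manifest["fit_loss"], dtype=float),
            y1=y1,
            kind=manifest.get("kind", "dissimilarity"),
            diagonal=diagonal,
            eigenvalues=None if eig is None else np.asarray(eig, dtype=float),
            info=manifest.get("info", {}),
        )


# ---------------------------------------------------------------------------
# SVD solver


def _sym_eig_sorted(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition sorted by |eigenvalue| descending with fixed signs.

    For a symmetric matrix this coincides with the SVD (singular values are
    the |eigenvalues|).  Each eigenvector's largest-magnitude entry is made
    positive so that the output is deterministic; equal-magnitude eigenvalues
    keep their original (stable) order.
    """
    y = (y + y.T) / 2.0
    lam, vec = np.linalg.eigh(y)
    order = np.argsort(-np.abs(lam), kind="stable")
    lam, vec = lam[order], vec[:, order]
    flip = vec[np.argmax(np.abs(vec), axis=0), np.arange(vec.shape[1])] < 0
    vec[:, flip] *= -1.0
    return lam, vec


def svd_scan(y1, k_max: int | None = None) -> StructureScan:
    """Unconstrained structure scan by truncated spectral decomposition.

    ``A_k`` holds the first k eigenvectors (|eigenvalue| order) and ``X^(k)``
    the corresponding diagonal eigenvalue block, so that ``A_k X^(k) A_k^T``
    is the best rank-k approximation of Y1 in Frobenius norm and the fit loss
    at k is ``sqrt(sum_{j>k} sigma_j^2)``.
    """
    yv = _as_values(y1)
    d = yv.shape[0]
    if k_max is None:
        k_max = d
    if not 1 <= k_max <= d:
        raise ValueError(f"k_max must be in [1, {d}], got {k_max}")
    lam, vec = _sym_eig_sorted(yv)
    tail = np.sqrt(np.concatenate([np.cumsum((lam**2)[::-1])[::-1][1:], [0.0]]))
    k_values = list(range(1, k_max + 1))
    A = {k: vec[:, :k].copy() for k in k_values}
    X = {k: np.diag(lam[:k]) for k in k_values}
    fit_loss = np.array([tail[k - 1] for k in k_values])
    return StructureScan(
        method="svd",
        labels=_labels_of(y1, d),
        k_values=k_values,
        A=A,
        X=X,
        fit_loss=fit_loss,
        y1=yv,
        kind=y1.kind if isinstance(y1, SimilarityMatrix) else "dissimilarity",
        eigenvalues=lam,
    )


# ---------------------------------------------------------------------------
# mixture solver


@dataclass
class MixtureFit:
    """One converged mixture solve at a single complexity."""

    A: np.ndarray
    X: np.ndarray
    loss_trace: np.ndarray
    status: str  # converged | stalled | max_iter
    n_iter: int

    @property
    def loss(self) -> float:
        return float(self.loss_trace[-1])


def _dirichlet_rows(d: int, k: int, rng: np.random.Generator) -> np.ndarray:
    a = rng.dirichlet(np.ones(k), size=d)
    # strictly positive: exact zeros are absorbing under multiplicative updates
    a = np.maximum(a, 1e-6)
    return a / a.sum(axis=1, keepdims=True)


def _mixture_x(a: np.ndarray, y: np.ndarray, x_prev: np.ndarray) -> np.ndarray:
    """Solve for X given A: pseudo-inverse when A has full column rank,
    otherwise one multiplicative update step."""
    if np.linalg.matrix_rank(a, tol=_rank_tolerance(a)) == a.shape[1]:
        ap = np.linalg.pinv(a)
        return ap @ y @ ap.T
    g = a.T @ a
    num = a.T @ y @ a
    den = g @ x_prev @ g + _MU_EPS
    return x_prev * num / den


def _mixture_loss(y: np.ndarray, a: np.ndarray, x: np.ndarray) -> float:
    return float(np.linalg.norm(y - a @ x @ a.T, "fro"))


def mixture_fit(
    y1,
    k: int,
    init: np.ndarray | int | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
    patience: int = 20,
) -> MixtureFit:
    """Fit the simplex-constrained structure at a single complexity k.

    ``init`` may be a starting d x k structure or an integer seed for the
    symmetric-Dirichlet random start.  Each iteration applies the
    multiplicative update to A, renormalises its rows onto the simplex and
    re-solves X.  The update rule is not guaranteed monotone for this
    quartic objective, so iterates are accepted greedily: the returned
    structure is the best iterate reached and ``loss_trace`` records the
    accepted (strictly improving) losses, making it non-increasing by
    construction while the internal iteration is free to explore.  The solve
    stops when an accepted improvement falls below ``tol`` relative
    ("converged"), when ``patience`` consecutive iterations fail to improve
    on the best loss ("stalled": poor model fit can prevent the
    multiplicative rule from finding a local optimum), or at ``max_iter``.
    """
    yv = _as_values(y1)
    d = yv.shape[0]
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}], got {k}")
    if yv.min() < 0:
        raise ValueError("mixture structure requires a non-negative matrix")

    if k == 1:
        a = np.ones((d, 1))
        x = np.array([[yv.sum() / d**2]])
        return MixtureFit(a, x, np.array([_mixture_loss(yv, a, x)]), "converged", 0)

    if init is None or isinstance(init, (int, np.integer)):
        rng = np.random.default_rng(0 if init is None else int(init))
        a = _dirichlet_rows(d, k, rng)
    else:
        a = np.asarray(init, dtype=float)
        if a.shape != (d, k):
            raise ValueError(f"init must be {d}x{k}, got {a.shape}")
        a = np.maximum(a, _MU_EPS)
        a = a / a.sum(axis=1, keepdims=True)

    ynorm = float(np.linalg.norm(yv, "fro"))
    x = _mixture_x(a, yv, np.eye(k))
    loss = _mixture_loss(yv, a, x)
    trace = [loss]
    best_a, best_x, best_loss = a.copy(), x.copy(), loss
    bad = 0
    status = "max_iter"
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ax, axt = a @ x, a @ x.T
        num = yv.T @ ax + yv @ axt
        g = a.T @ a
        den = ax @ g @ x.T + axt @ g @ x + _MU_EPS
        a = np.abs(a * num / den)
        a = np.maximum(a, _MU_EPS)
        a = a / a.sum(axis=1, keepdims=True)
        x = _mixture_x(a, yv, x)
        loss = _mixture_loss(yv, a, x)
        if loss < best_loss:
            gain = best_loss - loss
            trace.append(loss)
            best_a, best_x, best_loss = a.copy(), x.copy(), loss
            bad = 0
            if gain <= tol * max(best_loss, 1e-300) or best_loss <= 1e-12 * ynorm:
                status = "converged"
                break
        else:
            bad += 1
            if bad > patience:
                status = "stalled"
                break
    return MixtureFit(best_a, best_x, np.asarray(trace), status, n_iter)


def _spectral_init(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Near-vertex start from k-means on the spectral embedding.

    Nothing in the loss pushes mixture rows towards the simplex boundary, so
    a fit started at random interior points may converge to an equally good
    but uninterpretable mixing of the latent clusters.  Clustering the
    eigenvector embedding and starting just inside the corresponding
    vertices biases the solve towards the interpretable representative of
    that equivalence class.
    """
    from scipy.cluster.vq import kmeans2

    lam, vec = _sym_eig_sorted(y)
    emb = vec[:, :k] * np.sqrt(np.abs(lam[:k]))
    _, assign = kmeans2(
        emb, k, minit="++", seed=np.random.default_rng(seed), missing="warn"
    )
    a = np.full((y.shape[0], k), 1e-3)
    a[np.arange(y.shape[0]), assign] = 1.0
    return a / a.sum(axis=1, keepdims=True)


def _warm_start(y: np.ndarray, fit: MixtureFit) -> np.ndarray:
    """Grow a (k+1)-column start from a k-solution: the new latent cluster is
    seeded on the subject with the largest fit residual."""
    resid = y - fit.A @ fit.X @ fit.A.T
    worst = int(np.argmax((resid**2).sum(axis=1)))
    d, k = fit.A.shape
    a = np.hstack([fit.A, np.full((d, 1), 1e-3)])
    a[worst, :] = 1e-3
    a[worst, -1] = 1.0
    return a / a.sum(axis=1, keepdims=True)


def mixture_scan(
    y1,
    k_max: int | None = None,
    restarts: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 5000,
    patience: int = 20,
) -> StructureScan:
    """Mixture structure scan over k = 1..k_max.

    Each complexity is solved from several candidate starts, keeping the
    lowest-loss fit: a warm start grown out of the previous solution, a
    near-vertex start from k-means on the spectral embedding (which biases
    the solve towards the interpretable cluster-like representative), and
    ``restarts`` independent Dirichlet random starts.  Per-start RNG streams
    are derived from ``seed`` so results do not depend on evaluation order.
    Candidates with equal loss (relative ties below 1e-6) resolve to the one
    whose rows sit closest to the simplex vertices.
    """
    yv = _as_values(y1)
    d = yv.shape[0]
    if k_max is None:
        k_max = d
    if not 1 <= k_max <= d:
        raise ValueError(f"k_max must be in [1, {d}], got {k_max}")
    child_seeds = np.random.SeedSequence(seed).generate_state(k_max * max(restarts, 1) * 2)
    k_values = list(range(1, k_max + 1))
    A, X, losses, statuses = {}, {}, [], {}
    prev_best: MixtureFit | None = None
    si = 0
    for k in k_values:
        candidates: list[MixtureFit] = []
        if prev_best is not None:
            candidates.append(
                mixture_fit(yv, k, init=_warm_start(yv, prev_best), tol=tol,
                            max_iter=max_iter, patience=patience)
            )
        if k > 1:
            candidates.append(
                mixture_fit(
                    yv, k,
                    init=_spectral_init(yv, k, int(child_seeds[si] % (2**31))),
                    tol=tol, max_iter=max_iter, patience=patience,
                )
            )
        si += 1
        for _ in range(restarts if k > 1 else 1):
            candidates.append(
                mixture_fit(yv, k, init=int(child_seeds[si] % (2**31)), tol=tol,
                            max_iter=max_iter, patience=patience)
            )
            si += 1
        floor = min(f.loss for f in candidates)
        tied = [f for f in candidates if f.loss <= floor + 1e-6 * max(floor, 1.0)]
        fit = max(tied, key=lambda f: float(f.A.max(axis=1).mean()))
        prev_best = fit
        A[k], X[k] = fit.A, fit.X
        losses.append(fit.loss)
        statuses[k] = fit.status
    return StructureScan(
        method="mixture",
        labels=_labels_of(y1, d),
        k_values=k_values,
        A=A,
        X=X,
        fit_loss=np.asarray(losses),
        y1=yv,
        kind=y1.kind if isinstance(y1, SimilarityMatrix) else "dissimilarity",
        info={"seed": int(seed), "restarts": int(restarts), "statuses": statuses},
    )


# ---------------------------------------------------------------------------
# diagonal model


def diagonal_model_fit(
    y,
    k: int,
    method: str = "svd",
    tol: float = 1e-8,
    max_outer: int = 100,
    **solver_kwargs,
):
    """Fit ``Y ~ A X A^T + D`` with a free diagonal D at complexity k.

    Alternates (i) fitting A, X to ``Y - D`` with the chosen solver and
    (ii) ``D <- diag(Y - A X A^T)`` until the relative change of the total
    off-model loss drops below ``tol``.  Returns ``(A, X, D, loss, status)``.
    """
    yv = _as_values(y)
    d = yv.shape[0]
    dvec = np.zeros(d)
    best = None
    prev_loss = np.inf
    status = "max_outer"
    for _ in range(max_outer):
        target = yv - np.diag(dvec)
        if method == "svd":
            lam, vec = _sym_eig_sorted(target)
            a = vec[:, :k]
            x = np.diag(lam[:k])
        elif method == "mixture":
            fit = mixture_fit(np.maximum(target, 0.0), k, **solver_kwargs)
            a, x = fit.A, fit.X
        else:
            raise ValueError(f"unknown method {method!r}")
        approx = a @ x @ a.T
        dvec = np.diag(yv - approx).copy()
        resid = yv - approx - np.diag(dvec)
        loss = float(np.linalg.norm(resid, "fro"))
        if best is None or loss < best[3]:
            best = (a, x, dvec.copy(), loss)
        if np.isfinite(prev_loss) and (
            abs(prev_loss - loss) <= tol * max(prev_loss, 1e-300)
            or loss <= 1e-12 * np.linalg.norm(yv, "fro")
        ):
            status = "converged"
            break
        prev_loss = loss
    a, x, dvec, loss = best
    return a, x, dvec, loss, status


def _diagonal_scan(y, k_max: int, method: str, **kwargs) -> StructureScan:
    yv = _as_values(y)
    d = yv.shape[0]
    k_values = list(range(1, k_max + 1))
    A, X, D, losses, statuses = {}, {}, {}, [], {}
    for k in k_values:
        a, x, dvec, loss, status = diagonal_model_fit(yv, k, method=method, **kwargs)
        A[k], X[k], D[k] = a, x, dvec
        losses.append(loss)
        statuses[k] = status
    return StructureScan(
        method=method,
        labels=_labels_of(y, d),
        k_values=k_values,
        A=A,
        X=X,
        fit_loss=np.asarray(losses),
        y1=yv,
        kind=y.kind if isinstance(y, SimilarityMatrix) else "dissimilarity",
        diagonal=D,
        info={"statuses": statuses, "diagonal_model": True},
    )


# ---------------------------------------------------------------------------
# model front end


class StructuralModel:
    """Structural decomposition model for a reference (dis)similarity matrix.

    Parameters
    ----------
    y1
        Reference matrix: a :class:`SimilarityMatrix`, a labelled square
        :class:`pandas.DataFrame`, or a plain symmetric array.
    method
        ``"svd"`` (default; unconstrained, fast, best fit) or ``"mixture"``
        (simplex rows; slower but interpretable as soft clusters).
    k_max
        Largest complexity scanned; defaults to d for svd and min(d, 20)
        for the mixture solver.
    diagonal_model
        Fit an explicit diagonal D per complexity (self-similarity model)
        instead of using the raw diagonal.
    """

    def __init__(
        self,
        y1,
        method: str = "svd",
        k_max: int | None = None,
        diagonal_model: bool = False,
        **solver_options,
    ) -> None:
        if isinstance(y1, pd.DataFrame):
            y1 = SimilarityMatrix.from_frame(y1)
        elif not isinstance(y1, SimilarityMatrix):
            arr = np.asarray(y1, dtype=float)
            y1 = SimilarityMatrix(arr, [f"s{i}" for i in range(arr.shape[0])])
        if method not in ("svd", "mixture"):
            raise ValueError(f"unknown method {method!r}")
        self.y1 = y1
        self.method = method
        d = y1.n_subjects
        if k_max is None:
            k_max = d if method == "svd" else min(d, 20)
        if not 1 <= k_max <= d:
            raise ValueError(f"k_max must be in [1, {d}], got {k_max}")
        self.k_max = k_max
        self.diagonal_model = diagonal_model
        self.solver_options = solver_options

    @classmethod
    def from_features(
        cls,
        data: pd.DataFrame,
        builder: str = "euclidean",
        method: str = "svd",
        **kwargs,
    ) -> "StructuralModel":
        """Build the model from a subject x feature data frame."""
        from .matrix import covariance_similarity, euclidean_dissimilarity

        if builder == "euclidean":
            y1 = euclidean_dissimilarity(data)
        elif builder == "covariance":
            y1 = covariance_similarity(data)
        else:
            raise ValueError(f"unknown similarity builder {builder!r}")
        return cls(y1, method=method, **kwargs)

    def fit(self, seed: int = 0) -> StructureScan:
        if self.diagonal_model:
            scan = _diagonal_scan(
                self.y1, self.k_max, self.method, **self.solver_options
            )
        elif self.method == "svd":
            scan = svd_scan(self.y1, self.k_max)
        else:
            scan = mixture_scan(self.y1, self.k_max, seed=seed, **self.solver_options)
        return scan
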