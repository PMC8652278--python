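"""Resampling-based significance for persistences, and complexity estimation.

The null hypothesis is that the target matrix is a mean-scaled version of the
reference: structure learned from half of the reference features should
predict a similarity built from the *other* half of the reference features as
well as it predicts the (down-sampled) true target.  Each replicate therefore

1. splits the reference features into two disjoint halves, building a
   "sampled reference" and a "sampled target";
2. down-samples the true target's features to half, matching noise levels;
3. mean-centres and scales both the sampled target and the down-sampled true
   target onto the sampled reference (off-diagonal moments);
4. scans the sampled reference and predicts both aligned matrices, recording
   persistences: the sampled target supplies the null statistic, the true
   target the observed one.

The regularised empirical p-value for a cell is
``(1 + #{replicates with null >= observed}) / (1 + n_bs)``: small p means
the target's persistence exceeds what reference resampling alone produces.
(The direction is chosen so that small p-values flag significant cells,
matching how the p = 0.05/0.01 thresholds are used throughout.)

Because the resampling only measures predictability, not whether complexity k
reflects signal at all, a cross-validated complexity estimate k-hat of the
*target* is bootstrapped alongside: p(k) is the proportion of replicates with
k-hat >= k, and the combined p-value per cell is
``p_c = 1 - p(k) * (1 - p)``, close to 0 only when complexity k describes
structure (p(k) near 1) *and* the persistence is extreme (p near 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import (
    SimilarityMatrix,
    covariance_similarity,
    euclidean_dissimilarity,
    remove_diagonal,
)
from .model import StructuralModel

__all__ = [
    "ResampleSet",
    "SignificanceResult",
    "split_half_resample",
    "align_scale",
    "empirical_pvalues",
    "crossvalidate_k",
    "p_of_k",
    "combined_pc",
    "significance_pipeline",
]


def resolve_builder(builder):
    """Map a builder name to a feature-matrix -> SimilarityMatrix callable."""
    if callable(builder):
        return builder
    if builder == "euclidean":
        return euclidean_dissimilarity
    if builder == "covariance":
        return covariance_similarity
    raise ValueError(f"unknown similarity builder {builder!r}")


@dataclass
class Replicate:
    ref_sampled: SimilarityMatrix
    tgt_sampled: SimilarityMatrix
    tgt_downsampled: SimilarityMatrix
    ref_half1: np.ndarray  # feature indices of the sampled-reference half
    ref_half2: np.ndarray
    tgt_features: np.ndarray


@dataclass
class ResampleSet:
    """Split-half replicates of the reference plus down-sampled targets."""

    replicates: list[Replicate]
    seed: int
    builder_name: str

    @property
    def n_bs(self) -> int:
        return len(self.replicates)


def split_half_resample(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_bs: int,
    builder="euclidean",
    seed: int = 0,
    drop_diagonal: bool = True,
) -> ResampleSet:
    """Build ``n_bs`` split-half replicates from the two feature matrices.

    Within a replicate the two reference halves use disjoint feature subsets
    whose union is all features (sizes floor(L/2) and ceil(L/2) for odd L).
    RNG streams are derived from ``(seed, replicate index)`` so replicates
    are reproducible and order-independent.

    By default every built similarity has its diagonal replaced by the row's
    next most extreme value (``drop_diagonal``): the raw self-(dis)similarity
    is a full-rank isotropic component shared by any two feature-derived
    matrices, which would otherwise let every extra eigendirection improve
    held-out prediction regardless of structure.
    """
    if n_bs < 1:
        raise ValueError("n_bs must be at least 1")
    if list(d1.index) != list(d2.index):
        raise ValueError("reference and target subject labels must match")
    l1, l2 = d1.shape[1], d2.shape[1]
    if l1 < 4:
        raise ValueError("reference needs at least 4 features to split")
    base_build = resolve_builder(builder)
    build = (lambda df: remove_diagonal(base_build(df))) if drop_diagonal else base_build
    streams = np.random.SeedSequence(seed).spawn(n_bs)
    replicates = []
    for stream in streams:
        rng = np.random.default_rng(stream)
        perm = rng.permutation(l1)
        half1, half2 = np.sort(perm[: l1 // 2]), np.sort(perm[l1 // 2 :])
        tgt_idx = np.sort(rng.permutation(l2)[: max(l2 // 2, 2)])
        replicates.append(
            Replicate(
                ref_sampled=build(d1.iloc[:, half1]),
                tgt_sampled=build(d1.iloc[:, half2]),
                tgt_downsampled=build(d2.iloc[:, tgt_idx]),
                ref_half1=half1,
                ref_half2=half2,
                tgt_features=tgt_idx,
            )
        )
    return ResampleSet(
        replicates=replicates,
        seed=int(seed),
        builder_name=getattr(builder, "__name__", str(builder)),
    )


def _offdiag(values: np.ndarray) -> np.ndarray:
    d = values.shape[0]
    return values[~np.eye(d, dtype=bool)]


def align_scale(y: SimilarityMatrix, ref: SimilarityMatrix) -> SimilarityMatrix:
    """Affinely map a matrix so its off-diagonal moments match a reference.

    Returns ``(y - mean(y)) / sd(y) * sd(ref) + mean(ref)`` with the mean and
    standard deviation taken over off-diagonal entries only: the diagonal is
    governed by the self-similarity policy and should not leak into the
    scaling.  Absorbs any affine difference between the matrices.
    """
    yv, rv = y.values, ref.values
    if yv.shape != rv.shape:
        raise ValueError("matrices must have the same shape to be aligned")
    ym, ys = float(_offdiag(yv).mean()), float(_offdiag(yv).std())
    rm, rs = float(_offdiag(rv).mean()), float(_offdiag(rv).std())
    if ys == 0.0:
        raise ValueError("cannot align a matrix with zero off-diagonal spread")
    out = (yv - ym) / ys * rs + rm
    return SimilarityMatrix(
        out,
        list(y.labels),
        kind=y.kind,
        diagonal_policy=y.diagonal_policy,
        metadata={**y.metadata, "allow_negative": True, "aligned": True},
    )


def empirical_pvalues(null_stats, observed, n_bs: int | None = None) -> np.ndarray:
    """Regularised empirical p-values, elementwise over statistic arrays.

    ``null_stats`` has the replicate axis first; ``observed`` is either a
    single statistic array (compared against every replicate) or a
    per-replicate array of the same shape as ``null_stats`` (paired
    comparison).  Ties count towards the null:
    ``p = (1 + #{null >= observed}) / (1 + n_bs)``.
    """
    null_stats = np.asarray(null_stats, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if n_bs is None:
        n_bs = null_stats.shape[0]
    if n_bs == 0:
        raise ValueError("at least one replicate is required")
    if observed.shape == null_stats.shape:
        count = (null_stats >= observed).sum(axis=0)
    elif observed.shape == null_stats.shape[1:]:
        count = (null_stats >= observed[None, ...]).sum(axis=0)
    else:
        raise ValueError(
            f"observed shape {observed.shape} matches neither the replicate "
            f"array {null_stats.shape} nor a single statistic"
        )
    return (1.0 + count) / (1.0 + n_bs)


def crossvalidate_k(
    d2: pd.DataFrame,
    n_bs: int,
    builder="euclidean",
    method: str = "svd",
    k_max: int | None = None,
    seed: int = 0,
    drop_diagonal: bool = True,
) -> np.ndarray:
    """Bootstrap the cross-validated complexity estimate k-hat of a dataset.

    Per replicate the features are split in half; a scan of the fold-1
    similarity predicts the (aligned) fold-2 similarity using the fold-1
    structure *and relationship*, and k-hat is the complexity minimising the
    fold-2 residual norm (ties break to the smallest k).  Re-fitting the
    relationship on fold 2 would make the error non-increasing in k by
    construction, so the held-out prediction keeps X fixed: under pure noise
    extra components fit fold-1 noise only and k-hat stays small, while real
    shared structure keeps lowering the fold-2 error up to the true
    complexity.  ``drop_diagonal`` (default) removes the self-similarity
    diagonal in each fold, for the reason given in
    :func:`split_half_resample`.
    """
    if n_bs < 1:
        raise ValueError("n_bs must be at least 1")
    if d2.shape[1] < 4:
        raise ValueError("need at least 4 features to cross-validate")
    base_build = resolve_builder(builder)
    build = (lambda df: remove_diagonal(base_build(df))) if drop_diagonal else base_build
    d = d2.shape[0]
    if k_max is None:
        k_max = min(d, 20)
    streams = np.random.SeedSequence([seed, 1]).spawn(n_bs)
    k_hat = np.empty(n_bs, dtype=int)
    for b, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        perm = rng.permutation(d2.shape[1])
        ya = build(d2.iloc[:, np.sort(perm[: d2.shape[1] // 2])])
        yb = build(d2.iloc[:, np.sort(perm[d2.shape[1] // 2 :])])
        yb = align_scale(yb, ya)
        scan = StructuralModel(ya, method=method, k_max=k_max).fit(
            seed=int(stream.generate_state(1)[0] % (2**31))
        )
        errs = np.array(
            [
                np.linalg.norm(
                    yb.values - scan.A[k] @ scan.X[k] @ scan.A[k].T, "fro"
                )
                for k in scan.k_values
            ]
        )
        k_hat[b] = scan.k_values[int(np.argmin(errs))]
    return k_hat


def p_of_k(k_hat_samples, k_max: int) -> np.ndarray:
    """p(k): the proportion of bootstrap replicates with k-hat >= k."""
    k_hat = np.asarray(k_hat_samples)
    if k_hat.size == 0:
        raise ValueError("k-hat samples are empty")
    ks = np.arange(1, k_max + 1)
    return (k_hat[None, :] >= ks[:, None]).mean(axis=1)


def combined_pc(p_k, p_f) -> np.ndarray:
    """Combined p-value: ``p_c = 1 - p(k) * (1 - p_f)``.

    Close to 0 only when complexity k describes structure (p(k) near 1) and
    the persistence statistic is extreme (p_f near 0).
    """
    p_k = np.asarray(p_k, dtype=float)
    p_f = np.asarray(p_f, dtype=float)
    if np.any((p_k < 0) | (p_k > 1)) or np.any((p_f < 0) | (p_f > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return 1.0 - p_k * (1.0 - p_f)


@dataclass
class SignificanceResult:
    """Resampling significance for a structural comparison."""

    labels: list[str]
    k_values: list[int]
    n_bs: int
    seed: int
    p_persist: pd.DataFrame  # d x k_max
    p_c: pd.DataFrame  # d x k_max combined p-values
    k_hat_samples: np.ndarray
    p_k: np.ndarray
    p_frobenius: np.ndarray | None = None  # per-k global test on ||R||_F
    p_resid: np.ndarray | None = None  # optional d x d x k_max array
    info: dict = field(default_factory=dict)

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.p_persist.to_csv(directory / "p_persist.csv")
        self.p_c.to_csv(directory / "p_combined.csv")
        pd.DataFrame(
            {"k": self.k_values, "p_k": self.p_k}
        ).set_index("k").to_csv(directory / "p_k.csv")
        pd.DataFrame({"k_hat": self.k_hat_samples}).to_csv(
            directory / "k_hat_samples.csv", index=False
        )
        if self.p_frobenius is not None:
            pd.DataFrame(
                {"k": self.k_values, "p_frobenius": self.p_frobenius}
            ).set_index("k").to_csv(directory / "p_frobenius.csv")
        manifest = {
            "n_bs": self.n_bs,
            "seed": self.seed,
            "labels": self.labels,
            "k_values": self.k_values,
            "pvalue_direction": (
                "small p = observed persistence exceeds the resampled-"
                "reference null (count of null >= observed)"
            ),
            **self.info,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return directory


def _replicate_persistence(
    rep: Replicate, method, k_max, seed, order_labels, keep_residuals=False
):
    """Null and observed persistence arrays for one replicate."""
    scan = StructuralModel(rep.ref_sampled, method=method, k_max=k_max).fit(seed=seed)
    null_cmp = scan.predict(
        align_scale(rep.tgt_sampled, rep.ref_sampled),
        store_residuals=keep_residuals,
    )
    obs_cmp = scan.predict(
        align_scale(rep.tgt_downsampled.reordered(rep.ref_sampled.labels),
                    rep.ref_sampled),
        store_residuals=keep_residuals,
    )
    null_p = null_cmp.persistence.loc[order_labels].to_numpy()
    obs_p = obs_cmp.persistence.loc[order_labels].to_numpy()
    resid = None
    if keep_residuals:
        # squared residual statistics, d x d x k_max per side
        resid = (
            np.stack([null_cmp.residual(k) ** 2 for k in scan.k_values], axis=-1),
            np.stack([obs_cmp.residual(k) ** 2 for k in scan.k_values], axis=-1),
        )
    return null_p, obs_p, null_cmp.total_loss, obs_cmp.total_loss, resid


def significance_pipeline(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_bs: int = 199,
    builder="euclidean",
    method: str = "svd",
    k_max: int | None = None,
    seed: int = 0,
    threads: int = 1,
    resamples: ResampleSet | None = None,
    drop_diagonal: bool = True,
    residual_pvalues: bool = False,
) -> SignificanceResult:
    """End-to-end split-half significance for predicting d2's similarity from d1's.

    ``n_bs`` of the order of 200 is needed to resolve the 0.05 level (the
    regularised p-values are floored at 1/(1+n_bs)).  Externally
    bootstrapped matrices can be supplied via ``resamples`` instead of the
    internal feature split, e.g. when similarities are not feature-derived.
    ``threads`` > 1 evaluates replicates in a thread pool; results are
    identical to the serial run because every replicate owns its RNG stream.
    ``residual_pvalues`` additionally computes per-cell p-values for every
    squared residual entry (a d x d x k_max array whose memory cost is why
    it is off by default).
    """
    if list(d1.index) != list(d2.index):
        raise ValueError("reference and target subject labels must match")
    if n_bs < 1:
        raise ValueError("n_bs must be at least 1")
    labels = [str(x) for x in d1.index]
    d = len(labels)
    if k_max is None:
        k_max = min(d, 20)
    if resamples is None:
        resamples = split_half_resample(
            d1, d2, n_bs, builder=builder, seed=seed, drop_diagonal=drop_diagonal
        )
    if resamples.n_bs != n_bs:
        raise ValueError("resample set size does not match n_bs")

    fit_seeds = [
        int(s % (2**31))
        for s in np.random.SeedSequence([seed, 2]).generate_state(n_bs)
    ]
    args = [
        (rep, method, k_max, fit_seeds[i], labels, residual_pvalues)
        for i, rep in enumerate(resamples.replicates)
    ]
    if threads > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(lambda a: _replicate_persistence(*a), args))
    else:
        results = [_replicate_persistence(*a) for a in args]
    null_p = np.stack([r[0] for r in results])
    obs_p = np.stack([r[1] for r in results])
    null_fro = np.stack([r[2] for r in results])
    obs_fro = np.stack([r[3] for r in results])

    p_persist = empirical_pvalues(null_p, obs_p, n_bs)
    p_fro = empirical_pvalues(null_fro, obs_fro, n_bs)
    p_resid = None
    if residual_pvalues:
        null_r = np.stack([r[4][0] for r in results])
        obs_r = np.stack([r[4][1] for r in results])
        p_resid = empirical_pvalues(null_r, obs_r, n_bs)
    k_hat = crossvalidate_k(
        d2, n_bs, builder=builder, method=method, k_max=k_max, seed=seed,
        drop_diagonal=drop_diagonal,
    )
    p_k = p_of_k(k_hat, k_max)
    p_c = combined_pc(p_k[None, :], p_persist)
    k_values = list(range(1, k_max + 1))
    return SignificanceResult(
        labels=labels,
        k_values=k_values,
        n_bs=n_bs,
        seed=int(seed),
        p_persist=pd.DataFrame(p_persist, index=labels, columns=k_values),
        p_c=pd.DataFrame(p_c, index=labels, columns=k_values),
        k_hat_samples=k_hat,
        p_k=p_k,
        p_frobenius=p_fro,
        p_resid=p_resid,
        info={"method": method, "builder": resamples.builder_name},
    )
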