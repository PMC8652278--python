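"""Hierarchical mixture simulations: subjects in tree-related clusters.

A reference dataset is generated by (i) drawing a neutral coalescent tree on
k cluster tips, (ii) evolving L continuous features down the tree by Brownian
motion (so cluster feature profiles are correlated through shared ancestry),
and (iii) sampling subjects around their cluster profile with i.i.d. Gaussian
noise of standard deviation sigma0.  Targets are generated under

* scenario "null" -- the same tree, data re-simulated (a pure noise change);
* scenario "A"    -- branch lengths independently rescaled by U(0.1, 2)
  multipliers (a relationship change: same clusters, different tree shape);
* scenario "B"    -- as A, plus one mixture edge: a fraction r of the
  subjects of a recipient cluster become a (1-beta, beta) mixture of the
  recipient and a distant donor cluster (a structural change).

All randomness is driven by numpy Generator streams derived from a single
seed, so every simulated pair is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .matrix import SimilarityMatrix, euclidean_dissimilarity

__all__ = [
    "MixtureAssignment",
    "coalescent_tree",
    "brownian_traits",
    "simulate_subjects",
    "scenario_a",
    "scenario_b",
    "baseline_assignment",
    "make_pair",
    "tip_shared_path_matrix",
]


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(
        (t.label for t in tree.taxon_namespace), key=lambda s: (len(s), s)
    )


def coalescent_tree(k: int, seed: int = 0) -> dendropy.Tree:
    """Neutral coalescent tree on k tips labelled t1..tk.

    With m extant lineages the waiting time to the next merger is
    exponential with rate m(m-1)/2 and the merging pair is uniform, giving an
    ultrametric binary tree whose expected height is 2(1 - 1/k).
    """
    if k < 2:
        raise ValueError("a coalescent tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(k)]
    # grow the newick description bottom-up
    active = list(labels)  # newick fragment per active lineage
    height = {lab: 0.0 for lab in labels}
    t = 0.0
    while len(active) > 1:
        m = len(active)
        t += rng.exponential(2.0 / (m * (m - 1)))
        i, j = sorted(rng.choice(m, size=2, replace=False))
        a, b = active[i], active[j]
        merged = f"({a}:{t - height[a]:.17g},{b}:{t - height[b]:.17g})"
        active = [x for idx, x in enumerate(active) if idx not in (i, j)]
        active.append(merged)
        height[merged] = t
    tree = dendropy.Tree.get(data=active[0] + ";", schema="newick")
    tree.is_rooted = True
    return tree


def tip_shared_path_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Shared root-to-tip path length for every tip pair.

    Under Brownian motion with unit rate this is exactly the covariance of
    tip values, Cov(i, j) = depth of the most recent common ancestor.
    """
    labels = _tip_labels(tree)
    depth = {}
    for leaf in tree.leaf_node_iter():
        depth[leaf.taxon.label] = leaf.distance_from_root()
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    k = len(labels)
    out = np.zeros((k, k))
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            if i == j:
                out[i, j] = depth[li]
            else:
                p = pdm.patristic_distance(taxa[li], taxa[lj])
                out[i, j] = (depth[li] + depth[lj] - p) / 2.0
    return pd.DataFrame(out, index=labels, columns=labels)


def brownian_traits(
    tree: dendropy.Tree, L: int, rate: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Evolve L independent features down the tree by Brownian motion.

    Starting from 0 at the root, each branch adds a Normal(0, rate^2 * length)
    increment, so tips covary through their shared path from the root.
    Returns the k x L cluster-profile matrix with tips in t1..tk order.
    """
    if L < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(seed)
    values: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            v = np.zeros(L)
        else:
            length = node.edge.length or 0.0
            v = values[id(node.parent_node)] + rng.normal(
                0.0, rate * np.sqrt(length), size=L
            )
        values[id(node)] = v
        if node.is_leaf():
            out[node.taxon.label] = v
    labels = _tip_labels(tree)
    return pd.DataFrame(
        np.vstack([out[l] for l in labels]),
        index=labels,
        columns=[f"f{j + 1}" for j in range(L)],
    )


@dataclass
class MixtureAssignment:
    """Ground-truth mixture memberships of subjects over cluster tips."""

    subject_labels: list[str]
    cluster_labels: list[str]
    values: np.ndarray  # d x k, rows on the simplex
    cluster_of: list[str]  # baseline cluster per subject
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        rows = self.values.sum(axis=1)
        if self.values.min() < 0 or np.max(np.abs(rows - 1.0)) > 1e-8:
            raise ValueError("mixture rows must lie on the probability simplex")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_labels, columns=self.cluster_labels
        )


def baseline_assignment(d: int, cluster_labels: list[str]) -> MixtureAssignment:
    """One-hot memberships, subjects split as evenly as possible.

    When d is not a multiple of k the extra subjects go to the
    lowest-indexed clusters.
    """
    k = len(cluster_labels)
    if d < k:
        raise ValueError("need at least one subject per cluster")
    base, extra = divmod(d, k)
    sizes = [base + (1 if i < extra else 0) for i in range(k)]
    values = np.zeros((d, k))
    cluster_of = []
    row = 0
    for i, size in enumerate(sizes):
        for _ in range(size):
            values[row, i] = 1.0
            cluster_of.append(cluster_labels[i])
            row += 1
    subjects = [f"s{i + 1:03d}" for i in range(d)]
    return MixtureAssignment(subjects, list(cluster_labels), values, cluster_of)


def simulate_subjects(
    a: MixtureAssignment, d0: pd.DataFrame, sigma0: float, seed: int = 0
) -> pd.DataFrame:
    """Draw subject features Normal((a_i^T D0)_l, sigma0^2)."""
    if list(d0.index) != a.cluster_labels:
        d0 = d0.loc[a.cluster_labels]
    if a.values.shape[1] != d0.shape[0]:
        raise ValueError(
            f"assignment has {a.values.shape[1]} clusters but the profile "
            f"matrix has {d0.shape[0]} rows"
        )
    rng = np.random.default_rng(seed)
    mean = a.values @ d0.to_numpy(dtype=float)
    data = mean + rng.normal(0.0, sigma0, size=mean.shape) if sigma0 > 0 else mean
    return pd.DataFrame(data, index=a.subject_labels, columns=d0.columns)


def scenario_a(
    tree: dendropy.Tree, seed: int = 0, low: float = 0.1, high: float = 2.0
) -> dendropy.Tree:
    """Same topology, each branch length multiplied by an independent
    Uniform(low, high) draw (defaults U(0.1, 2)); the result is generally
    non-ultrametric."""
    rng = np.random.default_rng(seed)
    t2 = tree.clone(depth=1)
    for edge in t2.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length) * float(rng.uniform(low, high))
    return t2


def scenario_b(
    tree: dendropy.Tree,
    a: MixtureAssignment,
    beta: float = 0.5,
    r: float = 0.5,
    seed: int = 0,
    low: float = 0.1,
    high: float = 2.0,
) -> tuple[dendropy.Tree, MixtureAssignment]:
    """Branch-length change plus one mixture edge.

    After the scenario-A branch perturbation, a recipient tip i is drawn
    uniformly and a donor tip j uniformly among tips at least the median
    patristic distance from i (ties inclusive).  A fraction r (rounded half
    up) of the subjects in cluster i get the mixture row (1-beta) on i and
    beta on j.  r in {0, 1} would move the whole cluster, which is a
    relationship change rather than a structural one, so it is rejected.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must be strictly between 0 and 1")
    if not 0.0 < r < 1.0:
        raise ValueError("r must be strictly between 0 and 1")
    ss = _seedseq(seed).spawn(2)
    t2 = scenario_a(tree, seed=ss[0], low=low, high=high)
    rng = np.random.default_rng(ss[1])
    labels = a.cluster_labels
    recipient = labels[int(rng.integers(len(labels)))]
    pdm = t2.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in t2.taxon_namespace}
    dists = {
        l: pdm.patristic_distance(taxa[recipient], taxa[l])
        for l in labels
        if l != recipient
    }
    med = float(np.median(list(dists.values())))
    eligible = sorted(l for l, dist in dists.items() if dist >= med)
    donor = eligible[int(rng.integers(len(eligible)))]

    members = [i for i, c in enumerate(a.cluster_of) if c == recipient]
    if not members:
        raise ValueError(f"recipient cluster {recipient} has no subjects")
    n_affected = int(np.floor(r * len(members) + 0.5))
    affected = sorted(
        rng.choice(members, size=n_affected, replace=False).tolist()
    )
    values = a.values.copy()
    ri, di = labels.index(recipient), labels.index(donor)
    for i in affected:
        values[i, :] = 0.0
        values[i, ri] = 1.0 - beta
        values[i, di] = beta
    truth = {
        "recipient": recipient,
        "donor": donor,
        "beta": float(beta),
        "r": float(r),
        "affected_subjects": [a.subject_labels[i] for i in affected],
    }
    return t2, MixtureAssignment(
        list(a.subject_labels), list(labels), values, list(a.cluster_of), truth
    )


def make_pair(
    d: int = 100,
    k: int = 10,
    L: int = 2000,
    sigma0: float = 0.05,
    scenario: str = "A",
    params: dict | None = None,
    seed: int = 0,
    rate: float = 1.0,
) -> tuple[SimilarityMatrix, SimilarityMatrix, dict]:
    """Simulate a reference/target pair of Euclidean dissimilarity matrices.

    Returns ``(Y1, Y2, truth)`` where the truth bundle carries the trees
    (newick), the mixture assignments and the cluster label of every subject.
    Defaults follow the study conditions d=100 subjects, k=10 clusters,
    L=2000 features.
    """
    if d < k:
        raise ValueError("need at least one subject per cluster")
    params = dict(params or {})
    ss = _seedseq(seed).spawn(6)
    t1 = coalescent_tree(k, seed=ss[0])
    assign = baseline_assignment(d, _tip_labels(t1))
    d0_ref = brownian_traits(t1, L, rate=rate, seed=ss[1])
    data1 = simulate_subjects(assign, d0_ref, sigma0, seed=ss[2])
    y1 = euclidean_dissimilarity(data1)

    if scenario == "null":
        t2, assign2 = t1, assign
    elif scenario == "A":
        t2 = scenario_a(
            t1, seed=ss[3],
            low=params.get("low", 0.1), high=params.get("high", 2.0),
        )
        assign2 = assign
    elif scenario == "B":
        t2, assign2 = scenario_b(
            t1,
            assign,
            beta=params.get("beta", 0.5),
            r=params.get("r", 0.5),
            seed=ss[3],
            low=params.get("low", 0.1),
            high=params.get("high", 2.0),
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r} (use 'null', 'A' or 'B')")

    if params.get("reuse_profiles", False):
        # test hook: keep the reference cluster profiles instead of
        # re-simulating them on the target tree
        d0_tgt = d0_ref
    else:
        d0_tgt = brownian_traits(t2, L, rate=rate, seed=ss[4])
    data2 = simulate_subjects(assign2, d0_tgt, sigma0, seed=ss[5])
    y2 = euclidean_dissimilarity(data2)

    truth = {
        "scenario": scenario,
        "data_reference": data1,
        "data_target": data2,
        "tree_reference": t1.as_string(schema="newick").strip(),
        "tree_target": t2.as_string(schema="newick").strip(),
        "assignment_reference": assign,
        "assignment_target": assign2,
        "cluster_of": dict(zip(assign.subject_labels, assign.cluster_of)),
        **assign2.truth,
    }
    return y1, y2, truth
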