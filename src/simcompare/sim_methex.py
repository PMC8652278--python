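"""Case-control methylation/expression simulation with planted anomalies.

Loci (the subjects of the downstream comparison) fall into two classes:
"hypo"-methylated loci with low baseline methylation means mu_i ~ U(0.1, 0.4)
and "hyper"-methylated loci with high means mu_i ~ U(0.55, 0.85).  Tumour
samples draw methylation uniformly around mu_i (width mu_i for hypo loci,
width 1 - mu_i for hyper loci); control samples follow the same width rules
but around a mean shifted towards 0.5 by 0.2 (deterministically when mu_i is
below 0.3 or above 0.7, otherwise with a random sign).  Draws are clamped to
the unit interval.

Expression is measured on an *independent* cohort of samples that shares
only the loci: each expression sample gets a fresh latent methylation draw
under the same locus rules, and expression is Normal with that draw as the
(negated) mean and locus noise sd sigma_i ~ U(0.5, 0.9), then centred and
scaled per locus.  Methylation silences transcription, so the coupling is
negative; with these parameters the mean per-locus correlation between the
two assays across matched case-control sample indices is about -5%.

Anomalies reverse the methylation/expression relationship for two disjoint
segments of loci (expression replaced by -2e, for tumour samples in one
segment and control samples in the other), which is what the structural
comparison is asked to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import SimilarityMatrix, euclidean_dissimilarity

__all__ = [
    "MethExSim",
    "simulate_methylation",
    "simulate_expression",
    "insert_anomalies",
    "loci_similarity",
    "methylation_expression_correlation",
]


@dataclass
class MethExSim:
    """State of the simulation; populated stage by stage."""

    locus_labels: list[str]
    locus_class: np.ndarray  # "hypo" | "hyper" per locus
    mu: np.ndarray  # baseline methylation mean per locus
    methylation: pd.DataFrame | None = None  # loci x samples, in [0, 1]
    meth_status: np.ndarray | None = None  # "tumour" | "control" per sample
    expression: pd.DataFrame | None = None  # loci x samples, centred/scaled
    expr_status: np.ndarray | None = None
    expr_sd: np.ndarray | None = None  # sigma_i per locus
    expr_latent_meth: pd.DataFrame | None = None  # fresh draws conditioning e'
    expr_raw: pd.DataFrame | None = None  # expression before centring/scaling
    anomaly_segments: dict = field(default_factory=dict)
    n_clamped: int = 0


def _statuses(n_tumour: int, n_control: int) -> np.ndarray:
    return np.array(["tumour"] * n_tumour + ["control"] * n_control)


def _control_mu(mu: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shift locus means towards the middle for control samples."""
    shifted = mu.copy()
    lo, hi = mu < 0.3, mu > 0.7
    shifted[lo] = mu[lo] + 0.2
    shifted[hi] = mu[hi] - 0.2
    mid = ~(lo | hi)
    signs = rng.choice([-1.0, 1.0], size=int(mid.sum()))
    shifted[mid] = mu[mid] + 0.2 * signs
    return shifted


def _draw_methylation(
    mu: np.ndarray,
    locus_class: np.ndarray,
    status: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Uniform methylation draws per locus x sample under the class rules."""
    n_loci, n_samp = mu.size, status.size
    centre = np.empty((n_loci, n_samp))
    is_control = status == "control"
    centre[:, ~is_control] = mu[:, None]
    mu_ctrl = _control_mu(mu, rng)
    centre[:, is_control] = mu_ctrl[:, None]
    half = np.where(locus_class[:, None] == "hypo", centre / 2.0, (1.0 - centre) / 2.0)
    draws = rng.uniform(centre - half, centre + half)
    clamped = int(((draws < 0) | (draws > 1)).sum())
    return np.clip(draws, 0.0, 1.0), clamped


def simulate_methylation(
    n_hypo: int = 300,
    n_hyper: int = 700,
    n_tumour: int = 50,
    n_control: int = 50,
    seed: int = 0,
) -> MethExSim:
    """Simulate the methylation assay (loci x samples, proportions in [0, 1]).

    Samples are laid out tumour-first then control, the same case-control
    design used for the (independent) expression cohort, so that sample index
    j has the same status in both assays.
    """
    if min(n_hypo, n_hyper, n_tumour, n_control) < 1:
        raise ValueError("all class and cohort counts must be at least 1")
    rng = np.random.default_rng(seed)
    locus_class = np.array(["hypo"] * n_hypo + ["hyper"] * n_hyper)
    mu = np.where(
        locus_class == "hypo",
        rng.uniform(0.1, 0.4, size=n_hypo + n_hyper),
        rng.uniform(0.55, 0.85, size=n_hypo + n_hyper),
    )
    status = _statuses(n_tumour, n_control)
    draws, clamped = _draw_methylation(mu, locus_class, status, rng)
    loci = [f"locus{i + 1:04d}" for i in range(n_hypo + n_hyper)]
    samples = [f"m{j + 1:03d}" for j in range(status.size)]
    return MethExSim(
        locus_labels=loci,
        locus_class=locus_class,
        mu=mu,
        methylation=pd.DataFrame(draws, index=loci, columns=samples),
        meth_status=status,
        n_clamped=clamped,
    )


def simulate_expression(
    sim: MethExSim,
    seed: int = 1,
    n_tumour: int | None = None,
    n_control: int | None = None,
) -> MethExSim:
    """Simulate the expression assay on an independent sample cohort.

    Each expression sample receives a fresh methylation realisation under the
    same locus parameters (the cohorts share loci, not people); expression is
    then Normal(-m, sigma_i^2) -- methylation suppresses transcription --
    and finally centred and scaled per locus.
    """
    if sim.methylation is None:
        raise ValueError("simulate_methylation must run first")
    rng = np.random.default_rng(seed)
    if n_tumour is None:
        n_tumour = int((sim.meth_status == "tumour").sum())
    if n_control is None:
        n_control = int((sim.meth_status == "control").sum())
    status = _statuses(n_tumour, n_control)
    latent, clamped = _draw_methylation(sim.mu, sim.locus_class, status, rng)
    sigma = rng.uniform(0.5, 0.9, size=sim.mu.size)
    raw = rng.normal(-latent, sigma[:, None])
    centred = raw - raw.mean(axis=1, keepdims=True)
    scaled = centred / centred.std(axis=1, keepdims=True)
    samples = [f"e{j + 1:03d}" for j in range(status.size)]
    sim.expression = pd.DataFrame(scaled, index=sim.locus_labels, columns=samples)
    sim.expr_status = status
    sim.expr_sd = sigma
    sim.expr_latent_meth = pd.DataFrame(
        latent, index=sim.locus_labels, columns=samples
    )
    sim.expr_raw = pd.DataFrame(raw, index=sim.locus_labels, columns=samples)
    sim.n_clamped += clamped
    return sim


def insert_anomalies(
    sim: MethExSim, segment_length: int = 10, seed: int = 2
) -> MethExSim:
    """Reverse the methylation/expression link for two locus segments.

    Two disjoint segments of ``segment_length`` consecutive loci are chosen;
    in the first only tumour samples' expression is replaced by -2e, in the
    second only control samples'.  Segment indices are recorded as ground
    truth.
    """
    if sim.expression is None:
        raise ValueError("simulate_expression must run first")
    n_loci = len(sim.locus_labels)
    if 2 * segment_length > n_loci:
        raise ValueError("segments do not fit within the locus range")
    rng = np.random.default_rng(seed)
    start1 = int(rng.integers(0, n_loci - segment_length + 1))
    while True:
        start2 = int(rng.integers(0, n_loci - segment_length + 1))
        if abs(start2 - start1) >= segment_length:
            break
    expr = sim.expression.to_numpy()
    seg1 = np.arange(start1, start1 + segment_length)
    seg2 = np.arange(start2, start2 + segment_length)
    tum = sim.expr_status == "tumour"
    expr[np.ix_(seg1, tum)] *= -2.0
    expr[np.ix_(seg2, ~tum)] *= -2.0
    sim.expression = pd.DataFrame(
        expr, index=sim.locus_labels, columns=sim.expression.columns
    )
    sim.anomaly_segments = {
        "tumour_altered": [sim.locus_labels[i] for i in seg1],
        "control_altered": [sim.locus_labels[i] for i in seg2],
    }
    return sim


def loci_similarity(sim: MethExSim, assay: str) -> SimilarityMatrix:
    """Euclidean dissimilarity between loci across one assay's samples."""
    if assay == "meth":
        data = sim.methylation
    elif assay == "expr":
        data = sim.expression
    else:
        raise ValueError(f"unknown assay {assay!r} (use 'meth' or 'expr')")
    if data is None:
        raise ValueError(f"assay {assay!r} has not been simulated yet")
    return euclidean_dissimilarity(data)


def methylation_expression_correlation(sim: MethExSim) -> float:
    """Mean per-locus Pearson correlation between the two assays.

    Sample j of the methylation cohort is matched with sample j of the
    expression cohort (same position in the shared case-control design);
    the correlation is computed per locus across matched indices and
    averaged over loci.  Run before :func:`insert_anomalies` for the
    baseline coupling of the generative model.
    """
    if sim.expression is None:
        raise ValueError("both assays must be simulated")
    m = sim.methylation.to_numpy()
    e = sim.expression.to_numpy()
    n = min(m.shape[1], e.shape[1])
    m, e = m[:, :n], e[:, :n]
    mc = m - m.mean(axis=1, keepdims=True)
    ec = e - e.mean(axis=1, keepdims=True)
    num = (mc * ec).sum(axis=1)
    den = np.sqrt((mc**2).sum(axis=1) * (ec**2).sum(axis=1))
    ok = den > 0
    return float((num[ok] / den[ok]).mean())
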