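"""Spectral embedding and von Mises-Fisher mixture soft clustering.

Genes are clustered in three steps:

1. A gene-gene similarity matrix ``W`` is formed from the data matrix ``X``
   as the row-cosine Gram matrix (rows unit-normalized before ``X Xᵀ``),
   with negative entries clipped to zero so the graph is valid.
2. The normalized graph Laplacian ``L = I − D^{-1/2} W D^{-1/2}`` is
   eigendecomposed and the eigenvectors of the ``k`` smallest eigenvalues
   give each gene a coordinate, re-normalized to the unit sphere.
3. A mixture of von Mises-Fisher (vMF) distributions with a shared, fixed
   concentration κ is fitted to the embedded points by multi-restart EM;
   the restart with the highest final log-likelihood wins.  Posterior
   cluster probabilities give a soft clustering; ``hard_assign`` takes the
   maximum-posterior cluster when a partition is needed.

The vMF density on the (d−1)-sphere is ``f(x; μ, κ) = c_d(κ) exp(κ μᵀx)``
with ``c_d(κ) = κ^{d/2−1} / ((2π)^{d/2} I_{d/2−1}(κ))`` where ``I_ν`` is the
modified Bessel function of the first kind.  κ acts as an inverse variance:
large κ concentrates each component around its mean direction.  Because κ
is shared and held fixed, the EM updates are closed-form: the E-step is a
softmax of ``κ μ_hᵀ x + log α_h`` and the M-step sets each mean to the
normalized resultant of its posterior-weighted points.

``stability_scan`` implements the reproducibility diagnostic used to choose
``k`` and κ: the full clustering procedure is repeated, centroid sets are
aligned across repeats by greedy maximal-cosine matching, and the variance
of the centroid coordinates is reported — small variance indicates a stable,
reproducible clustering at that parameter setting.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.special import ive

from .data_io import GeneMatrix

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-10


@dataclass
class SpectralEmbedding:
    """Unit-norm spectral coordinates, one row per gene."""

    gene_ids: list[str]
    coords: np.ndarray  # (n_genes, k), rows unit-norm

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.coords, axis=1)
        if not np.allclose(norms, 1.0, atol=_NORM_TOL):
            raise ValueError("embedding rows must have unit Euclidean norm")

    @property
    def n_genes(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


@dataclass
class SoftClusterModel:
    """Fitted vMF mixture: unit-norm means, mixing weights, fixed κ."""

    k: int
    kappa: float
    means: np.ndarray        # (k, d), unit rows
    weights: np.ndarray      # (k,), sums to 1
    posteriors: np.ndarray   # (n, k), rows sum to 1
    log_likelihood: float
    gene_ids: list[str]
    seed: int | None = None
    restart_index: int = 0
    n_iter: int = 0
    converged: bool = True
    #: smallest per-iteration log-likelihood increase observed over all
    #: restarts; EM guarantees this is ≥ 0 up to floating-point error
    min_loglik_increase: float = 0.0
    #: largest deviations from the normalization invariants seen after any
    #: EM step of any restart
    max_invariant_error: float = 0.0

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "kappa": self.kappa,
            "means": self.means.tolist(),
            "weights": self.weights.tolist(),
            "log_likelihood": self.log_likelihood,
            "seed": self.seed,
            "restart_index": self.restart_index,
        }

    def posterior_frame(self) -> pd.DataFrame:
        cols = [f"cluster_{h + 1}" for h in range(self.k)]
        return pd.DataFrame(self.posteriors, index=self.gene_ids, columns=cols)


@dataclass
class StabilityReport:
    """Centroid-coordinate variance per (k, κ) over repeated clusterings."""

    variances: dict[tuple[int, float], float]
    repeats: int

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"k": k, "kappa": kappa, "centroid_variance": v}
            for (k, kappa), v in sorted(self.variances.items())
        ]
        return pd.DataFrame(rows)


def build_similarity(x: GeneMatrix) -> pd.DataFrame:
    """Row-cosine similarity of genes, negatives clipped to zero.

    Genes whose rows have zero norm carry no directional information and are
    dropped with a warning.
    """
    values = x.values
    if values.shape[0] < 2 or values.shape[1] < 1:
        raise ValueError("similarity needs at least two genes and one feature")
    norms = np.linalg.norm(values, axis=1)
    keep = norms > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("build_similarity: dropped %d zero-norm gene row(s)", n_dropped)
    genes = [g for g, ok in zip(x.gene_ids, keep) if ok]
    unit = values[keep] / norms[keep, None]
    w = unit @ unit.T
    np.clip(w, 0.0, None, out=w)
    w = (w + w.T) / 2.0  # enforce exact symmetry against round-off
    return pd.DataFrame(w, index=genes, columns=genes)


def build_laplacian(w: pd.DataFrame) -> pd.DataFrame:
    """Normalized graph Laplacian ``I − D^{-1/2} W D^{-1/2}``."""
    values = np.asarray(w, dtype=float)
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    if (values < 0).any():
        raise ValueError("similarity matrix must be non-negative")
    degree = values.sum(axis=1)
    if (degree <= 0).any():
        gene = w.index[int(np.argmax(degree <= 0))]
        raise ValueError(f"gene {gene!r} has zero degree in the similarity graph")
    inv_sqrt = 1.0 / np.sqrt(degree)
    lap = -values * inv_sqrt[:, None] * inv_sqrt[None, :]
    np.fill_diagonal(lap, lap.diagonal() + 1.0)
    lap = (lap + lap.T) / 2.0
    return pd.DataFrame(lap, index=w.index, columns=w.columns)


def embed(laplacian: pd.DataFrame, k: int) -> SpectralEmbedding:
    """Coordinates from the eigenvectors of the ``k`` smallest eigenvalues.

    Rows are re-normalized to the unit sphere, the support of the vMF
    mixture fitted downstream.
    """
    n = laplacian.shape[0]
    if k < 2:
        raise ValueError("embedding dimension k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genes ({n})")
    values = np.asarray(laplacian, dtype=float)
    _, vectors = eigh(values, subset_by_index=[0, k - 1])
    norms = np.linalg.norm(vectors, axis=1)
    if (norms < 1e-12).any():
        raise ValueError("degenerate zero row in spectral embedding")
    coords = vectors / norms[:, None]
    return SpectralEmbedding(list(laplacian.index), coords)


def log_vmf_normalizer(dim: int, kappa: float) -> float:
    """``log c_d(κ)`` computed with exponentially scaled Bessel functions."""
    nu = dim / 2.0 - 1.0
    log_bessel = np.log(ive(nu, kappa)) + kappa
    return nu * np.log(kappa) - (dim / 2.0) * np.log(2.0 * np.pi) - log_bessel


def _mixture_estep(
    coords: np.ndarray, means: np.ndarray, log_weights: np.ndarray, kappa: float, log_const: float
) -> tuple[np.ndarray, float]:
    logits = kappa * coords @ means.T + log_weights[None, :]
    # inline log-sum-exp: the matrices are small and called thousands of times
    top = logits.max(axis=1)
    shifted = np.exp(logits - top[:, None])
    row_sum = shifted.sum(axis=1)
    lse = top + np.log(row_sum)
    posteriors = shifted / row_sum[:, None]
    loglik = float(lse.sum() + coords.shape[0] * log_const)
    return posteriors, loglik


def _init_means(coords: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.choice(coords.shape[0], size=k, replace=False)
    return coords[idx].copy()


def fit_movmf(
    embedding: SpectralEmbedding,
    k: int,
    kappa: float = 10.0,
    n_restarts: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> SoftClusterModel:
    """Fit a vMF mixture by EM with multiple random restarts.

    Each restart initializes the means at ``k`` distinct embedded points with
    equal weights and iterates EM until the relative log-likelihood change
    falls below ``tol``; the restart with the highest final log-likelihood is
    returned.  κ is shared across components and never updated.  A restart
    that produces a degenerate component (vanishing resultant or weight) is
    re-initialized a few times and discarded with a warning if it keeps
    failing.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if n_restarts < 1:
        raise ValueError("n_restarts must be at least 1")
    coords = embedding.coords
    n, d = coords.shape
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points ({n})")

    log_const = log_vmf_normalizer(d, kappa)
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = master.spawn(n_restarts)

    best: dict | None = None
    min_increase = np.inf
    max_inv_err = 0.0

    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        outcome = None
        for _attempt in range(5):
            outcome = _run_em(coords, k, kappa, log_const, rng, tol, max_iter)
            if outcome is not None:
                break
        if outcome is None:
            logger.warning("fit_movmf: restart %d discarded (persistent degeneracy)", r)
            continue
        min_increase = min(min_increase, outcome["min_increase"])
        max_inv_err = max(max_inv_err, outcome["max_inv_err"])
        if not np.isfinite(outcome["loglik"]):
            logger.warning("fit_movmf: restart %d discarded (non-finite likelihood)", r)
            continue
        if best is None or outcome["loglik"] > best["loglik"]:
            best = outcome
            best["restart"] = r

    if best is None:
        raise RuntimeError("all EM restarts failed")

    seed_val = None
    if not isinstance(seed, np.random.SeedSequence):
        seed_val = seed
    return SoftClusterModel(
        k=k,
        kappa=kappa,
        means=best["means"],
        weights=best["weights"],
        posteriors=best["posteriors"],
        log_likelihood=best["loglik"],
        gene_ids=embedding.gene_ids,
        seed=seed_val,
        restart_index=best["restart"],
        n_iter=best["n_iter"],
        converged=best["converged"],
        min_loglik_increase=float(min_increase) if np.isfinite(min_increase) else 0.0,
        max_invariant_error=float(max_inv_err),
    )


def _run_em(
    coords: np.ndarray,
    k: int,
    kappa: float,
    log_const: float,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> dict | None:
    """One EM run; returns None on degeneracy so the caller can re-initialize."""
    means = _init_means(coords, k, rng)
    weights = np.full(k, 1.0 / k)
    prev = -np.inf
    min_increase = np.inf
    max_inv_err = 0.0
    converged = False
    n_iter = 0

    for it in range(max_iter):
        posteriors, loglik = _mixture_estep(coords, means, np.log(weights), kappa, log_const)
        if not np.isfinite(loglik):
            return None
        if it > 0:
            min_increase = min(min_increase, loglik - prev)
        if it > 0 and abs(loglik - prev) <= tol * (1.0 + abs(prev)):
            converged = True
            n_iter = it
            break
        prev = loglik

        resultant = posteriors.T @ coords
        resultant_norm = np.linalg.norm(resultant, axis=1)
        weights = posteriors.mean(axis=0)
        if (resultant_norm < 1e-12).any() or (weights < 1e-10).any():
            return None
        means = resultant / resultant_norm[:, None]
        max_inv_err = max(
            max_inv_err,
            float(abs(np.linalg.norm(means, axis=1) - 1.0).max()),
            float(abs(weights.sum() - 1.0)),
            float(abs(posteriors.sum(axis=1) - 1.0).max()),
        )
        n_iter = it + 1

    # final E-step so stored posteriors / likelihood match the stored params
    posteriors, loglik = _mixture_estep(coords, means, np.log(weights), kappa, log_const)
    if np.isfinite(prev):
        min_increase = min(min_increase, loglik - prev)
    return {
        "means": means,
        "weights": weights,
        "posteriors": posteriors,
        "loglik": loglik,
        "n_iter": n_iter,
        "converged": converged,
        "min_increase": float(min_increase) if np.isfinite(min_increase) else 0.0,
        "max_inv_err": max_inv_err,
    }


def hard_assign(model: SoftClusterModel) -> pd.Series:
    """Maximum-posterior cluster label per gene (1-based; ties → lowest)."""
    labels = model.posteriors.argmax(axis=1) + 1
    return pd.Series(labels, index=model.gene_ids, name="cluster")


def cluster_genes(
    x: GeneMatrix,
    k: int,
    kappa: float = 10.0,
    n_restarts: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> SoftClusterModel:
    """Full clustering procedure: similarity → Laplacian → embed → vMF EM."""
    w = build_similarity(x)
    lap = build_laplacian(w)
    emb = embed(lap, k)
    return fit_movmf(emb, k, kappa=kappa, n_restarts=n_restarts, seed=seed, tol=tol, max_iter=max_iter)


def _greedy_cosine_match(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Permutation aligning ``other``'s centroids to ``reference`` greedily."""
    k = reference.shape[0]
    cos = reference @ other.T
    perm = np.full(k, -1)
    used_ref = np.zeros(k, dtype=bool)
    used_oth = np.zeros(k, dtype=bool)
    for _ in range(k):
        masked = np.where(used_ref[:, None] | used_oth[None, :], -np.inf, cos)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        perm[i] = j
        used_ref[i] = True
        used_oth[j] = True
    return perm


def stability_scan(
    x: GeneMatrix,
    ks: Sequence[int] = (5, 10, 20),
    kappas: Sequence[float] = (5.0, 10.0, 20.0),
    repeats: int = 3,
    n_restarts: int = 1000,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> StabilityReport:
    """Centroid-variance diagnostic over a (k, κ) grid.

    For each setting the full clustering procedure is run ``repeats`` times
    with independent restart streams; centroid sets are aligned by greedy
    maximal-cosine matching against the first repeat, and the mean variance
    of the aligned centroid coordinates is reported.
    """
    if repeats < 2:
        raise ValueError("repeats must be at least 2")
    w = build_similarity(x)
    lap = build_laplacian(w)
    master = np.random.SeedSequence(seed)
    variances: dict[tuple[int, float], float] = {}
    for k in ks:
        emb = embed(lap, k)
        for kappa in kappas:
            centroid_sets = []
            for child in master.spawn(repeats):
                model = fit_movmf(
                    emb, k, kappa=kappa, n_restarts=n_restarts, seed=child,
                    tol=tol, max_iter=max_iter,
                )
                centroid_sets.append(model.means)
            reference = centroid_sets[0]
            aligned = [reference]
            for other in centroid_sets[1:]:
                perm = _greedy_cosine_match(reference, other)
                aligned.append(other[perm])
            stack = np.stack(aligned)  # (repeats, k, d)
            variances[(int(k), float(kappa))] = float(np.var(stack, axis=0, ddof=1).mean())
    return StabilityReport(variances=variances, repeats=repeats)
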