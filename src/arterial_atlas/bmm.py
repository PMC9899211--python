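"""Bernoulli mixture model over binary lesion masks.

Each subject's mask X_i is modelled as drawn from one of K clusters: cluster
k has prior pi_k and voxelwise Bernoulli rates mu_{k,j}, so

    P(X | pi, mu) = sum_k pi_k prod_j mu_{k,j}^{x_j} (1 - mu_{k,j})^{1-x_j}.

Fitting is plain EM with log-sum-exp normalization, Dirichlet-random
responsibility initialization, multiple restarts keeping the best final
log-likelihood, and rate clipping to [eps, 1-eps] so the likelihood stays
finite (the binary MLE hits {0,1}).  The M-step normalizes mu_k by the
cluster's effective count N_k = sum_i E[z_{i,k}] — the update consistent with
the E-step and with the K=1 case collapsing exactly to the average-method
frequency map.

Model selection follows the minimum-cluster-fraction rule: the chosen K is
the largest for which every fitted cluster retains at least a given fraction
(default 10%) of the group's subjects.

The per-territory probability map is the voxelwise maximum over cluster
rates, mu_max(j) = max_k mu_{k,j}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core_io import LesionCohort, VolumeGrid
from .average_maps import ProbMapSet

DEFAULT_EPS = 1e-6
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500
DEFAULT_N_RESTARTS = 10


class DegenerateClusterError(RuntimeError):
    """An EM restart produced a cluster with vanishing effective count."""


def clip_rates(mu: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    return np.clip(mu, eps, 1.0 - eps)


def unclip_rates(mu: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Undo rate clipping: values at the clip bounds map back to exact 0/1."""
    out = np.array(mu, dtype=float)
    out[out <= eps] = 0.0
    out[out >= 1.0 - eps] = 1.0
    return out


def _per_cluster_loglik(masks: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """(N, K) matrix of log P(X_i | mu_k), for masks (N, J) and mu (K, J).

    Uses log P = X @ log(mu/(1-mu)) + sum_j log(1-mu): exact and O(NJK) via
    one matrix product.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_mu = np.log(mu)
        log_1m = np.log1p(-mu)
        return masks @ (log_mu - log_1m).T + log_1m.sum(axis=1)


def bmm_loglik(masks: np.ndarray, pi: np.ndarray, mu: np.ndarray) -> float:
    """Total log-likelihood sum_i log sum_k pi_k P(X_i|mu_k), via log-sum-exp."""
    masks = np.asarray(masks, dtype=float).reshape(len(masks), -1)
    pi = np.asarray(pi, dtype=float)
    mu = np.asarray(mu, dtype=float).reshape(len(pi), -1)
    ll = _per_cluster_loglik(masks, mu)
    out = float(logsumexp(ll + np.log(pi), axis=1).sum())
    if not np.isfinite(out):
        raise FloatingPointError(
            "non-finite log-likelihood: rates must be clipped away from {0,1}"
        )
    return out


def e_step(masks: np.ndarray, pi: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Responsibilities E[z_{i,k}] = pi_k P(X_i|mu_k) / sum_k pi_k P(X_i|mu_k).

    Computed in log space; rows sum to one even when all clusters assign the
    subject vanishing probability.
    """
    masks = np.asarray(masks, dtype=float).reshape(len(masks), -1)
    pi = np.asarray(pi, dtype=float)
    mu = np.asarray(mu, dtype=float).reshape(len(pi), -1)
    log_r = _per_cluster_loglik(masks, mu) + np.log(pi)
    log_r -= logsumexp(log_r, axis=1, keepdims=True)
    return np.exp(log_r)


def m_step(
    masks: np.ndarray, responsibilities: np.ndarray, eps: float = DEFAULT_EPS
) -> tuple[np.ndarray, np.ndarray]:
    """Update (pi, mu): pi_k = N_k/N, mu_k = sum_i E[z_{i,k}] X_i / N_k (clipped)."""
    masks = np.asarray(masks, dtype=float).reshape(len(masks), -1)
    r = np.asarray(responsibilities, dtype=float)
    n_k = r.sum(axis=0)
    if np.any(n_k < 1e-12):
        raise DegenerateClusterError(
            f"cluster effective counts collapsed: N_k = {n_k.tolist()}"
        )
    pi = n_k / len(masks)
    mu = (r.T @ masks) / n_k[:, None]
    return pi, clip_rates(mu, eps)


@dataclass
class BMMFit:
    """A fitted per-territory Bernoulli mixture."""

    territory: str
    grid: VolumeGrid
    K: int
    pi: np.ndarray
    mu: np.ndarray  # (K, *grid.shape), clipped rates
    responsibilities: np.ndarray  # (N, K)
    loglik_trace: np.ndarray
    n_subjects: int
    seed: int
    n_restarts: int
    tol: float
    max_iter: int
    eps: float = DEFAULT_EPS
    degenerate: bool = False  # near-empty cluster warning flag

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def cluster_counts(self) -> np.ndarray:
        """Effective subject counts N_k = pi_k * N."""
        return self.pi * self.n_subjects

    def mu_volumes(self, unclipped: bool = False) -> list[np.ndarray]:
        vols = [self.mu[k].reshape(self.grid.shape) for k in range(self.K)]
        if unclipped:
            vols = [unclip_rates(v, self.eps) for v in vols]
        return vols


def _em_run(
    masks: np.ndarray, K: int, rng: np.random.Generator, tol: float,
    max_iter: int, eps: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    n = len(masks)
    # symmetric-Dirichlet responsibilities per subject, then a first M-step
    r = rng.dirichlet(np.ones(K), size=n)
    pi, mu = m_step(masks, r, eps)
    trace = [bmm_loglik(masks, pi, mu)]
    for _ in range(max_iter):
        r = e_step(masks, pi, mu)
        pi, mu = m_step(masks, r, eps)
        trace.append(bmm_loglik(masks, pi, mu))
        if trace[-1] - trace[-2] < tol:
            break
    return pi, mu, r, trace


def fit_bmm(
    masks: np.ndarray,
    K: int,
    grid: VolumeGrid,
    territory: str = "",
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    eps: float = DEFAULT_EPS,
) -> BMMFit:
    """Fit a K-cluster Bernoulli mixture by best-of-restarts EM.

    `masks` is the (N, x, y, z) stack of one territory's binary masks.
    Internally the fit runs on the union support of the masks: a voxel never
    lesioned in any subject has MLE rate 0 -> eps for every cluster and
    contributes a cluster-independent constant to the log-likelihood, which
    is added back to the trace.  Reproducible bit-for-bit from `seed`.
    """
    masks = np.asarray(masks, dtype=float)
    n = len(masks)
    if n < K:
        raise ValueError(f"need at least K={K} subjects, got {n}")
    flat = masks.reshape(n, -1)
    j_total = flat.shape[1]

    active = flat.any(axis=0)
    reduced = flat[:, active]
    # inactive voxels: every cluster's rate is eps; each subject contributes
    # (J - J_active) * log(1 - eps) regardless of cluster assignment
    const = n * (j_total - int(active.sum())) * np.log1p(-eps)

    rng = np.random.default_rng(seed)
    best = None
    degenerate = False
    for _ in range(max(1, n_restarts)):
        try:
            pi, mu_red, r, trace = _em_run(reduced, K, rng, tol, max_iter, eps)
        except DegenerateClusterError:
            degenerate = True
            continue
        if best is None or trace[-1] > best[3][-1]:
            best = (pi, mu_red, r, trace)
    if best is None:
        raise DegenerateClusterError(
            f"all {n_restarts} EM restarts degenerated for {territory or 'territory'} K={K}"
        )
    pi, mu_red, r, trace = best
    n_patterns = len(np.unique(reduced, axis=0)) if reduced.size else 1
    if n_patterns < K:
        degenerate = True
        warnings.warn(
            f"BMM fit ({territory or 'territory'}): only {n_patterns} distinct mask "
            f"patterns for K={K}; clusters are not identifiable",
            RuntimeWarning,
            stacklevel=2,
        )
    if np.any(pi * n < 0.5):
        degenerate = True
        warnings.warn(
            f"BMM fit ({territory or 'territory'}, K={K}) has a near-empty cluster",
            RuntimeWarning,
            stacklevel=2,
        )
    mu = np.full((K, j_total), eps)
    mu[:, active] = mu_red
    return BMMFit(
        territory=territory,
        grid=grid,
        K=K,
        pi=pi,
        mu=mu.reshape(K, *grid.shape),
        responsibilities=r,
        loglik_trace=np.asarray(trace) + const,
        n_subjects=n,
        seed=seed,
        n_restarts=n_restarts,
        tol=tol,
        max_iter=max_iter,
        eps=eps,
        degenerate=degenerate,
    )


def select_k(
    masks: np.ndarray,
    grid: VolumeGrid,
    territory: str = "",
    min_fraction: float = 0.10,
    k_max: int = 4,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, dict[int, BMMFit]]:
    """Choose K by the minimum-cluster-fraction rule.

    Fits K = 1..k_max and returns the largest K whose fitted effective counts
    satisfy N_k >= min_fraction * N for every cluster (always >= 1), together
    with all fits.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    n = len(masks)
    fits: dict[int, BMMFit] = {}
    chosen = 1
    for K in range(1, min(k_max, n) + 1):
        fit = fit_bmm(masks, K, grid, territory=territory, seed=seed + K, **fit_kwargs)
        fits[K] = fit
        if np.all(fit.cluster_counts >= min_fraction * n):
            chosen = K
    return chosen, fits


def mu_max_map(fit: BMMFit, unclipped: bool = True) -> np.ndarray:
    """Territory probability map P_s(j) = mu_max(j) = max_k mu_{k,j}."""
    vol = fit.mu.max(axis=0).reshape(fit.grid.shape)
    return unclip_rates(vol, fit.eps) if unclipped else vol


def bmm_prob_maps(fits: dict[str, BMMFit]) -> ProbMapSet:
    grids = {f.grid for f in fits.values()}
    if len(grids) != 1:
        raise ValueError("all fits must share one grid")
    grid = next(iter(grids))
    return ProbMapSet(
        grid=grid,
        maps={t: mu_max_map(f) for t, f in fits.items()},
        n_subjects={t: f.n_subjects for t, f in fits.items()},
        method="bmm",
    )


@dataclass
class ClusterSummary:
    """Per-cluster expectations: priors, subject counts, lesion volumes."""

    territory: str
    pi: np.ndarray
    n_k: np.ndarray  # expected subject count pi_k * N
    expected_volume_voxels: np.ndarray  # sum_j mu_{k,j}
    expected_volume_ml: np.ndarray


def round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (matches printed integer cluster counts)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def cluster_expectations(fit: BMMFit, voxel_volume_ml: float | None = None) -> ClusterSummary:
    """Expected subject count N_k = pi_k N and lesion volume E[V_k] = sum_j mu_{k,j}."""
    if voxel_volume_ml is None:
        voxel_volume_ml = fit.grid.voxel_volume_ml
    mu = unclip_rates(fit.mu.reshape(fit.K, -1), fit.eps)
    vol_vox = mu.sum(axis=1)
    return ClusterSummary(
        territory=fit.territory,
        pi=fit.pi.copy(),
        n_k=fit.pi * fit.n_subjects,
        expected_volume_voxels=vol_vox,
        expected_volume_ml=vol_vox * voxel_volume_ml,
    )


def model_moments(
    fit: BMMFit, voxel_subset: np.ndarray | None = None, max_subset: int = 500
) -> tuple[np.ndarray, np.ndarray | None]:
    """Mixture mean map E[X] = sum_k pi_k mu_k, and (optionally) the covariance
    on a small voxel subset:

        Cov = sum_k pi_k [diag(mu_k(1-mu_k)) + mu_k mu_k^T] - E[X] E[X]^T.

    Off-diagonal entries are generally nonzero when K > 1 — the mixture
    captures voxel-voxel correlation that the average method ignores.
    """
    mu = fit.mu.reshape(fit.K, -1)
    mean = (fit.pi[:, None] * mu).sum(axis=0)
    cov = None
    if voxel_subset is not None:
        voxel_subset = np.asarray(voxel_subset, dtype=int)
        if voxel_subset.size > max_subset:
            raise ValueError(
                f"covariance requested on {voxel_subset.size} voxels; limit is {max_subset}"
            )
        mus = mu[:, voxel_subset]  # (K, M)
        m = mean[voxel_subset]
        cov = np.zeros((voxel_subset.size, voxel_subset.size))
        for k in range(fit.K):
            cov += fit.pi[k] * (np.diag(mus[k] * (1 - mus[k])) + np.outer(mus[k], mus[k]))
        cov -= np.outer(m, m)
    return mean.reshape(fit.grid.shape), cov


def fit_cohort(
    cohort: LesionCohort,
    k_per_territory: dict[str, int] | None = None,
    min_fraction: float = 0.10,
    k_max: int = 4,
    seed: int = 0,
    **fit_kwargs,
) -> dict[str, BMMFit]:
    """Fit one mixture per territory present in the cohort.

    If `k_per_territory` is given those K values are used directly; otherwise
    K is chosen per territory by :func:`select_k`.
    """
    fits: dict[str, BMMFit] = {}
    for i, t in enumerate(sorted(set(cohort.group))):
        masks = cohort.territory_masks(t)
        t_seed = seed + 1000 * (i + 1)
        if k_per_territory and t in k_per_territory:
            fits[t] = fit_bmm(masks, k_per_territory[t], cohort.grid,
                              territory=t, seed=t_seed, **fit_kwargs)
        else:
            chosen, all_fits = select_k(masks, cohort.grid, territory=t,
                                        min_fraction=min_fraction, k_max=k_max,
                                        seed=t_seed, **fit_kwargs)
            fits[t] = all_fits[chosen]
    return fits
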