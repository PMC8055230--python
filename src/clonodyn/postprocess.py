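"""Posterior summaries: cluster pruning, mutation assignment, CCF trajectories.

A fitted truncation-K mixture typically concentrates its weight on a handful
of components; the rest are empty bookkeeping clusters. This module turns the
variational draws into the quantities practitioners read: per-mutation soft
membership probabilities (and the hard assignment to the highest-median
cluster), the surviving "major" clusters, continuous-time CCF reconstructions
with credible bands from the GP conditional, and posterior predictive VAF
densities for goodness-of-fit checks against the observed histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import betaln, gammaln, logsumexp

from .likelihood import THETA_CLIP
from .priors import JITTER, kernel_g

__all__ = [
    "ClusterReport",
    "membership_probabilities",
    "hard_assignment",
    "prune_clusters",
    "predict_trajectories",
    "posterior_predictive_vaf",
    "make_report",
]


@dataclass
class ClusterReport:
    """Summarized clustering output of a fit."""

    mutation_ids: list
    kept_clusters: list
    weights_posterior: np.ndarray  # posterior median w_k of the kept clusters
    weights_empirical: np.ndarray  # fraction of mutations hard-assigned to each
    membership: np.ndarray  # N x K_kept, rows sum to 1
    hard_labels: np.ndarray  # index into kept_clusters per mutation
    trajectories: dict = field(default_factory=dict)
    predictive: dict = field(default_factory=dict)
    flat_interpolated: bool = False


def _loglik_ik(fit, phi, v):
    """Per-(mutation, cluster) observation log likelihood summed over samples."""
    zeta3 = fit.zeta[:, :, None]
    theta = zeta3 * phi[None, :, :]
    eps = fit.spec.observation.error_rate
    if eps > 0.0:
        theta = eps + (1.0 - 2.0 * eps) * theta
    theta = np.clip(theta, THETA_CLIP, 1.0 - THETA_CLIP)
    r = fit.alt[:, :, None].astype(float)
    R = fit.total[:, :, None].astype(float)
    comb = gammaln(R + 1) - gammaln(r + 1) - gammaln(R - r + 1)
    if fit.spec.observation.family == "betabinomial":
        v3 = v[None, :, None]
        a = v3 * theta
        b = v3 * (1.0 - theta)
        cube = comb + betaln(r + a, R - r + b) - betaln(a, b)
    else:
        cube = comb + r * np.log(theta) + (R - r) * np.log1p(-theta)
    return cube.sum(axis=1)  # (N, K)


def membership_probabilities(fit, max_draws: int | None = None) -> np.ndarray:
    """N x K soft membership: p(z_i = k) by Bayes rule per draw, median-summarized.

    Per posterior draw, p(z_i = k) is proportional to w_k times the product of
    per-sample observation likelihoods at that draw's trajectories; the
    per-draw matrices are reduced by the elementwise median and rows are
    renormalized.
    """
    S = fit.draws["phi"].shape[0]
    use = S if max_draws is None else min(S, max_draws)
    N = fit.alt.shape[0]
    K = fit.spec.truncation
    probs = np.empty((use, N, K))
    for s in range(use):
        phi = fit.draws["phi"][s]
        v = fit.draws["v"][s] if "v" in fit.draws else None
        logw = np.log(np.maximum(fit.draws["weights"][s], 1e-300))
        ll = _loglik_ik(fit, phi, v) + logw[None, :]
        probs[s] = np.exp(ll - logsumexp(ll, axis=1)[:, None])
    med = np.median(probs, axis=0)
    return med / med.sum(axis=1, keepdims=True)


def hard_assignment(membership: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Argmax of (median) membership per row; exact ties go to the heavier cluster."""
    membership = np.asarray(membership)
    weights = np.asarray(weights)
    labels = np.empty(membership.shape[0], dtype=np.int64)
    for i, row in enumerate(membership):
        best = np.flatnonzero(row == row.max())
        labels[i] = best[np.argmax(weights[best])] if best.size > 1 else best[0]
    return labels


def prune_clusters(fit, min_weight: float = 0.02,
                   hard_labels: np.ndarray | None = None) -> list[int]:
    """Cluster ids whose posterior median weight is >= min_weight or that own
    at least one hard-assigned mutation."""
    med_w = np.median(fit.draws["weights"], axis=0)
    keep = set(np.flatnonzero(med_w >= min_weight).tolist())
    if hard_labels is not None:
        keep |= set(np.unique(hard_labels).tolist())
    return sorted(keep)


def predict_trajectories(fit, grid=None, clusters=None, credible: float = 0.95,
                         max_draws: int = 300) -> dict:
    """Continuous-time CCF reconstruction per cluster with credible bands.

    For GP families, each posterior draw of (psi at sample times, kernel
    hyperparameters) is extended to the grid by drawing from the pointwise GP
    conditional (zero prior mean); the curves are summarized by the median and
    the central ``credible`` band after the inverse-logit map. The Flat model
    has no between-sample process, so its draws are joined by straight
    segments and the result is flagged as non-inferential between samples.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 0.0 or grid.max() > 1.0:
        import warnings

        warnings.warn("grid extends outside the observed [0, 1] time range; "
                      "trajectories there are extrapolations", stacklevel=2)
    fam = fit.spec.prior_family
    S = fit.draws["phi"].shape[0]
    use = min(S, max_draws)
    K = fit.spec.truncation
    clusters = list(range(K)) if clusters is None else list(clusters)
    t = fit.times
    lo_q = 100 * (1.0 - credible) / 2.0
    rng = np.random.default_rng(fit.seed + 104729)

    curves = np.empty((use, grid.size, len(clusters)))
    if fam == "Flat":
        for s in range(use):
            phi = fit.draws["phi"][s]
            for c, k in enumerate(clusters):
                curves[s, :, c] = np.interp(grid, t, phi[:, k])
    else:
        kind = fit.spec.kernel
        for s in range(use):
            psi = fit.draws["psi"][s]
            h2 = np.atleast_1d(fit.draws["h2"][s])
            tau = np.atleast_1d(fit.draws["tau"][s])
            if fam == "GP3":
                psi_star = np.empty((grid.size, len(clusters)))
                var_star = np.empty((grid.size, len(clusters)))
                for c, k in enumerate(clusters):
                    m, q = _conditional(t, grid, kind, tau[k])
                    psi_star[:, c] = m @ psi[:, k]
                    var_star[:, c] = h2[k] * q
            else:
                m, q = _conditional(t, grid, kind, tau[0])
                psi_star = m @ psi[:, clusters]
                amp = h2[clusters] if h2.size > 1 else np.full(len(clusters), h2[0])
                var_star = q[:, None] * amp[None, :]
            draw = psi_star + np.sqrt(np.maximum(var_star, 0.0)) * rng.standard_normal(
                psi_star.shape
            )
            curves[s] = 1.0 / (1.0 + np.exp(-draw))
    out = {}
    for c, k in enumerate(clusters):
        band = np.percentile(curves[:, :, c], [lo_q, 50.0, 100.0 - lo_q], axis=0)
        out[k] = {"time": grid, "lo": band[0], "median": band[1], "hi": band[2]}
    return out


def _conditional(t, grid, kind, tau):
    """Pointwise GP conditional on the unit-amplitude Gram: (mean matrix, variance).

    Returns M_star (G x M) with conditional mean M_star @ psi, and the
    unit-amplitude conditional variance per grid point (scaled by h^2 by the
    caller). The jittered Gram matches the one used during fitting, so a grid
    point at a sample time reproduces the drawn value with ~zero variance.
    """
    G = kernel_g(kind, tau, t[:, None] - t[None, :])
    G[np.diag_indices_from(G)] += JITTER
    cf = cho_factor(G, lower=True)
    Gs = kernel_g(kind, tau, grid[:, None] - t[None, :])
    M_star = Gs @ cho_solve(cf, np.eye(t.size))
    q = (1.0 + JITTER) - np.sum(Gs * M_star, axis=1)
    return M_star, q


def posterior_predictive_vaf(fit, sample_id: str, vaf_grid=None,
                             max_draws: int = 300) -> dict:
    """Posterior predictive VAF density for one sample on a grid in [0, 1].

    Uses the sample's median depth and median clonal-VAF coefficient as the
    representative locus context, extends the count pmf continuously in the
    read count (r = vaf * depth) and renormalizes by the trapezoid rule.
    """
    if sample_id not in fit.sample_ids:
        raise KeyError(f"unknown sample {sample_id!r}; have {fit.sample_ids}")
    j = fit.sample_ids.index(sample_id)
    if vaf_grid is None:
        vaf_grid = np.linspace(0.0, 1.0, 201)
    vaf_grid = np.asarray(vaf_grid, dtype=float)
    depth = float(np.median(fit.total[:, j]))
    zbar = float(np.median(fit.zeta[:, j]))
    S = fit.draws["phi"].shape[0]
    use = min(S, max_draws)
    r = np.clip(vaf_grid * depth, 0.0, depth)
    comb = gammaln(depth + 1) - gammaln(r + 1) - gammaln(depth - r + 1)
    dens = np.zeros_like(vaf_grid)
    eps = fit.spec.observation.error_rate
    for s in range(use):
        phi_j = fit.draws["phi"][s][j]
        w = fit.draws["weights"][s]
        theta = zbar * phi_j
        if eps > 0.0:
            theta = eps + (1.0 - 2.0 * eps) * theta
        theta = np.clip(theta, THETA_CLIP, 1.0 - THETA_CLIP)
        if "v" in fit.draws:
            v = fit.draws["v"][s][j]
            a = v * theta
            b = v * (1.0 - theta)
            logpmf = (comb[:, None] + betaln(r[:, None] + a[None, :],
                                             depth - r[:, None] + b[None, :])
                      - betaln(a, b)[None, :])
        else:
            logpmf = (comb[:, None] + r[:, None] * np.log(theta)[None, :]
                      + (depth - r[:, None]) * np.log1p(-theta)[None, :])
        dens += (np.exp(logpmf) * w[None, :]).sum(axis=1) * depth
    dens /= use
    area = np.trapezoid(dens, vaf_grid)
    if area > 0:
        dens = dens / area
    return {"vaf": vaf_grid, "density": dens}


def make_report(fit, min_weight: float = 0.02, grid_points: int = 101,
                credible: float = 0.95, predictive: bool = True) -> ClusterReport:
    """Full post-processing pipeline: membership, pruning, trajectories, predictive."""
    member_full = membership_probabilities(fit)
    med_w_full = np.median(fit.draws["weights"], axis=0)
    labels_full = hard_assignment(member_full, med_w_full)
    kept = prune_clusters(fit, min_weight=min_weight, hard_labels=labels_full)
    member = member_full[:, kept]
    member = member / member.sum(axis=1, keepdims=True)
    med_w = med_w_full[kept]
    labels = hard_assignment(member, med_w)
    empirical = np.bincount(labels, minlength=len(kept)) / labels.size
    grid = np.linspace(0.0, 1.0, grid_points)
    traj = predict_trajectories(fit, grid, clusters=kept, credible=credible)
    report = ClusterReport(
        mutation_ids=list(fit.mutation_ids),
        kept_clusters=kept,
        weights_posterior=med_w / med_w.sum(),
        weights_empirical=empirical,
        membership=member,
        hard_labels=labels,
        trajectories=traj,
        flat_interpolated=fit.spec.prior_family == "Flat",
    )
    if predictive:
        for sid in fit.sample_ids:
            report.predictive[sid] = posterior_predictive_vaf(fit, sid)
    return report
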