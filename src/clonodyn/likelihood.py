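"""Observation models for alt-read counts and the marginalized mixture likelihood.

Read counts at a mutated locus are modelled as binomial draws around the
expected VAF, or beta-binomial draws when sequencing exhibits over-dispersion:
r ~ BBin(R, v*theta, v*(1-theta)) with sample-specific precision v (binomial is
the v -> infinity limit). The cluster assignment of each mutation is
marginalized analytically, giving a log-sum-exp mixture over the truncated
stick-breaking weights — required for gradient-based variational inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, digamma, gammaln, logsumexp

__all__ = [
    "ObservationSpec",
    "THETA_CLIP",
    "betabinomial_logpmf",
    "binomial_logpmf",
    "error_adjusted_theta",
    "mixture_loglik",
    "loglik_cube",
]

#: expected VAF is clipped to [THETA_CLIP, 1-THETA_CLIP] before evaluating the
#: observation model, so boundary CCFs never produce degenerate beta shapes
THETA_CLIP = 1e-9


@dataclass(frozen=True)
class ObservationSpec:
    """Choice of count model: family, dispersion sharing, optional error rate."""

    family: str = "betabinomial"
    dispersion_sharing: str = "per_sample"
    precision: float = 100.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "betabinomial"):
            raise ValueError(f"unknown observation family {self.family!r}")
        if self.dispersion_sharing not in ("per_sample", "shared"):
            raise ValueError("dispersion_sharing must be 'per_sample' or 'shared'")
        if self.family == "betabinomial" and self.precision <= 0:
            raise ValueError("beta-binomial precision must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")


def betabinomial_logpmf(r, R, theta, v):
    """Exact beta-binomial log pmf with shapes a = v*theta, b = v*(1-theta)."""
    r = np.asarray(r)
    R = np.asarray(R)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0.0) or np.any(theta >= 1.0):
        raise ValueError("theta must lie strictly in (0, 1); clip boundary CCFs first")
    a = v * theta
    b = v * (1.0 - theta)
    return (
        gammaln(R + 1)
        - gammaln(r + 1)
        - gammaln(R - r + 1)
        + betaln(r + a, R - r + b)
        - betaln(a, b)
    )


def binomial_logpmf(r, R, theta):
    """Standard binomial log pmf; tolerates theta in {0, 1} with -inf where impossible."""
    r = np.asarray(r, dtype=float)
    R = np.asarray(R, dtype=float)
    theta = np.asarray(theta, dtype=float)
    comb = gammaln(R + 1) - gammaln(r + 1) - gammaln(R - r + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(r == 0, 0.0, r * np.log(theta))
        term2 = np.where(R == r, 0.0, (R - r) * np.log1p(-theta))
    return comb + term1 + term2


def error_adjusted_theta(theta, eps: float):
    """Mix the expected VAF with a symmetric per-base misread rate.

    theta' = eps*(1-theta) + (1-eps)*theta maps [0,1] into [eps, 1-eps] and is
    the identity at eps = 0. This symmetric form is a documented stand-in for
    an error model whose exact shape is not pinned down; it captures the floor
    that sequencing error places under the VAF of absent mutations.
    """
    if not 0.0 <= eps < 0.5:
        raise ValueError("error rate must lie in [0, 0.5)")
    theta = np.asarray(theta, dtype=float)
    return eps * (1.0 - theta) + (1.0 - eps) * theta


def _clip_theta(theta):
    return np.clip(theta, THETA_CLIP, 1.0 - THETA_CLIP)


def loglik_cube(alt, total, zeta, phi, ospec: ObservationSpec, precisions=None):
    """Per-(mutation, sample, cluster) observation log pmf, shape (N, M, K).

    ``alt``, ``total`` and ``zeta`` are N x M arrays, ``phi`` is M x K;
    ``precisions`` is a length-M vector of beta-binomial precisions (ignored
    for the binomial family).
    """
    theta = zeta[:, :, None] * phi[None, :, :]
    if ospec.error_rate > 0.0:
        theta = error_adjusted_theta(theta, ospec.error_rate)
    theta = _clip_theta(theta)
    r = alt[:, :, None]
    R = total[:, :, None]
    if ospec.family == "binomial":
        return binomial_logpmf(r, R, theta)
    v = np.asarray(precisions if precisions is not None else np.full(zeta.shape[1], ospec.precision))
    return betabinomial_logpmf(r, R, theta, v[None, :, None])


def mixture_loglik(table, phi, weights, ctx=None, ospec: ObservationSpec | None = None,
                   precisions=None) -> float:
    """Marginalized mixture log likelihood of a mutation table.

    sum_i log sum_k w_k exp( sum_j log p(r_ij | R_ij, zeta_ij * phi_jk) ),
    evaluated with log-sum-exp stabilization. ``table`` may be a MutationTable
    (zeta taken from its resolved locus contexts) or a dict with arrays
    ``alt``, ``total``, ``zeta``.
    """
    ospec = ospec or ObservationSpec()
    if isinstance(table, dict):
        alt, total, zeta = table["alt"], table["total"], table["zeta"]
    else:
        alt, total, zeta = table.alt, table.total, table.zeta()
    phi = np.asarray(phi, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    if phi.shape[1] != w.size:
        raise ValueError("phi column count must match number of weights")
    cube = loglik_cube(alt, total, zeta, phi, ospec, precisions)
    per_ik = cube.sum(axis=1)  # (N, K)
    return float(np.sum(logsumexp(per_ik + np.log(w)[None, :], axis=1)))


# -- derivatives used by the VI engine ---------------------------------------

def dloglik_dtheta(alt, total, theta, family: str, v=None):
    """d log pmf / d theta for either family (theta already clipped)."""
    r = alt
    R = total
    if family == "binomial":
        with np.errstate(divide="ignore", invalid="ignore"):
            return r / theta - (R - r) / (1.0 - theta)
    a = v * theta
    b = v * (1.0 - theta)
    return v * (digamma(r + a) - digamma(a) - digamma(R - r + b) + digamma(b))


def dloglik_dv(alt, total, theta, v):
    """d beta-binomial log pmf / d precision v."""
    a = v * theta
    b = v * (1.0 - theta)
    return (
        theta * (digamma(alt + a) - digamma(a))
        + (1.0 - theta) * (digamma(total - alt + b) - digamma(b))
        - digamma(total + v)
        + digamma(v)
    )
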