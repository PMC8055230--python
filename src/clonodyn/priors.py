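"""Priors: stick-breaking DP weights, stationary kernels and GP covariances.

The mixture weights follow a truncated stick-breaking construction with
Beta(1, alpha) stick fractions and the heavy-tailed prior (1+alpha)^-2 on the
concentration. Cluster trajectories of logit-CCF are given zero-mean Gaussian
process priors built from one of four Matern-family kernels; the multi-output
variants couple clusters through a separable kernel g_tau(t,t') * Sigma_K with
Sigma_K either diagonal (per-cluster amplitudes), a full DCD correlation
structure with an LKJ prior, or a block-diagonal form with per-cluster
amplitude and time scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "KERNEL_KINDS",
    "KernelSpec",
    "MultiOutputSpec",
    "LatentTrajectories",
    "stick_breaking",
    "alpha_prior_logdensity",
    "kernel_g",
    "build_cov_gp0",
    "build_cov_multi",
    "trajectory_log_prior",
    "corr_cholesky_from_unconstrained",
    "lkj_logdensity_unconstrained",
]

KERNEL_KINDS = ("Exp", "Mat32", "Mat52", "ExpQ")

#: diagonal jitter factor applied (times h^2) before factorizing Gram matrices
JITTER = 1e-6


@dataclass(frozen=True)
class KernelSpec:
    """Stationary kernel: kappa(t, t') = amplitude_sq * g_tau(t, t')."""

    kind: str
    tau: float = 1.0
    amplitude_sq: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; choose from {KERNEL_KINDS}")
        if self.tau <= 0 or self.amplitude_sq <= 0:
            raise ValueError("tau and amplitude_sq must be positive")


@dataclass
class MultiOutputSpec:
    """Between-cluster covariance structure for the multi-output GP variants.

    GP1: Sigma_K = diag(h_k^2); GP2: Sigma_K = D C D with C ~ LKJ(eta);
    GP3: block-diagonal with per-cluster (h_k^2, tau_k).
    """

    variant: str
    amplitudes_sq: np.ndarray = field(default_factory=lambda: np.ones(1))
    correlation: np.ndarray | None = None
    lkj_eta: float = 2.0
    taus: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("GP0", "GP1", "GP2", "GP3"):
            raise ValueError(f"unknown GP variant {self.variant!r}")
        self.amplitudes_sq = np.asarray(self.amplitudes_sq, dtype=float)
        if np.any(self.amplitudes_sq <= 0):
            raise ValueError("amplitudes_sq must be positive")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
                raise ValueError("correlation must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError("correlation matrix must be positive semi-definite")
            self.correlation = C
        if self.taus is not None:
            self.taus = np.asarray(self.taus, dtype=float)
            if np.any(self.taus <= 0):
                raise ValueError("taus must be positive")


@dataclass
class LatentTrajectories:
    """M x K matrices of logit-CCF (psi) and CCF (phi) cluster trajectories."""

    psi: np.ndarray

    @property
    def phi(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.psi))


def stick_breaking(sticks: np.ndarray) -> np.ndarray:
    """Map stick fractions u_1..u_K in (0,1) to mixture weights on the simplex.

    w_1 = u_1 and w_k = u_k * prod_{l<k} (1 - u_l); the last weight absorbs the
    residual stick so the output sums to one exactly (truncation closure).
    """
    u = np.asarray(sticks, dtype=float)
    if u.ndim != 1 or u.size < 1:
        raise ValueError("sticks must be a non-empty 1-d array")
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("stick fractions must lie strictly in (0, 1)")
    u = u.copy()
    u[-1] = 1.0  # closure: final stick takes all remaining mass
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - u[:-1])])
    return u * remaining


def alpha_prior_logdensity(alpha: float) -> float:
    """Log density of the DP concentration prior p(alpha) = (1 + alpha)^-2.

    Equivalent to a uniform prior on 1/(1+alpha); proper on (0, inf), heavier
    tailed than Exp(1).
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return -2.0 * np.log1p(alpha)


def kernel_g(kind: str, tau: float, dt) -> np.ndarray:
    """Unit-amplitude stationary correlation g_tau at time difference dt.

    Exp:   exp(-tau |dt|)
    Mat32: (1 + sqrt(3) tau |dt|) exp(-sqrt(3) tau |dt|)
    Mat52: (1 + sqrt(5) tau |dt| + 5 tau^2 dt^2 / 3) exp(-sqrt(5) tau |dt|)
    ExpQ:  exp(-tau dt^2 / 2)

    All satisfy g(0) = 1 and decay monotonically in |dt|; they are ordered by
    increasing smoothness at the origin.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    a = np.abs(np.asarray(dt, dtype=float))
    if kind == "Exp":
        return np.exp(-tau * a)
    if kind == "Mat32":
        s = np.sqrt(3.0) * tau * a
        return (1.0 + s) * np.exp(-s)
    if kind == "Mat52":
        s = np.sqrt(5.0) * tau * a
        return (1.0 + s + 5.0 * tau * tau * a * a / 3.0) * np.exp(-s)
    if kind == "ExpQ":
        return np.exp(-0.5 * tau * a * a)
    raise ValueError(f"unknown kernel kind {kind!r}; choose from {KERNEL_KINDS}")


def _gram(times: np.ndarray, kind: str, tau: float) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    return kernel_g(kind, tau, t[:, None] - t[None, :])


def build_cov_gp0(times, spec: KernelSpec) -> np.ndarray:
    """M x M covariance h^2 * g_tau(t_j, t_j') shared by all cluster columns."""
    K = spec.amplitude_sq * _gram(np.asarray(times, dtype=float), spec.kind, spec.tau)
    K[np.diag_indices_from(K)] += JITTER * spec.amplitude_sq
    return K


def build_cov_multi(times, kind: str, mspec: MultiOutputSpec) -> np.ndarray:
    """MK x MK covariance of vec(Psi) for the multi-output variants.

    GP1/GP2 use the separable factorization Lambda = Sigma_K (x) G_M consistent
    with column-stacking vec(Psi) (columns = clusters); GP3 is block-diagonal
    with cluster-specific Gram blocks h_k^2 * g_{tau_k}.
    """
    t = np.asarray(times, dtype=float)
    h2 = mspec.amplitudes_sq
    K = h2.size
    if mspec.variant == "GP1":
        sigma = np.diag(h2)
    elif mspec.variant == "GP2":
        C = mspec.correlation if mspec.correlation is not None else np.eye(K)
        h = np.sqrt(h2)
        sigma = h[:, None] * C * h[None, :]
    elif mspec.variant == "GP3":
        taus = mspec.taus if mspec.taus is not None else np.full(K, 1.0)
        blocks = []
        for k in range(K):
            B = h2[k] * _gram(t, kind, taus[k])
            B[np.diag_indices_from(B)] += JITTER * h2[k]
            blocks.append(B)
        out = np.zeros((K * t.size, K * t.size))
        M = t.size
        for k, B in enumerate(blocks):
            out[k * M : (k + 1) * M, k * M : (k + 1) * M] = B
        return out
    else:
        raise ValueError("build_cov_multi handles GP1, GP2, GP3 only")
    if np.linalg.eigvalsh(sigma).min() < -1e-10:
        raise ValueError("between-cluster covariance is not positive semi-definite")
    tau = mspec.taus[0] if mspec.taus is not None else 1.0
    G = _gram(t, kind, tau)
    lam = np.kron(sigma, G)
    lam[np.diag_indices_from(lam)] += JITTER * np.max(h2)
    return lam


def trajectory_log_prior(psi: np.ndarray, cov: np.ndarray, variant: str) -> float:
    """Zero-mean multivariate normal log density of the latent trajectories.

    For GP0 the M x M covariance is applied independently to each of the K
    cluster columns; for GP1-GP3 the MK x MK covariance acts on vec(psi)
    (column stacking).
    """
    psi = np.asarray(psi, dtype=float)
    M, K = psi.shape
    if variant == "GP0":
        if cov.shape != (M, M):
            raise ValueError(f"GP0 expects an {M}x{M} covariance, got {cov.shape}")
        cf = cho_factor(cov, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        quad = float(np.sum(psi * cho_solve(cf, psi)))
        return -0.5 * (K * M * np.log(2.0 * np.pi) + K * logdet + quad)
    if cov.shape != (M * K, M * K):
        raise ValueError(f"{variant} expects an {M * K}x{M * K} covariance, got {cov.shape}")
    v = psi.reshape(-1, order="F")  # vec() by column stacking
    cf = cho_factor(cov, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    quad = float(v @ cho_solve(cf, v))
    return -0.5 * (M * K * np.log(2.0 * np.pi) + logdet + quad)


# -- LKJ correlation-matrix transform ---------------------------------------
#
# Unconstrained vector y (length K(K-1)/2) -> canonical partial correlations
# z = tanh(y) -> lower Cholesky factor L of a correlation matrix, filling rows
# top to bottom:  L[i,j] = z_ij * sqrt(1 - sum_{j'<j} L[i,j']^2),  L[i,i] the
# residual norm.  The log |det dC/dy| used to push densities through is
#   sum log(1 - z^2) + sum log s_ij + sum_j (K-1-j) log L_jj
# with s_ij the residual norms multiplying each z.


def corr_cholesky_from_unconstrained(y: np.ndarray, K: int) -> tuple[np.ndarray, float]:
    """Map an unconstrained vector to (L, log|Jacobian|) with C = L L^T."""
    y = np.asarray(y, dtype=float)
    if y.size != K * (K - 1) // 2:
        raise ValueError(f"expected {K * (K - 1) // 2} entries for K={K}, got {y.size}")
    z = np.tanh(y)
    L = np.zeros((K, K))
    L[0, 0] = 1.0
    logjac = float(np.sum(np.log1p(-z * z)))  # d tanh
    idx = 0
    for i in range(1, K):
        rem = 1.0
        for j in range(i):
            s = np.sqrt(rem)
            L[i, j] = z[idx] * s
            logjac += np.log(s)
            rem -= L[i, j] ** 2
            idx += 1
        L[i, i] = np.sqrt(max(rem, 1e-300))
    diag = np.diag(L)
    logjac += float(np.sum((K - 1 - np.arange(K)) * np.log(diag)))
    return L, logjac


def lkj_logdensity_unconstrained(y: np.ndarray, K: int, eta: float) -> tuple[np.ndarray, float]:
    """LKJ(eta) log density of C(y) plus transform log-Jacobian; returns (L, logp).

    The unnormalized LKJ density is |C|^(eta-1) = prod_j L_jj^(2(eta-1)).
    """
    L, logjac = corr_cholesky_from_unconstrained(y, K)
    logp = 2.0 * (eta - 1.0) * float(np.sum(np.log(np.diag(L)))) + logjac
    return L, logp
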