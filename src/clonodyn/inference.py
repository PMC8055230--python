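"""Variational inference for the clonal-deconvolution models.

Every model is a truncated Dirichlet-process mixture over mutation CCFs with
one of five priors on the cluster trajectories (Flat, GP0..GP3, the GP
variants crossed with four kernels — 17 configurations in total) and a
binomial or beta-binomial read-count model. Fitting maximizes a Monte-Carlo
estimate of the evidence lower bound (ELBO) over a mean-field Gaussian
variational family placed on unconstrained transforms of all latent variables
(logit for stick fractions and CCFs, log for alpha, h^2, tau and v, tanh-based
partial correlations for the GP2 correlation matrix).

Gradients of the joint log density are analytic for the large blocks
(trajectories, sticks, dispersions, concentration) and central finite
differences for the small kernel-hyperparameter block, whose prior term costs
only a couple of tiny Cholesky factorizations to evaluate. The maximized ELBO
doubles as the model-comparison score: being a lower bound on the log
evidence it penalizes parameter-heavy models automatically.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import betaln, gammaln, logsumexp

from .likelihood import (
    THETA_CLIP,
    ObservationSpec,
    dloglik_dtheta,
    dloglik_dv,
)
from .priors import JITTER, KERNEL_KINDS, kernel_g, lkj_logdensity_unconstrained

__all__ = [
    "ModelSpec",
    "VIConfig",
    "PosteriorFit",
    "enumerate_models",
    "fit",
    "elbo_components",
    "compare_models",
    "reevaluate_elbo",
    "importance_log_evidence",
]

_FAMILIES = ("Flat", "GP0", "GP1", "GP2", "GP3")
_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified model configuration.

    ``prior_family`` is one of Flat/GP0/GP1/GP2/GP3; GP families require a
    kernel kind. ``truncation`` is the stick-breaking truncation K (default 20,
    comfortably above the cluster counts seen in longitudinal tumour data).
    """

    prior_family: str = "GP0"
    kernel: str | None = "Mat32"
    truncation: int = 20
    observation: ObservationSpec = field(default_factory=ObservationSpec)
    lkj_eta: float = 2.0

    def __post_init__(self) -> None:
        if self.prior_family not in _FAMILIES:
            raise ValueError(f"unknown prior family {self.prior_family!r}")
        if self.prior_family == "Flat":
            if self.kernel not in (None, "none"):
                raise ValueError("the Flat model takes no kernel")
            object.__setattr__(self, "kernel", None)
        else:
            if self.kernel not in KERNEL_KINDS:
                raise ValueError(
                    f"GP families require a kernel in {KERNEL_KINDS}, got {self.kernel!r}"
                )
        if self.truncation < 2:
            raise ValueError("truncation K must be at least 2")
        if self.lkj_eta <= 0:
            raise ValueError("lkj_eta must be positive")

    @property
    def name(self) -> str:
        if self.prior_family == "Flat":
            return "Flat"
        return f"{self.prior_family}-{self.kernel}"


def enumerate_models(truncation: int = 20,
                     observation: ObservationSpec | None = None) -> list[ModelSpec]:
    """The Flat model plus each GP variant crossed with each kernel (17 specs)."""
    obs = observation or ObservationSpec()
    out = [ModelSpec(prior_family="Flat", kernel=None, truncation=truncation, observation=obs)]
    for fam in ("GP0", "GP1", "GP2", "GP3"):
        for kern in KERNEL_KINDS:
            out.append(ModelSpec(prior_family=fam, kernel=kern,
                                 truncation=truncation, observation=obs))
    return out


def model_by_name(name: str, **kwargs) -> ModelSpec:
    """Look up a ModelSpec by its registry name (e.g. 'GP0-Mat32')."""
    for spec in enumerate_models(**kwargs):
        if spec.name == name:
            return spec
    valid = ", ".join(s.name for s in enumerate_models())
    raise KeyError(f"unknown model {name!r}; valid names: {valid}")


@dataclass
class VIConfig:
    """Optimizer and Monte-Carlo settings for the ADVI fit."""

    max_iters: int = 20000
    learning_rate: float = 0.02
    mc_samples_per_step: int = 1
    seed: int = 0
    convergence_window: int = 500
    convergence_rel_tol: float = 1e-4
    n_posterior_draws: int = 1000
    n_elbo_draws: int = 500

    def __post_init__(self) -> None:
        for name in ("max_iters", "learning_rate", "mc_samples_per_step",
                     "convergence_window", "convergence_rel_tol",
                     "n_posterior_draws", "n_elbo_draws"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PosteriorFit:
    """Variational posterior draws plus the ELBO trace and bookkeeping."""

    spec: ModelSpec
    seed: int
    draws: dict
    elbo_trace: np.ndarray
    final_elbo: float
    final_elbo_se: float
    energy: float
    entropy: float
    n_iterations: int
    converged: bool
    data_fingerprint: str
    q_mu: np.ndarray
    q_log_sigma: np.ndarray
    # data views needed by post-processing
    mutation_ids: list
    sample_ids: list
    times: np.ndarray
    alt: np.ndarray
    total: np.ndarray
    zeta: np.ndarray


def _fingerprint(alt, total, zeta, times) -> str:
    h = hashlib.sha256()
    for arr in (alt, total, zeta, times):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class _Advi:
    """Joint log density with blockwise gradients for one (data, spec) pair."""

    def __init__(self, alt, total, zeta, times, spec: ModelSpec):
        self.alt = alt.astype(float)
        self.total = total.astype(float)
        self.zeta = zeta
        self.times = np.asarray(times, dtype=float)
        self.spec = spec
        self.N, self.M = alt.shape
        self.K = spec.truncation
        self.family = spec.prior_family
        self.obs = spec.observation
        self.betabin = self.obs.family == "betabinomial"
        self.n_v = 0
        if self.betabin:
            self.n_v = 1 if self.obs.dispersion_sharing == "shared" else self.M
        K = self.K
        self.n_hyper = {"Flat": 0, "GP0": 2, "GP1": K + 1,
                        "GP2": K + 1 + K * (K - 1) // 2, "GP3": 2 * K}[self.family]
        self.blocks = [("alpha", 1), ("sticks", K - 1), ("psi", self.M * K),
                       ("hyper", self.n_hyper), ("v", self.n_v)]
        self.slices = {}
        off = 0
        for name, size in self.blocks:
            self.slices[name] = slice(off, off + size)
            off += size
        self.dim = off
        # constant binomial-coefficient part of the count pmf
        self.log_comb = (gammaln(self.total + 1) - gammaln(self.alt + 1)
                         - gammaln(self.total - self.alt + 1))
        self.eps = self.obs.error_rate

    # -- GP prior term -------------------------------------------------------

    def _gram(self, tau: float) -> np.ndarray:
        t = self.times
        G = kernel_g(self.spec.kernel, tau, t[:, None] - t[None, :])
        G[np.diag_indices_from(G)] += JITTER
        return G

    def _gp_term(self, hz, psi, want_grad_psi=False):
        """GP prior on psi plus hyperparameter priors; optionally d/dpsi."""
        M, K = psi.shape
        fam = self.family
        if fam == "GP0":
            h2, tau = np.exp(hz[0]), np.exp(hz[1])
            Km = h2 * self._gram(tau)
            cf = cho_factor(Km, lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            S = cho_solve(cf, psi)
            lp = -0.5 * (M * K * _LOG2PI + K * logdet + float(np.sum(psi * S)))
            lp += (-h2 + hz[0]) + (-tau + hz[1])  # Gamma(1,1) priors + log-Jacobians
            return (lp, -S) if want_grad_psi else (lp, None)
        if fam in ("GP1", "GP2"):
            h2 = np.exp(hz[:K])
            tau = np.exp(hz[K])
            h = np.sqrt(h2)
            G = self._gram(tau)
            cfG = cho_factor(G, lower=True)
            logdetG = 2.0 * np.sum(np.log(np.diag(cfG[0])))
            lkj_lp = 0.0
            if fam == "GP2":
                L, lkj_lp = lkj_logdensity_unconstrained(hz[K + 1:], K, self.spec.lkj_eta)
                SigL = h[:, None] * L  # lower Cholesky of Sigma = D C D
            else:
                SigL = np.diag(h)
            logdetS = 2.0 * np.sum(np.log(np.diag(SigL)))
            B = cho_solve(cfG, psi)  # G^-1 Psi
            A = psi.T @ B  # Psi^T G^-1 Psi
            X = cho_solve((SigL, True), A)  # Sigma^-1 A
            lp = -0.5 * (M * K * _LOG2PI + K * logdetG + M * logdetS + float(np.trace(X)))
            lp += float(np.sum(-h2 + hz[:K])) + (-tau + hz[K]) + lkj_lp
            if not want_grad_psi:
                return lp, None
            sig_inv = cho_solve((SigL, True), np.eye(K))
            return lp, -B @ sig_inv
        if fam == "GP3":
            h2 = np.exp(hz[:K])
            taus = np.exp(hz[K:])
            lp = 0.0
            grad = np.empty_like(psi) if want_grad_psi else None
            for k in range(K):
                Km = h2[k] * self._gram(taus[k])
                cf = cho_factor(Km, lower=True)
                logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
                S = cho_solve(cf, psi[:, k])
                lp += -0.5 * (M * _LOG2PI + logdet + float(psi[:, k] @ S))
                if want_grad_psi:
                    grad[:, k] = -S
            lp += float(np.sum(-h2 + hz[:K])) + float(np.sum(-taus + hz[K:]))
            return lp, grad
        raise AssertionError(fam)

    # -- likelihood term -----------------------------------------------------

    def _lik_term(self, logw, phi, v, want_grads=False):
        zeta3 = self.zeta[:, :, None]
        theta_raw = zeta3 * phi[None, :, :]
        if self.eps > 0.0:
            theta_raw = self.eps + (1.0 - 2.0 * self.eps) * theta_raw
        lo, hi = THETA_CLIP, 1.0 - THETA_CLIP
        theta = np.clip(theta_raw, lo, hi)
        r = self.alt[:, :, None]
        R = self.total[:, :, None]
        if self.betabin:
            v3 = v[None, :, None]
            a = v3 * theta
            b = v3 * (1.0 - theta)
            cube = (self.log_comb[:, :, None] + betaln(r + a, R - r + b) - betaln(a, b))
        else:
            cube = (self.log_comb[:, :, None] + r * np.log(theta)
                    + (R - r) * np.log1p(-theta))
        per_ik = cube.sum(axis=1) + logw[None, :]
        Li = logsumexp(per_ik, axis=1)
        loglik = float(Li.sum())
        if not want_grads:
            return loglik, None, None, None
        resp = np.exp(per_ik - Li[:, None])  # (N, K) responsibilities
        grad_logw = resp.sum(axis=0)
        interior = (theta_raw > lo) & (theta_raw < hi)
        if self.betabin:
            dtheta = dloglik_dtheta(r, R, theta, "betabinomial", v3)
        else:
            dtheta = dloglik_dtheta(r, R, theta, "binomial")
        scale = (1.0 - 2.0 * self.eps) if self.eps > 0.0 else 1.0
        dtheta = np.where(interior, dtheta, 0.0) * zeta3 * scale
        grad_phi = np.einsum("ik,ijk->jk", resp, dtheta)
        grad_v = None
        if self.betabin:
            dv = dloglik_dv(r, R, theta, v3)
            grad_v = np.einsum("ik,ijk->j", resp, dv)
        return loglik, grad_logw, grad_phi, grad_v

    # -- joint density -------------------------------------------------------

    def unpack(self, z):
        s = self.slices
        alpha = np.exp(z[s["alpha"]][0])
        u = _sigmoid(z[s["sticks"]])
        psi = z[s["psi"]].reshape(self.M, self.K)
        hz = z[s["hyper"]]
        v = np.exp(z[s["v"]]) if self.n_v else None
        return alpha, u, psi, hz, v

    @staticmethod
    def _log_weights(u):
        """log stick-breaking weights with closure on the last component."""
        log1mu = np.log1p(-u)
        csum = np.concatenate([[0.0], np.cumsum(log1mu)])
        return np.concatenate([np.log(u) + csum[:-1], [csum[-1]]])

    def logp(self, z, want_grad=False):
        alpha, u, psi, hz, v = self.unpack(z)
        K = self.K
        logw = self._log_weights(u)
        phi = _sigmoid(psi)
        v_full = None
        if self.n_v:
            v_full = np.full(self.M, v[0]) if self.n_v == 1 else v

        lp = 0.0
        # concentration: p(alpha) = (1+alpha)^-2, log transform
        lp += -2.0 * np.log1p(alpha) + np.log(alpha)
        # sticks: u_l ~ Beta(1, alpha), logit transform
        lp += float(np.sum(np.log(alpha) + (alpha - 1.0) * np.log1p(-u)))
        lp += float(np.sum(np.log(u) + np.log1p(-u)))
        # trajectories
        if self.family == "Flat":
            lp += float(np.sum(np.log(phi) + np.log1p(-phi)))  # uniform prior, logit jac
            grad_psi_prior = (1.0 - 2.0 * phi) if want_grad else None
        else:
            gp_lp, grad_psi_prior = self._gp_term(hz, psi, want_grad_psi=want_grad)
            lp += gp_lp
        # dispersions: 1/(1+v) ~ U(0,1) -> p(v) = (1+v)^-2, log transform
        if self.n_v:
            lp += float(np.sum(-2.0 * np.log1p(v) + np.log(v)))
        loglik, grad_logw, grad_phi, grad_v = self._lik_term(
            logw, phi, v_full, want_grads=want_grad
        )
        lp += loglik
        if not want_grad:
            return lp, None

        grad = np.zeros(self.dim)
        s = self.slices
        # alpha (z-scale): prior, stick priors
        g_alpha = (-2.0 * alpha / (1.0 + alpha) + 1.0
                   + (K - 1) + alpha * float(np.sum(np.log1p(-u))))
        grad[s["alpha"]] = g_alpha
        # sticks (z-scale): likelihood via log-weights + priors + jacobian
        Rk = grad_logw
        tail = np.concatenate([np.cumsum(Rk[::-1])[::-1][1:], [0.0]])[: K - 1]
        g_sticks = Rk[: K - 1] * (1.0 - u) - tail * u
        g_sticks += (1.0 - 2.0 * u) - u * (alpha - 1.0)
        grad[s["sticks"]] = g_sticks
        # psi
        g_psi = grad_phi * phi * (1.0 - phi) + grad_psi_prior
        grad[s["psi"]] = g_psi.ravel()
        # kernel hyperparameters: central finite differences on the prior term
        if self.n_hyper:
            gh = np.empty(self.n_hyper)
            step = 1e-5
            for i in range(self.n_hyper):
                hp = hz.copy()
                hp[i] += step
                fp, _ = self._gp_term(hp, psi)
                hp[i] -= 2.0 * step
                fm, _ = self._gp_term(hp, psi)
                gh[i] = (fp - fm) / (2.0 * step)
            grad[s["hyper"]] = gh
        # dispersions (z-scale)
        if self.n_v:
            g_v_nat = grad_v  # d loglik / dv per sample
            prior_v = -2.0 * v_full / (1.0 + v_full) + 1.0
            if self.n_v == 1:
                grad[s["v"]] = float(np.sum(g_v_nat) * v[0]) + prior_v[0]
            else:
                grad[s["v"]] = g_v_nat * v_full + prior_v
        return lp, grad

    # -- variational draws ---------------------------------------------------

    def constrain(self, z):
        """Map one unconstrained draw to interpretable parameter values."""
        alpha, u, psi, hz, v = self.unpack(z)
        out = {
            "alpha": alpha,
            "weights": np.exp(self._log_weights(u)),
            "psi": psi,
            "phi": _sigmoid(psi),
        }
        K = self.K
        if self.family == "GP0":
            out["h2"] = np.exp(hz[0])
            out["tau"] = np.exp(hz[1])
        elif self.family in ("GP1", "GP2"):
            out["h2"] = np.exp(hz[:K])
            out["tau"] = np.exp(hz[K])
            if self.family == "GP2":
                L, _ = lkj_logdensity_unconstrained(hz[K + 1:], K, self.spec.lkj_eta)
                out["corr"] = L @ L.T
        elif self.family == "GP3":
            out["h2"] = np.exp(hz[:K])
            out["tau"] = np.exp(hz[K:])
        if self.n_v:
            out["v"] = np.full(self.M, v[0]) if self.n_v == 1 else v
        return out


def _init_mu(model: _Advi, rng: np.random.Generator) -> np.ndarray:
    """Data-driven initialization: anchor cluster trajectories at observed CCFs."""
    mu = np.zeros(model.dim)
    ccf_obs = np.clip(model.alt / model.total / model.zeta, 0.02, 0.98)
    logit_obs = np.log(ccf_obs) - np.log1p(-ccf_obs)  # (N, M)
    anchors = rng.permutation(model.N)
    psi0 = np.empty((model.M, model.K))
    for k in range(model.K):
        psi0[:, k] = logit_obs[anchors[k % model.N]]
    psi0 += 0.1 * rng.standard_normal(psi0.shape)
    mu[model.slices["psi"]] = psi0.ravel()
    if model.n_v:
        mu[model.slices["v"]] = np.log(100.0)
    return mu


def fit(table, spec: ModelSpec, cfg: VIConfig | None = None) -> PosteriorFit:
    """Fit a model to a MutationTable by maximizing the ELBO.

    Deterministic given ``cfg.seed``. Returns a PosteriorFit holding posterior
    draws, the per-iteration ELBO trace, and the smoothed terminal ELBO (mean
    over fresh Monte-Carlo draws) with its standard error.
    """
    cfg = cfg or VIConfig()
    alt, total, zeta, times = table.alt, table.total, table.zeta(), table.times
    if spec.prior_family != "Flat" and len(times) < 2:
        raise ValueError("GP families require at least two samples; use the Flat model")
    model = _Advi(alt, total, zeta, times, spec)
    rng = np.random.default_rng(cfg.seed)

    mu = _init_mu(model, rng)
    log_sigma = np.full(model.dim, -2.0)
    ent_const = 0.5 * model.dim * (1.0 + _LOG2PI)

    # Adam state
    lr, b1, b2, adam_eps = cfg.learning_rate, 0.9, 0.999, 1e-8
    m_mu = np.zeros(model.dim); v_mu = np.zeros(model.dim)
    m_ls = np.zeros(model.dim); v_ls = np.zeros(model.dim)

    trace = np.empty(cfg.max_iters)
    converged = False
    n_iter = cfg.max_iters
    for it in range(cfg.max_iters):
        g_mu = np.zeros(model.dim)
        g_ls = np.zeros(model.dim)
        elbo_est = 0.0
        for _ in range(cfg.mc_samples_per_step):
            eps_draw = rng.standard_normal(model.dim)
            sigma = np.exp(log_sigma)
            z = mu + sigma * eps_draw
            lp, grad = model.logp(z, want_grad=True)
            if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
                bad = [name for name, _ in model.blocks
                       if not np.all(np.isfinite(grad[model.slices[name]]))]
                raise RuntimeError(
                    f"non-finite ELBO gradient at iteration {it} "
                    f"in block(s) {bad or ['logp']} of model {spec.name}"
                )
            g_mu += grad
            g_ls += grad * eps_draw * sigma + 1.0
            elbo_est += lp + ent_const + float(np.sum(log_sigma))
        g_mu /= cfg.mc_samples_per_step
        g_ls /= cfg.mc_samples_per_step
        trace[it] = elbo_est / cfg.mc_samples_per_step

        t = it + 1
        m_mu = b1 * m_mu + (1 - b1) * g_mu
        v_mu = b2 * v_mu + (1 - b2) * g_mu**2
        mu += lr * (m_mu / (1 - b1**t)) / (np.sqrt(v_mu / (1 - b2**t)) + adam_eps)
        m_ls = b1 * m_ls + (1 - b1) * g_ls
        v_ls = b2 * v_ls + (1 - b2) * g_ls**2
        log_sigma += lr * (m_ls / (1 - b1**t)) / (np.sqrt(v_ls / (1 - b2**t)) + adam_eps)

        w = cfg.convergence_window
        if t >= 2 * w and t % w == 0:
            ma_cur = trace[t - w:t].mean()
            ma_prev = trace[t - 2 * w:t - w].mean()
            if abs(ma_cur - ma_prev) / (abs(ma_prev) + 1e-12) < cfg.convergence_rel_tol:
                converged = True
                n_iter = t
                break
    trace = trace[:n_iter]

    # terminal ELBO from fresh draws: per-draw logp - logq, mean and MC SE
    sigma = np.exp(log_sigma)
    vals = np.empty(cfg.n_elbo_draws)
    logps = np.empty(cfg.n_elbo_draws)
    logqs = np.empty(cfg.n_elbo_draws)
    for s_i in range(cfg.n_elbo_draws):
        eps_draw = rng.standard_normal(model.dim)
        z = mu + sigma * eps_draw
        lp, _ = model.logp(z)
        lq = float(-0.5 * np.sum(eps_draw**2) - np.sum(log_sigma)
                   - 0.5 * model.dim * _LOG2PI)
        logps[s_i] = lp
        logqs[s_i] = lq
        vals[s_i] = lp - lq
    final_elbo = float(vals.mean())
    final_se = float(vals.std(ddof=1) / np.sqrt(cfg.n_elbo_draws))

    # posterior draws
    S = cfg.n_posterior_draws
    draws: dict[str, list] = {}
    for _ in range(S):
        z = mu + sigma * rng.standard_normal(model.dim)
        for key, val in model.constrain(z).items():
            draws.setdefault(key, []).append(val)
    draw_arrays = {k: np.asarray(vlist) for k, vlist in draws.items()}

    return PosteriorFit(
        spec=spec,
        seed=cfg.seed,
        draws=draw_arrays,
        elbo_trace=trace,
        final_elbo=final_elbo,
        final_elbo_se=final_se,
        energy=float(logps.mean()),
        entropy=float(-logqs.mean()),
        n_iterations=n_iter,
        converged=converged,
        data_fingerprint=_fingerprint(alt, total, zeta, times),
        q_mu=mu,
        q_log_sigma=log_sigma,
        mutation_ids=list(table.mutation_ids),
        sample_ids=[s.sample_id for s in table.samples],
        times=times,
        alt=alt,
        total=total,
        zeta=zeta,
    )


def elbo_components(fit_result: PosteriorFit) -> tuple[float, float]:
    """(energy, entropy) of the terminal ELBO estimate; they sum to the ELBO.

    Energy is the average joint log density under q; entropy is the sampled
    entropy of q. ELBO = entropy + energy.
    """
    return fit_result.energy, fit_result.entropy


def _rebuild(fit_result: PosteriorFit) -> _Advi:
    return _Advi(fit_result.alt, fit_result.total, fit_result.zeta,
                 fit_result.times, fit_result.spec)


def reevaluate_elbo(fit_result: PosteriorFit, n_draws: int = 500,
                    seed: int = 0) -> tuple[float, float]:
    """Re-estimate the terminal ELBO with fresh Monte-Carlo draws: (mean, se)."""
    model = _rebuild(fit_result)
    rng = np.random.default_rng(seed)
    sigma = np.exp(fit_result.q_log_sigma)
    vals = np.empty(n_draws)
    for i in range(n_draws):
        eps_draw = rng.standard_normal(model.dim)
        z = fit_result.q_mu + sigma * eps_draw
        lp, _ = model.logp(z)
        lq = float(-0.5 * np.sum(eps_draw**2) - np.sum(fit_result.q_log_sigma)
                   - 0.5 * model.dim * _LOG2PI)
        vals[i] = lp - lq
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_draws))


def importance_log_evidence(fit_result: PosteriorFit, n_draws: int = 2000,
                            seed: int = 0) -> float:
    """Importance-sampling estimate of the log evidence using q as proposal.

    By Jensen's inequality this upper-bounds the ELBO in expectation; useful
    as an independent check that the reported ELBO is a genuine lower bound.
    """
    model = _rebuild(fit_result)
    rng = np.random.default_rng(seed)
    sigma = np.exp(fit_result.q_log_sigma)
    lw = np.empty(n_draws)
    for i in range(n_draws):
        eps_draw = rng.standard_normal(model.dim)
        z = fit_result.q_mu + sigma * eps_draw
        lp, _ = model.logp(z)
        lq = float(-0.5 * np.sum(eps_draw**2) - np.sum(fit_result.q_log_sigma)
                   - 0.5 * model.dim * _LOG2PI)
        lw[i] = lp - lq
    return float(logsumexp(lw) - np.log(n_draws))


def compare_models(fits: list[PosteriorFit]) -> list[dict]:
    """Rank fits of the same dataset by final ELBO (higher is better).

    Reports the Monte-Carlo standard error of each ELBO so near-ties between
    models are visible rather than silently ordered.
    """
    if not fits:
        raise ValueError("need at least one fit")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were computed on different datasets; refusing to rank")
    ordered = sorted(fits, key=lambda f: f.final_elbo, reverse=True)
    return [
        {"rank": i + 1, "model": f.spec.name, "elbo": f.final_elbo, "elbo_se": f.final_elbo_se}
        for i, f in enumerate(ordered)
    ]
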