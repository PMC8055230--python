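"""Posterior summaries: membership, pruning, trajectories, predictive densities."""

import numpy as np
import pytest
from scipy.special import logsumexp

from clonodyn.inference import VIConfig, fit, model_by_name
from clonodyn.likelihood import betabinomial_logpmf
from clonodyn.postprocess import (
    _conditional,
    hard_assignment,
    make_report,
    membership_probabilities,
    posterior_predictive_vaf,
    predict_trajectories,
    prune_clusters,
)
from clonodyn.simulate import SimConfig, simulate_dataset


class TestMembership:
    def test_rows_sum_to_one(self, gp0_fit):
        member = membership_probabilities(gp0_fit, max_draws=100)
        np.testing.assert_allclose(member.sum(axis=1), 1.0, atol=1e-12)

    def test_deep_separated_clusters_are_certain(self, gp0_fit):
        member = membership_probabilities(gp0_fit, max_draws=100)
        assert np.all(member.max(axis=1) > 0.99)

    def test_matches_bayes_rule_oracle_on_single_draw(self, gp0_fit):
        """Recompute p(z_i = k) for one draw by hand and compare."""
        f = gp0_fit
        s = 0
        phi = f.draws["phi"][s]
        w = f.draws["weights"][s]
        v = f.draws["v"][s]
        N, M = f.alt.shape
        K = phi.shape[1]
        oracle = np.empty((N, K))
        for i in range(N):
            for k in range(K):
                acc = np.log(w[k])
                for j in range(M):
                    theta = np.clip(f.zeta[i, j] * phi[j, k], 1e-9, 1 - 1e-9)
                    acc += float(betabinomial_logpmf(f.alt[i, j], f.total[i, j],
                                                     theta, v[j]))
                oracle[i, k] = acc
        oracle = np.exp(oracle - logsumexp(oracle, axis=1, keepdims=True))
        member_one = membership_probabilities(f, max_draws=1)
        np.testing.assert_allclose(member_one, oracle, atol=1e-9)


class TestHardAssignment:
    def test_argmax(self):
        labels = hard_assignment(np.array([[0.7, 0.3], [0.2, 0.8]]),
                                 np.array([0.5, 0.5]))
        np.testing.assert_array_equal(labels, [0, 1])

    def test_tie_goes_to_heavier_cluster(self):
        labels = hard_assignment(np.array([[0.5, 0.5]]), np.array([0.4, 0.6]))
        assert labels[0] == 1
        labels = hard_assignment(np.array([[0.5, 0.5]]), np.array([0.6, 0.4]))
        assert labels[0] == 0

    def test_consistent_under_cluster_reordering(self):
        member = np.array([[0.6, 0.1, 0.3], [0.2, 0.5, 0.3]])
        weights = np.array([0.5, 0.3, 0.2])
        base = hard_assignment(member, weights)
        perm = np.array([2, 0, 1])
        permuted = hard_assignment(member[:, perm], weights[perm])
        np.testing.assert_array_equal(perm[permuted], base)


class TestPruning:
    def test_two_true_clusters_survive(self, clean_two_cluster, gp0_fit):
        member = membership_probabilities(gp0_fit, max_draws=100)
        labels = hard_assignment(member, np.median(gp0_fit.draws["weights"], axis=0))
        kept = prune_clusters(gp0_fit, min_weight=0.02, hard_labels=labels)
        assert len(kept) == 2

    def test_report_weights_renormalized(self, gp0_fit):
        report = make_report(gp0_fit, predictive=False)
        assert report.weights_posterior.sum() == pytest.approx(1.0)
        assert report.weights_empirical.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(report.membership.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_threshold_keeps_assigned_clusters(self, gp0_fit):
        member = membership_probabilities(gp0_fit, max_draws=50)
        labels = hard_assignment(member, np.median(gp0_fit.draws["weights"], axis=0))
        kept = prune_clusters(gp0_fit, min_weight=0.0, hard_labels=labels)
        assert set(np.unique(labels)).issubset(set(kept))


class TestTrajectories:
    def test_interpolation_reproduces_sampled_times(self, gp0_fit):
        curves = predict_trajectories(gp0_fit, grid=gp0_fit.times, clusters=[0],
                                      max_draws=150)
        phi_med = np.median(gp0_fit.draws["phi"][:150, :, 0], axis=0)
        np.testing.assert_allclose(curves[0]["median"], phi_med, atol=0.02)

    def test_conditional_variance_smaller_at_sample_times(self, gp0_fit):
        t = gp0_fit.times
        mid = 0.5 * (t[:-1] + t[1:])
        _, q_at = _conditional(t, t, "ExpQ", 2.0)
        _, q_mid = _conditional(t, mid, "ExpQ", 2.0)
        assert q_at.max() <= q_mid.min() + 1e-9

    def test_tiny_tau_gives_flat_curve_at_average_level(self):
        """As tau -> 0 the kernel forgets time; the conditional mean between
        samples approaches the average of the drawn values."""
        t = np.array([0.0, 1.0])
        grid = np.array([0.5])
        m, _ = _conditional(t, grid, "Exp", 1e-7)
        psi = np.array([1.0, -3.0])
        assert (m @ psi)[0] == pytest.approx(psi.mean(), abs=1e-3)

    def test_flat_model_uses_piecewise_linear_interpolation(self):
        table, _ = simulate_dataset(SimConfig(n_samples=3, n_mutations=10,
                                              depth_mean=200, seed=12))
        f = fit(table, model_by_name("Flat", truncation=4),
                VIConfig(seed=1, max_iters=300))
        report = make_report(f, predictive=False)
        assert report.flat_interpolated
        k = report.kept_clusters[0]
        knots = predict_trajectories(f, grid=f.times, clusters=[k], max_draws=200)[k]
        mids = 0.5 * (f.times[:-1] + f.times[1:])
        between = predict_trajectories(f, grid=mids, clusters=[k], max_draws=200)[k]
        # straight segments: midpoint medians sit between the neighbouring knots
        med_k = knots["median"]
        for g, m in enumerate(between["median"]):
            lo = min(med_k[g], med_k[g + 1]) - 0.05
            hi = max(med_k[g], med_k[g + 1]) + 0.05
            assert lo <= m <= hi

    def test_out_of_range_grid_warns(self, gp0_fit):
        with pytest.warns(UserWarning, match="extrapolation"):
            predict_trajectories(gp0_fit, grid=np.array([0.0, 0.5, 1.2]),
                                 clusters=[0], max_draws=10)


class TestPredictive:
    def test_density_integrates_to_one(self, gp0_fit):
        out = posterior_predictive_vaf(gp0_fit, gp0_fit.sample_ids[0], max_draws=100)
        area = np.trapezoid(out["density"], out["vaf"])
        assert area == pytest.approx(1.0, abs=1e-3)
        assert np.all(out["density"] >= 0)

    def test_unknown_sample_rejected(self, gp0_fit):
        with pytest.raises(KeyError):
            posterior_predictive_vaf(gp0_fit, "nope")

    def test_matches_forward_simulated_vafs(self, gp0_fit):
        """KS distance between forward-simulated VAFs from the fitted model and
        the predictive density stays small."""
        f = gp0_fit
        sid = f.sample_ids[1]
        j = 1
        out = posterior_predictive_vaf(f, sid, max_draws=200)
        rng = np.random.default_rng(0)
        depth = int(np.median(f.total[:, j]))
        zbar = float(np.median(f.zeta[:, j]))
        S = f.draws["phi"].shape[0]
        sims = []
        for _ in range(4000):
            s = rng.integers(min(S, 200))
            w = f.draws["weights"][s]
            k = rng.choice(w.size, p=w / w.sum())
            theta = np.clip(zbar * f.draws["phi"][s, j, k], 1e-9, 1 - 1e-9)
            v = f.draws["v"][s, j]
            p = rng.beta(v * theta, v * (1 - theta))
            sims.append(rng.binomial(depth, p) / depth)
        sims = np.sort(np.asarray(sims))
        # predictive CDF on the grid via cumulative trapezoid
        grid, dens = out["vaf"], out["density"]
        cdf = np.concatenate([[0.0], np.cumsum(np.diff(grid) * 0.5 * (dens[1:] + dens[:-1]))])
        emp = np.searchsorted(sims, grid, side="right") / sims.size
        assert np.abs(cdf - emp).max() < 0.05
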