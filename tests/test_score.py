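import numpy as np
import pytest

import fmbayes as fb
from fmbayes._mbar import mbar, overlap_matrix, statistical_inefficiency
from fmbayes.forward_models import DihedralEnsemble, KarplusModel, replica_average
from fmbayes.likelihoods import PriorBounds, UncertaintyState, gaussian_energy
from fmbayes.sampler import SamplerConfig
from fmbayes.score import (
    FreeEnergyResult,
    XiSchedule,
    compute_score,
    hessian_uncertainty,
    optimize_xi_schedule,
    restraint_energy_at_xi,
    sample_xi_states,
    score_from_traces,
    score_gradient,
)
from fmbayes.toy_model import TRUTH


class TestMbar:
    def test_harmonic_oracle(self, rng):
        ks = np.array([1.0, 2.0, 4.0])
        n = 3000
        xs = np.concatenate([rng.normal(0, 1 / np.sqrt(k), n) for k in ks])
        u_kn = 0.5 * ks[:, None] * xs[None, :] ** 2
        f, th = mbar(u_kn, [n] * 3)
        f_true = -0.5 * np.log(2 * np.pi / ks)
        f_true -= f_true[0]
        d = np.sqrt(np.diag(th))
        assert np.all(np.abs(f - f_true) < 4 * np.maximum(d, 1e-3))

    def test_identical_states_give_zero(self, rng):
        u = np.tile(rng.normal(size=500), (3, 1))
        f, _ = mbar(u, [200, 200, 100])
        assert np.allclose(f, 0.0, atol=1e-10)

    def test_overlap_rows_normalized(self, rng):
        xs = np.concatenate([rng.normal(0, 1, 400), rng.normal(0.5, 1, 400)])
        u = np.stack([0.5 * xs**2, 0.5 * (xs - 0.5) ** 2])
        O = overlap_matrix(u, np.array([400.0, 400.0]))
        assert np.allclose(O.sum(axis=1), 1.0)

    def test_statistical_inefficiency(self, rng):
        assert statistical_inefficiency(rng.normal(size=4000)) < 1.5
        walk = np.cumsum(rng.normal(size=4000))
        assert statistical_inefficiency(walk) > 50


class TestXiSchedule:
    def test_endpoints_enforced(self):
        with pytest.raises(ValueError):
            XiSchedule((0.0, 0.5))
        with pytest.raises(ValueError):
            XiSchedule((0.1, 0.5, 1.0))
        with pytest.raises(ValueError):
            XiSchedule((0.0, 0.5, 0.5, 1.0))
        assert len(XiSchedule.uniform(11)) == 11

    def test_affine_energy_mixing(self):
        u0 = restraint_energy_at_xi(0.0, 3.0, 8.0)
        u1 = restraint_energy_at_xi(1.0, 3.0, 8.0)
        uh = restraint_energy_at_xi(0.5, 3.0, 8.0)
        assert u0 == 3.0 and u1 == 11.0
        assert uh == pytest.approx((u0 + u1) / 2)
        with pytest.raises(ValueError):
            restraint_energy_at_xi(1.2, 0.0, 0.0)


def _fake_traces(rng, xis, scale=1.0, n=400):
    """Synthetic per-xi traces with exponential u_data samples."""
    traces = []
    for xi in xis:
        tr = fb.PosteriorTrace(
            thetas=np.zeros((n, 1, 3)), sigmas=np.ones((n, 1)),
            phis=np.ones((n, 1, 2)),
            u=np.zeros(n), u_prior=np.zeros(n),
            u_data=rng.exponential(scale / (1 + 3 * xi), n),
            grads=np.zeros((n, 1, 3)),
            states=np.zeros((0, 1), dtype=np.int32), acceptance={},
            type_labels=["3J"], config=None)
        tr.u = tr.u_prior + xi * tr.u_data
        traces.append(tr)
    return traces


class TestScoreFromTraces:
    def test_zero_data_term_gives_exactly_zero(self, rng):
        sched = XiSchedule.uniform(5)
        traces = _fake_traces(rng, sched.xi_values, scale=1.0)
        for tr in traces:
            tr.u_data[:] = 0.0
            tr.u[:] = 0.0
        res = score_from_traces(traces, sched, n_replicas=4)
        assert res.f == 0.0 and res.f_reduced == 0.0

    def test_near_duplicate_state_invariance(self, rng):
        sched = XiSchedule.uniform(6)
        traces = _fake_traces(rng, sched.xi_values)
        f0 = score_from_traces(traces, sched, 4).f
        xis2 = sorted(set(sched.xi_values) | {0.4 + 1e-9})
        sched2 = XiSchedule(tuple(xis2))
        tr_dup = _fake_traces(rng, [0.4 + 1e-9])[0]
        traces2 = traces[:3] + [tr_dup] + traces[3:]
        f2 = score_from_traces(traces2, sched2, 4).f
        assert f2 == pytest.approx(f0, abs=0.1)


@pytest.fixture(scope="module")
def tiny_system():
    """3 states, 1 observable, 1 replica — exactly enumerable."""
    phi = np.array([[-120.0], [-60.0], [55.0]])
    ens = DihedralEnsemble(phi=phi, prior_pop=np.array([0.5, 0.3, 0.2]))
    d = np.array([3.2])
    bounds = PriorBounds(sigma_lo=0.3, sigma_hi=3.0, phi_lo=1.0,
                         phi_hi=1.0 + 1e-12)
    return ens, d, bounds


def _enumerate_f(ens, d, bounds, theta, xi_hi=1.0, xi_lo=0.0):
    """Exact -ln Z(xi_hi)/Z(xi_lo) over (state, sigma-grid) space."""
    model = TRUTH.with_theta(theta)
    grid = np.geomspace(bounds.sigma_lo, bounds.sigma_hi, 128)
    zs = {}
    for xi in (xi_lo, xi_hi):
        z = 0.0
        for s in range(ens.n_states):
            pred = replica_average([s], ens, model)
            for sig in grid:
                u = gaussian_energy(pred, d, UncertaintyState(sig),
                                    counting="evidence")
                z += ens.prior_pop[s] * (1 / grid.size) * np.exp(-xi * u)
        zs[xi] = z
    return -np.log(zs[xi_hi] / zs[xi_lo])


class TestComputeScore:
    def test_matches_exact_enumeration(self, tiny_system):
        ens, d, bounds = tiny_system
        f_exact = _enumerate_f(ens, d, bounds, TRUTH.theta)
        cfg = SamplerConfig(n_replicas=1, n_burn=500, n_steps=4000, seed=9,
                            likelihood="gaussian", counting="evidence",
                            bounds=bounds, lrate=0.0, eta=0.0,
                            step_theta=1e-12, gibbs_every=3,
                            nuisance_gibbs_every=5)
        res = compute_score(cfg, ens, d, TRUTH, XiSchedule.uniform(6))
        assert abs(res.f - f_exact) < max(3 * res.df, 0.05)
        assert res.f_reduced == pytest.approx(res.f)

    def test_path_additivity(self, tiny_system):
        ens, d, bounds = tiny_system
        f_half = _enumerate_f(ens, d, bounds, TRUTH.theta, xi_hi=0.5)
        f_full = _enumerate_f(ens, d, bounds, TRUTH.theta, xi_hi=1.0)
        f_second = _enumerate_f(ens, d, bounds, TRUTH.theta, xi_lo=0.5,
                                xi_hi=1.0)
        assert f_full == pytest.approx(f_half + f_second, abs=1e-12)
        # and the sampled MBAR estimate decomposes the same way
        cfg = SamplerConfig(n_replicas=1, n_burn=500, n_steps=3000, seed=10,
                            likelihood="gaussian", counting="evidence",
                            bounds=bounds, lrate=0.0, eta=0.0,
                            step_theta=1e-12, gibbs_every=3,
                            nuisance_gibbs_every=5)
        sched = XiSchedule(tuple(np.linspace(0, 1, 9)))
        traces = sample_xi_states(cfg, ens, d, TRUTH, sched)
        res = score_from_traces(traces, sched, 1)
        f_a = res.per_state_f[4] - res.per_state_f[0]   # 0 -> 0.5
        f_b = res.per_state_f[-1] - res.per_state_f[4]  # 0.5 -> 1
        assert res.f == pytest.approx(f_a + f_b, abs=1e-12)
        assert abs(res.f - f_full) < max(3 * res.df, 0.05)


class TestScoreGradient:
    def test_matches_enumeration_derivative(self, tiny_system):
        ens, d, bounds = tiny_system
        cfg = SamplerConfig(n_replicas=1, n_burn=500, n_steps=6000, seed=11,
                            likelihood="gaussian", counting="evidence",
                            bounds=bounds, lrate=0.0, eta=0.0,
                            step_theta=1e-12, gibbs_every=3,
                            nuisance_gibbs_every=5)
        traces = sample_xi_states(cfg, ens, d, TRUTH, XiSchedule.uniform(2))
        grad, sem = score_gradient(traces[-1])
        h = 1e-4
        for i in range(3):
            e = np.zeros(3)
            e[i] = h
            fd = (_enumerate_f(ens, d, bounds, TRUTH.theta + e)
                  - _enumerate_f(ens, d, bounds, TRUTH.theta - e)) / (2 * h)
            assert abs(grad[0, i] - fd) < max(5 * sem[0, i], 0.05)

    def test_empty_samples_rejected(self, rng):
        tr = _fake_traces(rng, [1.0], n=0)[0]
        with pytest.raises(ValueError):
            score_gradient(tr)


class TestXiScheduleOptimizer:
    def test_flat_metric_recovers_uniform(self, rng):
        sched = XiSchedule.uniform(6)
        traces = _fake_traces(rng, sched.xi_values, scale=1.0)
        for tr in traces:   # identical spread everywhere
            tr.u_data = rng.normal(5.0, 1.0, 400)
        out = optimize_xi_schedule(traces, sched, target_count=6)
        assert np.allclose(out.xi_values, np.linspace(0, 1, 6), atol=0.08)

    def test_monotone_with_pinned_endpoints(self, rng):
        sched = XiSchedule.uniform(8)
        traces = _fake_traces(rng, sched.xi_values, scale=7.0)
        out = optimize_xi_schedule(traces, sched, target_count=5)
        v = np.asarray(out.xi_values)
        assert v[0] == 0.0 and v[-1] == 1.0 and np.all(np.diff(v) > 0)

    def test_degenerate_pilot_warns_uniform(self, rng):
        sched = XiSchedule.uniform(4)
        traces = _fake_traces(rng, sched.xi_values)
        for tr in traces:
            tr.u_data[:] = 2.0
        with pytest.warns(UserWarning):
            out = optimize_xi_schedule(traces, sched, target_count=4)
        assert np.allclose(out.xi_values, np.linspace(0, 1, 4))

    def test_improves_neighbor_overlap_on_toy(self, tiny_system):
        ens, d, bounds = tiny_system
        cfg = SamplerConfig(n_replicas=1, n_burn=300, n_steps=2000, seed=12,
                            likelihood="gaussian", counting="evidence",
                            bounds=bounds, lrate=0.0, eta=0.0,
                            step_theta=1e-12, gibbs_every=3,
                            nuisance_gibbs_every=5)
        pilot_sched = XiSchedule.uniform(9)
        pilot = sample_xi_states(cfg, ens, d, TRUTH, pilot_sched)
        opt_sched = optimize_xi_schedule(pilot, pilot_sched, target_count=5)

        def min_neighbor_overlap(sched):
            traces = sample_xi_states(cfg, ens, d, TRUTH, sched)
            xis = np.asarray(sched.xi_values)
            upr = np.concatenate([t.u_prior for t in traces])
            uda = np.concatenate([t.u_data for t in traces])
            u_kn = upr[None, :] + xis[:, None] * uda[None, :]
            n_k = np.full(len(sched), len(traces[0]), dtype=float)
            O = overlap_matrix(u_kn, n_k)
            return min(O[i, i + 1] for i in range(len(sched) - 1))

        assert (min_neighbor_overlap(opt_sched)
                >= min_neighbor_overlap(XiSchedule.uniform(5)) - 0.02)


class TestHessianUncertainty:
    def test_quadratic_oracle(self, rng):
        H = np.array([[2.0, 0.3, 0.0], [0.3, 1.0, 0.1], [0.0, 0.1, 3.0]])
        cov = hessian_uncertainty(np.zeros(3), lambda t: H @ t, step=0.05)
        assert np.allclose(cov, np.linalg.inv(H), atol=1e-8)

    def test_diagonal_curvatures(self):
        H = np.diag([1.0, 4.0])
        cov = hessian_uncertainty(np.zeros(2), lambda t: H @ t)
        assert np.sqrt(cov[0, 0]) == pytest.approx(1.0)
        assert np.sqrt(cov[1, 1]) == pytest.approx(0.5)
        assert cov[0, 1] == pytest.approx(cov[1, 0])

    def test_non_positive_definite_raises(self):
        H = np.diag([1.0, -2.0])
        with pytest.raises(np.linalg.LinAlgError, match="multi-start"):
            hessian_uncertainty(np.zeros(2), lambda t: H @ t)


def test_reduced_score_roughly_replica_independent(toy_noisy):
    """f grows ~linearly with the replica count, so f/N_r is stable."""
    reduced = []
    for n_rep in (8, 16, 32):
        cfg = SamplerConfig(n_replicas=n_rep, n_burn=500, n_steps=2500,
                            seed=13, ensemble_average="population",
                            nuisance_gibbs_every=10)
        # denser bridge at larger N: the restraint (hence the energy gap
        # between neighboring xi states) grows linearly with N
        res = compute_score(cfg, toy_noisy.ensemble, toy_noisy.data,
                            KarplusModel(6.0, -1.5, 1.7),
                            XiSchedule.uniform(1 + n_rep))
        reduced.append(res.f_reduced)
    spread = max(reduced) - min(reduced)
    assert spread < 0.35 * abs(np.mean(reduced))
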