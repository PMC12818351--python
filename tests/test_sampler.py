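import numpy as np
import pytest
from scipy import stats

import fmbayes as fb
from fmbayes.forward_models import DihedralEnsemble, KarplusModel, replica_average
from fmbayes.likelihoods import PriorBounds, UncertaintyState, gaussian_energy, goodbad_energy
from fmbayes.sampler import (
    SamplerConfig,
    gelman_rubin,
    marginal_summary,
    mh_accept,
    propose_fm_params,
    run_chain,
)
from fmbayes.toy_model import TRUTH


class TestProposeFmParams:
    def test_identity_update(self, rng):
        th = np.array([1.0, 2.0, 3.0])
        out = propose_fm_params(th, np.array([5.0, -1.0, 0.5]), 0.0, 0.0, rng)
        assert np.array_equal(out, th)

    def test_halves_distance_on_quadratic(self, rng):
        # u = 0.5 (theta - t*)^2 has gradient theta - t*; lrate 0.5 halves it
        target = np.array([2.0, -1.0, 0.5])
        th = np.zeros(3)
        for _ in range(30):
            th = propose_fm_params(th, th - target, 0.5, 0.0, rng)
        assert np.allclose(th, target, atol=1e-8)

    def test_noise_moments(self, rng):
        eta = 0.3
        draws = np.array([propose_fm_params([0.0], [0.0], 0.0, eta, rng)[0]
                          for _ in range(100_000)])
        assert abs(draws.mean()) < 3 * eta / np.sqrt(draws.size)
        assert abs(draws.std() - eta) < 0.01


class TestMhAccept:
    def test_downhill_always_accepted(self, rng):
        assert all(mh_accept(1.0, 2.0, rng) for _ in range(100))
        assert mh_accept(2.0, 2.0, rng)

    def test_acceptance_rate_at_ln2(self, rng):
        n = 100_000
        acc = sum(mh_accept(np.log(2.0), 0.0, rng) for _ in range(n)) / n
        assert abs(acc - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_nan_rejected(self, rng):
        assert not mh_accept(np.nan, 0.0, rng)

    def test_two_state_boltzmann_occupancy(self, rng):
        # symmetric proposals between energies (0, ln 3) -> occupancy 3:1
        u = np.array([0.0, np.log(3.0)])
        state, visits = 0, np.zeros(2)
        for _ in range(40_000):
            prop = 1 - state
            if mh_accept(u[prop], u[state], rng):
                state = prop
            visits[state] += 1
        ratio = visits[0] / visits[1]
        assert abs(ratio - 3.0) < 0.25


class TestGelmanRubin:
    def test_convergent_chains(self, rng):
        chains = rng.normal(0, 1, size=(4, 10_000))
        assert gelman_rubin(chains) < 1.01

    def test_divergent_chains(self, rng):
        a = rng.normal(0, 1, 5000)
        b = rng.normal(10, 1, 5000)
        assert gelman_rubin(np.stack([a, b])) > 2.0

    def test_split_single_chain(self, rng):
        x = rng.normal(0, 1, 20_000)
        assert gelman_rubin(x.reshape(2, -1)) == pytest.approx(1.0, abs=0.01)

    def test_validation(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.normal(size=(1, 100)))
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((2, 50)))


def _dummy_trace(thetas):
    n = thetas.shape[0]
    return fb.PosteriorTrace(
        thetas=thetas, sigmas=np.ones((n, 1)), phis=np.ones((n, 1, 2)),
        u=np.zeros(n), u_prior=np.zeros(n), u_data=np.zeros(n),
        grads=np.zeros((n, 1, 3)), states=np.zeros((0, 1), dtype=np.int32),
        acceptance={}, type_labels=["3J"], config=None)


class TestMarginalSummary:
    def test_constant_trace(self):
        tr = _dummy_trace(np.full((50, 1, 3), 2.5))
        s = marginal_summary(tr)["3J"]["A"]
        assert s["sd"] == 0.0 and s["map"] == s["mean"] == 2.5

    def test_known_distribution(self, rng):
        th = rng.normal(0, 1, size=(100_000, 1, 3))
        s = marginal_summary(_dummy_trace(th))["3J"]["B"]
        assert abs(s["mean"]) < 0.01 and abs(s["sd"] - 1.0) < 0.01
        assert abs(s["map"]) < 0.1

    def test_pooling_duplicates_is_invariant(self, rng):
        th = rng.normal(2, 0.3, size=(5000, 1, 3))
        one = marginal_summary(_dummy_trace(th))
        two = marginal_summary([_dummy_trace(th), _dummy_trace(th)])
        for p in "ABC":
            assert one["3J"][p]["mean"] == pytest.approx(two["3J"][p]["mean"])

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            marginal_summary(_dummy_trace(np.zeros((0, 1, 3))))


class TestKernelMatchesReferenceEnergies:
    """The compiled kernel and the numpy likelihood module must agree."""

    @pytest.mark.parametrize("likelihood", ["gaussian", "good_bad"])
    @pytest.mark.parametrize("counting", ["evidence", "restraint"])
    def test_replica_mode_energies(self, toy_noisy, likelihood, counting):
        cfg = SamplerConfig(n_replicas=6, n_burn=200, n_steps=400, seed=3,
                            likelihood=likelihood, counting=counting)
        tr = run_chain(cfg, toy_noisy.ensemble, toy_noisy.data,
                       KarplusModel(5.0, -1.0, 2.0))
        for i in (0, 199, 399):
            pred = replica_average(tr.states[i], toy_noisy.ensemble,
                                   KarplusModel(*tr.thetas[i, 0]))
            unc = UncertaintyState(tr.sigmas[i, 0],
                                   tr.phis[i, 0, 1] if likelihood == "good_bad"
                                   else 1.0)
            fn = goodbad_energy if likelihood == "good_bad" else gaussian_energy
            u_ref = fn(pred, toy_noisy.data, unc, counting=counting)
            assert tr.u_data[i] == pytest.approx(u_ref, rel=1e-10)

    def test_population_mode_energies(self, toy_noisy):
        # population mode keeps the SEM in the gates but not in the
        # likelihood width (sigma0 = sigma_B); rebuild that energy from the
        # reference mixture directly
        from fmbayes.likelihoods import _mixture_logL

        cfg = SamplerConfig(n_replicas=8, n_burn=200, n_steps=300, seed=4,
                            ensemble_average="population", sem_in_width=False)
        tr = run_chain(cfg, toy_noisy.ensemble, toy_noisy.data,
                       KarplusModel(5.0, -1.0, 2.0))
        w = toy_noisy.ensemble.prior_pop
        for i in (0, 299):
            model = KarplusModel(*tr.thetas[i, 0])
            per_state = fb.karplus_predict(toy_noisy.ensemble.phi, model)
            g = w @ per_state
            var = w @ (per_state - g[None, :]) ** 2
            sem = np.sqrt(var / 8)
            phi_v = tr.phis[i, 0, 1]
            logL, _ = _mixture_logL(
                toy_noisy.data - g, np.full_like(g, tr.sigmas[i, 0]), sem,
                [1.0, phi_v], [np.log(0.5), np.log(0.5 / phi_v)],
                8, "restraint")
            assert tr.u_data[i] == pytest.approx(-logL.sum(), rel=1e-10)


class TestChainBehaviour:
    def test_prior_only_sampling_recovers_populations(self):
        # with the restraint switched off (xi = 0) replica occupancies must
        # reproduce a non-uniform prior within multinomial error
        prior = np.array([0.5, 0.3, 0.2])
        ens = DihedralEnsemble(phi=np.array([[-60.0, 30.0],
                                             [-110.0, 80.0],
                                             [60.0, -150.0]]),
                               prior_pop=prior)
        cfg = SamplerConfig(n_replicas=8, n_burn=500, n_steps=8000, seed=5,
                            xi=0.0, gibbs_every=3)
        tr = run_chain(cfg, ens, np.array([4.0, 3.0]), TRUTH)
        counts = np.bincount(tr.states.ravel(), minlength=3).astype(float)
        occ = counts / counts.sum()
        n_eff = tr.states.size / 50   # generous correlation allowance
        tol = 3 * np.sqrt(prior * (1 - prior) / n_eff)
        assert np.all(np.abs(occ - prior) < tol)

    def test_joint_distribution_matches_enumeration(self):
        # 3 states, 1 observable, 2 replicas, sigma pinned, theta fixed:
        # the sampled replica-pair distribution must match exact enumeration
        phi = np.array([[-120.0], [-60.0], [55.0]])
        ens = DihedralEnsemble(phi=phi, prior_pop=np.array([0.5, 0.3, 0.2]))
        d = np.array([3.2])
        bounds = PriorBounds(sigma_lo=0.6, sigma_hi=0.6, phi_lo=1.0,
                             phi_hi=1.0 + 1e-12)
        cfg = SamplerConfig(n_replicas=2, n_burn=1000, n_steps=60_000, seed=6,
                            likelihood="gaussian", counting="evidence",
                            bounds=bounds, lrate=0.0, eta=0.0,
                            step_theta=1e-12, gibbs_every=3)
        tr = run_chain(cfg, ens, d, TRUTH)
        # exact enumeration over ordered replica pairs
        logw = np.empty((3, 3))
        for a in range(3):
            for b in range(3):
                pred = replica_average([a, b], ens, TRUTH)
                u = gaussian_energy(pred, d, UncertaintyState(0.6),
                                    counting="evidence")
                logw[a, b] = np.log(ens.prior_pop[a] * ens.prior_pop[b]) - u
        p_exact = np.exp(logw - logw.max())
        p_exact /= p_exact.sum()
        counts = np.zeros((3, 3))
        for a, b in tr.states:
            counts[a, b] += 1
        p_emp = counts / counts.sum()
        # thinned effective sample size for the chi^2 comparison
        n_eff = len(tr) / 60
        chi2 = n_eff * np.sum((p_emp - p_exact) ** 2 / p_exact)
        assert chi2 < stats.chi2.ppf(0.999, df=8)

    def test_acceptance_rates_reasonable(self):
        # the standard study system (100 states x 60 observables); smaller
        # fixtures have softer posteriors and near-free sigma moves
        ds = fb.build_toy_dataset(100, 60, seed=21)
        noisy = fb.add_noise(ds, 0.5, seed=22)
        cfg = SamplerConfig(n_burn=1500, n_steps=6000, seed=7,
                            ensemble_average="population")
        tr = run_chain(cfg, ds.ensemble, noisy.data,
                       KarplusModel(4.0, 0.0, 3.0))
        rates = tr.acceptance_rates()
        for cls in ("sigma", "phi", "theta"):
            assert 0.05 <= rates[cls] <= 0.95, (cls, rates)

    def test_posterior_sharpens_with_data_size(self):
        sds = []
        for n_obs, seed in ((15, 1), (60, 2), (240, 3)):
            ds = fb.build_toy_dataset(40, n_obs, seed=seed)
            cfg = SamplerConfig(n_burn=2000, n_steps=6000, seed=seed,
                                ensemble_average="population")
            tr = run_chain(cfg, ds.ensemble, ds.J_true,
                           KarplusModel(5.0, -1.0, 2.0))
            sds.append(tr.thetas[:, 0, :].std(axis=0).mean())
        assert sds[0] > sds[2]

    def test_seeded_chains_reproduce(self, toy_noisy):
        cfg = SamplerConfig(n_burn=300, n_steps=500, seed=11,
                            ensemble_average="population")
        a = run_chain(cfg, toy_noisy.ensemble, toy_noisy.data, TRUTH)
        b = run_chain(cfg, toy_noisy.ensemble, toy_noisy.data, TRUTH)
        assert np.array_equal(a.thetas, b.thetas)
        assert np.array_equal(a.u, b.u)
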