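import numpy as np
import pytest

from fmbayes.forward_models import PredictionSet
from fmbayes.likelihoods import (
    PriorBounds,
    SeveritySpec,
    UncertaintyState,
    gaussian_energy,
    goodbad_energy,
    goodbad_grad_theta,
    multiseverity_energy,
)

LOG_2PI = np.log(2 * np.pi)


def pred_of(g, sem=None, n=1):
    g = np.atleast_1d(np.asarray(g, dtype=float))
    sem = np.zeros_like(g) if sem is None else np.atleast_1d(sem)
    return PredictionSet(g=g, sem=sem, n_replicas=n)


class TestGaussianEnergy:
    def test_single_observable_normalizer(self):
        # d = g, sigma0 = 1, N = 1, flat priors: u = 0.5 ln(2 pi)
        u = gaussian_energy(pred_of(3.0), [3.0], UncertaintyState(1.0))
        assert u == pytest.approx(0.5 * LOG_2PI, abs=1e-12)

    def test_unit_residual_adds_half_nat(self):
        u0 = gaussian_energy(pred_of(3.0), [3.0], UncertaintyState(1.0))
        u1 = gaussian_energy(pred_of(3.0), [4.0], UncertaintyState(1.0))
        assert u1 - u0 == pytest.approx(0.5, abs=1e-12)

    def test_replica_count_scales_data_term(self):
        unc = UncertaintyState(0.7)
        u1 = gaussian_energy(pred_of([2.0, 5.0], n=1), [2.5, 4.0], unc)
        u2 = gaussian_energy(pred_of([2.0, 5.0], n=2), [2.5, 4.0], unc)
        assert u2 == pytest.approx(2.0 * u1, rel=1e-12)

    def test_prior_energy_offsets(self):
        unc = UncertaintyState(1.0)
        u = gaussian_energy(pred_of(0.0), [0.0], unc, prior_energy=2.5)
        assert u == pytest.approx(2.5 + 0.5 * LOG_2PI)


class TestGoodBadEnergy:
    def test_reduces_to_gaussian_at_phi_one(self, rng):
        g = rng.normal(4, 1, 9)
        d = g + rng.normal(0, 0.5, 9)
        sem = np.abs(rng.normal(0, 0.1, 9))
        for n in (1, 16):
            for counting in ("evidence", "restraint"):
                ug = gaussian_energy(pred_of(g, sem, n), d,
                                     UncertaintyState(0.4), counting=counting)
                ub = goodbad_energy(pred_of(g, sem, n), d,
                                    UncertaintyState(0.4, 1.0),
                                    counting=counting)
                assert ub == pytest.approx(ug, rel=1e-12)

    def test_mixture_mode_value(self):
        # d = g, sigma0 = 1, phi = 2: u = 0.5 ln(2 pi) + ln(8/5)
        u = goodbad_energy(pred_of(0.0), [0.0], UncertaintyState(1.0, 2.0))
        assert u == pytest.approx(0.5 * LOG_2PI + np.log(8.0 / 5.0), abs=1e-9)

    def test_tail_grows_phi_squared_slower(self):
        # far in the tail the wide component dominates: quadratic growth in r
        # with curvature 1/(2 phi^2 sigma0^2) instead of 1/(2 sigma0^2)
        phi = 3.0
        unc = UncertaintyState(1.0, phi)
        r1, r2 = 40.0, 80.0
        du_mix = (goodbad_energy(pred_of(0.0), [r2], unc)
                  - goodbad_energy(pred_of(0.0), [r1], unc))
        expect = (r2**2 - r1**2) / (2 * phi**2)
        assert du_mix == pytest.approx(expect, rel=1e-3)

    def test_validation(self):
        with pytest.raises(ValueError):
            UncertaintyState(1.0, 0.5)
        with pytest.raises(ValueError):
            UncertaintyState(0.0)
        with pytest.raises(ValueError):
            goodbad_energy(pred_of([1.0, 2.0]), [1.0], UncertaintyState(1.0))

    def test_permutation_invariance(self, rng):
        g = rng.normal(4, 1, 7)
        d = g + rng.normal(0, 1, 7)
        sem = np.abs(rng.normal(0, 0.2, 7))
        perm = rng.permutation(7)
        unc = UncertaintyState(0.5, 3.0)
        assert goodbad_energy(pred_of(g, sem, 4), d, unc) == pytest.approx(
            goodbad_energy(pred_of(g[perm], sem[perm], 4), d[perm], unc))

    @pytest.mark.parametrize("param", ["sigma", "phi"])
    def test_continuity(self, param, rng):
        g = rng.normal(4, 1, 5)
        d = g + rng.normal(0, 0.7, 5)
        pred = pred_of(g, np.full(5, 0.1), 8)
        base = dict(sigma_B=0.5, phi_scale=2.0)
        eps = 1e-7
        vals = []
        for s in (-eps, 0, eps):
            kw = dict(base)
            kw["sigma_B" if param == "sigma" else "phi_scale"] += s
            vals.append(goodbad_energy(pred, d, UncertaintyState(**kw)))
        assert abs(vals[0] - vals[1]) < 1e-4 and abs(vals[2] - vals[1]) < 1e-4

    def test_jeffreys_prior_term(self):
        b = PriorBounds()
        u_flat = goodbad_energy(pred_of(0.0), [0.0], UncertaintyState(1.0, 2.0))
        u_pri = goodbad_energy(pred_of(0.0), [0.0], UncertaintyState(1.0, 2.0),
                               bounds=b)
        assert u_pri - u_flat == pytest.approx(-b.log_prior(1.0, 2.0))
        assert b.log_prior(1e9, 2.0) == -np.inf


class TestGoodBadGradient:
    def test_zero_at_perfect_fit(self, rng):
        g = rng.normal(4, 1, 6)
        grads = rng.normal(size=(6, 3))
        out = goodbad_grad_theta(pred_of(g, n=8), g, UncertaintyState(0.5, 2.5),
                                 grads)
        assert np.allclose(out, 0.0)

    def test_phi_one_is_plain_gaussian_pull(self, rng):
        g = rng.normal(4, 1, 6)
        d = g + rng.normal(0, 0.5, 6)
        basis = rng.normal(size=(6, 3))
        n = 16
        out = goodbad_grad_theta(pred_of(g, n=n), d, UncertaintyState(0.8, 1.0),
                                 basis, counting="evidence")
        expect = -n * basis.T @ ((d - g) / 0.8**2)
        assert np.allclose(out, expect)

    @pytest.mark.parametrize("counting", ["evidence", "restraint"])
    def test_matches_finite_differences(self, counting, rng):
        # analytic gradient vs central differences of the energy, holding the
        # prediction spread (SEM) fixed, as the gradient convention requires
        g = rng.normal(4, 1.5, 10)
        d = g + rng.normal(0, 0.8, 10)
        sem = np.abs(rng.normal(0, 0.15, 10))
        basis = rng.normal(size=(10, 3))
        unc = UncertaintyState(0.6, 2.2)
        n = 8
        ana = goodbad_grad_theta(pred_of(g, sem, n), d, unc, basis,
                                 counting=counting)
        h = 1e-6
        for i in range(3):
            up = goodbad_energy(pred_of(g + h * basis[:, i], sem, n), d, unc,
                                counting=counting)
            dn = goodbad_energy(pred_of(g - h * basis[:, i], sem, n), d, unc,
                                counting=counting)
            fd = (up - dn) / (2 * h)
            assert abs(ana[i] - fd) / max(abs(fd), 1e-8) < 1e-5


class TestMultiSeverity:
    def test_single_level_is_gaussian(self, rng):
        g = rng.normal(4, 1, 5)
        d = g + rng.normal(0, 0.5, 5)
        spec = SeveritySpec(np.array([1.0]))
        u = multiseverity_energy(pred_of(g, n=4), d, UncertaintyState(0.7), spec)
        assert u == pytest.approx(
            gaussian_energy(pred_of(g, n=4), d, UncertaintyState(0.7)))

    def test_three_level_mode_value(self):
        # M=3, d=g, sigma0=1, phi=(1,2,4): u = -ln[(1/3)(1/sqrt(2pi))(1+1/2+1/4)]
        spec = SeveritySpec(np.array([1.0, 2.0, 4.0]))
        u = multiseverity_energy(pred_of(0.0), [0.0], UncertaintyState(1.0),
                                 spec)
        expect = -np.log((1 / 3) * (1 / np.sqrt(2 * np.pi)) * 1.75)
        assert u == pytest.approx(expect, abs=1e-9)

    def test_severity_spec_validation(self):
        with pytest.raises(ValueError):
            SeveritySpec(np.array([2.0, 4.0]))      # phi_1 must be 1
        with pytest.raises(ValueError):
            SeveritySpec(np.array([1.0, 3.0, 2.0]))  # must increase
        with pytest.raises(ValueError):
            SeveritySpec(np.array([]))
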