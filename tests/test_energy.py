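"""Total strain energy and global Ogden/NeoHookean identification."""

import numpy as np
import pytest

from duramech.energy import (EnergyTrace, experimental_energy,
                             identify_parameters, model_energy)
from duramech.stress import solve_membrane_stress


def _trace(W, pressures, volumes):
    return EnergyTrace(W_exp=np.asarray(W, float),
                       pressures=np.asarray(pressures, float),
                       w=np.zeros((1, 1)), volumes=np.asarray(volumes, float))


@pytest.fixture(scope="module")
def sphere_energy_inputs(sphere_dataset, sphere_states):
    lam1 = np.stack([s.lambda1 for s in sphere_states])
    lam2 = np.stack([s.lambda2 for s in sphere_states])
    vols = sphere_states[0].volume
    return lam1, lam2, vols


class TestExperimentalEnergy:
    def test_zero_strain_history_gives_zero_energy(self):
        m = 4
        zeros = [np.zeros((m, 2, 2))] * 5
        ones = [np.full((m, 2, 2), 1e5)] * 5
        tr = experimental_energy(ones, zeros, np.full(m, 1e-9))
        np.testing.assert_array_equal(tr.W_exp, 0.0)

    def test_single_element_constant_stress_ramp(self):
        """Constant sigma_11 = c with E_11 ramped 0 -> e integrates to c*e
        per unit volume (the trapezoid is exact for a constant integrand)."""
        c, e, vol = 2.0e5, 0.04, 1e-9
        n = 6
        stress, strain = [], []
        for k in range(n):
            s = np.zeros((1, 2, 2))
            s[0, 0, 0] = c
            t = np.zeros((1, 2, 2))
            t[0, 0, 0] = e * k / (n - 1)
            stress.append(s)
            strain.append(t)
        tr = experimental_energy(stress, strain, np.array([vol]))
        assert tr.W_exp[-1] == pytest.approx(c * e * vol, rel=1e-12)

    def test_shear_component_counted_twice(self):
        tau, gamma, vol = 1e5, 0.02, 1e-9
        s = np.array([[[0.0, tau], [tau, 0.0]]])
        t = np.array([[[0.0, gamma], [gamma, 0.0]]])
        tr = experimental_energy([s, s], [0 * t, t], np.array([vol]))
        assert tr.W_exp[-1] == pytest.approx(2 * tau * gamma * vol, rel=1e-12)

    def test_sphere_energy_matches_closed_form_within_1pc(self):
        """Trapezoidal accumulation of the exact stress/strain history over
        the 50-frame schedule equals the closed-form hyperelastic energy of
        the same configuration to within 1%."""
        from duramech.kinematics import deformation_history
        from duramech.synthetic import (SphereInflationSpec,
                                        simulate_sphere_inflation)

        spec = SphereInflationSpec()   # default 50-frame schedule
        ds = simulate_sphere_inflation(spec)
        states = deformation_history(ds, h0=spec.initial_thickness)
        lam1 = np.stack([s.lambda1 for s in states])
        lam2 = np.stack([s.lambda2 for s in states])
        vols = states[0].volume
        gt_sig = ds.ground_truth["sigma1"]
        m = len(vols)
        stress = [np.einsum("m,ij->mij", np.full(m, gt_sig[k][0]), np.eye(2))
                  for k in range(ds.n_frames)]
        strain = [s.E for s in states]
        tr = experimental_energy(stress, strain, vols, ds.pressures)
        W_exact = model_energy(lam1, lam2, vols, "ogden",
                               mu=spec.mu, alpha=spec.alpha)
        # the first couple of increments integrate a curve rising from zero,
        # where the trapezoid's relative error is largest but the energies
        # are negligible; past that every frame agrees to 1%
        np.testing.assert_allclose(tr.W_exp[3:], W_exact[3:], rtol=0.01)
        np.testing.assert_allclose(tr.W_exp[1:3], W_exact[1:3], rtol=0.02)

    def test_energy_nondecreasing_under_monotone_loading(
            self, sphere_dataset, sphere_states):
        ds = sphere_dataset
        stress = [solve_membrane_stress(ds.mesh, ds.frames[k],
                                        ds.pressures[k],
                                        sphere_states[k].h).element_tensor
                  for k in range(ds.n_frames)]
        tr = experimental_energy(stress, [s.E for s in sphere_states],
                                 sphere_states[0].volume, ds.pressures)
        assert np.all(np.diff(tr.W_exp) >= 0)

    def test_mismatched_element_counts_rejected(self):
        with pytest.raises(ValueError, match="element count"):
            experimental_energy([np.zeros((3, 2, 2))], [np.zeros((3, 2, 2))],
                                np.ones(4))


class TestModelEnergy:
    def test_unit_stretch_zero_energy(self):
        lam = np.ones((3, 5))
        W = model_energy(lam, lam, np.full(5, 1e-9), "ogden",
                         mu=234e3, alpha=8.19)
        np.testing.assert_allclose(W, 0.0, atol=1e-25)

    def test_hand_evaluated_single_element(self):
        # mu/alpha (2 lam^a + lam^-2a - 3) V at lam=1.05
        lam = np.array([[1.05]])
        W = model_energy(lam, lam, np.array([1e-9]), "ogden",
                         mu=234e3, alpha=8.19)
        psi = 234e3 / 8.19 * (2 * 1.05 ** 8.19 + 1.05 ** -16.38 - 3)
        assert W[0] == pytest.approx(psi * 1e-9, rel=1e-12)
        assert W[0] == pytest.approx(1.23e-5, rel=0.01)

    def test_ogden_alpha_two_equals_neohookean(self):
        rng = np.random.default_rng(9)
        lam1 = rng.uniform(1.0, 1.4, (4, 20))
        lam2 = rng.uniform(0.9, 1.3, (4, 20))
        vols = rng.uniform(0.5e-9, 2e-9, 20)
        c1 = 117e3
        W_nh = model_energy(lam1, lam2, vols, "neohookean", c1=c1)
        W_og = model_energy(lam1, lam2, vols, "ogden", mu=2 * c1, alpha=2.0)
        np.testing.assert_allclose(W_og, W_nh, rtol=1e-12)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            model_energy(np.array([[0.0]]), np.array([[1.0]]),
                         np.array([1.0]), "ogden", mu=1.0, alpha=2.0)


class TestIdentification:
    def test_exact_energies_recovered_within_1pc(self, sphere_dataset,
                                                 sphere_energy_inputs,
                                                 sphere_spec):
        lam1, lam2, vols = sphere_energy_inputs
        W = model_energy(lam1, lam2, vols, "ogden", mu=sphere_spec.mu,
                         alpha=sphere_spec.alpha)
        p = identify_parameters(_trace(W, sphere_dataset.pressures, vols),
                                lam1, lam2, vols, "ogden")
        assert p.mu == pytest.approx(sphere_spec.mu, rel=0.01)
        assert p.alpha == pytest.approx(sphere_spec.alpha, rel=0.01)
        assert p.r2 > 0.999
        assert p.shear_modulus == pytest.approx(p.mu * p.alpha / 2, rel=1e-9)

    def test_neohookean_identification_and_ogden_limit(self, sphere_dataset,
                                                       sphere_energy_inputs):
        lam1, lam2, vols = sphere_energy_inputs
        c1 = 117e3
        W = model_energy(lam1, lam2, vols, "neohookean", c1=c1)
        pn = identify_parameters(_trace(W, sphere_dataset.pressures, vols),
                                 lam1, lam2, vols, "neohookean")
        assert pn.c1 == pytest.approx(c1, rel=1e-6)
        # the Ogden fit of NeoHookean data collapses to alpha = 2, mu = 2 C1
        po = identify_parameters(_trace(W, sphere_dataset.pressures, vols),
                                 lam1, lam2, vols, "ogden")
        assert po.alpha == pytest.approx(2.0, rel=1e-3)
        assert po.mu == pytest.approx(2 * c1, rel=1e-3)

    def test_noise_monte_carlo_median_within_10pc_and_ci_calibrated(
            self, sphere_dataset, sphere_spec):
        """2% multiplicative noise, 200 replicates: median estimates within
        10% of truth and ~95% CI coverage (50-frame schedule)."""
        from duramech.kinematics import deformation_history
        from duramech.synthetic import (SphereInflationSpec,
                                        simulate_sphere_inflation)

        spec = SphereInflationSpec()   # default 50-frame schedule
        ds = simulate_sphere_inflation(spec)
        states = deformation_history(ds, h0=spec.initial_thickness)
        lam1 = np.stack([s.lambda1 for s in states])
        lam2 = np.stack([s.lambda2 for s in states])
        vols = states[0].volume
        W0 = model_energy(lam1, lam2, vols, "ogden", mu=spec.mu,
                          alpha=spec.alpha)
        rng = np.random.default_rng(2024)
        mus, alphas, cover_mu, cover_a = [], [], 0, 0
        n_rep = 200
        for _ in range(n_rep):
            W = W0 * (1 + rng.normal(0, 0.02, W0.shape))
            p = identify_parameters(_trace(W, ds.pressures, vols),
                                    lam1, lam2, vols, "ogden")
            mus.append(p.mu)
            alphas.append(p.alpha)
            cover_mu += abs(p.mu - spec.mu) <= p.ci95["mu"]
            cover_a += abs(p.alpha - spec.alpha) <= p.ci95["alpha"]
        assert abs(np.median(mus) / spec.mu - 1) < 0.10
        assert abs(np.median(alphas) / spec.alpha - 1) < 0.10
        assert 0.88 <= cover_mu / n_rep <= 0.99
        assert 0.88 <= cover_a / n_rep <= 0.99

    def test_invariant_to_time_reparameterization(self, sphere_dataset,
                                                  sphere_energy_inputs,
                                                  sphere_spec):
        """Duplicating frame spacing (same states, different 'times') does not
        change the identified parameters: the fit sees only (W, stretches)."""
        lam1, lam2, vols = sphere_energy_inputs
        W = model_energy(lam1, lam2, vols, "ogden", mu=sphere_spec.mu,
                         alpha=sphere_spec.alpha)
        p1 = identify_parameters(_trace(W, sphere_dataset.pressures, vols),
                                 lam1, lam2, vols, "ogden")
        # non-uniform resampling of the same loading path
        idx = np.array([0, 1, 2, 3, 4, 5])
        p2 = identify_parameters(
            _trace(W[idx], sphere_dataset.pressures[idx] * 3.7, vols),
            lam1[idx], lam2[idx], vols, "ogden")
        assert p2.mu == pytest.approx(p1.mu, rel=1e-6)
        assert p2.alpha == pytest.approx(p1.alpha, rel=1e-6)

    def test_all_zero_energy_unidentifiable(self, sphere_energy_inputs):
        lam1, lam2, vols = sphere_energy_inputs
        with pytest.raises(ValueError, match="unidentifiable"):
            identify_parameters(_trace(np.zeros(6), np.zeros(6), vols),
                                lam1, lam2, vols, "ogden")

    def test_too_few_nonzero_frames_rejected(self, sphere_energy_inputs):
        lam1, lam2, vols = sphere_energy_inputs
        W = np.zeros(6)
        W[-2:] = [1e-6, 2e-6]
        with pytest.raises(ValueError, match=">= 5 frames"):
            identify_parameters(_trace(W, np.zeros(6), vols),
                                lam1[:6], lam2[:6], vols, "ogden")


def test_full_inverse_chain_recovers_generator_parameters(sphere_dataset,
                                                          sphere_states,
                                                          sphere_spec):
    """Kinematics -> inverse stress -> energy -> identification on noise-free
    synthetic data returns the generating Ogden parameters within 5%."""
    ds = sphere_dataset
    stress = [solve_membrane_stress(ds.mesh, ds.frames[k], ds.pressures[k],
                                    sphere_states[k].h).element_tensor
              for k in range(ds.n_frames)]
    vols = sphere_states[0].volume
    tr = experimental_energy(stress, [s.E for s in sphere_states], vols,
                             ds.pressures)
    lam1 = np.stack([s.lambda1 for s in sphere_states])
    lam2 = np.stack([s.lambda2 for s in sphere_states])
    p = identify_parameters(tr, lam1, lam2, vols, "ogden")
    assert p.mu == pytest.approx(sphere_spec.mu, rel=0.05)
    assert p.alpha == pytest.approx(sphere_spec.alpha, rel=0.05)
    assert p.r2 > 0.999
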