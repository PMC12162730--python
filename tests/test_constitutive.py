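"""Constitutive models: energies, stresses, mode drivers and calibration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from trivalve.constitutive import (
    AHYPER_PRINTED,
    HYPERFOAM_PURPLE,
    HYPERFOAM_ORANGE,
    AhyperParams,
    HyperfoamParams,
    DeformationState,
    InvalidDeformationError,
    StressStrainCurve,
    ahyper_energy,
    hyperfoam_energy,
    cauchy_stress,
    mode_response,
    incompressibility_error,
    fit_model,
    engineering_to_true,
    true_to_engineering,
)
from trivalve.fixtures import make_curves


class TestEnergies:
    def test_zero_at_identity_any_admissible_params(self):
        state = DeformationState.from_stretches(1.0, 1.0, 1.0)
        for p in (AHYPER_PRINTED, AhyperParams(0.01, 0.5, 0.1, 1.0, 2.0, 0.5, 3.0, 0.0)):
            assert ahyper_energy(state, p) == 0.0
        for p in (HYPERFOAM_PURPLE, HYPERFOAM_ORANGE):
            assert hyperfoam_energy(state, p) == 0.0

    def test_isochoric_uniaxial_value(self):
        # independent term-by-term evaluation of the energy froze this value
        state = DeformationState.from_stretches(1.1, 1.1**-0.5, 1.1**-0.5)
        w = ahyper_energy(state, AHYPER_PRINTED)
        assert w == pytest.approx(1.17e-2, rel=5e-3)

    def test_volumetric_term_closed_form(self):
        # pure dilation J = 1.1 with d = 0.002: (1/d)(J-1)^2 = 5 MPa exactly
        lam = 1.1 ** (1.0 / 3.0)
        state = DeformationState.from_stretches(lam, lam, lam)
        p = AhyperParams(0, 0, 0, 1e-12, 1.0, 1e-12, 1.0, 0.002)
        assert ahyper_energy(state, p) == pytest.approx(5.0, rel=1e-9)

    def test_printed_form_has_nonzero_rest_energy(self):
        state = DeformationState.from_stretches(1.0, 1.0, 1.0)
        w = ahyper_energy(state, AHYPER_PRINTED, printed_form=True)
        assert w != 0.0  # why the corrected bracket is the default

    def test_hyperfoam_isotropy_under_stretch_permutation(self):
        lams = (1.2, 0.9, 1.05)
        vals = {
            hyperfoam_energy(DeformationState.from_stretches(*perm), HYPERFOAM_PURPLE)
            for perm in [(lams[i], lams[j], lams[k])
                         for i, j, k in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]]
        }
        assert max(vals) - min(vals) < 1e-15

    def test_frame_indifference(self, rng):
        # energy invariant under rigid rotation of the deformation
        F = np.array([[1.1, 0.05, 0.0], [0.02, 0.95, 0.01], [0.0, 0.03, 1.02]])
        w0a = ahyper_energy(DeformationState(F), AHYPER_PRINTED)
        w0h = hyperfoam_energy(DeformationState(F), HYPERFOAM_PURPLE)
        for _ in range(100):
            R = Rotation.random(random_state=rng).as_matrix()
            state = DeformationState(R @ F)
            assert ahyper_energy(state, AHYPER_PRINTED) == pytest.approx(w0a, abs=1e-10)
            assert hyperfoam_energy(state, HYPERFOAM_PURPLE) == pytest.approx(
                w0h, abs=1e-10)

    def test_invalid_deformation_rejected(self):
        with pytest.raises(InvalidDeformationError):
            DeformationState.from_stretches(-0.5, 1.0, 1.0)
        with pytest.raises(InvalidDeformationError):
            DeformationState(np.diag([1.0, -1.0, 1.0]))


class TestCauchyStress:
    @pytest.mark.parametrize("params", [AHYPER_PRINTED, HYPERFOAM_PURPLE,
                                        HYPERFOAM_ORANGE],
                             ids=["ahyper", "foam_purple", "foam_orange"])
    def test_matches_finite_difference_of_energy(self, params, rng):
        energy = (ahyper_energy if isinstance(params, AhyperParams)
                  else hyperfoam_energy)
        for _ in range(5):
            F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.1:
                continue
            state = DeformationState(F)
            sig = cauchy_stress(state, params)
            assert np.allclose(sig, sig.T)
            h = 1e-6
            P = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    P[i, j] = (energy(DeformationState(Fp), params)
                               - energy(DeformationState(Fm), params)) / (2 * h)
            sig_fd = P @ F.T / np.linalg.det(F)
            scale = max(np.abs(sig_fd).max(), 1e-9)
            assert np.abs(sig - sig_fd).max() / scale < 1e-5

    def test_identity_stress(self):
        # the foam model is exactly stress-free at rest; the anisotropic model
        # as printed carries the negligible closed-form residual 2 a1 I
        state = DeformationState.from_stretches(1, 1, 1)
        assert np.allclose(cauchy_stress(state, HYPERFOAM_PURPLE), 0.0, atol=1e-14)
        expected = 2.0 * AHYPER_PRINTED.a1 * np.eye(3)
        assert np.allclose(cauchy_stress(state, AHYPER_PRINTED), expected, atol=1e-14)

    def test_coaxial_fiber_deformation_stays_diagonal(self):
        state = DeformationState.from_stretches(1.2, 0.95, 0.9)
        sig = cauchy_stress(state, AHYPER_PRINTED)
        off = sig - np.diag(np.diag(sig))
        assert np.abs(off).max() < 1e-12


class TestModeResponse:
    def test_zero_strain_zero_stress_all_modes(self):
        grid = np.array([0.0])
        for mode in ("equibiaxial_tension", "uniaxial_tension",
                     "unconfined_compression"):
            c = mode_response(AHYPER_PRINTED, mode, grid)
            assert c.stress[0] == 0.0

    def test_circumferential_dominates_axial_under_equibiaxial_stretch(self):
        # anisotropy ordering holds across the fitted strain range; the
        # contrast exceeds 5x at 20% strain
        grid = np.linspace(0.02, 0.25, 12)
        circ = mode_response(AHYPER_PRINTED, "equibiaxial_tension", grid).stress
        axial = mode_response(AHYPER_PRINTED, "equibiaxial_tension", grid,
                              direction="axial").stress
        assert np.all(circ >= axial)
        at20 = np.searchsorted(grid, 0.2) - 1
        ratio = circ[at20] / axial[at20]
        assert ratio > 5.0

    def test_unconfined_compression_small_strain_slope(self):
        # numeric slope vs the closed-form linearization of the foam energy
        # (true-stress/true-strain measure): E0 = mu alpha (1 + nu)
        grid = np.array([0.0, -1e-4])
        c = mode_response(HYPERFOAM_PURPLE, "unconfined_compression", grid,
                          direction="through_thickness")
        slope = c.stress[-1] / grid[-1]
        assert slope == pytest.approx(HYPERFOAM_PURPLE.youngs_modulus, rel=2e-3)
        assert HYPERFOAM_PURPLE.poisson == pytest.approx(
            HYPERFOAM_PURPLE.beta / (1 + 2 * HYPERFOAM_PURPLE.beta))

    def test_incompressible_equals_compressible_in_stiff_bulk_limit(self):
        grid = np.linspace(0.0, 0.2, 5)
        stiff = AhyperParams(**{**AHYPER_PRINTED.__dict__, "d": 1e-7})
        a = mode_response(stiff, "uniaxial_tension", grid).stress
        b = mode_response(AHYPER_PRINTED, "uniaxial_tension", grid,
                          compressibility="incompressible").stress
        assert np.allclose(a[1:], b[1:], rtol=1e-3)

    def test_strain_measure_conversions_roundtrip(self):
        eng = np.linspace(0.0, 0.3, 7)
        sig = np.linspace(0.0, 2.0, 7)
        eps, true_sig = engineering_to_true(eng, sig)
        eng2, sig2 = true_to_engineering(eps, true_sig)
        assert np.allclose(eng, eng2) and np.allclose(sig, sig2)


class TestIncompressibilityError:
    def test_printed_constants_stay_under_five_percent(self):
        assert incompressibility_error(AHYPER_PRINTED) <= 5.0

    def test_vanishes_as_d_goes_to_zero(self):
        tiny = AhyperParams(**{**AHYPER_PRINTED.__dict__, "d": 1e-9})
        assert incompressibility_error(tiny) < 1e-3

    def test_grows_monotonically_with_d(self):
        errs = [incompressibility_error(
            AhyperParams(**{**AHYPER_PRINTED.__dict__, "d": d}))
            for d in (0.002, 0.02, 0.2)]
        assert errs[0] < errs[1] < errs[2]

    def test_rejects_strain_beyond_fitted_range(self):
        with pytest.raises(ValueError):
            incompressibility_error(AHYPER_PRINTED, strain_max=0.4)


class TestFitModel:
    def test_noiseless_round_trip_recovers_parameters(self):
        curves = make_curves(AHYPER_PRINTED, noise_sd=0.0)
        res = fit_model(curves, "ahyper")
        assert res.success
        for name in ("c1", "c2", "a2", "a3"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(AHYPER_PRINTED, name), rel=0.01)

    def test_noisy_recovery_within_ten_percent(self):
        grid = np.linspace(0.0, 0.25, 60)
        curves = make_curves(AHYPER_PRINTED, strain_grid=grid, noise_sd=0.02,
                             seed=1)
        res = fit_model(curves, "ahyper")
        for name in ("c1", "c2"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(AHYPER_PRINTED, name), rel=0.10)

    def test_underdetermined_fit_rejected(self):
        one_point = StressStrainCurve("uniaxial_tension", "circumferential",
                                      np.array([0.1]), np.array([0.2]))
        with pytest.raises(ValueError, match="under-determined"):
            fit_model([one_point], "ahyper")

    def test_hyperfoam_round_trip(self):
        curves = make_curves(HYPERFOAM_PURPLE, model="hyperfoam", noise_sd=0.0,
                             compressibility="as_fitted")
        res = fit_model(curves, "hyperfoam", compressibility="as_fitted")
        assert res.params.mu == pytest.approx(HYPERFOAM_PURPLE.mu, rel=0.02)
        assert res.params.alpha == pytest.approx(HYPERFOAM_PURPLE.alpha, rel=0.02)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            AhyperParams(0, 0, 0, 1, -1, 1, 1, 0.002)
        with pytest.raises(ValueError):
            HyperfoamParams(mu=-1, alpha=2, beta=0.1)
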