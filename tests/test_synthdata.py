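import numpy as np
import pytest

from pvlhemo.compare import relative_error_series, summarize_errors
from pvlhemo.core import ThresholdSpec
from pvlhemo.errors import DomainError, ValidationError
from pvlhemo.geometry import enclosed_volume
from pvlhemo.rheostress import snapshot_stress
from pvlhemo.severity import critical_volume
from pvlhemo.synthdata import (
    PoiseuilleSpec,
    gaussian_jet_snapshot,
    icosphere,
    keyframe_set,
    newtonian_params,
    perturbed_variant,
    poiseuille_snapshot,
    synthetic_study,
)

from conftest import STUDY_VOLUMES


class TestPoiseuille:
    def test_total_volume_exact(self):
        spec = PoiseuilleSpec(n_r=16)
        snap = poiseuille_snapshot(spec)
        assert snap.total_fluid_volume == pytest.approx(
            np.pi * spec.R**2 * spec.L, rel=1e-12
        )

    def test_critical_fraction_converges_in_n_r(self):
        """The thresholded-volume error shrinks at first order or better in 1/n_r."""
        exact = 1.0 - 0.75**2
        errs = []
        for n_r in (25, 50, 100):
            spec = PoiseuilleSpec(n_r=n_r, n_theta=8, n_z=2)
            snap = snapshot_stress(poiseuille_snapshot(spec), newtonian_params(spec.mu))
            frac = critical_volume(snap, ThresholdSpec(300.0)) / snap.total_fluid_volume
            errs.append(abs(frac - exact))
        assert errs[2] <= errs[0] / 2 + 1e-12

    def test_above_wall_stress_empty(self, poiseuille):
        spec, snap = poiseuille
        assert critical_volume(snap, ThresholdSpec(spec.tau_wall * 1.01)) == 0.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            PoiseuilleSpec(n_r=4)
        with pytest.raises(ValidationError):
            PoiseuilleSpec(R=-1.0)


class TestGaussianJet:
    def test_centreline_shear_vanishes(self):
        snap = gaussian_jet_snapshot(bins=(4, 201, 2))  # odd ny puts cells at y ~ 0
        from pvlhemo.rheostress import strain_rate_and_shear

        _, gamma = strain_rate_and_shear(snap.cell_grad_v)
        y = snap.cell_centroid[:, 1]
        assert gamma[np.argmin(np.abs(y))] == pytest.approx(0.0, abs=1e-6)

    def test_shear_peaks_at_sigma(self):
        U, sigma = 4.0, 1e-3
        snap = gaussian_jet_snapshot(U=U, sigma=sigma, bins=(2, 400, 2))
        from pvlhemo.rheostress import strain_rate_and_shear

        _, gamma = strain_rate_and_shear(snap.cell_grad_v)
        y = snap.cell_centroid[:, 1]
        y_peak = abs(y[np.argmax(gamma)])
        assert y_peak == pytest.approx(sigma, rel=0.02)
        assert gamma.max() == pytest.approx(U / (sigma * np.sqrt(np.e)), rel=1e-3)

    def test_stress_linear_in_velocity(self):
        p = newtonian_params(3.5e-3)
        s1 = snapshot_stress(gaussian_jet_snapshot(U=2.0, bins=(2, 50, 2)), p)
        s2 = snapshot_stress(gaussian_jet_snapshot(U=4.0, bins=(2, 50, 2)), p)
        np.testing.assert_allclose(s2.cell_tau, 2.0 * s1.cell_tau, rtol=1e-12)


class TestKeyframeSet:
    def test_study_volumes_hit_exactly(self):
        kf = keyframe_set(icosphere(35.0, 2), STUDY_VOLUMES)
        for mesh, v in zip(kf.meshes, kf.volumes):
            assert enclosed_volume(mesh) == pytest.approx(v, rel=1e-12)

    def test_identity_when_volume_matches(self):
        base = icosphere(20.0, 2)
        v0 = enclosed_volume(base)
        kf = keyframe_set(base, [v0, v0 / 2.0])
        np.testing.assert_allclose(kf.meshes[0].vertices, base.vertices, atol=1e-9)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValidationError):
            keyframe_set(icosphere(20.0, 2), [1000.0, 2000.0])


class TestPerturbedVariant:
    def test_zero_delta_identity(self, poiseuille):
        from pvlhemo.severity import severity_series

        spec, snap = poiseuille
        ref = severity_series([snap], window=(0.0, 1.0))
        var = perturbed_variant(ref, 0.0)
        np.testing.assert_array_equal(var.frame.to_numpy(), ref.frame.to_numpy())

    def test_noisy_mean_matches_half_normal(self):
        """Mean |eps| of (1 + delta*eta) noise is 100|delta|sqrt(2/pi) %."""
        import pandas as pd

        from pvlhemo.severity import METRICS, SeveritySeries

        n = 10_000
        frame = pd.DataFrame({"time": np.linspace(0.04, 0.32, n)})
        for m in METRICS:
            frame[m] = 100.0
        ref = SeveritySeries(frame)
        delta = 0.04
        var = perturbed_variant(ref, delta, mode="noisy", seed=123)
        summ = summarize_errors(relative_error_series(ref, var))
        expected = 100.0 * delta * np.sqrt(2.0 / np.pi)
        se = 100.0 * delta * np.sqrt(1.0 - 2.0 / np.pi) / np.sqrt(n)
        assert summ.table.loc["V300", "eps_mean_pct"] == pytest.approx(expected, abs=3 * se)

    def test_large_delta_rejected(self, poiseuille):
        from pvlhemo.severity import severity_series

        spec, snap = poiseuille
        ref = severity_series([snap], window=(0.0, 1.0))
        with pytest.raises(DomainError):
            perturbed_variant(ref, 1.5)


@pytest.fixture(scope="module")
def study():
    return synthetic_study(seed=5, n_times=8, n_r=24)


class TestSyntheticStudy:
    def test_deterministic_given_seed(self, study):
        again = synthetic_study(seed=5, n_times=8, n_r=24)
        np.testing.assert_array_equal(
            study.reference.frame.to_numpy(), again.reference.frame.to_numpy()
        )
        for label in study.variants:
            np.testing.assert_array_equal(
                study.variants[label].frame.to_numpy(),
                again.variants[label].frame.to_numpy(),
            )

    def test_pipeline_recovers_injected_deltas(self, study):
        for label, delta in study.deltas.items():
            summ = summarize_errors(
                relative_error_series(study.reference, study.variants[label])
            )
            used = summ.table["n_used"] > 0
            np.testing.assert_allclose(
                summ.table.loc[used, "eps_mean_pct"].to_numpy(),
                100.0 * delta,
                rtol=1e-6,
            )

    def test_drive_integral_identity(self, study):
        assert study.drive.dV_total == pytest.approx(
            2.0 / 3.0 * study.drive.Qmax * study.drive.tmax, rel=1e-12
        )
        assert study.drive.dV_total == pytest.approx(
            (STUDY_VOLUMES[0] - STUDY_VOLUMES[-1]) * 1e-9, rel=1e-12
        )

    def test_snapshots_pass_schema_validation(self, study):
        for snap in study.snapshots:
            snap.validate()
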