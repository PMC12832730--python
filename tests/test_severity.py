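import dataclasses
import warnings

import numpy as np
import pytest

from pvlhemo.core import ThresholdSpec
from pvlhemo.errors import SchemaError, UsageError, ValidationError
from pvlhemo.severity import (
    FlowSnapshot,
    critical_volume,
    critical_wall_area,
    mean_wall_pressure,
    residence_time,
    severity_series,
    stress_extremes_and_averages,
)


class TestCriticalVolume:
    def test_all_or_nothing(self, toy_snapshot, threshold):
        hot = dataclasses.replace(toy_snapshot, cell_tau=np.array([600.0, 600.0]))
        assert critical_volume(hot, threshold) == pytest.approx(4e-9)
        cold = dataclasses.replace(toy_snapshot, cell_tau=np.array([0.0, 0.0]))
        assert critical_volume(cold, threshold) == 0.0

    def test_poiseuille_closed_form(self, poiseuille, threshold):
        """Linear tau(r) gives V(tau >= tau_c)/V = 1 - (tau_c/tau_wall)^2."""
        spec, snap = poiseuille
        frac = critical_volume(snap, threshold) / snap.total_fluid_volume
        assert frac == pytest.approx(1.0 - (300.0 / 400.0) ** 2, rel=1e-2)

    def test_partition_exact(self, poiseuille, threshold):
        """Critical and sub-critical volumes partition the fluid exactly."""
        spec, snap = poiseuille
        below = snap.cell_volume[~threshold.mask(snap.cell_tau)].sum()
        assert critical_volume(snap, threshold) + below == pytest.approx(
            snap.total_fluid_volume, rel=1e-14
        )

    @pytest.mark.parametrize("tau_pair", [(150.0, 300.0), (300.0, 400.0)])
    def test_monotone_in_threshold(self, poiseuille, tau_pair):
        spec, snap = poiseuille
        lo, hi = tau_pair
        assert critical_volume(snap, ThresholdSpec(lo)) >= critical_volume(
            snap, ThresholdSpec(hi)
        )

    def test_missing_tau_rejected(self, toy_snapshot, threshold):
        snap = dataclasses.replace(toy_snapshot, cell_tau=None)
        with pytest.raises(SchemaError):
            critical_volume(snap, threshold)


class TestCriticalWallArea:
    def test_hand_filter(self, toy_snapshot, threshold):
        # wall-pvl faces: (1e-6 m^2, 350 Pa) and (2e-6 m^2, 250 Pa) -> only the first
        assert critical_wall_area(toy_snapshot, threshold) == pytest.approx(1e-6)

    def test_inclusive_boundary(self, toy_snapshot):
        spec = ThresholdSpec(tau_c=350.0)
        assert critical_wall_area(toy_snapshot, spec) == pytest.approx(1e-6)
        strict = ThresholdSpec(tau_c=350.0, inclusive=False)
        assert critical_wall_area(toy_snapshot, strict) == 0.0

    def test_group_filter(self, toy_snapshot, threshold):
        all_walls = critical_wall_area(toy_snapshot, threshold, groups=None)
        assert all_walls == pytest.approx(6e-6)  # wall-lv face (420 Pa) included

    def test_unknown_group_rejected(self, toy_snapshot, threshold):
        with pytest.raises(UsageError):
            critical_wall_area(toy_snapshot, threshold, groups=("wall-aorta",))

    def test_threshold_above_all(self, toy_snapshot):
        assert critical_wall_area(toy_snapshot, ThresholdSpec(1e4)) == 0.0


class TestStressStats:
    def test_hand_averages(self, toy_snapshot, threshold):
        stats = stress_extremes_and_averages(toy_snapshot, threshold)
        # cells: tau 350 (V=1) and 500 (V=3) both critical
        assert stats.tauV_max == 500.0
        assert stats.tauV_avg == pytest.approx((350 * 1 + 500 * 3) / 4.0)
        # wall-pvl faces: max 350; only the 350 Pa face critical
        assert stats.tauA_max == 350.0
        assert stats.tauA_avg == pytest.approx(350.0)

    def test_uniform_field(self, toy_snapshot, threshold):
        snap = dataclasses.replace(
            toy_snapshot,
            cell_tau=np.array([400.0, 400.0]),
            wall_tau=np.array([400.0, 400.0, 400.0]),
        )
        stats = stress_extremes_and_averages(snap, threshold)
        assert stats.tauV_max == 400.0 and stats.tauA_max == 400.0
        assert stats.tauV_avg == pytest.approx(400.0, rel=1e-14)
        assert stats.tauA_avg == pytest.approx(400.0, rel=1e-14)

    def test_empty_critical_set_absent(self, toy_snapshot):
        stats = stress_extremes_and_averages(toy_snapshot, ThresholdSpec(1e4))
        assert np.isnan(stats.tauV_avg) and np.isnan(stats.tauA_avg)
        assert stats.tauV_max == 500.0  # maxima still reported

    def test_avg_bounded_by_threshold_and_max(self, poiseuille, threshold):
        spec, snap = poiseuille
        stats = stress_extremes_and_averages(snap, threshold)
        assert threshold.tau_c <= stats.tauV_avg <= stats.tauV_max


class TestResidenceTime:
    def test_uniform_cube(self, threshold):
        snap = FlowSnapshot(
            time=0.1,
            cell_volume=np.array([8e-6]),
            cell_centroid=np.zeros((1, 3)),
            cell_velocity=np.array([[2.0, 0, 0]]),
            cell_tau=np.array([400.0]),
        )
        u_avg, t300 = residence_time(snap, threshold)
        assert u_avg == pytest.approx(2.0)
        assert t300 == pytest.approx(0.02 / 2.0)

    def test_hand_weighting(self, toy_snapshot, threshold):
        u_avg, _ = residence_time(toy_snapshot, threshold)
        assert u_avg == pytest.approx((4.0 * 1 + 2.0 * 3) / 4.0)  # = 2.5

    def test_no_critical_cells_absent_with_warning(self, toy_snapshot):
        with pytest.warns(UserWarning):
            u_avg, t300 = residence_time(toy_snapshot, ThresholdSpec(1e4))
        assert np.isnan(u_avg) and np.isnan(t300)

    def test_t300_scales_linearly_with_geometry(self, toy_snapshot, threshold):
        """Cube-root homogeneity: scaling lengths by s scales t300 by s."""
        s = 2.0
        scaled = dataclasses.replace(
            toy_snapshot,
            cell_volume=toy_snapshot.cell_volume * s**3,
            cell_centroid=toy_snapshot.cell_centroid * s,
            wall_area=toy_snapshot.wall_area * s**2,
        )
        _, t300_base = residence_time(toy_snapshot, threshold)
        _, t300_scaled = residence_time(scaled, threshold)
        assert t300_scaled == pytest.approx(s * t300_base, rel=1e-12)


class TestMeanWallPressure:
    def test_hand_weighting(self, toy_snapshot):
        # wall-pvl: areas 1, 2 with pressures 100, 200 -> 500/3
        assert mean_wall_pressure(toy_snapshot, "wall-pvl") == pytest.approx(500.0 / 3.0)

    def test_uniform(self, toy_snapshot):
        snap = dataclasses.replace(toy_snapshot, wall_pressure=np.full(3, 123.0))
        assert mean_wall_pressure(snap, "wall-lv") == pytest.approx(123.0, rel=1e-14)

    def test_missing_channel_rejected(self, toy_snapshot):
        snap = dataclasses.replace(toy_snapshot, wall_pressure=None)
        with pytest.raises(SchemaError):
            mean_wall_pressure(snap, "wall-pvl")

    def test_unknown_group_rejected(self, toy_snapshot):
        with pytest.raises(UsageError):
            mean_wall_pressure(toy_snapshot, "wall-aorta")


class TestSeveritySeries:
    def _snap_at(self, t, toy_snapshot):
        return dataclasses.replace(toy_snapshot, time=t)

    def test_window_filter(self, toy_snapshot, threshold):
        snaps = [self._snap_at(t, toy_snapshot) for t in (0.02, 0.10, 0.35)]
        series = severity_series(snaps, threshold)
        assert series.times.tolist() == [0.10]

    def test_matches_per_snapshot_ops(self, toy_snapshot, threshold):
        series = severity_series([self._snap_at(0.1, toy_snapshot)], threshold)
        row = series.frame.iloc[0]
        assert row["V300"] == critical_volume(toy_snapshot, threshold)
        assert row["A300"] == critical_wall_area(toy_snapshot, threshold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u_avg, t300 = residence_time(toy_snapshot, threshold)
        assert row["u_avg"] == u_avg and row["t300"] == t300

    def test_unordered_times_rejected(self, toy_snapshot, threshold):
        snaps = [self._snap_at(t, toy_snapshot) for t in (0.2, 0.1)]
        with pytest.raises(ValidationError):
            severity_series(snaps, threshold)


class TestFlowSnapshotValidation:
    def test_negative_volume_rejected(self, toy_snapshot):
        with pytest.raises(ValidationError):
            dataclasses.replace(toy_snapshot, cell_volume=np.array([-1e-9, 1e-9]))

    def test_shape_mismatch_rejected(self, toy_snapshot):
        with pytest.raises(SchemaError):
            dataclasses.replace(toy_snapshot, cell_tau=np.array([1.0]))
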