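"""Ground-state-gated ensemble CD, delta-CD assembly, traces and windows."""

import numpy as np
import pytest

from trcdsim import (
    CDSpectrum,
    SpectralGrid,
    Transition,
    build_trcd,
    delta_cd,
    gaussian_broaden,
    instantaneous_spectrum,
    sampling_resolution_fs,
    trace,
    window_average,
)
from trcdsim.dynamics import DT_40AU_FS
from trcdsim.errors import (
    EmptyInputError,
    EmptyWindowError,
    GridMismatchError,
    ParameterError,
)
from trcdsim.trcd import first_extremum_fs

from conftest import make_trajectory


class TestInstantaneousSpectrum:
    def test_all_excited_gives_zero(self, grid):
        ens = [make_trajectory(traj_id=f"t{i}", n=10, hop_at=100.0) for i in range(4)]
        spec = instantaneous_spectrum(ens, 5.0, 0.5, grid)
        assert np.all(spec.delta_epsilon == 0.0)

    def test_two_identical_ground_equals_single_molecule(self, grid):
        ens = [make_trajectory(traj_id=f"t{i}", n=10) for i in range(2)]
        spec = instantaneous_spectrum(ens, 5.0, 0.5, grid)
        single = gaussian_broaden(
            [Transition(4.0, 100.0), Transition(4.8, -10.0)], grid, 0.5
        )
        np.testing.assert_allclose(spec.delta_epsilon, single.delta_epsilon,
                                   rtol=1e-12)

    def test_normalisation_by_total_ensemble_size(self, grid):
        # one decayed, one still excited: signal is S/2, not S
        ground = make_trajectory(traj_id="g", n=10)
        excited = make_trajectory(traj_id="e", n=10, hop_at=100.0)
        spec = instantaneous_spectrum([ground, excited], 5.0, 0.5, grid)
        single = gaussian_broaden(
            [Transition(4.0, 100.0), Transition(4.8, -10.0)], grid, 0.5
        )
        np.testing.assert_allclose(spec.delta_epsilon,
                                   0.5 * single.delta_epsilon, rtol=1e-12)

    def test_monotone_in_number_decayed(self, grid):
        specs = []
        for n_ground in (1, 2, 3):
            ens = [make_trajectory(traj_id=f"g{i}", n=10) for i in range(n_ground)]
            ens += [make_trajectory(traj_id=f"e{i}", n=10, hop_at=100.0)
                    for i in range(3 - n_ground)]
            specs.append(instantaneous_spectrum(ens, 5.0, 0.5, grid))
        mags = [np.abs(s.delta_epsilon).max() for s in specs]
        assert mags[0] <= mags[1] <= mags[2]

    def test_empty_ensemble_raises(self, grid):
        with pytest.raises(EmptyInputError):
            instantaneous_spectrum([], 0.0, 0.5, grid)

    def test_tau_out_of_range_raises(self, grid):
        ens = [make_trajectory(n=10)]
        with pytest.raises(ParameterError):
            instantaneous_spectrum(ens, 1e5, 0.5, grid)


class TestDeltaCD:
    def test_zero_instantaneous_keeps_reference(self, grid):
        ref = CDSpectrum(grid, np.linspace(-1, 1, len(grid)))
        zero = CDSpectrum(grid, np.zeros(len(grid)))
        for mode in ("add", "subtract"):
            out = delta_cd(zero, ref, mode)
            np.testing.assert_array_equal(out.delta_epsilon, ref.delta_epsilon)
            assert out.meta["combine_mode"] == mode

    def test_add_cancels_negated_reference(self, grid):
        ref = CDSpectrum(grid, np.linspace(-1, 1, len(grid)))
        out = delta_cd(-ref, ref, "add")
        assert np.allclose(out.delta_epsilon, 0.0)

    def test_modes_differ_by_twice_instantaneous(self, grid):
        rng = np.random.default_rng(0)
        inst = CDSpectrum(grid, rng.normal(size=len(grid)))
        ref = CDSpectrum(grid, rng.normal(size=len(grid)))
        diff = delta_cd(inst, ref, "add") - delta_cd(inst, ref, "subtract")
        np.testing.assert_allclose(diff.delta_epsilon, 2 * inst.delta_epsilon,
                                   rtol=1e-12)

    def test_grid_mismatch_raises(self, grid):
        other = SpectralGrid(np.linspace(250, 360, 30))
        with pytest.raises(GridMismatchError):
            delta_cd(CDSpectrum(grid, np.zeros(len(grid))),
                     CDSpectrum(other, np.zeros(len(other))))


def _toy_ensemble(n_frames=40, dt=1.0):
    rng = np.random.default_rng(8)
    out = []
    for i in range(3):
        hop = rng.uniform(5, 20)
        traj = make_trajectory(
            traj_id=f"toy{i}", n=n_frames, dt=dt, hop_at=hop,
            phi1=rng.uniform(-170, 170), phi2=rng.uniform(-170, 170),
            energies=(4.0 + 0.1 * i, 4.8 + 0.1 * i),
            rotatory=(50.0 + 20 * i, -5.0),
        )
        out.append(traj)
    return out


class TestBuildTRCD:
    def test_matrix_matches_per_delay_oracle(self, grid):
        ens = _toy_ensemble()
        ref = CDSpectrum(grid, np.linspace(-2, 0, len(grid)))
        matrix = build_trcd(ens, grid, lw_ev=0.5, stride=4, mode="add",
                            reference=ref)
        for row, tau in enumerate(matrix.delays_fs):
            inst = instantaneous_spectrum(ens, tau, 0.5, grid)
            expected = ref.delta_epsilon + inst.delta_epsilon
            np.testing.assert_allclose(matrix.values[row], expected, rtol=1e-12)

    def test_delay_spacing_is_stride_times_dt(self, grid):
        ens = _toy_ensemble(dt=DT_40AU_FS)
        ref = CDSpectrum(grid, np.zeros(len(grid)))
        matrix = build_trcd(ens, grid, stride=10, reference=ref)
        spacing = matrix.delays_fs[1] - matrix.delays_fs[0]
        assert spacing == pytest.approx(10 * DT_40AU_FS)

    def test_degenerate_stride_single_delay(self, grid):
        ens = _toy_ensemble(n_frames=30)
        ref = CDSpectrum(grid, np.zeros(len(grid)))
        matrix = build_trcd(ens, grid, stride=30, reference=ref)
        assert matrix.delays_fs.size == 1

    def test_reference_before_first_hop(self, grid):
        # gating: delta-CD rows before the earliest hop equal the reference
        ens = _toy_ensemble()
        first_hop = min(t.time_fs[t.hop_index] for t in ens)
        ref = CDSpectrum(grid, np.linspace(-3, 1, len(grid)))
        matrix = build_trcd(ens, grid, stride=1, reference=ref)
        rows = matrix.delays_fs < first_hop
        assert rows.any()
        for row in np.nonzero(rows)[0]:
            np.testing.assert_array_equal(matrix.values[row], ref.delta_epsilon)

    def test_mode_consistency(self, grid):
        ens = _toy_ensemble()
        ref = CDSpectrum(grid, np.linspace(-2, 0, len(grid)))
        add = build_trcd(ens, grid, stride=5, mode="add", reference=ref)
        sub = build_trcd(ens, grid, stride=5, mode="subtract", reference=ref)
        expected = np.broadcast_to(2 * ref.delta_epsilon,
                                   add.values.shape)
        np.testing.assert_allclose(add.values + sub.values, expected,
                                   rtol=1e-12)

    def test_ragged_ensemble_truncated_with_warning(self, grid):
        ens = _toy_ensemble() + [make_trajectory(traj_id="short", n=20)]
        ref = CDSpectrum(grid, np.zeros(len(grid)))
        with pytest.warns(UserWarning, match="ragged"):
            matrix = build_trcd(ens, grid, stride=5, reference=ref)
        assert matrix.delays_fs[-1] <= 19.0


class TestTraceAndWindows:
    def test_trace_exact_column(self, grid):
        ens = _toy_ensemble()
        ref = CDSpectrum(grid, np.zeros(len(grid)))
        matrix = build_trcd(ens, grid, stride=5, reference=ref)
        wl = grid.wavelengths_nm[17]
        np.testing.assert_array_equal(trace(matrix, wl), matrix.values[:, 17])

    def test_trace_nearest_neighbour(self, grid):
        ens = _toy_ensemble()
        ref = CDSpectrum(grid, np.zeros(len(grid)))
        matrix = build_trcd(ens, grid, stride=5, reference=ref)
        wl = grid.wavelengths_nm[17] + 0.3  # off-grid: snaps to 17
        np.testing.assert_array_equal(trace(matrix, wl), matrix.values[:, 17])

    def test_trace_out_of_range(self, grid):
        ens = _toy_ensemble()
        matrix = build_trcd(ens, grid, stride=5,
                            reference=CDSpectrum(grid, np.zeros(len(grid))))
        with pytest.raises(ParameterError):
            trace(matrix, 1000.0)

    def test_window_single_delay(self, grid):
        ens = _toy_ensemble()
        matrix = build_trcd(ens, grid, stride=5,
                            reference=CDSpectrum(grid, np.zeros(len(grid))))
        tau = matrix.delays_fs[2]
        spec = window_average(matrix, tau - 0.1, tau + 0.1)
        np.testing.assert_array_equal(spec.delta_epsilon, matrix.values[2])

    def test_window_full_range_is_grand_mean(self, grid):
        ens = _toy_ensemble()
        matrix = build_trcd(ens, grid, stride=5,
                            reference=CDSpectrum(grid, np.zeros(len(grid))))
        spec = window_average(matrix, -1.0, 1e9)
        np.testing.assert_allclose(spec.delta_epsilon, matrix.values.mean(axis=0))

    def test_window_mask_oracle(self, grid):
        ens = _toy_ensemble()
        matrix = build_trcd(ens, grid, stride=2,
                            reference=CDSpectrum(grid, np.zeros(len(grid))))
        t0, t1 = 6.0, 21.0
        mask = np.array([(t0 <= d <= t1) for d in matrix.delays_fs])
        spec = window_average(matrix, t0, t1)
        np.testing.assert_allclose(spec.delta_epsilon,
                                   matrix.values[mask].mean(axis=0))

    def test_empty_window_raises(self, grid):
        ens = _toy_ensemble()
        matrix = build_trcd(ens, grid, stride=5,
                            reference=CDSpectrum(grid, np.zeros(len(grid))))
        with pytest.raises(EmptyWindowError):
            window_average(matrix, 1e5, 2e5)


def test_sampling_resolution():
    assert sampling_resolution_fs(10, DT_40AU_FS) == pytest.approx(9.6754)
    with pytest.raises(ParameterError):
        sampling_resolution_fs(0, 1.0)


def test_first_extremum_detector():
    delays = np.arange(0.0, 3000.0, 10.0)
    curve = -3.0 + 2.0 * np.exp(-((delays - 800.0) ** 2) / (2 * 250.0**2))
    curve += 0.05 * np.sin(delays / 4.0)  # fast overlay to be smoothed away
    t = first_extremum_fs(delays, curve)
    assert t == pytest.approx(800.0, abs=60.0)
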