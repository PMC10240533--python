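"""Dihedrals, rotamer classification, occupancies and dephasing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trcdsim import DEFAULT_WINDOWS, classify, dephasing_time, dihedral, occupancy
from trcdsim.conformers import RotamerLabel, classify_codes, wrap_deg
from trcdsim.errors import GeometryError, SampleSizeError

from conftest import make_trajectory


class TestDihedral:
    def test_planar_cis_is_zero(self):
        # all four atoms in a plane, 1 and 4 on the same side
        assert dihedral((1, 1, 0), (0, 0, 0), (1, 0, 0), (2, 1, 0)) == pytest.approx(0.0)

    def test_planar_anti_is_180(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_matches_mdanalysis_oracle(self):
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(11)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3.0
            ref = np.degrees(
                calc_dihedrals(
                    pts[0][None].astype(np.float32),
                    pts[1][None].astype(np.float32),
                    pts[2][None].astype(np.float32),
                    pts[3][None].astype(np.float32),
                )
            )[0]
            got = dihedral(*pts)
            # compare on the circle (MDA may return -180 vs +180)
            assert abs(wrap_deg(got - ref)) < 1e-3

    def test_degenerate_geometry_raises(self):
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))  # coincident
        with pytest.raises(GeometryError):
            dihedral((2, 0, 0), (1, 0, 0), (0, 0, 0), (0, 1, 0))  # collinear


class TestClassify:
    @pytest.mark.parametrize(
        "phi1,phi2,expected",
        [
            (-60, -60, "g-Zg-"),
            (170, -65, "t+Zg-"),
            (120, 121, "g+Zt+"),  # boundary: |120| is still gauche
            (0, 180, "g+Zt+"),     # 0 -> g+, 180 -> t+ by the wrap convention
            (-121, 60, "t-Zg+"),
        ],
    )
    def test_examples(self, phi1, phi2, expected):
        assert str(classify(phi1, phi2)) == expected

    @given(
        # stay a few ulp away from the wrap boundary: adding 360k and
        # re-wrapping can legitimately cross it by one rounding step
        phi1=st.floats(-179.999, 179.999),
        phi2=st.floats(-179.999, 179.999),
        k1=st.integers(-3, 3),
        k2=st.integers(-3, 3),
    )
    @settings(max_examples=200, derandomize=True)
    def test_invariant_under_full_turns(self, phi1, phi2, k1, k2):
        assert classify(phi1 + 360 * k1, phi2 + 360 * k2) == classify(phi1, phi2)

    @given(
        phi1=st.floats(-179.5, 179.5),
        phi2=st.floats(-179.5, 179.5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_point_symmetry(self, phi1, phi2):
        # avoid the measure-zero boundaries where inversion is not exact
        for p in (phi1, phi2):
            if abs(abs(p) - 120.0) < 1e-6 or abs(p) < 1e-6:
                return
        assert classify(-phi1, -phi2) == classify(phi1, phi2).inverted

    def test_vectorised_codes_agree_with_scalar(self):
        rng = np.random.default_rng(3)
        p1 = rng.uniform(-400, 400, 100)
        p2 = rng.uniform(-400, 400, 100)
        codes = classify_codes(p1, p2)
        from trcdsim.conformers import LABELS

        for a, b, c in zip(p1, p2, codes):
            assert classify(a, b) == LABELS[c]


class TestOccupancy:
    def test_single_conformer_everywhere(self):
        trajs = [make_trajectory(n=5000, phi1=-60, phi2=-60) for _ in range(3)]
        table = occupancy(trajs, DEFAULT_WINDOWS)
        for window in table.fractions:
            assert table.fractions[window] == {"g-Zg-": pytest.approx(1.0)}

    def test_even_split(self):
        t1 = make_trajectory(n=2000, phi1=-60, phi2=-60)
        t2 = make_trajectory(n=2000, phi1=170, phi2=-65)
        table = occupancy([t1, t2], {"W": (0.0, 2000.0)})
        assert table.fractions["W"]["g-Zg-"] == pytest.approx(0.5)
        assert table.fractions["W"]["t+Zg-"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self, preset_ensemble):
        table = occupancy(preset_ensemble)
        for window, frac in table.fractions.items():
            assert sum(frac.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_window_warns_and_is_omitted(self):
        traj = make_trajectory(n=10, hop_at=None)
        with pytest.warns(UserWarning, match="no ground-state"):
            table = occupancy([traj], {"late": (1e6, 2e6)})
        assert "late" not in table.fractions

    def test_excited_and_closed_frames_excluded(self):
        # ring-closed trajectory contributes nothing
        closed = make_trajectory(n=100, ring_open=False)
        with pytest.warns(UserWarning):
            table = occupancy([closed], {"W": (0, 100)})
        assert table.fractions == {}


def _drift_ensemble(n_traj, sigma_omega_deg_fs, t_total=4000.0, dt=9.6, seed=5):
    """Trajectories with constant per-trajectory angular velocity; the
    circular order parameter is exp(-sigma^2 t^2 / 2) in closed form."""
    rng = np.random.default_rng(seed)
    omegas = rng.normal(0.0, sigma_omega_deg_fs, n_traj)
    n = int(t_total / dt)
    out = []
    for i, w in enumerate(omegas):
        times = np.arange(n) * dt
        out.append(
            make_trajectory(traj_id=f"d{i}", n=n, dt=dt, phi1=wrap_deg(w * times))
        )
    return out


class TestDephasing:
    def test_identical_trajectories_never_dephase(self):
        trajs = [make_trajectory(traj_id=f"t{i}", n=500, dt=9.6) for i in range(12)]
        res = dephasing_time(trajs)
        assert not res.reached
        assert res.time_fs == np.inf

    def test_gaussian_velocity_spread_closed_form(self):
        # r(t) = exp(-sigma_w^2 t^2 / 2)  =>  r = 1/e at t = sqrt(2)/sigma_w
        sigma_deg = 0.04  # deg/fs
        sigma_rad = np.radians(sigma_deg)
        expected = np.sqrt(2.0) / sigma_rad
        res = dephasing_time(_drift_ensemble(2000, sigma_deg))
        assert res.reached
        assert res.time_fs == pytest.approx(expected, rel=0.05)

    def test_nonincreasing_in_velocity_spread(self):
        t_small = dephasing_time(_drift_ensemble(800, 0.04)).time_fs
        t_large = dephasing_time(_drift_ensemble(800, 0.08)).time_fs
        assert t_large <= t_small

    def test_too_few_trajectories_raises(self):
        with pytest.raises(SampleSizeError):
            dephasing_time([make_trajectory(n=50)] * 5)


def test_rotamer_label_parsing_roundtrip():
    for s in ("g+Zg-", "t-Zt+", "t+Zg-"):
        assert str(RotamerLabel.from_string(s)) == s
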