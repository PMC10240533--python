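"""Fewest-switches surface hopping on the 1D two-state model."""

import numpy as np
import pytest
from scipy.optimize import brentq

from trcdsim.errors import ParameterError
from trcdsim.fssh import (
    ModelPotential,
    SHState,
    adiabats,
    fssh_step,
    ring_opening_preset,
    run_fssh_ensemble,
)


class TestAdiabats:
    def test_zero_coupling_equals_diabats(self):
        pot = ModelPotential(c0=0.0, c1=0.0)
        for x in (-1.5, 0.0, 1.2):
            lo, up, d = adiabats(pot, x)
            v1, v2 = pot.v1(x), pot.v2(x)
            assert lo == pytest.approx(min(v1, v2))
            assert up == pytest.approx(max(v1, v2))

    def test_gap_at_crossing_is_twice_coupling(self):
        pot = ring_opening_preset()
        x_cross = brentq(lambda x: pot.v1(x) - pot.v2(x), -1.3, -0.5)
        lo, up, _ = adiabats(pot, x_cross)
        assert up - lo == pytest.approx(2 * pot.coupling(x_cross), rel=1e-10)

    def test_matches_eigensolver_and_fd_coupling(self):
        pot = ring_opening_preset()
        rng = np.random.default_rng(5)
        h = 1e-5
        for x in rng.uniform(-2.0, 3.0, 25):
            hmat = np.array([[pot.v1(x), pot.coupling(x)],
                             [pot.coupling(x), pot.v2(x)]])
            evals = np.linalg.eigvalsh(hmat)
            lo, up, d = adiabats(pot, x)
            assert lo == pytest.approx(evals[0], rel=1e-10, abs=1e-14)
            assert up == pytest.approx(evals[1], rel=1e-10, abs=1e-14)
            # FD of the 2x2 mixing angle = derivative coupling
            def theta(xx):
                return 0.5 * np.arctan2(
                    2 * pot.coupling(xx), pot.v1(xx) - pot.v2(xx)
                )
            d_fd = (theta(x + h) - theta(x - h)) / (2 * h)
            assert d == pytest.approx(d_fd, rel=1e-5, abs=1e-8)


class TestStep:
    def test_zero_coupling_conserves_energy_and_populations(self):
        # small orbit inside the closed-ring well, far from any diabat
        # degeneracy, with the coupling switched off entirely
        pot = ModelPotential(c0=0.0, c1=0.0)
        rng = np.random.default_rng(0)
        s = SHState(x=pot.x_closed + 0.1, p=0.0, active=0,
                    c=np.array([np.sqrt(0.4), np.sqrt(0.6)], complex))
        e0 = s.total_energy(pot)
        pops0 = np.abs(s.c) ** 2
        for _ in range(10000):
            s = fssh_step(s, pot, 0.01, rng)
        assert abs(s.total_energy(pot) - e0) / abs(e0) < 1e-8
        np.testing.assert_allclose(np.abs(s.c) ** 2, pops0, atol=1e-12)

    def test_amplitude_norm_machine_conserved(self):
        pot = ring_opening_preset()
        rng = np.random.default_rng(1)
        s = SHState(x=-1.5, p=0.0, active=1, c=np.array([0, 1], complex))
        worst = 0.0
        prev = s.norm
        for _ in range(2000):
            s = fssh_step(s, pot, 2.0, rng)
            worst = max(worst, abs(s.norm - prev))
            prev = s.norm
        assert worst < 1e-6  # unitary propagator: in fact ~1e-15

    def test_hop_conserves_total_energy(self):
        """Force a hop via the hazard threshold and compare against the
        identical step without the hop: the rescale must leave the total
        energy unchanged to machine precision."""
        pot = ring_opening_preset()
        x_cross = brentq(lambda x: pot.v1(x) - pot.v2(x), -1.3, -0.5)
        base = dict(x=x_cross, p=4.0, active=1,
                    c=np.array([np.sqrt(0.3), np.sqrt(0.7)], complex))
        hop = fssh_step(SHState(**base, survival=1.0, threshold=1.0),
                        pot, 2.0, np.random.default_rng(0))
        nohop = fssh_step(SHState(**base, survival=1.0, threshold=0.0),
                          pot, 2.0, np.random.default_rng(0))
        assert hop.active == 0 and nohop.active == 1
        assert hop.total_energy(pot) == pytest.approx(
            nohop.total_energy(pot), rel=1e-9
        )

    def test_frustrated_hop_keeps_velocity(self):
        # far up the left wall with almost no kinetic energy: an upward hop
        # is forbidden; state and momentum must be untouched
        pot = ring_opening_preset()
        s = SHState(x=-1.5, p=0.5, active=0, c=np.array([1, 0], complex),
                    survival=1.0, threshold=1.0)
        out = fssh_step(s, pot, 1.0, np.random.default_rng(0))
        assert out.active == 0
        assert out.p == pytest.approx(s.p, rel=0.05)  # only Verlet evolution

    def test_invalid_dt_rejected(self):
        pot = ring_opening_preset()
        s = SHState(x=0.0, p=0.0, active=0, c=np.array([1, 0], complex))
        with pytest.raises(ParameterError):
            fssh_step(s, pot, -1.0)


class TestEnsemble:
    def test_same_seed_identical_hop_times(self):
        pot = ring_opening_preset()
        a = run_fssh_ensemble(pot, n=50, seed=3, dt_au=2.0, t_max_fs=400.0)
        b = run_fssh_ensemble(pot, n=50, seed=3, dt_au=2.0, t_max_fs=400.0)
        np.testing.assert_array_equal(a.hop_times_fs, b.hop_times_fs)

    def test_no_coupling_reach_means_no_hops(self):
        # couplings far outside the classically allowed region
        pot = ModelPotential(x_c=-30.0, x_c2=30.0)
        res = run_fssh_ensemble(pot, n=40, seed=0, dt_au=2.0, t_max_fs=300.0)
        assert res.no_hop.all()
        assert np.all(np.isnan(res.hop_times_fs))

    def test_preset_hops_complete_and_branching_sane(self):
        res = run_fssh_ensemble(n=200, seed=4, dt_au=2.0, t_max_fs=2000.0)
        assert res.no_hop.sum() == 0
        assert np.nanmax(res.hop_times_fs) <= 2000.0
        assert 0.40 < res.open_fraction < 0.80  # tight band checked at n=500

    def test_single_crossing_scattering_converges_with_dt(self):
        """Fixed incoming momentum through the inner crossing only; the
        hopped fraction at halved dt (the dense brute-force reference)
        agrees within one percentage point."""
        pot = ring_opening_preset()
        frac = {}
        for dt in (2.0, 1.0):
            res = run_fssh_ensemble(pot, n=600, seed=6, dt_au=dt, t_max_fs=40.0,
                                    x0_mean=-1.5, x0_sigma=0.01, p0_sigma=0.01)
            frac[dt] = 1.0 - res.no_hop.mean()
        assert frac[2.0] > 0.05  # the passage does produce hops
        assert abs(frac[2.0] - frac[1.0]) < 0.01
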