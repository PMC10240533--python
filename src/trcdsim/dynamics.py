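"""Synthetic surface-hopping trajectory ensembles.

This module emulates, statistically, a 116-trajectory nonadiabatic
ensemble of the provitamin D ring-opening: every trajectory starts in the
first excited state at the pump instant, decays to the ground state at a
random hop time (all within 2 ps, >90% within the first ~0.96 ps), and
with probability equal to the ring-opening quantum yield (62%) forms the
open-ring previtamin.  Open trajectories then walk through the observed
rotamer cascade

    g-Zg-  ->  t+Zg-  ->  {g+Zg+ | g+Zt-}  ->  t+Zt+  ->  t-Zg+  ->  equilibrium

as a continuous-time jump process with exponential waiting times; after
the last directed step the chain switches to memoryless exchange with the
equilibrium rotamer weights.  Between jumps the torsions relax toward the
current label center by exponential approach plus small Gaussian jitter.
The stochastic spread of the waiting times is the rotational-dephasing
mechanism: with the preset rates the circular order parameter crosses 1/e
in the 3-6 ps range.  A jump process rather than Langevin torsional
dynamics is a deliberate model choice: it reproduces the observed rotamer
sequence exactly, is exactly seedable, and exposes transparent rate knobs.

Failed (ring-closed) trajectories keep Pro-like torsions and revert to the
static two-state parent transition table (hot ground-state parent).
Per-frame transition energies and rotatory strengths come from the
surrogate surfaces with a per-trajectory bond-vibration phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformers import wrap_deg
from .errors import ParameterError
from .surrogate import (
    DEFAULT_PARAMS,
    SurrogateParams,
    label_center,
    load_equilibrium_weights,
    load_pro_transitions,
)
from .trcd import Trajectory

__all__ = [
    "GeneratorConfig",
    "sample_hop_time",
    "generate_trajectory",
    "generate_ensemble",
    "trajectory_rng",
    "vibration_period_fs",
]

#: 40 atomic time units, the nuclear time step of the reference dynamics.
DT_40AU_FS = 0.96754


@dataclass
class GeneratorConfig:
    """All stochastic-model parameters of the ensemble generator.

    The defaults *are* the paper-calibration preset: N = 116 trajectories,
    dt = 40 au, 4.8 ps horizon, 62% ring-opening yield, excited-state decay
    complete within 2 ps with >90% decayed by ~0.96 ps, the rotamer-cascade
    waiting times, and a 25 fs bond-vibration overlay.
    """

    n_trajectories: int = 116
    dt_fs: float = DT_40AU_FS
    t_total_fs: float = 4800.0
    quantum_yield: float = 0.62

    # Hop-time model: offset + Gamma(shape, scale), truncated by resampling.
    hop_shape: float = 2.0
    hop_scale_fs: float = 130.0
    hop_offset_fs: float = 50.0
    hop_truncation_fs: float = 2000.0

    # Mean exponential waiting times (fs) along the cascade edges.
    wait_gg_to_tg_fs: float = 200.0
    wait_tg_to_split_fs: float = 420.0
    wait_split_to_tt_fs: float = 650.0
    wait_tt_to_tg2_fs: float = 800.0
    wait_tg2_to_eq_fs: float = 800.0
    wait_eq_exchange_fs: float = 700.0
    split_fraction: float = 0.5  # branch weight of g+Zg+ vs g+Zt-

    # Torsional kinematics.
    relax_tau_fs: float = 80.0
    angle_jitter_deg: float = 12.0   # spread of the initial (-60,-60) draw
    frame_jitter_deg: float = 2.0    # per-frame Gaussian noise on angles
    omega_spread_deg_fs: float = 0.0  # optional per-trajectory constant drift

    # Fast-vibration overlay (delegated to the surrogate when evaluating
    # transitions; the period here controls the phase ramp).
    vib_period_fs: float = 25.0

    seed: int = 0
    surrogate: SurrogateParams = field(default_factory=lambda: DEFAULT_PARAMS)

    def __post_init__(self):
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise ParameterError("quantum_yield must be in [0, 1]")
        if not 0.0 <= self.split_fraction <= 1.0:
            raise ParameterError("split_fraction must be in [0, 1]")
        if self.dt_fs <= 0:
            raise ParameterError("dt_fs must be > 0")
        if self.n_trajectories < 1:
            raise ParameterError("n_trajectories must be >= 1")
        if self.hop_truncation_fs > self.t_total_fs:
            raise ParameterError("hop truncation must not exceed t_total")
        if min(self.hop_shape, self.hop_offset_fs, self.hop_scale_fs) < 0:
            raise ParameterError("hop-time parameters must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.t_total_fs / self.dt_fs)) + 1


def sample_hop_time(config: GeneratorConfig, rng: np.random.Generator) -> float:
    """Draw one S1->S0 hop time (fs): shifted gamma, truncated at 2 ps.

    Truncation is by resampling, so the returned value never exceeds
    ``hop_truncation_fs``.  A zero-variance configuration (scale 0)
    degenerates to the offset.
    """
    if config.hop_offset_fs > config.hop_truncation_fs:
        raise ParameterError("hop offset exceeds the truncation bound")
    for _ in range(10000):
        t = config.hop_offset_fs + config.hop_scale_fs * rng.standard_gamma(
            config.hop_shape
        )
        if t <= config.hop_truncation_fs:
            return float(t)
    raise ParameterError("hop-time distribution mass almost entirely above truncation")


def _label_sequence(config: GeneratorConfig, hop_fs: float,
                    rng: np.random.Generator, eq_labels, eq_probs):
    """Event list [(t_fs, label_str), ...] for one open trajectory.

    The first event is the hop itself (entering g-Zg-); the directed
    cascade follows, then memoryless equilibrium exchange to the horizon.
    """
    events = [(hop_fs, "g-Zg-")]
    t = hop_fs + rng.exponential(config.wait_gg_to_tg_fs)
    events.append((t, "t+Zg-"))
    t += rng.exponential(config.wait_tg_to_split_fs)
    branch = "g+Zg+" if rng.random() < config.split_fraction else "g+Zt-"
    events.append((t, branch))
    t += rng.exponential(config.wait_split_to_tt_fs)
    events.append((t, "t+Zt+"))
    t += rng.exponential(config.wait_tt_to_tg2_fs)
    events.append((t, "t-Zg+"))
    t += rng.exponential(config.wait_tg2_to_eq_fs)
    while t <= config.t_total_fs:
        events.append((t, eq_labels[rng.choice(len(eq_labels), p=eq_probs)]))
        t += rng.exponential(config.wait_eq_exchange_fs)
    return events


def _angles_from_events(times, start, events, config):
    """Piecewise exponential relaxation of (phi1, phi2) through the event
    list.  Returns two (n,) arrays (before jitter)."""
    phi1 = np.empty_like(times)
    phi2 = np.empty_like(times)
    cur = np.array(start, dtype=float)
    # segment 0 runs from t=0 relaxing toward the pre-hop (closed) center
    seg_list = [(0.0, np.array(label_center("g-Zg-")))]
    for (t_ev, lab) in events:
        seg_list.append((t_ev, np.array(label_center(lab))))
    seg_list.append((np.inf, None))
    for k in range(len(seg_list) - 1):
        t0, center = seg_list[k]
        t1 = seg_list[k + 1][0]
        m = (times >= t0) & (times < t1)
        if not m.any():
            # still advance the state to the segment end
            if np.isfinite(t1):
                delta = wrap_deg(cur - center)
                cur = wrap_deg(center + delta * np.exp(-(t1 - t0) / config.relax_tau_fs))
            continue
        delta = wrap_deg(cur - center)
        decay = np.exp(-(times[m] - t0) / config.relax_tau_fs)
        phi1[m] = center[0] + delta[0] * decay
        phi2[m] = center[1] + delta[1] * decay
        if np.isfinite(t1):
            end_decay = np.exp(-(t1 - t0) / config.relax_tau_fs)
            cur = wrap_deg(center + delta * end_decay)
    return phi1, phi2


def generate_trajectory(
    config: GeneratorConfig, rng: np.random.Generator, traj_id: str = "traj"
) -> Trajectory:
    """Generate one trajectory; fully determined by (config, rng state)."""
    n = config.n_frames
    times = np.arange(n) * config.dt_fs

    hop = sample_hop_time(config, rng)
    is_open = bool(rng.random() < config.quantum_yield)
    start = wrap_deg(
        np.array(label_center("g-Zg-")) + rng.normal(0.0, config.angle_jitter_deg, 2)
    )
    vib_phase0 = rng.uniform(0.0, 2.0 * np.pi)
    omega = rng.normal(0.0, config.omega_spread_deg_fs)

    state = np.where(times < hop, 1, 0)
    ring_open = np.zeros(n, dtype=bool)

    eqw = load_equilibrium_weights()
    eq_labels = [k for k, v in eqw.items() if v > 0]
    eq_probs = np.array([eqw[k] for k in eq_labels])
    eq_probs /= eq_probs.sum()

    if is_open:
        ring_open[times >= hop] = True
        events = _label_sequence(config, hop, rng, eq_labels, eq_probs)
        phi1, phi2 = _angles_from_events(times, start, events, config)
    else:
        # failed opening: torsions stay near the parent geometry
        phi1 = np.full(n, start[0])
        phi2 = np.full(n, start[1])

    jitter = rng.normal(0.0, config.frame_jitter_deg, size=(n, 2))
    phi1 = wrap_deg(phi1 + jitter[:, 0])
    phi2 = wrap_deg(phi2 + jitter[:, 1])
    if omega != 0.0:
        drift = omega * np.clip(times - hop, 0.0, None)
        phi1 = wrap_deg(phi1 + drift)

    vib_phase = 2.0 * np.pi * times / config.vib_period_fs + vib_phase0

    params = config.surrogate
    pro = load_pro_transitions()
    pro_e = np.array([t.energy_ev for t in pro])
    pro_r = np.array([t.rotatory for t in pro])
    # parent-like transitions with the fast-vibration overlay
    mod_e = params.e_vib_amp_ev * np.cos(vib_phase)
    mod_r = 1.0 + params.r_vib_eps * np.cos(vib_phase)
    energies = pro_e[None, :] + mod_e[:, None]
    rotatory = pro_r[None, :] * mod_r[:, None]
    if is_open:
        from .surrogate import transitions_at

        post = times >= hop
        e_open, r_open = transitions_at(phi1[post], phi2[post], vib_phase[post], params)
        energies = energies.copy()
        rotatory = rotatory.copy()
        energies[post] = e_open
        rotatory[post] = r_open

    return Trajectory(
        id=traj_id,
        time_fs=times,
        state=state,
        phi1=phi1,
        phi2=phi2,
        ring_open=ring_open,
        energies_ev=energies,
        rotatory=rotatory,
    )


def trajectory_rng(seed: int, index: int) -> np.random.Generator:
    """The independent substream used for trajectory ``index`` of an
    ensemble with master seed ``seed`` (counter-based spawn, so n and seed
    fully determine the output)."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(index + 1)[index])


def generate_ensemble(config: GeneratorConfig) -> list[Trajectory]:
    """Generate the full ensemble from the master seed; reproducible."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_trajectories)
    return [
        generate_trajectory(config, np.random.default_rng(children[i]),
                            traj_id=f"traj_{i:03d}")
        for i in range(config.n_trajectories)
    ]


def vibration_period_fs(traj: Trajectory, state_index: int = 0,
                        detrend_fs: float = 100.0,
                        period_band_fs: tuple = (5.0, 60.0)) -> float:
    """Dominant fast-oscillation period of a rotatory-strength series.

    Takes the post-hop part of the per-frame rotatory strength of one
    transition, removes the slow conformational drift with a moving-average
    high-pass (window ``detrend_fs``), and returns the periodogram peak
    inside ``period_band_fs``.  At the preset this recovers the 20-30 fs
    bond-vibration overlay of the conjugated triene.
    """
    from scipy.signal import periodogram

    k = traj.hop_index
    if k is None:
        raise ParameterError("trajectory never reached the ground state")
    series = traj.rotatory[k:, state_index]
    dt = traj.dt_fs
    w = max(3, int(round(detrend_fs / dt)))
    ypad = np.concatenate([np.full(w // 2, series[0]), series,
                           np.full(w - 1 - w // 2, series[-1])])
    trend = np.convolve(ypad, np.ones(w) / w, mode="valid")
    freq, power = periodogram(series - trend, fs=1.0 / dt)
    lo, hi = period_band_fs
    sel = (freq > 1.0 / hi) & (freq < 1.0 / lo)
    return float(1.0 / freq[sel][np.argmax(power[sel])])
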