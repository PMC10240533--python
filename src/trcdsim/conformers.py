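"""Dihedral geometry, rotamer classification and rotational dephasing.

The previtamin D triene conformation is summarised by two torsions,
phi1 (C10-C5-C6-C7) and phi2 (C6-C7-C8-C9).  Each torsion is binned into
four classes on the circle: gauche (|phi| <= 120 deg) or trans
(|phi| > 120 deg), with a sign suffix taken from the sign of the wrapped
angle.  The central double bond is Z throughout, so a conformer label reads
e.g. ``t+Zg-``.  The gauche/trans boundary at 120 deg bisects the canonical
60 deg / 180 deg minima; the boundary itself is counted as gauche, and the
wrap convention maps 180 deg to +180 (hence ``t+``) -- both choices only
affect measure-zero inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .errors import GeometryError, ParameterError, SampleSizeError

__all__ = [
    "wrap_deg",
    "dihedral",
    "RotamerLabel",
    "classify",
    "classify_codes",
    "CLASSES",
    "LABELS",
    "DEFAULT_WINDOWS",
    "OccupancyTable",
    "occupancy",
    "DephasingResult",
    "dephasing_time",
]

#: Analysis windows (fs) on the 4.8 ps trajectory horizon used to follow the
#: rotamer cascade: A 633-960, B 1180-1392, C 1516-1862, D 2179-2563,
#: E 3053-4800.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "A": (633.0, 960.0),
    "B": (1180.0, 1392.0),
    "C": (1516.0, 1862.0),
    "D": (2179.0, 2563.0),
    "E": (3053.0, 4800.0),
}


def wrap_deg(angle):
    """Wrap angle(s) in degrees to the interval (-180, 180].

    Accepts scalars or arrays; -180 maps to +180.
    """
    a = np.asarray(angle, dtype=float)
    w = (a + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    if np.ndim(angle) == 0:
        return float(w)
    return w


_DEGEN_EPS = 1e-10


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees in (-180, 180]) of four 3D points.

    IUPAC sign convention: looking from p2 towards p3, a clockwise rotation
    of the far bond relative to the near bond is positive.  A planar cis
    (syn) arrangement gives 0, planar anti gives 180.

    Raises
    ------
    GeometryError
        If consecutive points coincide or three consecutive points are
        collinear (the torsion is undefined).
    """
    p = [np.asarray(q, dtype=float) for q in (p1, p2, p3, p4)]
    for q in p:
        if q.shape != (3,):
            raise ParameterError("dihedral points must be 3-vectors")
    b1 = p[1] - p[0]
    b2 = p[2] - p[1]
    b3 = p[3] - p[2]
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < _DEGEN_EPS:
            raise GeometryError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _DEGEN_EPS or np.linalg.norm(n2) < _DEGEN_EPS:
        raise GeometryError("three consecutive points are collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    # atan2(y, x) yields the anticlockwise-positive angle; IUPAC torsions
    # are clockwise-positive viewed along p2 -> p3, hence the sign flip
    return wrap_deg(-np.degrees(np.arctan2(y, x)))


#: Per-angle class codes in a fixed order; a rotamer index is
#: ``4 * code(phi1) + code(phi2)``.
CLASSES: tuple[str, ...] = ("g+", "g-", "t+", "t-")

_INVERTED = {"g+": "g-", "g-": "g+", "t+": "t-", "t-": "t+"}


@dataclass(frozen=True)
class RotamerLabel:
    """A conformer class on the phi1/phi2 torus, e.g. ``t+Zg-``."""

    phi1_class: str
    phi2_class: str

    def __post_init__(self):
        for c in (self.phi1_class, self.phi2_class):
            if c not in CLASSES:
                raise ParameterError(f"unknown torsion class {c!r}")

    def __str__(self) -> str:
        return f"{self.phi1_class}Z{self.phi2_class}"

    @classmethod
    def from_string(cls, s: str) -> "RotamerLabel":
        parts = s.split("Z")
        if len(parts) != 2:
            raise ParameterError(f"malformed rotamer label {s!r}")
        return cls(parts[0], parts[1])

    @property
    def inverted(self) -> "RotamerLabel":
        """The point-symmetric partner (both torsion signs flipped)."""
        return RotamerLabel(_INVERTED[self.phi1_class], _INVERTED[self.phi2_class])


#: All 16 labels, indexed by ``4 * code(phi1) + code(phi2)``.
LABELS: tuple[RotamerLabel, ...] = tuple(
    RotamerLabel(c1, c2) for c1 in CLASSES for c2 in CLASSES
)


def _angle_codes(phi) -> np.ndarray:
    w = np.asarray(wrap_deg(phi), dtype=float)
    gauche = np.abs(w) <= 120.0
    positive = w >= 0.0
    return np.where(gauche, np.where(positive, 0, 1), np.where(positive, 2, 3))


def classify_codes(phi1, phi2) -> np.ndarray:
    """Vectorised classification returning integer indices into LABELS."""
    return (_angle_codes(phi1) * 4 + _angle_codes(phi2)).astype(int)


def classify(phi1: float, phi2: float) -> RotamerLabel:
    """Classify a (phi1, phi2) pair (degrees, any branch) into a rotamer."""
    return LABELS[int(classify_codes(phi1, phi2))]


@dataclass
class OccupancyTable:
    """Per-window rotamer fractions over ground-state, ring-open frames.

    ``fractions[window][label_string]`` sums to 1 over emitted labels in
    each window; windows with no qualifying frames are absent.
    """

    windows: dict[str, tuple[float, float]]
    fractions: dict[str, dict[str, float]]

    def modal_label(self, window: str) -> str:
        frac = self.fractions[window]
        return max(frac, key=frac.get)


def occupancy(
    ensemble: Sequence,
    windows: Mapping[str, tuple[float, float]] = DEFAULT_WINDOWS,
) -> OccupancyTable:
    """Tabulate rotamer fractions per time window.

    Only frames that are both in the electronic ground state and ring-open
    contribute (the rotamer cascade only exists for the open-ring
    photoproduct).  Counting is per frame, so long-lived conformers weigh
    more, matching a density-plot view of the torus.  A window with zero
    qualifying frames is dropped with a warning.
    """
    windows = dict(windows)
    counts = {name: np.zeros(len(LABELS), dtype=np.int64) for name in windows}
    for traj in ensemble:
        qualify = (traj.state == 0) & traj.ring_open
        if not qualify.any():
            continue
        codes = classify_codes(traj.phi1, traj.phi2)
        for name, (t0, t1) in windows.items():
            m = qualify & (traj.time_fs >= t0) & (traj.time_fs <= t1)
            if m.any():
                counts[name] += np.bincount(codes[m], minlength=len(LABELS))
    fractions: dict[str, dict[str, float]] = {}
    for name in windows:
        total = counts[name].sum()
        if total == 0:
            warnings.warn(
                f"window {name!r} contains no ground-state ring-open frames; omitted",
                stacklevel=2,
            )
            continue
        fractions[name] = {
            str(LABELS[i]): counts[name][i] / total
            for i in np.nonzero(counts[name])[0]
        }
    return OccupancyTable(windows=windows, fractions=fractions)


class DephasingResult(NamedTuple):
    """Outcome of the circular-order-parameter dephasing estimate."""

    time_fs: float  #: first sustained crossing below the threshold; inf if never
    reached: bool
    times_fs: np.ndarray
    order_parameter: np.ndarray


def dephasing_time(
    ensemble: Sequence,
    angle: str = "phi1",
    threshold: float = float(np.exp(-1.0)),
    persistence_fs: float = 1000.0,
    min_trajectories: int = 10,
) -> DephasingResult:
    """Rotational dephasing time from the circular order parameter.

    At each delay tau the order parameter is
    ``r(tau) = |mean_i exp(i phi_i(tau))|`` over trajectories whose frame at
    tau is ground-state and ring-open.  The dephasing time is the first tau
    at which r drops below ``threshold`` (default 1/e) and stays below it
    for at least ``persistence_fs`` or until the record ends.  The guard
    rejects transient dips: while the first large-amplitude rotation is
    under way, staggered hop times briefly spread the ensemble phases along
    the transit arc before they re-cluster at the new rotamer, producing a
    coherent dip of several hundred fs that is not dephasing; the default
    1 ps persistence outlasts it.  If no sustained crossing occurs within
    the common time range the result has ``reached=False`` and
    ``time_fs=inf``.

    Raises
    ------
    SampleSizeError
        If fewer than ``min_trajectories`` ring-open trajectories exist.
    """
    if angle not in ("phi1", "phi2"):
        raise ParameterError("angle must be 'phi1' or 'phi2'")
    open_trajs = [t for t in ensemble if bool(np.any(t.ring_open))]
    if len(open_trajs) < min_trajectories:
        raise SampleSizeError(
            f"need >= {min_trajectories} ring-open trajectories, "
            f"got {len(open_trajs)}"
        )
    n_t = min(t.n_frames for t in open_trajs)
    times = open_trajs[0].time_fs[:n_t]
    phi = np.stack([np.radians(getattr(t, angle)[:n_t]) for t in open_trajs])
    mask = np.stack([(t.state[:n_t] == 0) & t.ring_open[:n_t] for t in open_trajs])
    z = np.exp(1j * phi) * mask
    count = mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        r = np.abs(z.sum(axis=0)) / count
    # the order parameter is only meaningful once a minimal ring-open
    # ground-state subensemble exists; earlier delays are left undefined
    r[count < min_trajectories] = np.nan

    below = (r < threshold) & np.isfinite(r)
    dt = float(times[1] - times[0]) if n_t > 1 else 0.0
    span = max(1, int(np.ceil(persistence_fs / dt))) if dt > 0 else 1
    # first index i with `below` true on [i, i+span] (window truncated at
    # the record end, otherwise no crossing in the last persistence_fs
    # could ever be detected)
    csum = np.concatenate([[0], np.cumsum(below.astype(int))])
    for i in range(0, n_t):
        j = min(i + span, n_t - 1)
        if csum[j + 1] - csum[i] == j - i + 1:
            return DephasingResult(float(times[i]), True, times, r)
    return DephasingResult(float("inf"), False, times, r)
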