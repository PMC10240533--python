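"""Surrogate electronic structure on the (phi1, phi2) torus.

Full ab initio response calculations along every trajectory frame are far
outside this package's scope; instead, smooth periodic surfaces supply the
S1 rotatory strength and excitation energy as functions of the two triene
torsions, calibrated to the known qualitative landscape of previtamin D:

* t+Zg- conformers carry strongly positive rotatory strengths in the
  (100-250) x 1e-40 cgs range, and their mirror-helical t-Zg+ partners the
  exact negatives; the same opposition holds for t+Zt+ / t-Zt-.
* gZg conformers sit close to zero.
* The surface is exactly odd under simultaneous inversion of both torsions,
  R(-phi1, -phi2) = -R(phi1, phi2) -- torsion inversion flips the triene
  helicality and hence the CD sign.

The interpolant is a periodic squared-exponential RBF through a small
anchor table (shipped as a data file), explicitly antisymmetrised.  A slow
cosine in a "vibration phase" coordinate overlays the 20-30 fs bond-length
oscillations of the conjugated system seen in both rotatory strengths and
S1 energies; its amplitude is small relative to the torsional variation.

The absolute delta_eps scale of all shipped spectra is arbitrary (only
signs and ratios are constrained); see the Pro/Pre reference builders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .conformers import RotamerLabel, wrap_deg
from .errors import ParameterError, SampleSizeError
from .spectra import CDSpectrum, SpectralGrid, Transition, _broaden_arrays

__all__ = [
    "LABEL_CENTERS",
    "label_center",
    "load_anchor_table",
    "load_pro_transitions",
    "load_equilibrium_weights",
    "SurrogateParams",
    "DEFAULT_PARAMS",
    "surrogate_R",
    "surrogate_E",
    "transitions_at",
    "pro_reference",
    "pre_equilibrium_spectrum",
]

#: Canonical torsion value (deg) for each per-angle class.  Gauche minima sit
#: at +-60; the trans centers are placed at +-165, inside the |phi|>120 bins
#: and consistent with the slightly-distorted trans geometries of the real
#: rotamer ensemble (e.g. t+Zg- near (+170, -65)).
_CLASS_CENTER = {"g+": 60.0, "g-": -60.0, "t+": 165.0, "t-": -165.0}

LABEL_CENTERS: dict[str, tuple[float, float]] = {
    f"{c1}Z{c2}": (_CLASS_CENTER[c1], _CLASS_CENTER[c2])
    for c1 in _CLASS_CENTER
    for c2 in _CLASS_CENTER
}


def label_center(label) -> tuple[float, float]:
    """(phi1, phi2) center (deg) of a rotamer label or label string."""
    return LABEL_CENTERS[str(label)]


_DATA_CACHE: dict[str, pd.DataFrame] = {}


def _read_data_tsv(name: str) -> pd.DataFrame:
    # tiny shipped tables, parsed once per process
    if name not in _DATA_CACHE:
        with resources.files("trcdsim.data").joinpath(name).open("r") as fh:
            _DATA_CACHE[name] = pd.read_csv(fh, sep="\t")
    return _DATA_CACHE[name]


def load_anchor_table() -> np.ndarray:
    """Shipped anchor table as an (n, 3) array [phi1, phi2, R].

    The table satisfies antisymmetric closure: for every row, the
    point-inverted row with negated R is also present.
    """
    df = _read_data_tsv("anchors.tsv")
    return df[["phi1_deg", "phi2_deg", "rotatory_1e-40cgs"]].to_numpy(float)


def load_pro_transitions() -> list[Transition]:
    """Two-state static table for the closed-ring parent (provitamin).

    Synthetic surrogate data: magnitudes are calibration choices; the only
    physical constraint is a net negative CD band in the 240-380 nm region,
    opposite in sign to the open-ring product ensemble.
    """
    df = _read_data_tsv("pro_transitions.tsv")
    return [
        Transition(float(r["energy_eV"]), float(r["rotatory_1e-40cgs"]))
        for _, r in df.iterrows()
    ]


def load_equilibrium_weights() -> dict[str, float]:
    """Equilibrated rotamer weights (label -> probability, sums to 1)."""
    df = _read_data_tsv("equilibrium_weights.tsv")
    w = {str(r["label"]): float(r["weight"]) for _, r in df.iterrows()}
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


def _validate_antisymmetry(anchors: np.ndarray):
    pts = {(round(a, 6), round(b, 6)): r for a, b, r in anchors}
    for (a, b), r in pts.items():
        inv = (round(wrap_deg(-a), 6), round(wrap_deg(-b), 6))
        if inv not in pts or abs(pts[inv] + r) > 1e-9:
            raise ParameterError(
                f"anchor table lacks antisymmetric closure at ({a}, {b})"
            )


@dataclass
class SurrogateParams:
    """All tunable surrogate parameters with shipped defaults.

    Attributes
    ----------
    anchors : (n, 3) array
        Rotatory-strength anchors [phi1 deg, phi2 deg, R 1e-40 cgs].
    length_scale_deg : float
        Smoothness scale of the periodic squared-exponential kernel.
    e0_ev : float
        Baseline S1 excitation energy; 4.0 eV puts lambda_max near 310 nm.
    e_torsion_amp_ev : float
        Amplitude of the smooth torsional modulation of the S1 energy;
        chosen so lambda_max stays inside 240-380 nm everywhere.
    e_vib_amp_ev, r_vib_eps : float
        Amplitudes of the fast bond-vibration overlay on E and (relative)
        on R.
    vib_period_fs : float
        Bond-vibration period; defaults inside the 20-30 fs band.
    e2_offset_ev, r2_ratio : float
        The second excited state is modelled as E2 = E1 + e2_offset with
        R2 = r2_ratio * R1 (weak, partially cancelling upper band).
    """

    anchors: np.ndarray = field(default_factory=load_anchor_table)
    length_scale_deg: float = 45.0
    e0_ev: float = 4.0
    e_torsion_amp_ev: float = 0.2
    e_vib_amp_ev: float = 0.03
    r_vib_eps: float = 0.05
    vib_period_fs: float = 25.0
    e2_offset_ev: float = 0.8
    r2_ratio: float = -0.10
    _rbf_weights: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.anchors = np.asarray(self.anchors, dtype=float)
        if self.anchors.ndim != 2 or self.anchors.shape[1] != 3:
            raise ParameterError("anchors must be an (n, 3) array")
        if self.length_scale_deg <= 0:
            raise ParameterError("length_scale_deg must be > 0")
        if self.vib_period_fs <= 0:
            raise ParameterError("vib_period_fs must be > 0")
        _validate_antisymmetry(self.anchors)
        k = self._kernel(self.anchors[:, 0], self.anchors[:, 1])
        k[np.diag_indices_from(k)] += 1e-10  # numerical conditioning only
        self._rbf_weights = np.linalg.solve(k, self.anchors[:, 2])

    def _kernel(self, phi1, phi2) -> np.ndarray:
        """Periodic SE kernel between query points and the anchors."""
        p1 = np.atleast_1d(np.asarray(phi1, dtype=float))
        p2 = np.atleast_1d(np.asarray(phi2, dtype=float))
        a1 = self.anchors[:, 0]
        a2 = self.anchors[:, 1]
        d1 = wrap_deg(p1[:, None] - a1[None, :])
        d2 = wrap_deg(p2[:, None] - a2[None, :])
        d1 = np.where(d1 == 180.0, -180.0, d1)  # distance only; sign irrelevant
        d2 = np.where(d2 == 180.0, -180.0, d2)
        ell2 = 2.0 * self.length_scale_deg**2
        return np.exp(-(d1**2 + d2**2) / ell2)

    def _interp(self, phi1, phi2) -> np.ndarray:
        return self._kernel(phi1, phi2) @ self._rbf_weights


DEFAULT_PARAMS = SurrogateParams()


def surrogate_R(phi1, phi2, vib_phase=0.0, params: SurrogateParams = DEFAULT_PARAMS):
    """S0->S1 rotatory strength (1e-40 cgs) at torsions (phi1, phi2) deg.

    The RBF interpolant of the anchor table is antisymmetrised so that
    ``surrogate_R(-phi1, -phi2) == -surrogate_R(phi1, phi2)`` holds exactly
    (to floating point), then modulated by ``1 + eps*cos(vib_phase)``.
    Scalars in, scalar out; arrays broadcast elementwise.
    """
    scalar = np.ndim(phi1) == 0 and np.ndim(phi2) == 0 and np.ndim(vib_phase) == 0
    base = 0.5 * (params._interp(phi1, phi2) - params._interp(
        np.negative(phi1), np.negative(phi2)
    ))
    out = base * (1.0 + params.r_vib_eps * np.cos(np.atleast_1d(vib_phase)))
    return float(out[0]) if scalar else out


def surrogate_E(phi1, phi2, vib_phase=0.0, params: SurrogateParams = DEFAULT_PARAMS):
    """S1 excitation energy (eV) at torsions (phi1, phi2) deg.

    Baseline plus a smooth even torsional shift plus the fast cosine
    vibration term.  With the default amplitudes the corresponding
    lambda_max = hc/E stays inside the 240-380 nm band everywhere.
    """
    scalar = np.ndim(phi1) == 0 and np.ndim(phi2) == 0 and np.ndim(vib_phase) == 0
    c1 = np.cos(np.radians(np.atleast_1d(np.asarray(phi1, float))))
    c2 = np.cos(np.radians(np.atleast_1d(np.asarray(phi2, float))))
    out = (
        params.e0_ev
        + params.e_torsion_amp_ev * 0.5 * (c1 + c2)
        + params.e_vib_amp_ev * np.cos(np.atleast_1d(vib_phase))
    )
    return float(out[0]) if scalar else out


def transitions_at(phi1, phi2, vib_phase=0.0, params: SurrogateParams = DEFAULT_PARAMS):
    """Lowest two transitions at given torsions: ((m,2) E array, (m,2) R).

    The second state is a fixed-offset, scaled companion of the first (see
    :class:`SurrogateParams`); energies are ascending by construction.
    """
    e1 = np.atleast_1d(surrogate_E(phi1, phi2, vib_phase, params))
    r1 = np.atleast_1d(surrogate_R(phi1, phi2, vib_phase, params))
    e = np.stack([e1, e1 + params.e2_offset_ev], axis=-1)
    r = np.stack([r1, params.r2_ratio * r1], axis=-1)
    return e, r


def pro_reference(
    grid: SpectralGrid,
    lw_ev: float = 0.5,
    transitions: list[Transition] | None = None,
) -> CDSpectrum:
    """Static 2-state CD reference spectrum of the closed-ring parent.

    The default line width of 0.5 eV matches the broad reference used when
    assembling the time-resolved signal; the net band in 240-380 nm is
    negative, opposite to the open-ring product ensemble.
    """
    if transitions is None:
        transitions = load_pro_transitions()
    e0 = np.array([t.energy_ev for t in transitions])
    rr = np.array([t.rotatory for t in transitions])
    spec = CDSpectrum(grid, _broaden_arrays(e0, rr, grid, lw_ev))
    spec.meta["kind"] = "pro_reference"
    return spec


def pre_equilibrium_spectrum(
    grid: SpectralGrid,
    lw_ev: float = 0.1,
    n_samples: int = 500,
    rng: np.random.Generator | None = None,
    weights: dict[str, float] | None = None,
    angle_sigma_deg: float = 15.0,
    params: SurrogateParams = DEFAULT_PARAMS,
) -> CDSpectrum:
    """Ensemble-averaged CD spectrum of the equilibrated open-ring product.

    Rotamer labels are drawn from the shipped (or supplied) equilibrium
    weights, torsions sampled around each label center with Gaussian spread
    ``angle_sigma_deg``, and the surrogate two-state spectra averaged.  With
    the shipped weights the net 240-380 nm band is positive.

    Raises
    ------
    SampleSizeError
        If ``n_samples < 100`` (the band sign is a statistical statement).
    """
    if n_samples < 100:
        raise SampleSizeError("pre_equilibrium_spectrum needs >= 100 samples")
    rng = np.random.default_rng(rng)
    if weights is None:
        weights = load_equilibrium_weights()
    labels = [k for k, v in weights.items() if v > 0]
    probs = np.array([weights[k] for k in labels])
    probs = probs / probs.sum()
    idx = rng.choice(len(labels), size=n_samples, p=probs)
    centers = np.array([label_center(labels[i]) for i in idx])
    angles = wrap_deg(centers + rng.normal(0.0, angle_sigma_deg, size=centers.shape))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_samples)
    e, r = transitions_at(angles[:, 0], angles[:, 1], phases, params)
    # mean of individually broadened spectra == broaden(all)/n by linearity
    spec = CDSpectrum(grid, _broaden_arrays(e, r, grid, lw_ev) / n_samples)
    spec.meta["kind"] = "pre_equilibrium"
    spec.meta["n_samples"] = n_samples
    return spec
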