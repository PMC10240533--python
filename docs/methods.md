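# Methods

This note documents the models behind `trcdsim`: what is computed, which
parts are physics and which are calibrated surrogates, the numerical
conventions, and what the shipped defaults do and do not represent.

## Spectra

A CD-active electronic transition is characterised by its excitation
energy E (eV) and rotatory strength R = Im(**μ**·**m**) in 10⁻⁴⁰ cgs
units. Broadening is Gaussian **on the energy axis**; each transition
contributes

    Δε(E') = (R / 22.97) · E' · N(E'; E, σ),

with N a unit-area Gaussian in eV and σ the line-width parameter `lw`.
Two conventions are fixed here because the field uses several:

* `lw` is the Gaussian **standard deviation**, not the FWHM;
* the amplitude anchors to the standard CD sum rule
  R = 22.97 ∫ Δε(ν̃)/ν̃ dν̃ (R in 10⁻⁴⁰ cgs, Δε in L mol⁻¹ cm⁻¹, ν̃ in
  cm⁻¹). Because ν̃ ∝ E the eV↔cm⁻¹ factor cancels inside the integral,
  so the whole computation lives on the eV axis and is evaluated at the
  grid wavelengths through λ = 1239.841 eV·nm / E.

The test suite closes the loop by numerically integrating Δε/ν̃ back to
R (trapezoid quadrature, agreement to 0.5 % on a dense grid).

Line widths follow the reference protocol: 0.1 eV for static spectra,
0.5 eV for the time-resolved signal and its reference (the broad width
suppresses sampling noise of a 116-member ensemble).

## Time-resolved signal

At delay τ the instantaneous spectrum is the ground-state-gated ensemble
average Δε(τ) = (1/N) Σ over trajectories with state(τ) = 0 of their
broadened two-state spectra. Normalisation is by the **total** N — an
easy quantity to get wrong; a dedicated test pins the one-of-two-decayed
case to S/2. ΔCD(τ) adds the instantaneous spectrum to the static parent
reference ("add" default; "subtract" available — the experimental probe
scheme cannot fix the instantaneous sign). Delays run from the pump
instant (τ = 0 = trajectory start) every `stride` frames; with the 40 au
nuclear step and stride 10 the spacing is 9.6754 fs (printed elsewhere
as "9.6 fs", a one-decimal truncation). Ragged ensembles are truncated
to the common horizon rather than renormalised, keeping N fixed. Trace
extraction is nearest-neighbour in wavelength, deliberately not
interpolated, to preserve the high-frequency oscillation structure.

The helper `first_extremum_fs` locates the early dip of a trace: it
smooths with a 150 fs moving average (edge-padded) to suppress the
bond-vibration overlay and returns the first local extremum whose
deviation from the initial value exceeds 35 % of the maximum deviation.
Both constants are estimator choices; the smoothing window sits between
the ~25 fs vibration period and the ~500 fs width of the dip.

## Conformer analysis

Torsions are signed per IUPAC (clockwise positive viewed along the
central bond; validated against an independent geometry library in the
tests). Each torsion is binned gauche (|ϕ| ≤ 120°) or trans (|ϕ| > 120°)
with the sign of the wrapped angle as suffix; the 120° boundary bisects
the canonical 60°/180° minima, the boundary itself counts as gauche, and
180° wraps to +180° (hence t+) — both conventions only affect
measure-zero inputs. Occupancy tables count **frames** (not
trajectories) over ground-state, ring-open frames, matching a
density-plot view of the torus; windows with no qualifying frames are
dropped with a warning.

The rotational dephasing time uses the circular order parameter
r(τ) = |mean over qualifying trajectories of exp(iϕ(τ))| and reports the
first τ at which r drops below 1/e and stays below for at least 1 ps (or
to the end of the record, whichever comes first). Two estimator details
matter and are deliberate: (i) delays where fewer than
`min_trajectories` trajectories qualify are left undefined rather than
evaluated on a tiny subensemble; (ii) the persistence guard is 1 ps, not
a few hundred fs, because the first large-amplitude rotation produces a
*coherent* transient — staggered hop times briefly spread the ensemble
phases along the 135° transit arc before they re-cluster at the new
rotamer, dipping r below 1/e for several hundred fs without any loss of
phase memory. A shorter guard latches onto that transient. The
closed-form check (per-trajectory constant angular velocities
ω ~ N(0, σ²) give r(τ) = exp(−σ²τ²/2), threshold at √2/σ) is unaffected
because r is then monotone.

## Surrogate electronic structure

No formula for R(ϕ₁, ϕ₂) exists to fit; only signs and ranges are
known. The surface is therefore a periodic squared-exponential RBF
interpolant (length scale 45°) through a small anchor table — t+Zg− and
t+Zt+ at +175 (midpoint of the printed 100–250 range), their point
inversions at −175, the four gZg centres at 0, g+Zt− at +25 — explicitly
antisymmetrised so that R(−ϕ₁, −ϕ₂) = −R(ϕ₁, ϕ₂) holds to the last bit
(torsion inversion flips the triene helicality and hence the CD sign).
Trans centres sit at ±165°, inside the trans bins and consistent with
the distorted-trans geometries of the real rotamers. The S₁ energy is a
baseline 4.0 eV plus a smooth even torsional shift (amplitude chosen so
λ_max never leaves 240–380 nm); both surfaces carry a small cosine
overlay in a vibration phase with a 25 fs default period, emulating the
bond-length oscillations of the conjugated system. The second state is
modelled as E₂ = E₁ + 0.8 eV with R₂ = −0.10 R₁ — a weak, partially
cancelling upper band; only the lowest two states enter the TRCD.

The shipped parent table (4.10 eV / −25, 5.30 eV / +15) and the
equilibrium rotamer weights are **synthetic calibration data**, not
literature values. They encode three qualitative constraints
simultaneously: the parent band in 240–380 nm is net negative and the
equilibrated product band net positive; the long-time instantaneous
spectrum (0.62 · product + 0.38 · hot parent) is net positive, so the
long-time ΔCD is less negative than at delay zero; and the
circular-mean vector of the equilibrium weights on ϕ₁ nearly cancels
(trans-group weight ≈ 0.38), so the order parameter decays to a small
asymptote and the dephasing time is well defined. Absolute Δε is
arbitrary throughout; only signs and ratios are meaningful.

## Trajectory generator

A continuous-time jump process replaces Langevin torsional dynamics: it
reproduces the observed rotamer sequence exactly, is exactly seedable,
and its rates are transparent knobs. Per trajectory: a hop time drawn
from 50 fs + Gamma(shape 2, scale 130 fs), resampled above the 2 ps
truncation (preset: ~98 % decayed by 960 fs, all by 2 ps); a Bernoulli
ring-opening with the 62 % quantum yield; for open trajectories the
cascade g−Zg− → t+Zg− → {g+Zg+ | g+Zt−, 50/50} → t+Zt+ → t−Zg+ →
equilibrium with exponential waiting times of mean 200, 420, 650, 800,
800 fs along the edges and memoryless 700 fs exchanges against the
equilibrium weights thereafter. Between jumps the torsions relax toward
the current label centre along the shortest arc with an 80 fs time
constant plus 2° per-frame Gaussian jitter. Closed (failed) trajectories
keep parent-like torsions and revert to the parent transition table
(hot ground-state parent) — the simplest choice consistent with the
gating formula. All randomness flows from one master seed through
counter-based per-trajectory substreams, so (n, seed) fully determine
the output.

The waiting times and the relaxation constant are calibrated jointly —
against the A–E window boundaries (window A modal label t+Zg−, the
split pair dominant in B, t+Zt+ peaking in C, t−Zg+ rising in D, no
dominant conformer in E), the ~0.8 ps first extremum of the 280 nm
trace, and a ϕ₁ dephasing time in the 3–6 ps band. They are kinetic
model parameters of a cartoon, not fitted molecular constants. The
calibration was done across an ensemble of generator seeds before the
test seeds were fixed.

What the generator does *not* emulate: solvent friction (which slows
the real isomerisation roughly threefold in solution), anharmonic
couplings between the torsions, excited-state absorption, and any
geometry beyond the two torsions — so passing tests validate the
spectroscopy pipeline and the kinetic cartoon, not ab initio dynamics.

## 1D fewest-switches model

The mechanistic mode propagates walkers on two diabats over a
ring-opening coordinate (atomic units): a quartic double well
(closed-ring minimum at −1.5, open-ring at +2.0, small positive tilt —
the photoproduct is the less stable species), a displaced harmonic
excited state (k = 0.005, minimum at +1.0, offset 0.08), and a Gaussian
coupling lobe at **each** diabat crossing (−0.9 and +2.4, strength
0.004, width 0.25) — an uncoupled crossing would be a spurious
degeneracy with divergent derivative coupling. Mass 2000, default step
2 au.

Nuclei follow velocity Verlet on the active adiabat with analytic
gradients; the two amplitudes are propagated in the adiabatic basis by
the exact unitary 2×2 propagator per step (norm conserved to machine
precision), with the derivative coupling
d₁₂ = (C′ΔV − CΔV′)/(ΔV² + 4C²). Hops use Tully's fewest-switches flux,
sampled in hazard form: each walker carries a survival product
S = Π(1 − g_k) and a uniform threshold, hopping when S crosses it. This
is identical in law to the textbook per-step uniform test, but because
the realised hop times converge with the *same* random numbers as
dt → 0, halving the time step isolates discretization error instead of
re-rolling the Monte Carlo noise. Momentum is rescaled on accepted hops
(energy conserved exactly); frustrated hops leave the velocity unchanged
(no reversal — a documented choice); decoherence corrections are
omitted. A conservative 1D model cannot trap its products, so the
final-well assignment reads the position at the time cap relative to the
inter-well midpoint; individual late-time phases are not dt-stable, but
the ensemble branching fraction is a well-behaved average, and the
calibrated preset lands in 0.55–0.70 with all hops far inside 2 ps.

## Degenerate inputs and numerical guards

Wavelength grids must be strictly increasing and positive; torsion
wrap maps −180° to +180°; coincident or collinear dihedral points raise
a geometry error; the RBF system carries a 10⁻¹⁰ diagonal jitter purely
for conditioning; hop probabilities are clamped to [0, 1]; the
amplitude-norm guard aborts integration if drift exceeds 10⁻⁴ per step
(unreachable with the unitary propagator, kept as a NaN trap).

## Problem sizes

Defaults everywhere are the full study conditions: 116 trajectories ×
4962 frames, 141-point wavelength grid, 497 delays. The generator
builds an ensemble in well under a second and the TRCD matrix in about
one, so no scaled-down variants are needed; statistical statements in
the tests use 200 generator replicates and 500–600 surface-hopping
walkers.

## Known limitations

* The surrogate surfaces interpolate ten anchors; away from the anchor
  set their values are smooth guesses constrained only by symmetry.
* The jump-process cascade has no inertia: torsional angular momentum
  and recrossings are absent, and the dephasing mechanism is waiting-time
  randomness rather than dynamical anharmonicity.
* The 1D hopping model is schematic; its branching fraction is a
  calibration target, not a prediction.
* Absolute Δε scales are arbitrary; comparisons across spectra are
  meaningful only within one run's conventions.
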