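# trcdsim

Simulation of ultrafast pump–probe time-resolved circular dichroism
(TRCD) spectra from ensembles of nonadiabatic surface-hopping
trajectories, applied to the photoinduced ring-opening of provitamin D
(7-dehydrocholesterol) into the rotationally flexible previtamin D
seco-steroid.

## The problem and who this is for

Electronic circular dichroism, Δε = ε_L − ε_R, is exquisitely sensitive
to three-dimensional structure; measured with sub-picosecond pump–probe
resolution it can in principle watch chirality change *during* a
photoreaction. For the provitamin → previtamin ring-opening, the TRCD
signal carries an oscillatory fine structure whose origin is the
sequence of rotational isomerisations of the newly formed triene unit.
This package provides the simulation side of that analysis for
computational photochemists: it turns per-frame electronic-state and
conformational information of a trajectory ensemble into the broadband
ΔCD(τ, λ) surface and the conformer-population analysis that explains
its oscillations.

The ab initio layers (TDDFT response, excited-state forces) are
deliberately replaced by two transparent components so the spectroscopic
pipeline can be studied, tested and seeded end to end:

* a **surrogate electronic structure** — smooth periodic surfaces for the
  S₁ rotatory strength R(ϕ₁, ϕ₂) and excitation energy E(ϕ₁, ϕ₂) on the
  torus of the two triene torsions ϕ₁ (C10–C5–C6–C7) and ϕ₂
  (C6–C7–C8–C9), calibrated to the known sign/magnitude landscape
  (t+Zg− strongly positive, its mirror t−Zg+ the exact negative, gZg
  near zero), with a 20–30 fs bond-vibration overlay;
* a **synthetic trajectory generator** — a seeded stochastic emulation of
  a 116-trajectory surface-hopping ensemble: excited-state decay
  complete within 2 ps, 62 % ring-opening quantum yield, and the rotamer
  cascade g−Zg− → t+Zg− → (g+Zg+/g+Zt−) → t+Zt+ → t−Zg+ → equilibrated
  mixture, dephasing on the 4–5 ps scale.

A 1D two-state fewest-switches surface-hopping model of the ring-opening
coordinate is included as an optional mechanistic mode that produces hop
times and branching from dynamics instead of a fitted distribution.

## The central quantities

A transition with rotatory strength R = Im(**μ**·**m**) (10⁻⁴⁰ cgs) and
excitation energy E becomes a Gaussian Δε band; the amplitude is fixed
by the CD sum rule R = 22.97 ∫ Δε(ν̃)/ν̃ dν̃. The time-resolved signal at
pump–probe delay τ is the ground-state-gated ensemble average

    Δε(τ) = (1/N) Σ_{i : state_i(τ)=0} Δε_i(τ),

summing the broadened spectra of the trajectories that have decayed to
S₀ by τ and normalising by the **total** ensemble size N — trajectories
still excited contribute zero but still count. The reported ΔCD adds
this instantaneous spectrum to the static reference spectrum of the
closed-ring parent (the sign of the instantaneous spectrum is not
experimentally fixed; subtraction is retained as an option).

## Worked example

```
$ python examples/03_build_trcd.py
delta-CD matrix: 497 delays x 141 wavelengths, spacing 9.68 fs
280 nm trace: starts at -2.60, first extremum at 803 fs
band mean at delay 0      : -1.72 L/(mol cm)
band mean in window E     : -0.49 L/(mol cm)  (long-time limit less negative than time zero)
```

The 497 × 141 matrix samples every 10th nuclear step (40 au each, i.e.
a ~9.7 fs delay spacing, printed as 9.6 fs at one truncated decimal).
The 280 nm trace starts at the negative parent reference value, rises to
its first extremum near 0.8 ps — the strongly positive band of the
freshly formed t+Zg− rotamers overcompensating the parent band — and
partially recovers as they convert onward. The long-time band mean is
less negative than at delay zero because the equilibrated open-ring
product has a net positive band. Absolute Δε values are on an arbitrary
per-molecule scale (experimental concentrations are unknown); signs and
relative amplitudes are the meaningful output.

The rotamer analysis on the same ensemble:

```
$ python examples/04_rotamer_analysis.py
window A (633-960 fs): t+Zg- 31%, g-Zg- 19%, g+Zt- 16%
...
window D (2179-2563 fs): t+Zt+ 37%, t-Zg+ 28%, g+Zt- 9%
rotational dephasing (phi1): r < 1/e from 4018 fs on (4.0 ps, coherent isomerisation lost)
```

`examples/` contains one short script per capability (static reference
spectra, ensemble generation, TRCD assembly, rotamer/dephasing analysis,
the 1D hopping model). The same operations are scriptable from a shell
via the `trcdsim` command (`simulate`, `spectrum`, `trcd`, `trace`,
`conformers`, `fssh`); every run is reproducible from (config, seed) and
ensemble manifests record both.

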