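"""Static CD references: closed-ring parent vs equilibrated photoproduct.

Builds the two-state parent reference spectrum (broad 0.5 eV bands, as
used behind the time-resolved signal) and the ensemble-averaged spectrum
of the equilibrated open-ring rotamer mixture, then prints their net band
integrals over 240-380 nm.  Opposite signs are the point: the parent band
is negative, the photoproduct band positive, which is what makes the
time-resolved difference signal move as the reaction proceeds.
"""

import numpy as np

from trcdsim import SpectralGrid, pre_equilibrium_spectrum, pro_reference

grid = SpectralGrid.default()  # 240-380 nm, 1 nm spacing

pro = pro_reference(grid, lw_ev=0.5)
pre = pre_equilibrium_spectrum(grid, lw_ev=0.1, n_samples=500,
                               rng=np.random.default_rng(0))

print(f"parent (closed ring)  integral 240-380 nm: {pro.integral_nm():+8.1f}")
print(f"product (equilibrium) integral 240-380 nm: {pre.integral_nm():+8.1f}")
print("opposite signs: photoexcitation flips the net CD of the band region")
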