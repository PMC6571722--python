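"""Microcanonical analysis: caloric curves and transition orders.

NVU: T^-1(U) = dS_B/dU from the projected 1D DoS; a backbending loop
(positive peak of dT^-1/dU) is a first-order-like transition, an inflection
(negative peak) second-order-like.  NVE: convolving with the kinetic-energy
density of d degrees of freedom smooths the curve without moving T*.
"""
import numpy as np

from sfcopoly import (classify_transitions, inverse_temperature_U, make_model,
                      nve_curve, project_dos_1d, refine)

model = make_model("S-attract-stronger", N=8, b=4)
dos = refine(model, n_mcs=(100_000, 400_000), seed=1).dos

eps_st = -1.0
d1 = project_dos_1d(dos, model, eps_st=eps_st)
print(f"1D DoS at eps_st={eps_st}: {d1.U.size} bins, width {d1.bin_width}")

nvu = inverse_temperature_U(d1, smoothing=1.0)
for t in classify_transitions(nvu, prominence=0.02):
    print(f"NVU {t.order}-order transition: U*={t.U_star:.1f}, T*={t.T_star:.2f}")

d = 3 * model.N   # kinetic degrees of freedom
nve = nve_curve(d1, d=d)
for t in classify_transitions(nve, prominence=5e-3):
    print(f"NVE {t.order}-order transition: <U>(E*)={t.U_star:.1f}, "
          f"T*={t.T_star:.2f}")
# The NVE temperatures should sit close to the NVU ones; order labels can
# legitimately differ when a peak height is near zero (method dependence).
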