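"""Canonical analysis: C_V(T) maxima and a small state diagram.

Heat-capacity maxima along T (at fixed stiffness) and along eps_st (at fixed
T) trace the pseudo-phase boundaries in the (eps_st/eps_ff, eps_ff/T) plane.
"""
import numpy as np

from sfcopoly import (build_state_diagram, cv_profile_T, make_model,
                      most_probable_macrostate, refine)

model = make_model("S-attract-stronger", N=8, b=4)
dos = refine(model, n_mcs=(100_000, 400_000), seed=1).dos

prof = cv_profile_T(dos, model, eps_st=-1.0, T_grid=np.linspace(0.2, 6.0, 400),
                    prominence=0.2)
for p in prof.maxima:
    print(f"CV(T) maximum at T={p.x:.2f} (|eps_ff|/T={1/p.x:.2f}), "
          f"CV={p.CV:.1f}, prominence={p.prominence:.1f}")

for T in (4.0, 0.5):
    key = most_probable_macrostate(dos, model, T, eps_st=-1.0)
    print(f"most probable macrostate at T={T}: Env_raw={key.env_raw}, "
          f"nst={key.nst}")

sd = build_state_diagram(dos, model,
                         stiffness_ratio_grid=np.arange(0.0, 4.01, 0.5),
                         inv_T_grid=np.arange(0.2, 4.0, 0.05))
print(f"state diagram: {sd.cv.shape} CV surface, "
      f"{len(sd.loci_T)} maxima along T, {len(sd.loci_stiffness)} along eps_st")
# Cooling moves the most probable macrostate from the zero-contact coil
# (Env_raw ~ 0) to the compact ground state; the CV maxima mark where.
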