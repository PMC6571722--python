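"""Build a chain model, grow a conformation, and decompose its energy.

The model: N hard-sphere beads in S/F blocks of length b, square-well
contacts (cutoff 1.5 sigma) and a square-well stiffness term on S-block
valence angles in [150, 170] degrees.
"""
import numpy as np

from sfcopoly import (count_contacts, energy, initial_conformation,
                      make_model, validate)

model = make_model("S-attract-stronger", N=32, b=8, eps_st=-2.0)
print(f"pattern      : {model.pattern}")
print(f"contact eps  : ss={model.eps_ss} sf={model.eps_sf} ff={model.eps_ff}")
print(f"raw integers : {model.eps_raw.tolist()} x raw_scale={model.raw_scale}")
print(f"nst_max      : {model.nst_max} (eligible all-S angle triplets)")

conf = initial_conformation(model, seed=0)
print(f"valid        : {bool(validate(conf, model))}")

c = count_contacts(conf, model)
e = energy(c, model)
print(f"contacts     : nss={c.nss} nsf={c.nsf} nff={c.nff}; stiff angles nst={c.nst}")
print(f"energy       : Env={e.Env} (raw {e.Env_raw}), Est={e.Est}, U={e.U}")
# A near-straight starting chain has no contacts and no favorable angles
# (a perfectly stretched chain is energetically unfavorable), so U ~ 0.
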