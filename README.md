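# sfcopoly

Single-chain thermodynamics of flexible–semiflexible (SF) multiblock
copolymers in implicit selective solvents, by flat-histogram Monte Carlo.

**Who it is for.**  Polymer physicists studying the pseudo-phase behavior of
individual macromolecules: how intramolecular stiffness, block length and
solvent selectivity decide whether a single chain is a coil, a liquid or
frozen globule, or one of the anisotropic "small globule" morphologies
(dumbbells, lamellar globules, toroidal Saturn-like structures).  Everything
is importable Python; a thin `sfcopoly` CLI wraps the pipeline for shell use,
and `examples/` holds one short narrative script per capability.

## The model and the method

A chain of `N` hard-sphere beads (diameter σ = 1) with free bond lengths
`l ∈ [0.8, 1.25] σ` carries S/F blocks of length `b`.  The energy is a pair
of square wells,

    U = Env + Est,
    Env = ε_ss·n_ss + ε_ff·n_ff + ε_sf·n_sf      (contacts within 1.5 σ),
    Est = ε_st·n_st                               (S-block angles in [150°,170°]),

with Lorentz–Berthelot contact energies encoding the solvent selectivity
("S-attract-stronger": ε_ss, ε_sf, ε_ff = −4, −2, −1; "F-attract-stronger":
−0.25, −0.5, −1).  The sampler estimates the two-dimensional density of
states g(Env, n_st) by Stochastic Approximation Monte Carlo: acceptance
min(1, g_old/g_new) and, after every trial, ln g of the resulting macrostate
is raised by a decaying gain γ_t = γ0·min(1, t0/t).  From the converged DoS,

* **canonical analysis** reweights to any (T, ε_st): partition function,
  ⟨U⟩, the heat capacity C_V = (⟨U²⟩−⟨U⟩²)/T², C_V maxima along both axes,
  and full state diagrams over (ε_st/ε_ff, |ε_ff|/T);
* **microcanonical analysis** takes S_B(U) = ln g(U), T⁻¹ = dS_B/dU, and
  classifies transitions by the sign of the dT⁻¹/dU peak (positive
  backbending → first-order-like, negative inflection → second-order-like),
  in both the conformational (NVU) and the kinetic-convolved true
  microcanonical (NVE) ensembles;
* **morphology analysis** computes gyration/shape/nematic/demixing features
  per macrostate and assigns the taxonomy Ia–IIIe′ with an auditable rule
  trace.

## A worked example

Three independent two-stage SAMC runs for an N = 8, b = 4 chain in the
S-attract-stronger solvent, averaged (`examples/02_sample_density_of_states.py`):

    seed 0: 119 macrostates, final-stage visit flatness 0.63, acceptance local 0.62 / regrow 0.09
    seed 1: 118 macrostates, final-stage visit flatness 0.72, acceptance local 0.66 / regrow 0.09
    seed 2: 119 macrostates, final-stage visit flatness 0.49, acceptance local 0.56 / regrow 0.06
    averaged DoS: 118 macrostates (median run-to-run std of log g = 0.242)
    log g span: 55.9

The ground-state macrostate is e^55.9 times rarer than the coil — the reason
a flat-histogram method is needed at all.  Canonical analysis of that DoS
(`examples/03_heat_capacity_and_diagram.py`):

    CV(T) maximum at T=0.24 (|eps_ff|/T=4.10), CV=32.7, prominence=12.6
    CV(T) maximum at T=0.75 (|eps_ff|/T=1.33), CV=20.5, prominence=8.6
    most probable macrostate at T=4.0: Env_raw=-12, nst=0
    most probable macrostate at T=0.5: Env_raw=-39, nst=0

The high-T maximum is the collapse of the chain into a globule, the low-T
one its freezing; the most probable macrostate moves from a loose coil
(12 contacts) to the near-ground state (39 contacts) accordingly.  The
microcanonical view of the same DoS (`examples/04_microcanonical_transitions.py`)
marks the collapse as first-order-like for this tiny chain:

    NVU first-order transition: U*=-19.0, T*=2.45

and the NVE convolution keeps its temperature (⟨U⟩(E*) = −17.2, T* = 2.67)
while smoothing the discretization wiggles.  At N = 32, b = 8 the same
pipeline shows the coil–globule maximum near |ε_ff|/T ≈ 0.22 and freezing
near 0.7–1, with the morphology sequence Ia → IIa → IIb on cooling (run by the
acceptance script below).

## Layout

    src/sfcopoly/      model, _kernel (numba inner loop), samc, canonical,
                       microcanonical, morphology, oracles, io, cli
    examples/          one narrative script per capability
    tests/             pytest suite (unit, property and end-to-end)
    docs/methods.md    the science, assumptions, defaults and limitations
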