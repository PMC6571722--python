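# Methods

## The model

A single coarse-grained copolymer chain of `N` hard-sphere beads (diameter
`sigma = 1`, the length unit) is connected by bonds whose length may vary
freely in `[0.8, 1.25] sigma`; there is no elastic bond energy, and bonded
beads may interpenetrate.  Because the maximal bond length stays below
`sqrt(2) sigma`, two bonds can never cut through each other, so the chain is
self-avoiding by construction.  Beads are of two types, semiflexible (S) and
flexible (F), in equal numbers, arranged in regularly alternating blocks of
length `b` (the pattern starts with an S block by default; an arbitrary S/F
pattern can be supplied for reference systems such as homopolymers).

Two square-well terms make up the conformational energy `U = Env + Est`:

* **Contacts.**  Every non-bonded pair (`|i-j| > 1`) closer than
  `R_cut = 1.5 sigma` contributes `eps_ss`, `eps_ff` or `eps_sf` by type.
  The implicit selective solvent is encoded in these three numbers, related
  by the Lorentz-Berthelot rule `|eps_sf| = sqrt(|eps_ss| |eps_ff|)`.  Two
  presets are built in, in units of `|eps_ff|`: *S-attract-stronger*
  `(-4, -2, -1)` and *F-attract-stronger* `(-0.25, -0.5, -1)`; the latter is
  run internally with integer raw energies `(-1, -2, -4)` and a 0.25
  rescaling so that the contact energy is always an exact integer.
* **Stiffness.**  Each valence angle whose three beads all lie in one S block
  contributes `eps_st <= 0` when the interior angle falls in
  `[150, 170]` degrees.  A perfectly straight chain (180 degrees) is
  therefore *not* favorable; the window selects slightly bent, zig-zag or
  helical local conformations.  Restricting eligibility to all-S triplets is
  the most conservative reading of "stiff S-blocks" (junction angles carry no
  stiffness); it makes `nst_max = (b-2) N / 2b`.

Boundary conventions (measure-zero, fixed for reproducibility): a contact is
`r <= R_cut`; a hard-sphere placement is valid at `r >= sigma`; the angle
window is closed.

## Flat-histogram sampling (SAMC)

Macrostates are labelled by the pair `(Env_raw, nst)` — both exact integers,
so there is no floating-point binning anywhere.  The sampler performs, per
Monte Carlo step (MCS), `2N` local displacements (one bead, uniform in
`[-0.05, 0.05]` per axis) and one end-cut-and-regrow trial (a uniform cut
length `1..k_max`, `k_max = min(b, N-1)` by default, with each new bond drawn
uniformly *with respect to volume* from the `[0.8, 1.25]` shell).  Both
proposals are symmetric under the same Cartesian configuration measure:
mixing a Lebesgue-measure move with a non-volume-uniform regrow would bias
the estimated density of states, which is why the regrow radii are drawn with
the `r^2`-weighted inverse-CDF.

Acceptance is `min(1, g_old/g_new)`; after *every* trial (accepted or not)
the resulting macrostate receives `log g += gamma_t` and one visit.  The gain
`gamma_t = gamma0 * min(1, t0/t)` is indexed per MCS.  Unseen macrostates are
registered optimistically at the current minimum of `log g`, so the frontier
is always easy to enter.  A run is a pure function of
`(model, schedule, n_mcs, seed)`: the RNG is a single-word splitmix64 counter
that is serialized into checkpoints, so an interrupted run resumes
bit-identically.

Refinement chains stages with decreasing gain.  The classic two-stage recipe
`(gamma0=1, t0=1e3)` then `(gamma0=0.01, t0=1e4)` is the default; for chains
long enough to have a deep frozen-globule region (N >= 32 here) we insert an
intermediate stage, e.g. `(1, 1e3) -> (0.1, 1e5) -> (0.01, 2e5)`, because a
unit-gain first stage leaves overshoots of several `ln` units that a 0.01
gain corrects only slowly, while the deep tail of the spectrum still needs a
large cumulative gain budget to be carved out.  Independent runs are averaged
key-by-key (after anchoring `max log g = 0`); keys seen in fewer than a
configurable quorum of runs (default 2) are dropped, and the across-run
standard deviation is kept as the convergence diagnostic.  Production runs
freeze the DoS and accumulate per-macrostate means of the morphology
observables once per MCS, reporting keys that fall below a sample floor
(default 1e3, following the usual flat-histogram practice).

## Canonical analysis

All canonical quantities are log-sum-exp reweightings of the 2D DoS with
`U_k = raw_scale * Env_raw,k + eps_st * nst_k`; `<U>` and `<U^2>` are
accumulated in the same max-subtracted pass so the fluctuation formula
`C_V = (<U^2> - <U>^2)/T^2` stays accurate at low `T`.  Because `eps_st`
enters only through the `nst` coordinate, a single DoS serves the whole
`(eps_st, T)` plane: maxima of `C_V(T)` at fixed stiffness and of
`C_V(eps_st)` at fixed temperature give the two loci that bound the regions
of the state diagram over `(eps_st/eps_ff, |eps_ff|/T)`.  Maxima are discrete
local maxima after optional Savitzky-Golay smoothing, each reported with its
prominence so downstream consumers can filter noise-level wiggles; the
default diagram grids are `|eps_ff|/T in [0.05, 5]` step 0.01 and
`eps_st/|eps_ff|` up to 20 (F-attract) or 80 (S-attract) step 0.25, matching
the parameter ranges where diagram topology still changes.

## Microcanonical analysis

The 1D conformational DoS `g(U)` is the per-bin log-sum of the 2D DoS with
`U = Env + eps_st * nst`.  The default bin width is the smallest positive gap
of the attainable-energy lattice (so no two distinct `U` values share a bin);
for incommensurate `eps_st` it falls back to 0.5.  The Boltzmann entropy
`S_B = ln g(U)` is differentiated by central differences (optionally after a
Gaussian pre-smoothing of width ~1 bin, useful at large `|eps_st|` where the
mismatch of the stiffness and contact energy scales produces a sawtooth).
Local maxima of `dT^-1/dU` above a prominence threshold (default 1e-3) are
transition points at `U*` with `T* = T(U*)`; a positive peak means the
caloric curve backbends (the small-system Maxwell construction, first-order
like), a negative peak an inflection (second-order-like).

The NVE route convolves `g(U)` with the kinetic density `(E-U)^(d/2-1)`;
`d` defaults to `3N` Cartesian degrees of freedom (3N-3 or 3N-6 are available
— the choice shifts nothing at the transition, it only rescales the kinetic
tail).  The default `E` grid has 800 points up to `U_max + 1.5 d`, covering
kinetic energies up to `T ~ 3`.  The conditional `p(U|E)` and `<U>(E)` put
the NVE caloric curve back on the conformational energy scale; the
convolution demonstrably smooths short-wavelength oscillations of `T^-1(U)`
while leaving `T*` within a bin.  Order labels may legitimately differ
between NVU and NVE when the defining peak height is close to zero; both
labels are reported with their ensemble tag rather than reconciled.

One caveat found while validating against closed forms: for a strongly
degeneracy-asymmetric two-level system (the isolated stiff angle, favorable
with solid-angle fraction p0 ~ 0.0594), the NVU transition temperature
`T* = |eps_st| / ln((1-p0)/p0)` — the equal-occupation temperature — lies
well above the Schottky maximum of `C_V(T)`.  The two scales coincide only
for nearly symmetric two-level systems, so canonical peak positions and
microcanonical `T*` should not be expected to agree at the few-percent level
for angle-dominated crossovers.

## Morphology classification

Features per conformation (and, via the production tables, per macrostate):
squared gyration radii and gyration-tensor eigenvalues for the whole chain
and for the S and F subsets; normalized asphericity and prolateness;
nematic order `S_nem` of S-block bonds (largest eigenvalue of the traceless
second-rank bond tensor; F bonds excluded since the liquid-crystalline
ordering concerns the stiff blocks); per-S-block end-to-end/contour extension;
contact counts and the S-F demixing ratio; a toroid "hole" statistic (minimal
S-bead distance from the S centroid); and a sharp-fold count (S-triplet
angles below 90 degrees).

The classifier applies the criteria hierarchically — collapse per subset,
coil sub-classes by S-extension, liquid/frozen by contacts per bead,
isotropic/anisotropic by `S_nem`, then shape/hole/fold/shell-adsorption rules
for the anisotropic sub-classes (dumbbell IIIa, racket IIIb, lamellar IIIc,
Saturn-like IIId, folded lamellar IIIe and its loose-shell variant IIIe') —
and returns the full rule trace with every label.  The numeric thresholds are
not universal: they are versioned defaults calibrated on this package's own
N=32, b=8 S-attract runs (liquid globules showed ~2.6-3.1 contacts per bead,
frozen ones >= 3.7, hence the 3.5 cut; collapse uses
`Rg^2 <= 0.45 n^(2/3) sigma^2`, between the dense-globule and coil scalings
at these chain lengths).  Users should recalibrate for other chain lengths;
the rule traces make miscalibrations visible.  The anisotropic sub-class
rules are heuristic summaries of geometric archetypes and are the least
certain part of the taxonomy, mirroring the fact that such assignments are
partly expert judgment in the first place.

## What the desk-scale studies do and do not show

The validation suite runs at desk scale: a phantom hexamer against the exact
binomial angle DoS, an N=4 interacting chain against brute-force
shell-volume sampling, N=8 canonical cross-checks against Metropolis, and the
N=32, b=8 study (two runs of 1.73e7 MCS each, averaged, with pooled
production runs started from each sampling run's final conformation) that
exhibits the
coil-globule collapse followed by the liquid-solid freezing and the
morphology sequence Ia -> IIa -> IIb on cooling.  These sizes establish the
correctness of the estimator and the analysis chain, and qualitatively
reproduce the short-chain physics; they do not reproduce long-chain (N=64,
>= 1e10 MCS per DoS) transition loci, block-length systematics, or the rarer
anisotropic morphologies (toroids, rackets, folded lamellae), which require
cluster-scale sampling with the same code paths.  The scaled study's
transition locations (coil-globule near `|eps_ff|/T ~ 0.23`, freezing near
`~ 1`) are reported as computed, not as stand-ins for long-chain values.

## Numerical choices

* Macrostate bookkeeping is exact integer arithmetic; physical energies are
  reconstructed only at analysis time.
* The dense DoS table is bounded by `max|eps_raw|` times the number of
  non-bonded pairs; memory stays in the megabyte range for N <= 64.
* The running minimum of `log g` (needed for optimistic registration) is
  maintained exactly: a rescan is triggered only when the updated key was at
  the minimum, which amortizes to O(1) per trial.
* Local moves update contacts and angles incrementally (O(N) per trial);
  regrow trials recount from scratch (O(N^2), once per MCS).
* Degenerate inputs: empty DoS, non-positive temperatures, `d < 2`,
  fewer than 3 support bins, and fingerprint mismatches between chained
  artifacts all raise immediately rather than propagating NaNs.
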