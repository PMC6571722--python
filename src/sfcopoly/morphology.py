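"""Morphology observables and the hierarchical pseudo-phase classifier.

Five criteria, applied in order, separate the conformational classes of a
single SF-multiblock chain:

(i)   squared gyration radii of the whole chain and of each bead type
      (coil vs. compact globule),
(ii)  the number of non-bonded contacts per bead (liquid vs. frozen packing),
(iii) shape parameters from the gyration-tensor eigenvalues
      (sphere / prolate / oblate),
(iv)  nematic bond order of the S-block bonds (isotropic vs. anisotropic), and
(v)   S-F demixing / shell adsorption (core-shell composition).

Labels: coils Ia/Ib; isotropic globules IIa (liquid), IIb (frozen), IIc
(collapsed F-globule with extended S-blocks, "flower"/"tadpole"); anisotropic
globules IIIa (dumbbell), IIIb (tennis racket), IIIc (lamellar, no S-folds),
IIId (Saturn-like toroidal S-shell), IIIe (folded lamellar) and IIIe'
(folded lamellar with a loose F-shell).

The numeric thresholds are not universal constants; the defaults here were
calibrated on this package's own small-chain runs and are versioned so users
can audit and recalibrate them.  Every label carries the trace of the rules
that fired.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import _kernel
from .canonical import canonical_average
from .model import Conformation, ModelParams, count_contacts
from .samc import DoSGrid, MacrostateKey, ObservableTable

__all__ = [
    "MorphologyFeatures", "MorphologyLabel", "ThresholdConfig",
    "features", "classify", "mean_features_by_macrostate",
    "rg2_derivative_curve", "Rg2DerivativeCurve",
]


@dataclass(frozen=True)
class MorphologyFeatures:
    """Deterministic feature vector of one conformation (or macrostate mean)."""

    n_beads: int
    n_S: int
    n_F: int
    rg2_all: float
    rg2_S: float
    rg2_F: float
    lam_all: tuple      # gyration-tensor eigenvalues, descending
    lam_S: tuple
    lam_F: tuple
    s_nem: float        # nematic order of S-block bonds
    ext_S: float        # mean per-S-block end-to-end / contour ratio
    min_r_S_centroid: float
    r_mean_S: float     # mean distance of S beads from the whole-chain centroid
    r_mean_F: float
    n_sharp_folds: float
    nss: float
    nsf: float
    nff: float
    nst: float

    @property
    def contacts_per_bead(self) -> float:
        return (self.nss + self.nsf + self.nff) / self.n_beads

    @property
    def demix_ratio(self) -> float:
        tot = self.nss + self.nsf + self.nff
        return self.nsf / tot if tot > 0 else 0.0

    @staticmethod
    def _shape(lam) -> tuple[float, float]:
        """(normalized asphericity, prolateness) from sorted eigenvalues."""
        l1, l2, l3 = lam
        tr = l1 + l2 + l3
        if tr <= 0:
            return 0.0, 0.0
        asph = (l1 - 0.5 * (l2 + l3)) / tr
        lm = tr / 3.0
        prol = 27.0 * (l1 - lm) * (l2 - lm) * (l3 - lm) / tr**3
        return float(asph), float(prol)

    @property
    def asphericity_S(self) -> float:
        return self._shape(self.lam_S)[0]

    @property
    def prolateness_S(self) -> float:
        return self._shape(self.lam_S)[1]

    @property
    def asphericity_all(self) -> float:
        return self._shape(self.lam_all)[0]

    @property
    def prolateness_all(self) -> float:
        return self._shape(self.lam_all)[1]


@dataclass(frozen=True)
class MorphologyLabel:
    label: str
    trace: tuple  # human-readable rule trace, in firing order


@dataclass
class ThresholdConfig:
    """Versioned classifier thresholds (scale-free where possible).

    ``collapse_coeff``: a bead subset of size n counts as collapsed when its
    Rg^2 <= collapse_coeff * n^(2/3) sigma^2 (globule scaling); calibrated on
    this package's own runs.  ``frozen_contacts_per_bead`` separates liquid
    from solid packing; ``s_nem_cut`` isotropic from nematic;
    ``ext_cut`` coiled from extended S-blocks.
    """

    schema_version: int = 1
    collapse_coeff: float = 0.45
    frozen_contacts_per_bead: float = 3.5
    s_nem_cut: float = 0.5
    ext_cut: float = 0.8
    oblate_prolateness: float = -0.02
    hole_radius: float = 1.0
    loose_shell_nsf_per_F: float = 1.0
    fold_count_cut: float = 1.0

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_file(cls, path) -> "ThresholdConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def features(conf: Conformation, model: ModelParams) -> MorphologyFeatures:
    """Feature vector of one conformation (matches production-run observables)."""
    c = count_contacts(conf, model)
    out = np.empty(_kernel.N_OBS)
    cos_lo, cos_hi = model.cos_window
    _kernel.compute_observables(conf.coords, model.types, model.angle_eligible,
                                cos_lo, cos_hi, c.nss, c.nsf, c.nff, c.nst, out)
    return _features_from_vector(out, model)


def _features_from_vector(v: np.ndarray, model: ModelParams) -> MorphologyFeatures:
    t = model.types
    return MorphologyFeatures(
        n_beads=model.N, n_S=int((t == 0).sum()), n_F=int((t == 1).sum()),
        rg2_all=float(v[0]), rg2_S=float(v[1]), rg2_F=float(v[2]),
        lam_all=(float(v[3]), float(v[4]), float(v[5])),
        lam_S=(float(v[6]), float(v[7]), float(v[8])),
        lam_F=(float(v[9]), float(v[10]), float(v[11])),
        s_nem=float(v[12]), ext_S=float(v[13]), min_r_S_centroid=float(v[14]),
        r_mean_S=float(v[15]), r_mean_F=float(v[16]), n_sharp_folds=float(v[17]),
        nss=float(v[18]), nsf=float(v[19]), nff=float(v[20]), nst=float(v[21]))


def classify(f: MorphologyFeatures,
             thresholds: ThresholdConfig | None = None) -> MorphologyLabel:
    """Assign one taxonomy label by the hierarchical criteria (i)-(v)."""
    th = thresholds or ThresholdConfig()
    trace: list[str] = []

    def collapsed(rg2, n, tag):
        cut = th.collapse_coeff * n ** (2.0 / 3.0)
        hit = rg2 <= cut
        trace.append(f"{tag}: Rg2={rg2:.3g} {'<=' if hit else '>'} "
                     f"{th.collapse_coeff}*n^(2/3)={cut:.3g}")
        return hit

    s_col = collapsed(f.rg2_S, f.n_S, "S-collapse")
    f_col = collapsed(f.rg2_F, f.n_F, "F-collapse")
    all_col = collapsed(f.rg2_all, f.n_beads, "whole-collapse")
    extended = f.ext_S >= th.ext_cut
    trace.append(f"S-extension: ext_S={f.ext_S:.3f} "
                 f"{'>=' if extended else '<'} {th.ext_cut}")

    if not all_col and not f_col:
        label = "Ib" if extended else "Ia"
        trace.append(f"coil class -> {label}")
        return MorphologyLabel(label, tuple(trace))

    if f_col and not s_col and extended:
        trace.append("collapsed F-globule with extended S-blocks -> IIc")
        return MorphologyLabel("IIc", tuple(trace))

    nematic = f.s_nem >= th.s_nem_cut
    trace.append(f"nematic order: S_nem={f.s_nem:.3f} "
                 f"{'>=' if nematic else '<'} {th.s_nem_cut}")
    if not nematic:
        frozen = f.contacts_per_bead >= th.frozen_contacts_per_bead
        trace.append(f"contacts/bead={f.contacts_per_bead:.2f} "
                     f"{'>=' if frozen else '<'} {th.frozen_contacts_per_bead}")
        label = "IIb" if frozen else "IIa"
        trace.append(f"isotropic globule -> {label}")
        return MorphologyLabel(label, tuple(trace))

    # anisotropic globules
    oblate = f.prolateness_S <= th.oblate_prolateness
    hole = f.min_r_S_centroid >= th.hole_radius
    loose = (f.nsf / max(f.n_F, 1)) < th.loose_shell_nsf_per_F
    trace.append(f"S-shape: prolateness={f.prolateness_S:.3f} "
                 f"({'oblate' if oblate else 'prolate/spherical'}); "
                 f"hole={hole} (min r={f.min_r_S_centroid:.2f}); "
                 f"F-shell {'loose' if loose else 'adsorbed'} "
                 f"(nsf/F={f.nsf / max(f.n_F, 1):.2f})")
    if oblate and hole:
        trace.append("toroidal S-shell -> IIId")
        return MorphologyLabel("IIId", tuple(trace))
    if oblate:
        trace.append("oblate S without hole -> IIIb")
        return MorphologyLabel("IIIb", tuple(trace))
    if f.n_sharp_folds >= th.fold_count_cut:
        label = "IIIe'" if loose else "IIIe"
        trace.append(f"folded S-blocks ({f.n_sharp_folds:.1f} folds) -> {label}")
        return MorphologyLabel(label, tuple(trace))
    label = "IIIa" if loose else "IIIc"
    trace.append(f"straight S-stems, F-shell {'loose (caps)' if loose else 'dense'}"
                 f" -> {label}")
    return MorphologyLabel(label, tuple(trace))


def mean_features_by_macrostate(table: ObservableTable, model: ModelParams
                                ) -> dict[MacrostateKey, MorphologyFeatures]:
    """Per-macrostate feature means from a production-run observable table."""
    out = {}
    for i in range(table.n_keys):
        key = MacrostateKey(int(table.env_raw[i]), int(table.nst[i]))
        out[key] = _features_from_vector(table.means[i], model)
    return out


@dataclass
class Rg2DerivativeCurve:
    inv_T: np.ndarray            # |eps_ff| / T
    rg2: np.ndarray              # <Rg^2>(T) by canonical reweighting
    derivative: np.ndarray       # d<Rg^2>/d(|eps_ff|/T)
    subset: str
    maxima: list = field(default_factory=list)  # (inv_T, |derivative|) peaks


def rg2_derivative_curve(dos: DoSGrid, model: ModelParams, table: ObservableTable,
                         eps_st: float, inv_T_grid: np.ndarray,
                         subset: str = "all") -> Rg2DerivativeCurve:
    """Collapse indicator: d<Rg^2>/d(|eps_ff|/T) along an inverse-T grid.

    Useful where a transition (e.g. a smeared coil-globule collapse) leaves no
    maximum in the specific heat but a clear step in the gyration radius.
    Maxima are reported on the collapse rate -d<Rg^2>/dx.
    """
    col = {"all": "rg2_all", "S": "rg2_S", "F": "rg2_F"}[subset]
    x = np.asarray(inv_T_grid, dtype=float)
    aff = abs(model.eps_ff)
    rg2 = np.array([
        canonical_average(dos, model, (table, col), T=aff / xi, eps_st=eps_st)
        for xi in x])
    deriv = np.gradient(rg2, x)
    from scipy.signal import find_peaks
    # prominence floor suppresses machine-epsilon wiggles of flat curves
    floor = max(1e-10, 1e-9 * float(np.abs(rg2).max()))
    idx, _ = find_peaks(-deriv, prominence=floor)
    maxima = [(float(x[i]), float(-deriv[i])) for i in idx]
    return Rg2DerivativeCurve(inv_T=x, rg2=rg2, derivative=deriv,
                              subset=subset, maxima=maxima)
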