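"""Microcanonical analysis: NVU and NVE caloric curves and transition orders.

The conformational (NVU) route projects the 2D DoS onto the total
conformational energy U = Env + eps_st*nst, takes the Boltzmann entropy
S_B(U) = ln g(U), and differentiates twice:

    T^-1(U) = dS_B/dU,          d T^-1 / dU.

Local maxima of dT^-1/dU mark pseudo-phase transitions at U*; a positive peak
(backbending of the caloric curve, the small-system Maxwell construction)
signals a first-order-like transition, a negative peak an inflection, i.e. a
second-order-like transition.  The transition temperature is T* = T(U*).

The true microcanonical (NVE) route convolves g(U) with the kinetic-energy
density (E-U)^(d/2-1) of d quadratic degrees of freedom, yielding g(E); the
conditional p(U|E) and the mean <U>(E) allow the NVE caloric curve to be
plotted against the conformational energy scale.  The convolution smooths
discretization oscillations but leaves transition temperatures unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.special import logsumexp

from .model import ModelParams
from .samc import DoSGrid

__all__ = [
    "DoS1D", "MicrocanonicalCurve", "TransitionPoint",
    "project_dos_1d", "inverse_temperature_U", "classify_transitions",
    "convolve_kinetic", "inverse_temperature_E", "conditional_U_given_E",
    "mean_U_of_E", "nve_curve", "default_bin_width",
]


@dataclass
class DoS1D:
    """1D log-density-of-states on an energy grid (bin centers)."""

    U: np.ndarray        # strictly increasing bin centers
    log_g: np.ndarray    # natural log, relative
    bin_width: float
    eps_st: float = 0.0
    kind: str = "U"      # "U" (conformational) or "E" (total)
    d: int | None = None  # degrees of freedom (set for kind="E")

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        self.log_g = np.asarray(self.log_g, dtype=float)
        if self.U.size != self.log_g.size:
            raise ValueError("U and log_g must align")
        if self.U.size > 1 and not np.all(np.diff(self.U) > 0):
            raise ValueError("energy grid must be strictly increasing")

    @property
    def support(self) -> np.ndarray:
        return np.isfinite(self.log_g)


@dataclass
class MicrocanonicalCurve:
    """Inverse-temperature curve and its derivative on an energy abscissa."""

    energy: np.ndarray        # U, E, or <U>(E)
    inv_T: np.ndarray
    d_inv_T: np.ndarray       # d(T^-1)/d(energy)
    abscissa: str = "U"       # which energy variable `energy` holds
    ensemble: str = "NVU"
    eps_st: float = 0.0
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TransitionPoint:
    U_star: float
    T_star: float
    order: str              # "first" | "second"
    peak_height: float      # value of dT^-1/dU at the peak (sign fixes order)
    ensemble: str = "NVU"


def default_bin_width(dos: DoSGrid, model: ModelParams, eps_st: float) -> float:
    """Largest width whose bin boundaries separate all attainable U values.

    Computed as the minimum positive gap of the attainable energy lattice
    U = raw_scale*Env_raw + eps_st*nst over the DoS keys; falls back to 0.5
    when eps_st is incommensurate with the contact-energy scale and the gaps
    collapse toward zero.
    """
    U = np.unique(np.round(dos.energies(model, eps_st), 12))
    if U.size < 2:
        return 1.0
    gaps = np.diff(U)
    gap = float(gaps[gaps > 1e-9].min(initial=np.inf))
    if not np.isfinite(gap) or gap < 1e-6:
        return 0.5
    return gap


def project_dos_1d(dos: DoSGrid, model: ModelParams, eps_st: float | None = None,
                   bin_width: float | None = None) -> DoS1D:
    """Project g(Env, nst) onto U = Env + eps_st*nst (log-sum-exp per bin)."""
    if dos.n_keys == 0:
        raise ValueError("empty DoS")
    e = model.eps_st if eps_st is None else eps_st
    U = dos.energies(model, e)
    if bin_width is None:
        bin_width = default_bin_width(dos, model, e)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = U.min()
    idx = np.floor((U - lo) / bin_width + 0.5).astype(np.int64)
    n_bins = int(idx.max()) + 1
    lg = np.full(n_bins, -np.inf)
    for i, k in enumerate(idx):
        lg[k] = np.logaddexp(lg[k], dos.log_g[i])
    centers = lo + bin_width * np.arange(n_bins)
    keep = np.isfinite(lg)
    return DoS1D(U=centers[keep], log_g=lg[keep], bin_width=float(bin_width),
                 eps_st=e, kind="U")


def _central_diff(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Central differences on a (possibly non-uniform) grid; one-sided ends."""
    return np.gradient(y, x, edge_order=1)


def inverse_temperature_U(dos1d: DoS1D, smoothing: float = 0.0) -> MicrocanonicalCurve:
    """T^-1(U) = dS_B/dU and its derivative, by central differences.

    ``smoothing`` is the width (in bins) of an optional Gaussian pre-smoothing
    of S_B; useful when disparate energy scales produce sawtooth oscillations.
    """
    sup = dos1d.support
    U = dos1d.U[sup]
    sb = dos1d.log_g[sup]
    if U.size < 3:
        raise ValueError("need at least 3 support bins")
    if smoothing and smoothing > 0:
        sb = gaussian_filter1d(sb, sigma=smoothing, mode="nearest")
    inv_t = _central_diff(U, sb)
    d_inv_t = _central_diff(U, inv_t)
    return MicrocanonicalCurve(energy=U, inv_T=inv_t, d_inv_T=d_inv_t,
                               abscissa=dos1d.kind, ensemble="NVU" if dos1d.kind == "U" else "NVE",
                               eps_st=dos1d.eps_st,
                               meta={"smoothing": smoothing,
                                     "bin_width": dos1d.bin_width})


def classify_transitions(curve: MicrocanonicalCurve,
                         prominence: float = 1e-3) -> list[TransitionPoint]:
    """Peaks of dT^-1/dU; positive peak height => first order, negative => second."""
    y = curve.d_inv_T
    if y.size < 3:
        return []
    idx, _ = find_peaks(y, prominence=prominence)
    out = []
    for i in idx:
        h = float(y[i])
        invt = float(curve.inv_T[i])
        t_star = 1.0 / invt if invt > 0 else np.inf
        out.append(TransitionPoint(
            U_star=float(curve.energy[i]), T_star=t_star,
            order="first" if h > 0 else "second",
            peak_height=h, ensemble=curve.ensemble))
    return out


def convolve_kinetic(dos1d: DoS1D, d: int, E_grid: np.ndarray | None = None,
                     n_E: int = 800) -> DoS1D:
    """NVE DoS: g(E) = C * sum_U (E-U)^(d/2-1) g(U) Theta(E-U).

    d is the number of kinetic degrees of freedom (default choice elsewhere:
    3N).  The normalization constant is irrelevant for the caloric curve.
    The default E grid spans (Umin, Umax + 1.5*d], covering kinetic energies
    up to a temperature of about 3.
    """
    if d < 2:
        raise ValueError("need d >= 2 degrees of freedom")
    sup = dos1d.support
    U = dos1d.U[sup]
    lg = dos1d.log_g[sup]
    umin, umax = U[0], U[-1]
    if E_grid is None:
        eps = max(1e-6, 1e-4 * (umax - umin + 1.0))
        E_grid = np.linspace(umin + eps, umax + 1.5 * d, n_E)
    E = np.asarray(E_grid, dtype=float)
    if np.all(E <= umin):
        raise ValueError("E grid must extend above Umin")
    a = 0.5 * d - 1.0
    log_gE = np.full(E.size, -np.inf)
    for i, e in enumerate(E):
        mask = U < e
        if not mask.any():
            continue
        log_gE[i] = logsumexp(a * np.log(e - U[mask]) + lg[mask])
    keep = np.isfinite(log_gE)
    be = float(E[1] - E[0]) if E.size > 1 else dos1d.bin_width
    return DoS1D(U=E[keep], log_g=log_gE[keep] - log_gE[keep].max(),
                 bin_width=be, eps_st=dos1d.eps_st, kind="E", d=d)


def inverse_temperature_E(dosE: DoS1D, smoothing: float = 0.0) -> MicrocanonicalCurve:
    """T^-1(E) = d ln g(E)/dE on the NVE grid."""
    curve = inverse_temperature_U(dosE, smoothing=smoothing)
    curve.ensemble = "NVE"
    curve.abscissa = "E"
    return curve


def conditional_U_given_E(dos1d: DoS1D, d: int, E: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized p(U|E) on Umin <= U <= min(E, Umax).

    Returns (U_bins, p); p sums to 1.
    """
    sup = dos1d.support
    U = dos1d.U[sup]
    lg = dos1d.log_g[sup]
    if E <= U[0]:
        raise ValueError("E must exceed Umin")
    a = 0.5 * d - 1.0
    mask = U < E
    w = a * np.log(E - U[mask]) + lg[mask]
    p = np.exp(w - logsumexp(w))
    p /= p.sum()
    return U[mask], p


def mean_U_of_E(dos1d: DoS1D, d: int, E_grid: np.ndarray) -> np.ndarray:
    """<U>(E) = sum_U U * p(U|E) over the E grid."""
    out = np.empty(len(E_grid))
    for i, e in enumerate(E_grid):
        ub, p = conditional_U_given_E(dos1d, d, float(e))
        out[i] = float(ub @ p)
    return out


def nve_curve(dos1d: DoS1D, d: int, E_grid: np.ndarray | None = None,
              n_E: int = 800, smoothing: float = 0.0) -> MicrocanonicalCurve:
    """T^-1 against <U>(E): the NVE caloric curve on the conformational scale.

    The derivative is taken with respect to <U>(E) so that transition points
    can be compared bin-for-bin with the NVU curve.
    """
    dosE = convolve_kinetic(dos1d, d, E_grid=E_grid, n_E=n_E)
    base = inverse_temperature_E(dosE, smoothing=smoothing)
    muE = mean_U_of_E(dos1d, d, dosE.U)
    # <U>(E) can plateau at Umin/Umax to machine precision; keep a strictly
    # increasing subsequence so the derivative grid is well defined
    keep = np.concatenate([[True], np.diff(muE) > 1e-12])
    muE, inv_T = muE[keep], base.inv_T[keep]
    d_inv_t = _central_diff(muE, inv_T)
    return MicrocanonicalCurve(energy=muE, inv_T=inv_T, d_inv_T=d_inv_t,
                               abscissa="<U>(E)", ensemble="NVE",
                               eps_st=dos1d.eps_st,
                               meta={"d": d, "smoothing": smoothing})
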