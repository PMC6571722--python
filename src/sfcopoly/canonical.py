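"""Canonical-ensemble analysis of a 2D density of states.

All quantities follow from reweighting the macrostate DoS g(Env, nst):

    Z(T, eps_st)   = sum_k g_k exp(-U_k / T),   U_k = Env_k + eps_st * nst_k
    <A>(T, eps_st) = Z^-1 sum_k Abar_k g_k exp(-U_k / T)
    C_V            = (<U^2> - <U>^2) / T^2

with k_B = 1 and temperature in units of |eps_ff|.  Because U depends on the
stiffness eps_st only through the nst coordinate, a single 2D DoS serves every
(T, eps_st) pair; heat-capacity maxima along both axes trace the pseudo-phase
boundaries of the state diagram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from scipy.special import logsumexp

from .model import ModelParams
from .samc import DoSGrid, MacrostateKey, ObservableTable

__all__ = [
    "CanonicalPoint", "CvPeak", "CvProfile", "StateDiagram",
    "log_partition", "canonical_average", "heat_capacity",
    "macrostate_probability", "most_probable_macrostate",
    "cv_profile_T", "cv_profile_stiffness", "build_state_diagram",
]


@dataclass(frozen=True)
class CanonicalPoint:
    T: float
    eps_st: float
    logZ: float
    mean_U: float
    mean_U2: float
    CV: float


@dataclass(frozen=True)
class CvPeak:
    """A local maximum of a 1D C_V profile."""

    index: int
    x: float          # grid coordinate (T or eps_st, depending on the profile)
    CV: float
    prominence: float


@dataclass
class CvProfile:
    x: np.ndarray         # T grid or eps_st grid
    axis: str             # "T" or "eps_st"
    fixed: float          # the value of the other coordinate
    logZ: np.ndarray
    mean_U: np.ndarray
    CV: np.ndarray
    maxima: list[CvPeak] = field(default_factory=list)


def _stats(dos: DoSGrid, model: ModelParams, T: np.ndarray, eps_st: float):
    """(logZ, <U>, <U^2>) for a vector of temperatures at fixed eps_st.

    <U> and <U^2> are accumulated in the same max-subtracted pass as Z to
    avoid catastrophic cancellation at low T.
    """
    if dos.n_keys == 0:
        raise ValueError("empty DoS")
    T = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive")
    U = dos.energies(model, eps_st)
    W = dos.log_g[:, None] - U[:, None] / T[None, :]
    m = W.max(axis=0)
    P = np.exp(W - m[None, :])
    Z = P.sum(axis=0)
    logZ = m + np.log(Z)
    mean_U = (U[:, None] * P).sum(axis=0) / Z
    mean_U2 = (U[:, None] ** 2 * P).sum(axis=0) / Z
    return logZ, mean_U, mean_U2


def log_partition(dos: DoSGrid, model: ModelParams, T: float,
                  eps_st: float | None = None) -> float:
    """log Z(T, eps_st) by overflow-safe log-sum-exp over all macrostates."""
    e = model.eps_st if eps_st is None else eps_st
    logZ, _, _ = _stats(dos, model, np.array([T]), e)
    return float(logZ[0])


def canonical_average(dos: DoSGrid, model: ModelParams, observable, T: float,
                      eps_st: float | None = None) -> float:
    """Boltzmann-weighted mean of a per-macrostate observable Abar.

    ``observable`` may be a per-key array aligned with the DoS, a callable
    ``f(env_raw, nst) -> array``, or a pair ``(ObservableTable, column)``;
    table keys missing from the DoS are ignored, DoS keys missing from the
    table are masked out of the average (with their weight dropped).
    """
    e = model.eps_st if eps_st is None else eps_st
    U = dos.energies(model, e)
    w = dos.log_g - U / T
    if callable(observable):
        A = np.asarray(observable(dos.env_raw, dos.nst), dtype=float)
        mask = np.ones(dos.n_keys, dtype=bool)
    elif isinstance(observable, tuple) and isinstance(observable[0], ObservableTable):
        table, colname = observable
        col = table.column(colname)
        lut = {(int(ei), int(ni)): float(v)
               for ei, ni, v in zip(table.env_raw, table.nst, col)}
        A = np.zeros(dos.n_keys)
        mask = np.zeros(dos.n_keys, dtype=bool)
        for i, (ei, ni) in enumerate(zip(dos.env_raw, dos.nst)):
            v = lut.get((int(ei), int(ni)))
            if v is not None:
                A[i] = v
                mask[i] = True
    else:
        A = np.asarray(observable, dtype=float)
        if A.shape != (dos.n_keys,):
            raise ValueError("observable array must align with the DoS keys")
        mask = np.ones(dos.n_keys, dtype=bool)
    if not mask.any():
        raise ValueError("observable is undefined on every macrostate")
    wm = w[mask]
    m = wm.max()
    p = np.exp(wm - m)
    return float((A[mask] * p).sum() / p.sum())


def heat_capacity(dos: DoSGrid, model: ModelParams, T: float,
                  eps_st: float | None = None) -> CanonicalPoint:
    """C_V from the energy-fluctuation formula at one (T, eps_st) point."""
    e = model.eps_st if eps_st is None else eps_st
    logZ, mu, mu2 = _stats(dos, model, np.array([T]), e)
    cv = max((mu2[0] - mu[0] ** 2) / T**2, 0.0)
    return CanonicalPoint(T=float(T), eps_st=e, logZ=float(logZ[0]),
                          mean_U=float(mu[0]), mean_U2=float(mu2[0]), CV=float(cv))


def macrostate_probability(dos: DoSGrid, model: ModelParams, T: float,
                           eps_st: float | None = None) -> dict[MacrostateKey, float]:
    """Normalized Boltzmann probability of each macrostate."""
    e = model.eps_st if eps_st is None else eps_st
    U = dos.energies(model, e)
    w = dos.log_g - U / T
    p = np.exp(w - logsumexp(w))
    p /= p.sum()
    return {MacrostateKey(int(ei), int(ni)): float(pi)
            for ei, ni, pi in zip(dos.env_raw, dos.nst, p)}


def most_probable_macrostate(dos: DoSGrid, model: ModelParams, T: float,
                             eps_st: float | None = None) -> MacrostateKey:
    rho = macrostate_probability(dos, model, T, eps_st)
    return max(rho, key=rho.get)


def _find_maxima(x: np.ndarray, cv: np.ndarray, smooth_window: int,
                 prominence: float) -> list[CvPeak]:
    y = cv
    if smooth_window and smooth_window >= 3:
        w = smooth_window + 1 if smooth_window % 2 == 0 else smooth_window
        y = savgol_filter(cv, min(w, len(cv) // 2 * 2 + 1), 2)
    idx, props = find_peaks(y, prominence=prominence if prominence > 0 else None)
    proms = props.get("prominences")
    if proms is None:
        from scipy.signal import peak_prominences
        proms = peak_prominences(y, idx)[0] if idx.size else np.array([])
    return [CvPeak(index=int(i), x=float(x[i]), CV=float(cv[i]), prominence=float(p))
            for i, p in zip(idx, proms)]


def cv_profile_T(dos: DoSGrid, model: ModelParams, eps_st: float,
                 T_grid: np.ndarray, smooth_window: int = 0,
                 prominence: float = 0.0) -> CvProfile:
    """C_V(T) at fixed stiffness, with local maxima and their prominences."""
    T = np.asarray(T_grid, dtype=float)
    if T.size < 3:
        raise ValueError("T grid must have at least 3 points")
    if not (np.all(np.diff(T) > 0) or np.all(np.diff(T) < 0)):
        raise ValueError("T grid must be monotone")
    logZ, mu, mu2 = _stats(dos, model, T, eps_st)
    cv = np.maximum((mu2 - mu**2) / T**2, 0.0)
    prof = CvProfile(x=T, axis="T", fixed=eps_st, logZ=logZ, mean_U=mu, CV=cv)
    prof.maxima = _find_maxima(T, cv, smooth_window, prominence)
    return prof


def cv_profile_stiffness(dos: DoSGrid, model: ModelParams, T: float,
                         eps_st_grid: np.ndarray, smooth_window: int = 0,
                         prominence: float = 0.0) -> CvProfile:
    """C_V(eps_st) at fixed temperature (same 2D DoS, stiffness swept)."""
    es = np.asarray(eps_st_grid, dtype=float)
    if es.size < 3:
        raise ValueError("eps_st grid must have at least 3 points")
    logZ = np.empty(es.size)
    mu = np.empty(es.size)
    mu2 = np.empty(es.size)
    for i, e in enumerate(es):
        z, m1, m2 = _stats(dos, model, np.array([T]), float(e))
        logZ[i], mu[i], mu2[i] = z[0], m1[0], m2[0]
    cv = np.maximum((mu2 - mu**2) / T**2, 0.0)
    prof = CvProfile(x=es, axis="eps_st", fixed=T, logZ=logZ, mean_U=mu, CV=cv)
    prof.maxima = _find_maxima(es, cv, smooth_window, prominence)
    return prof


@dataclass
class StateDiagram:
    """C_V surface over (eps_st/|eps_ff|, |eps_ff|/T) with maxima loci."""

    stiffness_ratio: np.ndarray    # x grid: eps_st / eps_ff  (>= 0)
    inv_temperature: np.ndarray    # y grid: |eps_ff| / T
    cv: np.ndarray                 # (nx, ny)
    loci_T: list[tuple[int, int, float]] = field(default_factory=list)
    loci_stiffness: list[tuple[int, int, float]] = field(default_factory=list)
    markers: list = field(default_factory=list)   # microcanonical overlays
    meta: dict = field(default_factory=dict)

    def cv_at(self, ix: int, iy: int) -> float:
        return float(self.cv[ix, iy])


def build_state_diagram(dos: DoSGrid, model: ModelParams,
                        stiffness_ratio_grid: np.ndarray | None = None,
                        inv_T_grid: np.ndarray | None = None,
                        smooth_window: int = 0, prominence: float = 0.0,
                        markers: list | None = None) -> StateDiagram:
    """Heat-capacity surface plus maxima loci along both axes.

    x = eps_st/eps_ff (both negative, so the ratio is >= 0) and
    y = |eps_ff|/T, following the conventional state-diagram axes.  Maxima of
    C_V(T) at fixed eps_st give one locus; maxima of C_V(eps_st) at fixed T
    give the other.  Microcanonical transition markers may be attached.
    """
    aff = abs(model.eps_ff)
    if stiffness_ratio_grid is None:
        hi = 80.0 if abs(model.eps_ss) > abs(model.eps_ff) else 20.0
        stiffness_ratio_grid = np.arange(0.0, hi + 1e-9, 0.25)
    if inv_T_grid is None:
        inv_T_grid = np.arange(0.05, 5.0 + 1e-9, 0.01)
    x = np.asarray(stiffness_ratio_grid, dtype=float)
    y = np.asarray(inv_T_grid, dtype=float)
    T = aff / y
    cv = np.empty((x.size, y.size))
    loci_T: list[tuple[int, int, float]] = []
    for ix, xr in enumerate(x):
        eps_st = -xr * aff
        _, mu, mu2 = _stats(dos, model, T, eps_st)
        cv[ix] = np.maximum((mu2 - mu**2) / T**2, 0.0)
        for pk in _find_maxima(y, cv[ix], smooth_window, prominence):
            loci_T.append((ix, pk.index, pk.prominence))
    loci_st: list[tuple[int, int, float]] = []
    for iy in range(y.size):
        for pk in _find_maxima(x, cv[:, iy], smooth_window, prominence):
            loci_st.append((pk.index, iy, pk.prominence))
    return StateDiagram(
        stiffness_ratio=x, inv_temperature=y, cv=cv,
        loci_T=loci_T, loci_stiffness=loci_st,
        markers=list(markers) if markers else [],
        meta={"fingerprint": dos.fingerprint, "smooth_window": smooth_window,
              "prominence": prominence})
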