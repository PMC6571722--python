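"""Independent reference computations used to validate the sampler and analyses.

Nothing here shares a code path with the components it checks: contact
counting is re-derived with plain double loops, the Metropolis sampler
recomputes the full energy for every trial, the brute-force sampler draws
whole chains bond-by-bond with Gaussian-direction sphere picking, and the
closed forms (binomial phantom DoS, Schottky heat capacity, ideal-gas caloric
curve) come straight from textbook formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.stats import binom

from .model import ModelParams

__all__ = [
    "PhantomSpec", "phantom_dos", "phantom_p0",
    "BruteForceDoS", "brute_force_dos",
    "MetropolisResult", "metropolis_reference", "blocked_sem",
    "analytic_limits_suite",
]


# ---------------------------------------------------------------------------
# phantom-chain closed form


def phantom_p0(theta_min: float = 150.0, theta_max: float = 170.0) -> float:
    """Probability that one angle of an ideal chain is favorable.

    For i.i.d. uniformly distributed bond directions the cosine of each
    valence angle is uniform on [-1, 1], so the solid-angle fraction of the
    window is (cos(theta_min) - cos(theta_max)) / 2.
    """
    return (math.cos(math.radians(theta_min)) - math.cos(math.radians(theta_max))) / 2.0


@dataclass(frozen=True)
class PhantomSpec:
    n_angles: int
    p0: float = phantom_p0()

    def __post_init__(self):
        if self.n_angles < 1:
            raise ValueError("need at least one angle")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie in (0, 1)")


def phantom_dos(spec: PhantomSpec) -> np.ndarray:
    """Exact normalized DoS over nst for a phantom all-S chain: Binomial(n, p0)."""
    return binom.pmf(np.arange(spec.n_angles + 1), spec.n_angles, spec.p0)


# ---------------------------------------------------------------------------
# brute-force uniform sampling (tiny chains)


@dataclass
class BruteForceDoS:
    env_raw: np.ndarray
    nst: np.ndarray
    count: np.ndarray
    freq: np.ndarray          # count / n_valid
    se: np.ndarray            # multinomial standard error of freq
    n_valid: int
    n_total: int

    @property
    def acceptance(self) -> float:
        return self.n_valid / self.n_total

    def as_dict(self) -> dict[tuple[int, int], float]:
        return {(int(e), int(n)): float(f)
                for e, n, f in zip(self.env_raw, self.nst, self.freq)}


def brute_force_dos(model: ModelParams, n_samples: int, seed: int,
                    batch: int = 200_000, min_acceptance: float = 1e-4
                    ) -> BruteForceDoS:
    """Estimate the relative DoS of a tiny chain by direct uniform sampling.

    Bond vectors are drawn uniformly with respect to volume from the
    spherical shell [l_min, l_max] (Gaussian-direction sphere picking), which
    is the same Cartesian configuration measure the Monte Carlo move set
    targets; hard-sphere-invalid chains are rejected and the surviving
    macrostate histogram estimates g(Env_raw, nst) up to normalization.
    """
    if model.N > 5:
        raise ValueError("brute-force sampling is for tiny chains (N <= 5)")
    rng = np.random.default_rng(seed)
    N = model.N
    t = model.types
    eps = model.eps_raw
    cos_lo, cos_hi = model.cos_window
    elig = model.angle_eligible
    counts: dict[tuple[int, int], int] = {}
    n_valid = 0
    n_total = 0
    pairs = [(i, j) for i in range(N) for j in range(i + 2, N)]
    while n_total < n_samples:
        m = min(batch, n_samples - n_total)
        n_total += m
        u = rng.random((m, N - 1))
        r = (model.l_min**3 + u * (model.l_max**3 - model.l_min**3)) ** (1 / 3)
        d = rng.normal(size=(m, N - 1, 3))
        d /= np.linalg.norm(d, axis=2, keepdims=True)
        bonds = r[:, :, None] * d
        coords = np.concatenate(
            [np.zeros((m, 1, 3)), np.cumsum(bonds, axis=1)], axis=1)
        valid = np.ones(m, dtype=bool)
        env = np.zeros(m, dtype=np.int64)
        if not model.phantom:
            for i, j in pairs:
                d2 = np.sum((coords[:, i] - coords[:, j]) ** 2, axis=1)
                valid &= d2 >= model.sigma**2
                contact = d2 <= model.R_cut**2
                tt = t[i] + t[j]
                e = eps[0] if tt == 0 else (eps[2] if tt == 2 else eps[1])
                env += np.where(contact, e, 0)
        nst = np.zeros(m, dtype=np.int64)
        for j in range(1, N - 1):
            if not elig[j]:
                continue
            a = coords[:, j] - coords[:, j - 1]
            c = coords[:, j + 1] - coords[:, j]
            cosang = -np.sum(a * c, axis=1) / np.sqrt(
                np.sum(a * a, axis=1) * np.sum(c * c, axis=1))
            nst += ((cosang >= cos_lo) & (cosang <= cos_hi)).astype(np.int64)
        for e, n in zip(env[valid], nst[valid]):
            counts[(int(e), int(n))] = counts.get((int(e), int(n)), 0) + 1
        n_valid += int(valid.sum())
    if n_valid < min_acceptance * n_total:
        raise RuntimeError(
            f"acceptance rate {n_valid / n_total:.2e} below floor {min_acceptance}")
    keys = sorted(counts)
    cnt = np.array([counts[k] for k in keys], dtype=np.int64)
    freq = cnt / n_valid
    se = np.sqrt(freq * (1 - freq) / n_valid)
    return BruteForceDoS(
        env_raw=np.array([k[0] for k in keys], dtype=np.int64),
        nst=np.array([k[1] for k in keys], dtype=np.int64),
        count=cnt, freq=freq, se=se, n_valid=n_valid, n_total=n_total)


# ---------------------------------------------------------------------------
# fixed-temperature Metropolis reference


@njit(cache=True)
def _energy_oracle(x, types, elig, sigma2, r_cut2, cos_lo, cos_hi,
                   e_ss, e_sf, e_ff, eps_st, phantom):
    """Plain double-loop energy; returns (U, valid). Independent of the
    incremental bookkeeping used by the flat-histogram kernel."""
    N = x.shape[0]
    env = 0.0
    for i in range(N):
        for j in range(i + 2, N):
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if not phantom:
                if r2 < sigma2:
                    return 0.0, False
                if r2 <= r_cut2:
                    ts = types[i] + types[j]
                    if ts == 0:
                        env += e_ss
                    elif ts == 2:
                        env += e_ff
                    else:
                        env += e_sf
    est = 0.0
    for j in range(1, N - 1):
        if elig[j] == 1:
            ax = x[j, 0] - x[j - 1, 0]
            ay = x[j, 1] - x[j - 1, 1]
            az = x[j, 2] - x[j - 1, 2]
            cx = x[j + 1, 0] - x[j, 0]
            cy = x[j + 1, 1] - x[j, 1]
            cz = x[j + 1, 2] - x[j, 2]
            c = -(ax * cx + ay * cy + az * cz) / np.sqrt(
                (ax * ax + ay * ay + az * az) * (cx * cx + cy * cy + cz * cz))
            if cos_lo <= c <= cos_hi:
                est += eps_st
    return env + est, True


@njit(cache=True)
def _metropolis_kernel(x, types, elig, n_mcs, T, sigma2, r_cut2,
                       l_min, l_max, cos_lo, cos_hi,
                       e_ss, e_sf, e_ff, eps_st, phantom,
                       disp, k_max, seed, u_series, rg2_series):
    np.random.seed(seed)
    N = x.shape[0]
    if k_max > N - 1:
        k_max = N - 1
    buf = x.copy()
    u_cur, ok = _energy_oracle(x, types, elig, sigma2, r_cut2, cos_lo, cos_hi,
                               e_ss, e_sf, e_ff, eps_st, phantom)
    l_min3 = l_min**3
    l_range3 = l_max**3 - l_min3
    for t in range(n_mcs):
        for trial in range(2 * N + 1):
            for m in range(N):
                for a in range(3):
                    buf[m, a] = x[m, a]
            if trial < 2 * N:
                i = np.random.randint(N)
                for a in range(3):
                    buf[i, a] = x[i, a] + disp * (2.0 * np.random.random() - 1.0)
                ok = True
                if i > 0:
                    d2 = ((buf[i, 0] - buf[i - 1, 0])**2
                          + (buf[i, 1] - buf[i - 1, 1])**2
                          + (buf[i, 2] - buf[i - 1, 2])**2)
                    if d2 < l_min * l_min or d2 > l_max * l_max:
                        ok = False
                if ok and i < N - 1:
                    d2 = ((buf[i, 0] - buf[i + 1, 0])**2
                          + (buf[i, 1] - buf[i + 1, 1])**2
                          + (buf[i, 2] - buf[i + 1, 2])**2)
                    if d2 < l_min * l_min or d2 > l_max * l_max:
                        ok = False
            else:
                k = 1 + np.random.randint(k_max)
                grow_tail = np.random.random() < 0.5
                ok = True
                for s in range(k):
                    r = (l_min3 + np.random.random() * l_range3) ** (1.0 / 3.0)
                    while True:
                        aa = 2.0 * np.random.random() - 1.0
                        bb = 2.0 * np.random.random() - 1.0
                        ss = aa * aa + bb * bb
                        if ss < 1.0:
                            break
                    f = 2.0 * np.sqrt(1.0 - ss)
                    vx, vy, vz = r * aa * f, r * bb * f, r * (1.0 - 2.0 * ss)
                    if grow_tail:
                        m = N - k + s
                        buf[m, 0] = buf[m - 1, 0] + vx
                        buf[m, 1] = buf[m - 1, 1] + vy
                        buf[m, 2] = buf[m - 1, 2] + vz
                    else:
                        m = k - 1 - s
                        buf[m, 0] = buf[m + 1, 0] + vx
                        buf[m, 1] = buf[m + 1, 1] + vy
                        buf[m, 2] = buf[m + 1, 2] + vz
            if not ok:
                continue
            u_new, ok = _energy_oracle(buf, types, elig, sigma2, r_cut2,
                                       cos_lo, cos_hi, e_ss, e_sf, e_ff,
                                       eps_st, phantom)
            if not ok:
                continue
            if u_new <= u_cur or np.random.random() < np.exp(-(u_new - u_cur) / T):
                for m in range(N):
                    for a in range(3):
                        x[m, a] = buf[m, a]
                u_cur = u_new
        u_series[t] = u_cur
        cx = 0.0
        cy = 0.0
        cz = 0.0
        for m in range(N):
            cx += x[m, 0]
            cy += x[m, 1]
            cz += x[m, 2]
        cx /= N
        cy /= N
        cz /= N
        s = 0.0
        for m in range(N):
            s += ((x[m, 0] - cx)**2 + (x[m, 1] - cy)**2 + (x[m, 2] - cz)**2)
        rg2_series[t] = s / N


def blocked_sem(series: np.ndarray, min_blocks: int = 16) -> float:
    """Autocorrelation-aware standard error by blocking (max over block sizes)."""
    x = np.asarray(series, dtype=float)
    best = x.std(ddof=1) / math.sqrt(len(x))
    size = 2
    while len(x) // size >= min_blocks:
        nb = len(x) // size
        bm = x[: nb * size].reshape(nb, size).mean(axis=1)
        best = max(best, bm.std(ddof=1) / math.sqrt(nb))
        size *= 2
    return float(best)


@dataclass
class MetropolisResult:
    T: float
    mean_U: float
    sem_U: float
    CV: float
    sem_CV: float
    mean_rg2: float
    sem_rg2: float
    u_series: np.ndarray = field(repr=False, default=None)


def metropolis_reference(model: ModelParams, T: float, n_mcs: int, seed: int,
                         burn_frac: float = 0.2, k_max: int | None = None,
                         displacement: float = 0.05) -> MetropolisResult:
    """Fixed-temperature Metropolis with the same move geometry.

    Full energy recomputation per trial; per-MCS series of U and Rg^2 with
    blocking error bars, and C_V from the energy fluctuations with a
    block-jackknife error estimate.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    from .model import initial_conformation

    conf = initial_conformation(model, seed=seed)
    x = conf.coords.copy()
    u_series = np.empty(n_mcs)
    rg2_series = np.empty(n_mcs)
    cos_lo, cos_hi = model.cos_window
    _metropolis_kernel(
        x, model.types, model.angle_eligible, int(n_mcs), float(T),
        model.sigma**2, model.R_cut**2, model.l_min, model.l_max,
        cos_lo, cos_hi,
        float(model.eps_ss), float(model.eps_sf), float(model.eps_ff),
        float(model.eps_st), model.phantom,
        float(displacement), int(model.b if k_max is None else k_max),
        int(seed) % 2**31, u_series, rg2_series)
    burn = int(burn_frac * n_mcs)
    u = u_series[burn:]
    r = rg2_series[burn:]
    cv = float(u.var() / T**2)
    # block jackknife for the fluctuation-based C_V
    nb = 16
    bs = len(u) // nb
    cv_jk = np.array([
        np.delete(u[: nb * bs].reshape(nb, bs), i, axis=0).ravel().var() / T**2
        for i in range(nb)])
    sem_cv = float(np.sqrt((nb - 1) / nb * ((cv_jk - cv_jk.mean())**2).sum()))
    return MetropolisResult(
        T=float(T), mean_U=float(u.mean()), sem_U=blocked_sem(u),
        CV=cv, sem_CV=sem_cv,
        mean_rg2=float(r.mean()), sem_rg2=blocked_sem(r),
        u_series=u_series)


# ---------------------------------------------------------------------------
# analytic limits


def analytic_limits_suite(tol_exact: float = 1e-10, tol_closed: float = 1e-6) -> dict:
    """Machine-checkable closed-form limits of the analysis machinery.

    1. ideal gas: a delta-function g(U) at U0 convolved with d kinetic degrees
       of freedom gives ln g(E) = (d/2-1) ln(E-U0) exactly on the grid, hence
       T(E) = 2 (E-U0) / (d-2);
    2. Schottky: the two-level heat capacity from the fluctuation formula
       matches (D/T)^2 e^(D/T) / (1+e^(D/T))^2;
    3. linear entropy: S_B = a U + b gives a constant T^-1 = a.
    """
    from .canonical import heat_capacity
    from .microcanonical import DoS1D, convolve_kinetic, inverse_temperature_U
    from .model import make_model
    from .samc import DoSGrid

    report: dict[str, dict] = {}

    # 1 -- ideal-gas caloric curve
    d = 6
    u0 = 0.0
    delta = DoS1D(U=np.array([u0 - 0.5, u0, u0 + 0.5]),
                  log_g=np.array([-np.inf, 0.0, -np.inf]),
                  bin_width=0.5)
    E = np.linspace(u0 + 0.5, u0 + 12.0, 200)
    gE = convolve_kinetic(delta, d, E_grid=E)
    expected = (0.5 * d - 1.0) * np.log(gE.U - u0)
    expected -= expected.max()
    err1 = float(np.abs(gE.log_g - expected).max())
    report["ideal_gas"] = {
        "max_abs_err_log_g": err1, "ok": bool(err1 <= tol_exact),
        "relation": "T = 2 (E - U0) / (d - 2)"}

    # 2 -- Schottky anomaly
    model = make_model("non-selective", N=4, b=2)
    dlt = 1.0
    two_level = DoSGrid(env_raw=np.array([0, -1]), nst=np.array([0, 0]),
                        log_g=np.zeros(2), visits=np.ones(2, dtype=np.int64),
                        fingerprint=model.fingerprint())
    T_grid = np.linspace(0.1, 3.0, 60)
    errs = []
    for T in T_grid:
        cv = heat_capacity(two_level, model, T, eps_st=0.0).CV
        x = dlt / T
        closed = x**2 * math.exp(x) / (1.0 + math.exp(x))**2
        errs.append(abs(cv - closed))
    err2 = float(max(errs))
    report["schottky"] = {"max_abs_err_CV": err2, "ok": bool(err2 <= tol_closed)}

    # 3 -- linear entropy
    a = 0.7
    U = np.linspace(-10.0, 0.0, 101)
    lin = DoS1D(U=U, log_g=a * U + 2.0, bin_width=float(U[1] - U[0]))
    curve = inverse_temperature_U(lin)
    err3 = float(np.abs(curve.inv_T - a).max())
    report["linear_entropy"] = {"max_abs_err_invT": err3,
                                "ok": bool(err3 <= tol_exact)}

    report["all_ok"] = all(v["ok"] for v in report.values() if isinstance(v, dict))
    return report
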