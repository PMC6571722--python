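"""Numba inner loop for the flat-histogram sampler.

One Monte Carlo step (MCS) is 2N local-displacement trials plus one
end-cut-and-regrow trial.  Contact bookkeeping is incremental for local moves
(only pairs and angles touching the displaced bead change) and a full recount
for regrow trials.  The log-density-of-states table is dense over
(row = -Env_raw, nst); unregistered cells hold +inf.

The random stream is a splitmix64 counter generator whose single uint64 word
of state is carried in an array, so a run can be checkpointed and resumed
bit-identically.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_C1 = np.uint64(0x9E3779B97F4A7C15)
_C2 = np.uint64(0xBF58476D1CE4E5B9)
_C3 = np.uint64(0x94D049BB133111EB)
_S30 = np.uint64(30)
_S27 = np.uint64(27)
_S31 = np.uint64(31)
_S11 = np.uint64(11)
_INV53 = 1.0 / 9007199254740992.0
_UNSET = 1e300  # log_g sentinel for unregistered macrostates

N_OBS = 22
OBS_COLUMNS = (
    "rg2_all", "rg2_S", "rg2_F",
    "lam1_all", "lam2_all", "lam3_all",
    "lam1_S", "lam2_S", "lam3_S",
    "lam1_F", "lam2_F", "lam3_F",
    "s_nem", "ext_S", "min_r_S_centroid", "r_mean_S", "r_mean_F",
    "n_sharp_folds", "nss", "nsf", "nff", "nst",
)


@njit(cache=True, inline="always")
def _next_u64(st):
    st[0] = st[0] + _C1
    z = st[0]
    z = (z ^ (z >> _S30)) * _C2
    z = (z ^ (z >> _S27)) * _C3
    return z ^ (z >> _S31)


@njit(cache=True, inline="always")
def _uniform(st):
    return float(_next_u64(st) >> _S11) * _INV53


def seed_state(seed: int, stream: int = 0) -> np.ndarray:
    """Initial RNG state word for (seed, stream); burns a few outputs."""
    word = (int(seed) * 0x2545F4914F6CDD1D
            + int(stream) * 0x94D049BB133111EB + 0x9E3779B97F4A7C15) % 2**64
    st = np.array([word], dtype=np.uint64)
    for _ in range(4):
        _next_u64(st)
    return st


@njit(cache=True, inline="always")
def _dist2(x, i, j):
    dx = x[i, 0] - x[j, 0]
    dy = x[i, 1] - x[j, 1]
    dz = x[i, 2] - x[j, 2]
    return dx * dx + dy * dy + dz * dz


@njit(cache=True, inline="always")
def _cos_interior(x, j):
    """cos of the interior valence angle at center j (=-1 never; 180deg -> cos=-(-1)=1? no).

    Convention: theta = 180 deg for collinear bonds, i.e.
    cos(theta) = -(a . c)/(|a||c|) with a = x[j]-x[j-1], c = x[j+1]-x[j].
    """
    ax = x[j, 0] - x[j - 1, 0]
    ay = x[j, 1] - x[j - 1, 1]
    az = x[j, 2] - x[j - 1, 2]
    cx = x[j + 1, 0] - x[j, 0]
    cy = x[j + 1, 1] - x[j, 1]
    cz = x[j + 1, 2] - x[j, 2]
    dot = ax * cx + ay * cy + az * cz
    return -dot / np.sqrt((ax * ax + ay * ay + az * az) * (cx * cx + cy * cy + cz * cz))


@njit(cache=True)
def count_full(x, types, elig, r_cut2, sigma2, cos_lo, cos_hi, phantom):
    """Full O(N^2) contact/angle count.  Returns (nss, nsf, nff, nst, valid).

    valid is the hard-sphere check over non-bonded pairs (always True for a
    phantom chain); bond lengths are assumed maintained by the move set.
    """
    N = x.shape[0]
    nss = 0
    nsf = 0
    nff = 0
    valid = True
    if not phantom:
        for i in range(N):
            for j in range(i + 2, N):
                r2 = _dist2(x, i, j)
                if r2 < sigma2:
                    valid = False
                if r2 <= r_cut2:
                    tt = types[i] + types[j]
                    if tt == 0:
                        nss += 1
                    elif tt == 2:
                        nff += 1
                    else:
                        nsf += 1
    nst = 0
    for j in range(1, N - 1):
        if elig[j] == 1:
            c = _cos_interior(x, j)
            if cos_lo <= c <= cos_hi:
                nst += 1
    return nss, nsf, nff, nst, valid


@njit(cache=True, inline="always")
def _shell_vector(st, l_min3, l_range3):
    r = (l_min3 + _uniform(st) * l_range3) ** (1.0 / 3.0)
    while True:
        a = 2.0 * _uniform(st) - 1.0
        b = 2.0 * _uniform(st) - 1.0
        s = a * a + b * b
        if s < 1.0:
            break
    f = 2.0 * np.sqrt(1.0 - s)
    return r * a * f, r * b * f, r * (1.0 - 2.0 * s)


@njit(cache=True)
def _scan_min(log_g):
    m = _UNSET
    for r in range(log_g.shape[0]):
        for c in range(log_g.shape[1]):
            v = log_g[r, c]
            if v < m:
                m = v
    if m >= _UNSET:
        m = 0.0
    return m


@njit(cache=True)
def _eig3_desc(t):
    w = np.linalg.eigvalsh(t)
    return w[2], w[1], w[0]


@njit(cache=True)
def compute_observables(x, types, elig, cos_lo, cos_hi,
                        nss, nsf, nff, nst, out):
    """Morphology observable vector for one conformation (see OBS_COLUMNS)."""
    N = x.shape[0]
    # centroids
    com = np.zeros(3)
    com_s = np.zeros(3)
    com_f = np.zeros(3)
    n_s = 0
    n_f = 0
    for i in range(N):
        for a in range(3):
            com[a] += x[i, a]
        if types[i] == 0:
            n_s += 1
            for a in range(3):
                com_s[a] += x[i, a]
        else:
            n_f += 1
            for a in range(3):
                com_f[a] += x[i, a]
    for a in range(3):
        com[a] /= N
        if n_s > 0:
            com_s[a] /= n_s
        if n_f > 0:
            com_f[a] /= n_f

    t_all = np.zeros((3, 3))
    t_s = np.zeros((3, 3))
    t_f = np.zeros((3, 3))
    r_mean_s = 0.0
    r_mean_f = 0.0
    min_r_s = 1e30
    for i in range(N):
        d = np.empty(3)
        for a in range(3):
            d[a] = x[i, a] - com[a]
        r_mean = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        for a in range(3):
            for bb in range(3):
                t_all[a, bb] += d[a] * d[bb]
        if types[i] == 0:
            r_mean_s += r_mean
            ds0 = x[i, 0] - com_s[0]
            ds1 = x[i, 1] - com_s[1]
            ds2 = x[i, 2] - com_s[2]
            rs = np.sqrt(ds0 * ds0 + ds1 * ds1 + ds2 * ds2)
            if rs < min_r_s:
                min_r_s = rs
            for a in range(3):
                for bb in range(3):
                    t_s[a, bb] += (x[i, a] - com_s[a]) * (x[i, bb] - com_s[bb])
        else:
            r_mean_f += r_mean
            for a in range(3):
                for bb in range(3):
                    t_f[a, bb] += (x[i, a] - com_f[a]) * (x[i, bb] - com_f[bb])
    for a in range(3):
        for bb in range(3):
            t_all[a, bb] /= N
            if n_s > 0:
                t_s[a, bb] /= n_s
            if n_f > 0:
                t_f[a, bb] /= n_f
    if n_s > 0:
        r_mean_s /= n_s
    if n_f > 0:
        r_mean_f /= n_f

    l1a, l2a, l3a = _eig3_desc(t_all)
    l1s, l2s, l3s = _eig3_desc(t_s) if n_s > 0 else (0.0, 0.0, 0.0)
    l1f, l2f, l3f = _eig3_desc(t_f) if n_f > 0 else (0.0, 0.0, 0.0)

    # nematic order of bonds internal to S blocks
    q = np.zeros((3, 3))
    nb = 0
    for i in range(N - 1):
        if types[i] == 0 and types[i + 1] == 0:
            ux = x[i + 1, 0] - x[i, 0]
            uy = x[i + 1, 1] - x[i, 1]
            uz = x[i + 1, 2] - x[i, 2]
            norm = np.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm
            q[0, 0] += 1.5 * ux * ux - 0.5
            q[0, 1] += 1.5 * ux * uy
            q[0, 2] += 1.5 * ux * uz
            q[1, 1] += 1.5 * uy * uy - 0.5
            q[1, 2] += 1.5 * uy * uz
            q[2, 2] += 1.5 * uz * uz - 0.5
            nb += 1
    s_nem = 0.0
    if nb > 0:
        q[1, 0] = q[0, 1]
        q[2, 0] = q[0, 2]
        q[2, 1] = q[1, 2]
        for a in range(3):
            for bb in range(3):
                q[a, bb] /= nb
        e1, _, _ = _eig3_desc(q)
        s_nem = e1

    # mean per-S-block end-to-end extension relative to contour length
    ext_sum = 0.0
    n_blocks = 0
    i = 0
    while i < N:
        if types[i] == 0:
            j = i
            while j + 1 < N and types[j + 1] == 0:
                j += 1
            if j > i:
                contour = 0.0
                for m in range(i, j):
                    contour += np.sqrt(_dist2(x, m, m + 1))
                e2e = np.sqrt(_dist2(x, i, j))
                ext_sum += e2e / contour
                n_blocks += 1
            i = j + 1
        else:
            i += 1
    ext_s = ext_sum / n_blocks if n_blocks > 0 else 0.0

    n_folds = 0
    for j in range(1, N - 1):
        if elig[j] == 1 and _cos_interior(x, j) < 0.0:
            n_folds += 1

    out[0] = t_all[0, 0] + t_all[1, 1] + t_all[2, 2]
    out[1] = t_s[0, 0] + t_s[1, 1] + t_s[2, 2]
    out[2] = t_f[0, 0] + t_f[1, 1] + t_f[2, 2]
    out[3] = l1a
    out[4] = l2a
    out[5] = l3a
    out[6] = l1s
    out[7] = l2s
    out[8] = l3s
    out[9] = l1f
    out[10] = l2f
    out[11] = l3f
    out[12] = s_nem
    out[13] = ext_s
    out[14] = min_r_s if n_s > 0 else 0.0
    out[15] = r_mean_s
    out[16] = r_mean_f
    out[17] = float(n_folds)
    out[18] = float(nss)
    out[19] = float(nsf)
    out[20] = float(nff)
    out[21] = float(nst)


@njit(cache=True)
def run_kernel(coords, types, elig, n_mcs, mode,
               gamma0, t0, t_offset,
               log_g, visits, obs_sum, obs_cnt,
               eps_ss, eps_sf, eps_ff,
               l_min, l_max, r_cut, sigma,
               cos_lo, cos_hi, phantom,
               disp, k_max, rng_state, stats):
    """Advance the chain by n_mcs sweeps.

    mode 0: SAMC -- after every trial the resulting macrostate's log_g is
            incremented by the current gain and its visit count by one.
    mode 1: production -- log_g frozen; per-MCS observables accumulated into
            obs_sum/obs_cnt at the current macrostate.

    All tables are modified in place; stats collects
    [local attempts, local accepts, regrow attempts, regrow accepts].
    """
    N = coords.shape[0]
    if k_max > N - 1:      # a full-chain regrow would detach the anchor
        k_max = N - 1
    sigma2 = sigma * sigma
    r_cut2 = r_cut * r_cut
    l_min2 = l_min * l_min
    l_max2 = l_max * l_max
    l_min3 = l_min ** 3
    l_range3 = l_max ** 3 - l_min3

    nss, nsf, nff, nst, ok = count_full(
        coords, types, elig, r_cut2, sigma2, cos_lo, cos_hi, phantom)
    if not ok:
        return -1  # corrupted input conformation
    row = -(eps_ss * nss + eps_sf * nsf + eps_ff * nff)

    cur_min = _scan_min(log_g)
    if log_g[row, nst] >= _UNSET:
        log_g[row, nst] = cur_min

    buf = coords.copy()
    obs = np.empty(N_OBS)

    for t in range(1, n_mcs + 1):
        tt_global = t_offset + t
        if tt_global <= t0:
            gamma = gamma0
        else:
            gamma = gamma0 * t0 / tt_global

        for trial in range(2 * N + 1):
            if trial < 2 * N:
                # ---- local displacement ----
                stats[0] += 1
                i = int(_uniform(rng_state) * N)
                if i == N:
                    i = N - 1
                ox = coords[i, 0]
                oy = coords[i, 1]
                oz = coords[i, 2]
                nx = ox + disp * (2.0 * _uniform(rng_state) - 1.0)
                ny = oy + disp * (2.0 * _uniform(rng_state) - 1.0)
                nz = oz + disp * (2.0 * _uniform(rng_state) - 1.0)

                valid = True
                # bond-length windows
                if i > 0:
                    dx = nx - coords[i - 1, 0]
                    dy = ny - coords[i - 1, 1]
                    dz = nz - coords[i - 1, 2]
                    l2 = dx * dx + dy * dy + dz * dz
                    if l2 < l_min2 or l2 > l_max2:
                        valid = False
                if valid and i < N - 1:
                    dx = nx - coords[i + 1, 0]
                    dy = ny - coords[i + 1, 1]
                    dz = nz - coords[i + 1, 2]
                    l2 = dx * dx + dy * dy + dz * dz
                    if l2 < l_min2 or l2 > l_max2:
                        valid = False

                d_ss = 0
                d_sf = 0
                d_ff = 0
                if valid and not phantom:
                    for j in range(N):
                        if j == i or j == i - 1 or j == i + 1:
                            continue
                        dxn = nx - coords[j, 0]
                        dyn = ny - coords[j, 1]
                        dzn = nz - coords[j, 2]
                        r2n = dxn * dxn + dyn * dyn + dzn * dzn
                        if r2n < sigma2:
                            valid = False
                            break
                        dxo = ox - coords[j, 0]
                        dyo = oy - coords[j, 1]
                        dzo = oz - coords[j, 2]
                        r2o = dxo * dxo + dyo * dyo + dzo * dzo
                        co = r2o <= r_cut2
                        cn = r2n <= r_cut2
                        if co != cn:
                            inc = 1 if cn else -1
                            tsum = types[i] + types[j]
                            if tsum == 0:
                                d_ss += inc
                            elif tsum == 2:
                                d_ff += inc
                            else:
                                d_sf += inc

                d_st = 0
                if valid:
                    jlo = i - 1 if i - 1 >= 1 else 1
                    jhi = i + 1 if i + 1 <= N - 2 else N - 2
                    for j in range(jlo, jhi + 1):
                        if elig[j] == 1:
                            c = _cos_interior(coords, j)
                            if cos_lo <= c <= cos_hi:
                                d_st -= 1
                    coords[i, 0] = nx
                    coords[i, 1] = ny
                    coords[i, 2] = nz
                    for j in range(jlo, jhi + 1):
                        if elig[j] == 1:
                            c = _cos_interior(coords, j)
                            if cos_lo <= c <= cos_hi:
                                d_st += 1
                    coords[i, 0] = ox
                    coords[i, 1] = oy
                    coords[i, 2] = oz

                if valid:
                    row_new = row - (eps_ss * d_ss + eps_sf * d_sf + eps_ff * d_ff)
                    nst_new = nst + d_st
                    lg_old = log_g[row, nst]
                    lg_new = log_g[row_new, nst_new]
                    if lg_new >= _UNSET:
                        lg_new = cur_min
                    accept = False
                    if lg_new <= lg_old:
                        accept = True
                    elif _uniform(rng_state) < np.exp(lg_old - lg_new):
                        accept = True
                    if accept:
                        coords[i, 0] = nx
                        coords[i, 1] = ny
                        coords[i, 2] = nz
                        nss += d_ss
                        nsf += d_sf
                        nff += d_ff
                        nst = nst_new
                        row = row_new
                        stats[1] += 1
            else:
                # ---- end-cut-and-regrow ----
                stats[2] += 1
                k = 1 + int(_uniform(rng_state) * k_max)
                if k > k_max:
                    k = k_max
                end = 1 if _uniform(rng_state) < 0.5 else 0
                for m in range(N):
                    buf[m, 0] = coords[m, 0]
                    buf[m, 1] = coords[m, 1]
                    buf[m, 2] = coords[m, 2]
                if end == 0:
                    for m in range(k - 1, -1, -1):
                        vx, vy, vz = _shell_vector(rng_state, l_min3, l_range3)
                        buf[m, 0] = buf[m + 1, 0] + vx
                        buf[m, 1] = buf[m + 1, 1] + vy
                        buf[m, 2] = buf[m + 1, 2] + vz
                else:
                    for m in range(N - k, N):
                        vx, vy, vz = _shell_vector(rng_state, l_min3, l_range3)
                        buf[m, 0] = buf[m - 1, 0] + vx
                        buf[m, 1] = buf[m - 1, 1] + vy
                        buf[m, 2] = buf[m - 1, 2] + vz
                nss2, nsf2, nff2, nst2, valid = count_full(
                    buf, types, elig, r_cut2, sigma2, cos_lo, cos_hi, phantom)
                if valid:
                    row_new = -(eps_ss * nss2 + eps_sf * nsf2 + eps_ff * nff2)
                    lg_old = log_g[row, nst]
                    lg_new = log_g[row_new, nst2]
                    if lg_new >= _UNSET:
                        lg_new = cur_min
                    accept = False
                    if lg_new <= lg_old:
                        accept = True
                    elif _uniform(rng_state) < np.exp(lg_old - lg_new):
                        accept = True
                    if accept:
                        for m in range(N):
                            coords[m, 0] = buf[m, 0]
                            coords[m, 1] = buf[m, 1]
                            coords[m, 2] = buf[m, 2]
                        nss = nss2
                        nsf = nsf2
                        nff = nff2
                        nst = nst2
                        row = row_new
                        stats[3] += 1

            # ---- per-trial flat-histogram update of the resulting state ----
            if mode == 0:
                lg = log_g[row, nst]
                if lg >= _UNSET:
                    lg = cur_min
                was_min = lg <= cur_min
                log_g[row, nst] = lg + gamma
                visits[row, nst] += 1
                if was_min:
                    cur_min = _scan_min(log_g)
            else:
                visits[row, nst] += 1

        if mode == 1:
            compute_observables(coords, types, elig, cos_lo, cos_hi,
                                nss, nsf, nff, nst, obs)
            for c in range(N_OBS):
                obs_sum[row, nst, c] += obs[c]
            obs_cnt[row, nst] += 1

    return 0
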