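"""Stochastic Approximation Monte Carlo accumulation of the 2D density of states.

The sampler walks the chain through conformation space with 2N local
displacements plus one end-regrow trial per Monte Carlo step (MCS), accepting
a trial with probability min(1, g_old/g_new) and, after every trial, raising
the log-density-of-states of the resulting macrostate (Env_raw, nst) by the
current gain gamma_t = gamma0 * min(1, t0/t).  As the gain decays the visit
histogram over macrostates flattens and log g converges to the relative
conformational entropy of each macrostate.

Macrostates are labelled by the *integer* raw contact energy Env_raw and the
stiff-angle count nst, so binning is exact; physical energies are recovered at
analysis time as U = raw_scale * Env_raw + eps_st * nst.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from ._kernel import N_OBS, OBS_COLUMNS, seed_state
from .model import Conformation, ModelParams, initial_conformation

__all__ = [
    "MacrostateKey", "GainSchedule", "DoSGrid", "ObservableTable",
    "SamplerState", "SamcResult", "StageDiagnostics",
    "DEFAULT_SCHEDULES", "gain", "samc_accept", "samc_update",
    "run_samc", "refine", "average_dos", "production_run", "merge_observables",
    "save_checkpoint", "load_checkpoint",
]

_UNSET = _kernel._UNSET


@dataclass(frozen=True, order=True)
class MacrostateKey:
    env_raw: int
    nst: int


@dataclass(frozen=True)
class GainSchedule:
    """Decaying gain gamma_t = gamma0 * min(1, t0/t), t counted in MCS."""

    gamma0: float
    t0: int

    def __post_init__(self):
        if self.gamma0 <= 0:
            raise ValueError("gamma0 must be positive")
        if self.t0 < 1:
            raise ValueError("t0 must be >= 1")


#: Two-stage refinement used throughout: a coarse pass with unit gain and a
#: fine pass with gamma0 = 0.01, t0 = 1e4 MCS.
DEFAULT_SCHEDULES = (GainSchedule(1.0, 1_000), GainSchedule(0.01, 10_000))


def gain(t: int, schedule: GainSchedule) -> float:
    """Gain factor at MCS index t (1-based)."""
    if t < 1:
        raise ValueError("t must be >= 1 (MCS index)")
    return schedule.gamma0 * min(1.0, schedule.t0 / t)


def samc_accept(log_g_old: float, log_g_new: float, rng: np.random.Generator) -> bool:
    """Flat-histogram acceptance: accept with prob min(1, g_old/g_new)."""
    if log_g_new <= log_g_old:
        return True
    return rng.random() < np.exp(log_g_old - log_g_new)


@dataclass
class DoSGrid:
    """Sparse log-density-of-states over macrostates plus visit histogram."""

    env_raw: np.ndarray  # (K,) int64, <= 0
    nst: np.ndarray      # (K,) int64
    log_g: np.ndarray    # (K,) float64, relative (max anchored to 0)
    visits: np.ndarray   # (K,) int64
    fingerprint: str = ""
    n_mcs: int = 0
    std_log_g: np.ndarray | None = None  # populated by average_dos

    def __post_init__(self):
        self.env_raw = np.asarray(self.env_raw, dtype=np.int64)
        self.nst = np.asarray(self.nst, dtype=np.int64)
        self.log_g = np.asarray(self.log_g, dtype=np.float64)
        self.visits = np.asarray(self.visits, dtype=np.int64)

    @property
    def n_keys(self) -> int:
        return self.env_raw.size

    def keys(self) -> list[MacrostateKey]:
        return [MacrostateKey(int(e), int(n)) for e, n in zip(self.env_raw, self.nst)]

    def index_of(self, key: MacrostateKey) -> int:
        hit = np.where((self.env_raw == key.env_raw) & (self.nst == key.nst))[0]
        if hit.size == 0:
            raise KeyError(key)
        return int(hit[0])

    def anchored(self) -> "DoSGrid":
        """Shift log_g so its maximum is 0 (the gauge used on disk)."""
        lg = self.log_g - (self.log_g.max() if self.n_keys else 0.0)
        return replace(self, log_g=lg)

    def energies(self, model: ModelParams, eps_st: float | None = None) -> np.ndarray:
        """Physical U per key at the given stiffness (defaults to the model's)."""
        e = model.eps_st if eps_st is None else eps_st
        return model.raw_scale * self.env_raw.astype(float) + e * self.nst.astype(float)

    # dense <-> sparse -----------------------------------------------------
    def to_dense(self, model: ModelParams) -> tuple[np.ndarray, np.ndarray]:
        n_rows, n_nst = model.n_env_rows, model.nst_max + 1
        lg = np.full((n_rows, n_nst), _UNSET)
        vis = np.zeros((n_rows, n_nst), dtype=np.int64)
        rows = -self.env_raw
        if rows.size and (rows.max() >= n_rows or self.nst.max() >= n_nst):
            raise ValueError("DoS keys outside the model's macrostate bounds")
        lg[rows, self.nst] = self.log_g
        vis[rows, self.nst] = self.visits
        return lg, vis

    @classmethod
    def from_dense(cls, model: ModelParams, log_g: np.ndarray, visits: np.ndarray,
                   n_mcs: int = 0) -> "DoSGrid":
        rows, cols = np.where(log_g < _UNSET)
        order = np.lexsort((cols, rows))
        rows, cols = rows[order], cols[order]
        lg = log_g[rows, cols]
        lg = lg - (lg.max() if lg.size else 0.0)
        return cls(env_raw=-rows.astype(np.int64), nst=cols.astype(np.int64),
                   log_g=lg, visits=visits[rows, cols],
                   fingerprint=model.fingerprint(), n_mcs=n_mcs)


def samc_update(dos: DoSGrid, current: MacrostateKey, gamma_t: float) -> DoSGrid:
    """Apply one flat-histogram update: log_g[current] += gamma_t, visit += 1.

    The key is registered (at the current minimum of log_g) if unseen.
    Mutates and returns ``dos``.
    """
    try:
        i = dos.index_of(current)
    except KeyError:
        base = dos.log_g.min() if dos.n_keys else 0.0
        dos.env_raw = np.append(dos.env_raw, current.env_raw)
        dos.nst = np.append(dos.nst, current.nst)
        dos.log_g = np.append(dos.log_g, base)
        dos.visits = np.append(dos.visits, 0)
        i = dos.n_keys - 1
    dos.log_g[i] += gamma_t
    dos.visits[i] += 1
    return dos


# ---------------------------------------------------------------------------
# sampler state and drivers


@dataclass
class SamplerState:
    """Complete, serializable state of a (possibly interrupted) run."""

    coords: np.ndarray
    rng_state: np.ndarray       # (1,) uint64
    t_done: int                 # completed MCS
    log_g: np.ndarray           # dense (n_rows, n_nst)
    visits: np.ndarray
    obs_sum: np.ndarray
    obs_cnt: np.ndarray
    fingerprint: str
    stats: np.ndarray           # [local att, local acc, regrow att, regrow acc]
    seed: int = 0
    stream: int = 0


@dataclass
class SamcResult:
    dos: DoSGrid
    conformation: Conformation
    state: SamplerState

    def __iter__(self):  # allow dos, conf = run_samc(...)
        return iter((self.dos, self.conformation))


def _fresh_state(model: ModelParams, seed: int, stream: int,
                 initial: DoSGrid | None, with_obs: bool,
                 conf: Conformation | None = None) -> SamplerState:
    n_rows, n_nst = model.n_env_rows, model.nst_max + 1
    if initial is not None:
        if initial.fingerprint and initial.fingerprint != model.fingerprint():
            raise ValueError("initial DoS fingerprint does not match the model")
        lg, _ = initial.to_dense(model)
        vis = np.zeros((n_rows, n_nst), dtype=np.int64)
    else:
        lg = np.full((n_rows, n_nst), _UNSET)
        vis = np.zeros((n_rows, n_nst), dtype=np.int64)
    if with_obs:
        obs_sum = np.zeros((n_rows, n_nst, N_OBS))
        obs_cnt = np.zeros((n_rows, n_nst), dtype=np.int64)
    else:
        obs_sum = np.zeros((1, 1, 1))
        obs_cnt = np.zeros((1, 1), dtype=np.int64)
    if conf is None:
        conf = initial_conformation(model, seed=seed)
    return SamplerState(
        coords=conf.coords.copy(), rng_state=seed_state(seed, stream),
        t_done=0, log_g=lg, visits=vis, obs_sum=obs_sum, obs_cnt=obs_cnt,
        fingerprint=model.fingerprint(), stats=np.zeros(4, dtype=np.int64),
        seed=seed, stream=stream)


def _advance(state: SamplerState, model: ModelParams, schedule: GainSchedule,
             n_mcs: int, mode: int, k_max: int | None, displacement: float) -> None:
    cos_lo, cos_hi = model.cos_window
    eps = model.eps_raw
    rc = _kernel.run_kernel(
        state.coords, model.types, model.angle_eligible,
        int(n_mcs), int(mode),
        float(schedule.gamma0), float(schedule.t0), int(state.t_done),
        state.log_g, state.visits, state.obs_sum, state.obs_cnt,
        int(eps[0]), int(eps[1]), int(eps[2]),
        model.l_min, model.l_max, model.R_cut, model.sigma,
        cos_lo, cos_hi, model.phantom,
        float(displacement), int(model.b if k_max is None else k_max),
        state.rng_state, state.stats)
    if rc != 0:
        raise RuntimeError("sampler detected a corrupted (invalid) conformation")
    state.t_done += int(n_mcs)


def run_samc(model: ModelParams, schedule: GainSchedule, n_mcs: int,
             seed: int | None = None, initial: DoSGrid | None = None,
             state: SamplerState | None = None, stream: int = 0,
             k_max: int | None = None, displacement: float = 0.05) -> SamcResult:
    """Accumulate the 2D DoS for n_mcs sweeps.

    Fully reproducible: the result is a pure function of
    (model, schedule, n_mcs, seed[, initial]).  Pass ``state`` (from a
    checkpoint) instead of ``seed`` to resume a run bit-identically.
    """
    if state is None:
        if seed is None:
            raise ValueError("either seed or state is required")
        state = _fresh_state(model, seed, stream, initial, with_obs=False)
    elif state.fingerprint != model.fingerprint():
        raise ValueError("sampler state fingerprint does not match the model")
    if n_mcs > 0:
        _advance(state, model, schedule, n_mcs, mode=0,
                 k_max=k_max, displacement=displacement)
    dos = DoSGrid.from_dense(model, state.log_g, state.visits, n_mcs=state.t_done)
    return SamcResult(dos=dos, conformation=Conformation(state.coords.copy()),
                      state=state)


@dataclass
class StageDiagnostics:
    schedule: GainSchedule
    n_mcs: int
    n_keys: int
    flatness: float          # min/mean visit count over visited keys
    max_increment: float     # largest single-trial gain during the stage
    acceptance_local: float
    acceptance_regrow: float


@dataclass
class RefineResult:
    dos: DoSGrid
    conformation: Conformation
    state: SamplerState
    diagnostics: list[StageDiagnostics]

    def __iter__(self):
        return iter((self.dos, self.conformation))


def refine(model: ModelParams, schedules=DEFAULT_SCHEDULES,
           n_mcs=(200_000, 800_000), seed: int = 0, stream: int = 0,
           initial: DoSGrid | None = None, k_max: int | None = None,
           displacement: float = 0.05) -> RefineResult:
    """Chain SAMC stages, each seeded from the previous DoS estimate.

    The default two-stage schedule is (gamma0=1, t0=1e3) followed by
    (gamma0=0.01, t0=1e4).  Visit histograms restart per stage; the gain index
    t also restarts per stage so each stage's plateau applies from its start.
    """
    schedules = list(schedules)
    n_list = [int(n_mcs)] * len(schedules) if np.isscalar(n_mcs) else list(n_mcs)
    if len(n_list) != len(schedules):
        raise ValueError("need one MCS count per stage")
    if not schedules:
        raise ValueError("at least one stage is required")
    diags: list[StageDiagnostics] = []
    state = _fresh_state(model, seed, stream, initial, with_obs=False)
    res = None
    for stage, (sch, n) in enumerate(zip(schedules, n_list)):
        state.t_done = 0
        state.visits[:] = 0
        s0 = state.stats.copy()
        res = run_samc(model, sch, n, state=state)
        vis = state.visits[state.visits > 0]
        ds = state.stats - s0
        diags.append(StageDiagnostics(
            schedule=sch, n_mcs=n, n_keys=int(vis.size),
            flatness=float(vis.min() / vis.mean()) if vis.size else 0.0,
            max_increment=gain(1, sch),
            acceptance_local=float(ds[1] / max(ds[0], 1)),
            acceptance_regrow=float(ds[3] / max(ds[2], 1))))
    return RefineResult(dos=res.dos, conformation=res.conformation,
                        state=state, diagnostics=diags)


def average_dos(runs: list[DoSGrid], quorum: int = 2) -> DoSGrid:
    """Arithmetic per-key mean of anchored log_g over independent runs.

    Keys visited in fewer than ``quorum`` runs are dropped.  The per-key
    standard deviation across runs is returned in ``std_log_g`` as a
    convergence diagnostic.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs to average")
    fp = runs[0].fingerprint
    for r in runs[1:]:
        if r.fingerprint != fp:
            raise ValueError("model fingerprints differ between runs")
    quorum = min(quorum, len(runs))
    acc: dict[tuple[int, int], list[float]] = {}
    vis: dict[tuple[int, int], int] = {}
    for r in runs:
        a = r.anchored()
        for e, n, lg, v in zip(a.env_raw, a.nst, a.log_g, a.visits):
            k = (int(e), int(n))
            acc.setdefault(k, []).append(float(lg))
            vis[k] = vis.get(k, 0) + int(v)
    keys = sorted(k for k, vals in acc.items() if len(vals) >= quorum)
    env = np.array([k[0] for k in keys], dtype=np.int64)
    nst = np.array([k[1] for k in keys], dtype=np.int64)
    lg = np.array([np.mean(acc[k]) for k in keys])
    sd = np.array([np.std(acc[k], ddof=1) if len(acc[k]) > 1 else 0.0 for k in keys])
    out = DoSGrid(env_raw=env, nst=nst, log_g=lg,
                  visits=np.array([vis[k] for k in keys], dtype=np.int64),
                  fingerprint=fp, n_mcs=sum(r.n_mcs for r in runs))
    out = out.anchored()
    out.std_log_g = sd
    return out


@dataclass
class ObservableTable:
    """Per-macrostate running means of the registered observables."""

    env_raw: np.ndarray
    nst: np.ndarray
    count: np.ndarray
    means: np.ndarray            # (K, n_obs)
    columns: tuple = OBS_COLUMNS
    fingerprint: str = ""
    sample_floor: int = 1_000

    @property
    def n_keys(self) -> int:
        return self.env_raw.size

    def column(self, name: str) -> np.ndarray:
        return self.means[:, self.columns.index(name)]

    def low_count_keys(self) -> list[MacrostateKey]:
        """Macrostates sampled fewer than sample_floor times."""
        idx = np.where(self.count < self.sample_floor)[0]
        return [MacrostateKey(int(self.env_raw[i]), int(self.nst[i])) for i in idx]


def merge_observables(tables: list[ObservableTable]) -> ObservableTable:
    """Pool production tables (counts summed, means count-weighted).

    Used to combine production runs started from different conformations, so
    macrostate coverage does not depend on a single walk crossing every
    barrier of an imperfect DoS.
    """
    if not tables:
        raise ValueError("need at least one table")
    fp = tables[0].fingerprint
    cols = tables[0].columns
    for t in tables[1:]:
        if t.fingerprint != fp:
            raise ValueError("model fingerprints differ between tables")
        if t.columns != cols:
            raise ValueError("observable columns differ between tables")
    acc: dict[tuple[int, int], tuple[int, np.ndarray]] = {}
    for t in tables:
        for i in range(t.n_keys):
            k = (int(t.env_raw[i]), int(t.nst[i]))
            c = int(t.count[i])
            if k in acc:
                c0, s0 = acc[k]
                acc[k] = (c0 + c, s0 + c * t.means[i])
            else:
                acc[k] = (c, c * t.means[i].copy())
    keys = sorted(acc)
    cnt = np.array([acc[k][0] for k in keys], dtype=np.int64)
    means = np.vstack([acc[k][1] / acc[k][0] for k in keys])
    return ObservableTable(
        env_raw=np.array([k[0] for k in keys], dtype=np.int64),
        nst=np.array([k[1] for k in keys], dtype=np.int64),
        count=cnt, means=means, columns=cols, fingerprint=fp,
        sample_floor=tables[0].sample_floor)


def production_run(model: ModelParams, dos: DoSGrid, n_mcs: int, seed: int,
                   sample_floor: int = 1_000, stream: int = 1,
                   k_max: int | None = None, displacement: float = 0.05,
                   start: Conformation | None = None) -> ObservableTable:
    """Sample with the frozen DoS and accumulate per-macrostate observables.

    Acceptance still uses min(1, g_old/g_new) so visits stay (asymptotically)
    flat over macrostates, but log g is no longer updated.  One observable
    vector is accumulated per MCS at the current macrostate.  ``start`` sets
    the initial conformation (e.g. the final state of a sampling run, so the
    walk begins on the compact side of any residual free-energy barrier of an
    imperfect DoS); by default a near-straight coil is used.
    """
    state = _fresh_state(model, seed, stream, dos, with_obs=True, conf=start)
    _advance(state, model, GainSchedule(1.0, 1), n_mcs, mode=1,
             k_max=k_max, displacement=displacement)
    rows, cols = np.where(state.obs_cnt > 0)
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    cnt = state.obs_cnt[rows, cols]
    means = state.obs_sum[rows, cols, :] / cnt[:, None]
    return ObservableTable(env_raw=-rows.astype(np.int64), nst=cols.astype(np.int64),
                           count=cnt, means=means, columns=OBS_COLUMNS,
                           fingerprint=model.fingerprint(),
                           sample_floor=sample_floor)


# ---------------------------------------------------------------------------
# checkpointing (JSON; see cli_io for the file format helpers)


def save_checkpoint(state: SamplerState, path) -> None:
    from .io import write_checkpoint

    write_checkpoint(state, path)


def load_checkpoint(path) -> SamplerState:
    from .io import read_checkpoint

    return read_checkpoint(path)
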