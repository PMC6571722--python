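"""Coarse-grained single-chain model of a flexible-semiflexible multiblock copolymer.

The chain is a string of ``N`` hard spheres (diameter ``sigma = 1``) connected by
freely variable bonds of length ``l in [0.8, 1.25] sigma``.  Beads come in two
types, semiflexible (S) and flexible (F), arranged in regularly alternating
blocks of length ``b``.  Two square-well energy terms act on a conformation:

* a non-valent contact energy ``Env = eps_ss*nss + eps_ff*nff + eps_sf*nsf``
  over non-bonded bead pairs closer than ``R_cut = 1.5 sigma``, and
* a bending stiffness energy ``Est = eps_st * nst`` where ``nst`` counts
  valence angles inside the favorable window ``[150, 170]`` degrees, applied
  only to angles whose three beads all belong to an S block.

The solvent is implicit: its selectivity is encoded in the relative magnitudes
of the three contact energies.  Contact energies are stored as exact integers
in "raw" units together with a multiplicative ``raw_scale`` so that the
macrostate label ``(Env_raw, nst)`` is integer arithmetic throughout.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelParams",
    "Conformation",
    "ContactCounts",
    "EnergyBreakdown",
    "ValidationReport",
    "PRESETS",
    "make_model",
    "count_contacts",
    "energy",
    "validate",
    "propose_local_move",
    "propose_end_regrow",
    "random_bond_vector",
    "initial_conformation",
]

# Named selective-solvent parameter sets (physical units of |eps_ff|).
# "F-attract-stronger" is run internally with integer raw energies
# (-1, -2, -4) and rescaled by 0.25 so that Env_raw stays integer.
PRESETS = {
    "S-attract-stronger": {"eps_ss": -4.0, "eps_sf": -2.0, "eps_ff": -1.0, "raw_scale": 1.0},
    "F-attract-stronger": {"eps_ss": -0.25, "eps_sf": -0.5, "eps_ff": -1.0, "raw_scale": 0.25},
    "non-selective": {"eps_ss": -1.0, "eps_sf": -1.0, "eps_ff": -1.0, "raw_scale": 1.0},
}


@dataclass(frozen=True)
class ModelParams:
    """Validated chain topology, geometry and energy parameters."""

    N: int
    b: int
    pattern: str  # string of 'S'/'F' of length N
    eps_ss: float
    eps_sf: float
    eps_ff: float
    eps_st: float = 0.0
    raw_scale: float = 1.0
    sigma: float = 1.0
    l_min: float = 0.8
    l_max: float = 1.25
    R_cut: float = 1.5
    theta_min: float = 150.0
    theta_max: float = 170.0
    phantom: bool = False  # disable hard spheres and contacts (stiffness only)
    preset: str | None = None

    # ---- derived helpers -------------------------------------------------
    @property
    def types(self) -> np.ndarray:
        """Bead types as int64 (0 = S, 1 = F)."""
        return np.array([0 if c == "S" else 1 for c in self.pattern], dtype=np.int64)

    @property
    def eps_raw(self) -> np.ndarray:
        """Integer contact energies in raw units, ordered (ss, sf, ff)."""
        raw = np.array(
            [
                self.eps_ss / self.raw_scale,
                self.eps_sf / self.raw_scale,
                self.eps_ff / self.raw_scale,
            ]
        )
        out = np.rint(raw).astype(np.int64)
        if not np.allclose(raw, out, atol=1e-9):
            raise ValueError(
                "contact energies divided by raw_scale must be integers "
                f"(got {raw.tolist()}); choose raw_scale accordingly"
            )
        return out

    @property
    def angle_eligible(self) -> np.ndarray:
        """Boolean mask over angle centers j = 1..N-2: all-S triplet rule."""
        t = self.types
        el = np.zeros(self.N, dtype=np.uint8)
        for j in range(1, self.N - 1):
            if t[j - 1] == 0 and t[j] == 0 and t[j + 1] == 0:
                el[j] = 1
        return el

    @property
    def nst_max(self) -> int:
        return int(self.angle_eligible.sum())

    @property
    def n_nonbonded_pairs(self) -> int:
        return self.N * (self.N - 1) // 2 - (self.N - 1)

    @property
    def n_env_rows(self) -> int:
        """Dense-table row count for Env_raw = 0 .. -(n_rows-1)."""
        if self.phantom:
            return 1
        bound = int(np.abs(self.eps_raw).max()) * self.n_nonbonded_pairs
        return bound + 1

    @property
    def cos_window(self) -> tuple[float, float]:
        """(cos_lo, cos_hi): favorable iff cos_lo <= cos(theta) <= cos_hi.

        theta is the interior valence angle (180 deg for collinear bonds).
        """
        return (
            math.cos(math.radians(self.theta_max)),
            math.cos(math.radians(self.theta_min)),
        )

    def fingerprint(self) -> str:
        payload = {
            k: getattr(self, k)
            for k in (
                "N", "b", "pattern", "eps_ss", "eps_sf", "eps_ff", "eps_st",
                "raw_scale", "sigma", "l_min", "l_max", "R_cut",
                "theta_min", "theta_max", "phantom",
            )
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "N", "b", "pattern", "eps_ss", "eps_sf", "eps_ff", "eps_st",
                "raw_scale", "sigma", "l_min", "l_max", "R_cut",
                "theta_min", "theta_max", "phantom", "preset",
            )
        }
        return d

    def with_eps_st(self, eps_st: float) -> "ModelParams":
        return replace(self, eps_st=eps_st)


@dataclass
class Conformation:
    """Bead coordinates of one chain microstate (units of sigma)."""

    coords: np.ndarray  # (N, 3) float64

    def __post_init__(self):
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")

    @property
    def N(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Conformation":
        return Conformation(self.coords.copy())


@dataclass(frozen=True)
class ContactCounts:
    nss: int
    nff: int
    nsf: int
    nst: int = 0

    @property
    def total_contacts(self) -> int:
        return self.nss + self.nff + self.nsf


@dataclass(frozen=True)
class EnergyBreakdown:
    Env: float
    Est: float
    U: float
    Env_raw: int


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    message: str = ""

    def __bool__(self) -> bool:
        return self.ok


def _block_pattern(N: int, b: int, start_type: str) -> str:
    other = "F" if start_type == "S" else "S"
    blocks = []
    for i in range(N // b):
        blocks.append((start_type if i % 2 == 0 else other) * b)
    return "".join(blocks)


def make_model(
    preset: str | None = None,
    *,
    N: int = 64,
    b: int | None = None,
    eps_st: float = 0.0,
    eps_ss: float | None = None,
    eps_sf: float | None = None,
    eps_ff: float | None = None,
    raw_scale: float | None = None,
    lorentz_berthelot: bool = True,
    start_type: str = "S",
    pattern: str | None = None,
    phantom: bool = False,
    **geometry,
) -> ModelParams:
    """Build and validate a :class:`ModelParams`.

    Either a ``preset`` name ("S-attract-stronger", "F-attract-stronger",
    "non-selective") or explicit contact energies must be given.  A custom
    ``pattern`` (string of 'S'/'F') overrides the regular block layout, e.g.
    for homopolymer or phantom-chain reference systems.
    """
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        p = PRESETS[preset]
        eps_ss = p["eps_ss"] if eps_ss is None else eps_ss
        eps_sf = p["eps_sf"] if eps_sf is None else eps_sf
        eps_ff = p["eps_ff"] if eps_ff is None else eps_ff
        raw_scale = p["raw_scale"] if raw_scale is None else raw_scale
    if eps_ss is None or eps_ff is None:
        raise ValueError("explicit eps_ss and eps_ff (or a preset) are required")
    if eps_sf is None:
        eps_sf = -math.sqrt(abs(eps_ss) * abs(eps_ff))
    raw_scale = 1.0 if raw_scale is None else raw_scale

    if lorentz_berthelot and not math.isclose(
        abs(eps_sf), math.sqrt(abs(eps_ss) * abs(eps_ff)), rel_tol=1e-9
    ):
        raise ValueError(
            "Lorentz-Berthelot violated: |eps_sf| must equal sqrt(|eps_ss|*|eps_ff|)"
        )

    if pattern is not None:
        if len(pattern) != N or set(pattern) - {"S", "F"}:
            raise ValueError("pattern must be a string of 'S'/'F' of length N")
        b = b if b is not None else N
    else:
        if b is None:
            raise ValueError("block length b is required")
        if N % (2 * b) != 0 or N % 2 != 0:
            raise ValueError(f"N={N} must be even and divisible by 2*b={2*b}")
        pattern = _block_pattern(N, b, start_type)

    m = ModelParams(
        N=N, b=b, pattern=pattern,
        eps_ss=float(eps_ss), eps_sf=float(eps_sf), eps_ff=float(eps_ff),
        eps_st=float(eps_st), raw_scale=float(raw_scale),
        phantom=phantom, preset=preset, **geometry,
    )
    if not (0.0 < m.l_min < m.l_max):
        raise ValueError("need 0 < l_min < l_max")
    if m.l_max >= math.sqrt(2.0) * m.sigma:
        # bonds could cross: two bonds between hard spheres can intersect
        # once the bond length reaches sqrt(2)*sigma
        raise ValueError("l_max must stay below sqrt(2)*sigma to keep bonds uncrossable")
    if not (0.0 < m.theta_min < m.theta_max < 180.0):
        raise ValueError("need 0 < theta_min < theta_max < 180 degrees")
    if m.eps_st > 0:
        raise ValueError("eps_st must be <= 0 (favorable angles lower the energy)")
    m.eps_raw  # noqa: B018 -- raises if energies are not integral in raw units
    return m


# ---------------------------------------------------------------------------
# counting, energy, validity


def count_contacts(conf: Conformation, model: ModelParams) -> ContactCounts:
    """Count non-bonded contacts by type pair and favorable stiff angles.

    A contact is an unordered non-bonded pair (|i-j| > 1) with distance
    <= R_cut.  An angle counts toward nst when its triplet is all-S and the
    interior angle lies in [theta_min, theta_max].
    """
    x = conf.coords
    N = model.N
    t = model.types
    nss = nff = nsf = 0
    if not model.phantom:
        diff = x[:, None, :] - x[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        iu, ju = np.triu_indices(N, k=2)
        mask = d2[iu, ju] <= model.R_cut**2
        ti, tj = t[iu[mask]], t[ju[mask]]
        nss = int(np.sum((ti == 0) & (tj == 0)))
        nff = int(np.sum((ti == 1) & (tj == 1)))
        nsf = int(np.sum(ti != tj))
    nst = 0
    cos_lo, cos_hi = model.cos_window
    el = model.angle_eligible
    for j in range(1, N - 1):
        if not el[j]:
            continue
        a = x[j] - x[j - 1]
        c = x[j + 1] - x[j]
        cosang = -float(a @ c) / math.sqrt(float(a @ a) * float(c @ c))
        if cos_lo <= cosang <= cos_hi:
            nst += 1
    return ContactCounts(nss=nss, nff=nff, nsf=nsf, nst=nst)


def energy(counts: ContactCounts, model: ModelParams) -> EnergyBreakdown:
    """Square-well energies from contact counts: U = Env + eps_st * nst."""
    raw = model.eps_raw
    env_raw = int(raw[0] * counts.nss + raw[1] * counts.nsf + raw[2] * counts.nff)
    env = model.raw_scale * env_raw
    est = model.eps_st * counts.nst
    return EnergyBreakdown(Env=env, Est=est, U=env + est, Env_raw=env_raw)


def validate(conf: Conformation, model: ModelParams) -> ValidationReport:
    """Check bond-length bounds and hard-sphere non-overlap.

    Bonded beads are exempt from the hard-sphere constraint (they may
    interpenetrate); every other pair must keep distance >= sigma.
    """
    x = conf.coords
    if not np.all(np.isfinite(x)):
        return ValidationReport(False, "non-finite coordinates")
    if conf.N != model.N:
        return ValidationReport(False, f"expected {model.N} beads, got {conf.N}")
    bl = np.linalg.norm(np.diff(x, axis=0), axis=1)
    bad = np.where((bl < model.l_min) | (bl > model.l_max))[0]
    if bad.size:
        i = int(bad[0])
        return ValidationReport(False, f"bond {i}-{i+1} length {bl[i]:.4f} outside "
                                       f"[{model.l_min}, {model.l_max}]")
    if not model.phantom:
        diff = x[:, None, :] - x[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        iu, ju = np.triu_indices(model.N, k=2)
        viol = np.where(d2[iu, ju] < model.sigma**2)[0]
        if viol.size:
            i, j = int(iu[viol[0]]), int(ju[viol[0]])
            return ValidationReport(
                False, f"hard-sphere overlap between beads {i} and {j} "
                       f"(distance {math.sqrt(d2[i, j]):.4f} < sigma)")
    return ValidationReport(True, "")


# ---------------------------------------------------------------------------
# trial moves (reference implementations; the sampler kernel mirrors these)


def propose_local_move(
    conf: Conformation, model: ModelParams, rng: np.random.Generator,
    displacement: float = 0.05,
) -> tuple[Conformation, int]:
    """Displace one uniformly chosen bead by U[-disp, disp] per axis.

    The proposal density is symmetric; geometric validity of the candidate is
    left to the caller (an invalid candidate is simply rejected).
    """
    i = int(rng.integers(model.N))
    cand = conf.copy()
    cand.coords[i] += rng.uniform(-displacement, displacement, size=3)
    return cand, i


def random_bond_vector(
    rng: np.random.Generator, l_min: float, l_max: float
) -> np.ndarray:
    """Bond vector uniform w.r.t. volume on the shell l_min <= |v| <= l_max."""
    u = rng.random()
    r = (l_min**3 + u * (l_max**3 - l_min**3)) ** (1.0 / 3.0)
    while True:
        a, c = rng.uniform(-1, 1), rng.uniform(-1, 1)
        s = a * a + c * c
        if s < 1.0:
            break
    f = 2.0 * math.sqrt(1.0 - s)
    return r * np.array([a * f, c * f, 1.0 - 2.0 * s])


def propose_end_regrow(
    conf: Conformation, model: ModelParams, rng: np.random.Generator,
    k_max: int | None = None,
) -> tuple[Conformation, int]:
    """Cut k terminal beads from a random chain end and regrow them.

    Each regrown bond vector is drawn uniformly with respect to volume from
    the spherical shell [l_min, l_max], so the proposal density is constant on
    the allowed set and symmetric under the Cartesian configuration measure
    (the same base measure the local-displacement move targets).  k is uniform
    on 1..k_max; k_max defaults to the block length b.
    """
    k_max = min(model.b if k_max is None else k_max, model.N - 1)
    k = int(rng.integers(1, k_max + 1))
    end = int(rng.integers(2))
    cand = conf.copy()
    if end == 0:
        for m in range(k - 1, -1, -1):
            cand.coords[m] = cand.coords[m + 1] + random_bond_vector(
                rng, model.l_min, model.l_max)
    else:
        for m in range(model.N - k, model.N):
            cand.coords[m] = cand.coords[m - 1] + random_bond_vector(
                rng, model.l_min, model.l_max)
    return cand, k


def initial_conformation(model: ModelParams, seed: int = 0) -> Conformation:
    """Slightly perturbed straight chain with bond length 1, validated."""
    rng = np.random.default_rng(seed)
    x = np.zeros((model.N, 3))
    x[:, 0] = np.arange(model.N, dtype=float)
    for _ in range(1000):
        pert = x + rng.uniform(-0.02, 0.02, size=x.shape)
        conf = Conformation(pert)
        if validate(conf, model):
            return conf
    # fall back to the exact straight line (always valid)
    return Conformation(x)
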