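"""Configuration, table I/O, snapshots, manifests and checkpoints.

All interchange formats are plain text: TSV tables with JSON metadata
sidecars (``<file>.meta.json``), TOML or JSON run configuration, extended-XYZ
conformation snapshots, and JSON checkpoints.  Floats are written with 17
significant digits so round-trips are lossless.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .model import Conformation, ModelParams, make_model
from .samc import DoSGrid, ObservableTable, SamplerState

__all__ = [
    "RunManifest", "read_config", "model_from_config",
    "write_dos", "read_dos", "write_observables", "read_observables",
    "write_curve", "write_conformation_xyz", "read_conformation_xyz",
    "write_manifest", "write_checkpoint", "read_checkpoint",
]

_F = "%.17g"


@dataclass
class RunManifest:
    """Provenance record attached to every artifact."""

    fingerprint: str
    seeds: list = field(default_factory=list)
    schedule: list = field(default_factory=list)   # [(gamma0, t0, n_mcs), ...]
    mcs: int = 0
    files: list = field(default_factory=list)
    code_version: str = "0.1.0"
    timestamp: str = ""
    parent: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(manifest.to_json() + "\n")


# ---------------------------------------------------------------------------
# configuration

_MODEL_KEYS = {
    "preset", "N", "b", "eps_st", "eps_ss", "eps_sf", "eps_ff", "raw_scale",
    "lorentz_berthelot", "start_type", "pattern", "phantom",
    "sigma", "l_min", "l_max", "R_cut", "theta_min", "theta_max",
}
_RUN_KEYS = {"seed", "mcs", "gamma0", "t0", "stages", "out", "checkpoint_every",
             "k_max", "displacement", "sample_floor", "quorum"}


def read_config(path) -> tuple[ModelParams, dict]:
    """Parse a TOML or JSON run configuration into (ModelParams, run settings).

    The document has a ``[model]`` table mirroring the model-parameter names
    and an optional ``[run]`` table; unknown keys are rejected with a
    field-level message.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        doc = tomllib.loads(text)
    else:
        doc = json.loads(text)
    unknown = set(doc) - {"model", "run"}
    if unknown:
        raise ValueError(f"unknown top-level config sections: {sorted(unknown)}")
    model_cfg = dict(doc.get("model", {}))
    run_cfg = dict(doc.get("run", {}))
    bad = set(model_cfg) - _MODEL_KEYS
    if bad:
        raise ValueError(f"unknown [model] keys: {sorted(bad)}")
    bad = set(run_cfg) - _RUN_KEYS
    if bad:
        raise ValueError(f"unknown [run] keys: {sorted(bad)}")
    if "N" not in model_cfg:
        raise ValueError("config error: [model] is missing required key 'N'")
    return model_from_config(model_cfg), run_cfg


def model_from_config(cfg: dict) -> ModelParams:
    cfg = dict(cfg)
    preset = cfg.pop("preset", None)
    return make_model(preset, **cfg)


def write_model_config(model: ModelParams, run: dict, path) -> None:
    """Write a JSON config document that read_config round-trips."""
    m = {k: v for k, v in model.to_dict().items() if v is not None}
    # pattern is derivable unless it is irregular; keep it for fidelity
    Path(path).write_text(json.dumps({"model": m, "run": run}, indent=1) + "\n")


# ---------------------------------------------------------------------------
# DoS and observable tables


def _write_meta(path, meta: dict) -> None:
    Path(str(path) + ".meta.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True) + "\n")


def _read_meta(path) -> dict:
    p = Path(str(path) + ".meta.json")
    return json.loads(p.read_text()) if p.exists() else {}


def write_dos(dos: DoSGrid, path, extra_meta: dict | None = None) -> None:
    """DoS table as TSV (Env_raw, nst, log_g, visits[, std_log_g]), anchored."""
    d = dos.anchored()
    cols = ["Env_raw", "nst", "log_g", "visits"]
    rows = [d.env_raw, d.nst, d.log_g, d.visits]
    if d.std_log_g is not None:
        cols.append("std_log_g")
        rows.append(d.std_log_g)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for vals in zip(*rows):
            fh.write("\t".join(
                _F % v if isinstance(v, float | np.floating) else str(int(v))
                for v in vals) + "\n")
    meta = {"fingerprint": d.fingerprint, "n_mcs": d.n_mcs,
            "kind": "dos2d", "code_version": "0.1.0"}
    meta.update(extra_meta or {})
    _write_meta(path, meta)


def read_dos(path) -> DoSGrid:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = _read_meta(path)
    dos = DoSGrid(env_raw=df["Env_raw"].to_numpy(np.int64),
                  nst=df["nst"].to_numpy(np.int64),
                  log_g=df["log_g"].to_numpy(float),
                  visits=df["visits"].to_numpy(np.int64),
                  fingerprint=meta.get("fingerprint", ""),
                  n_mcs=int(meta.get("n_mcs", 0)))
    if "std_log_g" in df:
        dos.std_log_g = df["std_log_g"].to_numpy(float)
    return dos


def write_observables(table: ObservableTable, path,
                      extra_meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["Env_raw", "nst", "count", *table.columns]) + "\n")
        for i in range(table.n_keys):
            cells = [str(int(table.env_raw[i])), str(int(table.nst[i])),
                     str(int(table.count[i]))]
            cells += [_F % v for v in table.means[i]]
            fh.write("\t".join(cells) + "\n")
    meta = {"fingerprint": table.fingerprint, "sample_floor": table.sample_floor,
            "columns": list(table.columns), "kind": "observables",
            "code_version": "0.1.0"}
    meta.update(extra_meta or {})
    _write_meta(path, meta)


def read_observables(path) -> ObservableTable:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = _read_meta(path)
    cols = tuple(meta.get("columns") or df.columns[3:])
    return ObservableTable(
        env_raw=df["Env_raw"].to_numpy(np.int64),
        nst=df["nst"].to_numpy(np.int64),
        count=df["count"].to_numpy(np.int64),
        means=df[list(cols)].to_numpy(float),
        columns=cols, fingerprint=meta.get("fingerprint", ""),
        sample_floor=int(meta.get("sample_floor", 1000)))


def write_curve(path, columns: dict[str, np.ndarray],
                meta: dict | None = None) -> None:
    """Generic TSV writer for analysis curves (aligned 1D columns)."""
    names = list(columns)
    arrays = [np.asarray(columns[n]) for n in names]
    n = len(arrays[0])
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for i in range(n):
            fh.write("\t".join(_F % a[i] for a in arrays) + "\n")
    if meta is not None:
        _write_meta(path, meta)


# ---------------------------------------------------------------------------
# extended-XYZ snapshots


def write_conformation_xyz(conf: Conformation, model: ModelParams, path,
                           comment_fields: dict | None = None) -> None:
    """Extended XYZ: the element column is the bead type S/F; the comment line
    carries run metadata as key=value pairs."""
    fields = {"N": model.N, "b": model.b, "preset": model.preset,
              "eps_st": model.eps_st}
    fields.update(comment_fields or {})
    comment = " ".join(f"{k}={v}" for k, v in fields.items() if v is not None)
    with open(path, "w") as fh:
        fh.write(f"{conf.N}\n{comment}\n")
        for t, (x, y, z) in zip(model.pattern, conf.coords):
            fh.write(f"{t} {_F % x} {_F % y} {_F % z}\n")


def read_conformation_xyz(path) -> tuple[Conformation, str, dict]:
    """Returns (conformation, pattern string, comment fields)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0])
    fields = {}
    for tok in lines[1].split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            fields[k] = v
    pattern = []
    coords = np.empty((n, 3))
    for i, line in enumerate(lines[2:2 + n]):
        parts = line.split()
        pattern.append(parts[0])
        coords[i] = [float(p) for p in parts[1:4]]
    return Conformation(coords), "".join(pattern), fields


# ---------------------------------------------------------------------------
# checkpoints (JSON; sparse tables, exact float round-trip via hex floats)


def _arr_to_json(a: np.ndarray) -> dict:
    if a.dtype.kind == "f":
        return {"dtype": "f8", "shape": list(a.shape),
                "data": [v.hex() for v in a.ravel().tolist()]}
    if a.dtype == np.uint64:
        return {"dtype": "u8", "shape": list(a.shape),
                "data": [int(v) for v in a.ravel().tolist()]}
    return {"dtype": "i8", "shape": list(a.shape),
            "data": [int(v) for v in a.ravel().tolist()]}


def _arr_from_json(d: dict) -> np.ndarray:
    if d["dtype"] == "f8":
        a = np.array([float.fromhex(v) for v in d["data"]], dtype=np.float64)
    elif d["dtype"] == "u8":
        a = np.array(d["data"], dtype=np.uint64)
    else:
        a = np.array(d["data"], dtype=np.int64)
    return a.reshape(d["shape"])


_CKPT_VERSION = 1


def write_checkpoint(state: SamplerState, path) -> None:
    """Serialize the complete sampler state (RNG word included) to JSON."""
    rows, cols = np.where(state.log_g < 1e300)
    doc = {
        "version": _CKPT_VERSION,
        "fingerprint": state.fingerprint,
        "seed": state.seed, "stream": state.stream, "t_done": state.t_done,
        "shape": list(state.log_g.shape),
        "coords": _arr_to_json(state.coords),
        "rng_state": _arr_to_json(state.rng_state),
        "stats": _arr_to_json(state.stats),
        "rows": rows.tolist(), "cols": cols.tolist(),
        "log_g": [v.hex() for v in state.log_g[rows, cols].tolist()],
        "visits": [int(v) for v in state.visits[rows, cols].tolist()],
    }
    Path(path).write_text(json.dumps(doc) + "\n")


def read_checkpoint(path) -> SamplerState:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no checkpoint at {path}")
    doc = json.loads(p.read_text())
    if doc.get("version") != _CKPT_VERSION:
        raise ValueError(f"checkpoint schema version {doc.get('version')} "
                         f"is not supported (expected {_CKPT_VERSION})")
    shape = tuple(doc["shape"])
    log_g = np.full(shape, 1e300)
    visits = np.zeros(shape, dtype=np.int64)
    rows = np.array(doc["rows"], dtype=np.int64)
    cols = np.array(doc["cols"], dtype=np.int64)
    if rows.size:
        log_g[rows, cols] = [float.fromhex(v) for v in doc["log_g"]]
        visits[rows, cols] = doc["visits"]
    return SamplerState(
        coords=_arr_from_json(doc["coords"]),
        rng_state=_arr_from_json(doc["rng_state"]),
        t_done=int(doc["t_done"]), log_g=log_g, visits=visits,
        obs_sum=np.zeros((1, 1, 1)), obs_cnt=np.zeros((1, 1), dtype=np.int64),
        fingerprint=doc["fingerprint"],
        stats=_arr_from_json(doc["stats"]),
        seed=int(doc["seed"]), stream=int(doc["stream"]))
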