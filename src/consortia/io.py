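"""Configuration, seeding, serialization, and deterministic test fixtures.

Experiments are described by YAML configuration files; outputs are CSV for
scalar time series and a compressed ``.npz`` container (with a JSON metadata
sidecar carrying the config hash, seed, and format version) for grids and
cell tables, so every stochastic run is reproducible from its recorded
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abm, lattice
from .abm import ABMParams, MechParams, StrainParams, TrapGeometry
from .lattice import LMParams
from .oscillator import OscParams
from .qs import QSParams

FORMAT_VERSION = 1

__all__ = [
    "ExperimentConfig",
    "load_config",
    "config_hash",
    "make_seeding",
    "write_trajectory",
    "read_trajectory",
    "fixture_suite",
]


@dataclass
class ExperimentConfig:
    """Parsed experiment description.

    engine: "lm", "abm" or "osc"; ``params`` is the engine parameter object;
    ``seeding`` the initial-condition mode; ``replicates``/``seed`` control
    the ensemble; sampling and horizon set the output grid.
    """

    engine: str
    params: object
    seeding: str = "random-mixed"
    n_seed_cells: int = 64
    t_end: float = 3.0
    sample_interval: float = 0.05
    replicates: int = 1
    seed: int = 0
    qs: QSParams | None = None
    out: str | None = None

    def __post_init__(self) -> None:
        if self.engine not in ("lm", "abm", "osc"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.t_end <= 0 or self.sample_interval <= 0:
            raise ValueError("t_end and sample_interval must be positive")


def _build_params(engine: str, block: dict):
    if engine == "lm":
        if "p_rot" in block:
            block["p_rot"] = tuple(block["p_rot"])
        if block.get("p_rot_post") is not None:
            block["p_rot_post"] = tuple(block["p_rot_post"])
        return LMParams(**block)
    if engine == "abm":
        geo = TrapGeometry(**block.pop("geometry", {}))
        strains = tuple(
            StrainParams(**s) for s in block.pop(
                "strains",
                [{"name": "blue"}, {"name": "orange"}],
            )
        )
        mech = MechParams(**block.pop("mechanics", {}))
        return ABMParams(geometry=geo, strains=strains, mech=mech, **block)
    return OscParams(**block)


def load_config(path) -> ExperimentConfig:
    """Read and validate a YAML experiment configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "engine" not in raw:
        raise ValueError("config must be a mapping with an 'engine' key")
    engine = raw["engine"]
    params = _build_params(engine, dict(raw.get("params", {})))
    qs = QSParams(**raw["qs"]) if "qs" in raw else None
    fields = {
        k: raw[k]
        for k in (
            "seeding", "n_seed_cells", "t_end", "sample_interval",
            "replicates", "seed", "out",
        )
        if k in raw
    }
    return ExperimentConfig(engine=engine, params=params, qs=qs, **fields)


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable short hash of a configuration (recorded in outputs)."""

    def default(o):
        if hasattr(o, "__dict__") or hasattr(o, "__dataclass_fields__"):
            return asdict(o) if hasattr(o, "__dataclass_fields__") else vars(o)
        return str(o)

    blob = json.dumps(asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def make_seeding(
    engine: str,
    spec: str,
    params,
    rng: np.random.Generator,
    n_cells: int = 64,
):
    """Initial state for any engine: a full lattice (LM) or non-overlapping
    seed cells (ABM), per mode {"single", "random-mixed", "separated"}."""
    if engine == "lm":
        return lattice.make_lattice(params, spec, rng)
    if engine == "abm":
        return abm.seed_cells(params, n_cells, spec, rng)
    raise ValueError(f"no seeding for engine {engine!r}")


def write_trajectory(path, snapshots, metadata: dict) -> None:
    """Lossless snapshot container: compressed arrays + JSON metadata sidecar.

    ``snapshots`` is a list of dict snapshots (ABM) or (t, strain, orient)
    tuples (LM grids).
    """
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    if snapshots and isinstance(snapshots[0], dict):
        kind = "abm"
        for i, s in enumerate(snapshots):
            for key, val in s.items():
                arrays[f"s{i}_{key}"] = np.asarray(val)
    else:
        kind = "lm"
        for i, (t, strain, orient) in enumerate(snapshots):
            arrays[f"s{i}_t"] = np.asarray(t)
            arrays[f"s{i}_strain"] = strain
            arrays[f"s{i}_orient"] = orient
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    meta = dict(metadata)
    meta.update({"format_version": FORMAT_VERSION, "kind": kind,
                 "n_snapshots": len(snapshots)})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_trajectory(path):
    """Round-trip reader for :func:`write_trajectory`.

    Raises ``ValueError`` on a missing/garbled container or an unsupported
    format version.
    """
    path = Path(path)
    meta_file = path.with_suffix(".json")
    if not meta_file.exists():
        raise ValueError(f"missing metadata sidecar {meta_file}")
    meta = json.loads(meta_file.read_text())
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"unsupported trajectory format version {version!r} "
            f"(this build reads version {FORMAT_VERSION})"
        )
    try:
        data = np.load(path.with_suffix(".npz"))
    except Exception as exc:
        raise ValueError(f"unreadable trajectory container: {exc}") from exc
    snaps = []
    for i in range(meta["n_snapshots"]):
        if meta["kind"] == "abm":
            keys = [k for k in data.files if k.startswith(f"s{i}_")]
            snap = {k.split("_", 1)[1]: data[k] for k in keys}
            snap["t"] = float(snap["t"])
            snaps.append(snap)
        else:
            snaps.append(
                (float(data[f"s{i}_t"]), data[f"s{i}_strain"], data[f"s{i}_orient"])
            )
    return snaps, meta


def fixture_suite(name: str, seed: int = 123):
    """Small deterministic scenarios for tests and demos.

    - "lm-2x2": 4-cell lattice with enumerable event space (kappa = 0).
    - "abm-column": three stacked, touching vertical cells mid-trap.
    - "osc-cycle": reduced-oscillator series containing full cycles.
    - "exp-series": exact invasion-form fraction series (alpha = 0.7).
    """
    rng = np.random.default_rng(seed)
    if name == "lm-2x2":
        params = LMParams(M=2, N=2, lam=1.0, kappa=0.0, p_rot=(0.2, 0.5))
        state = lattice.make_lattice(params, "random-mixed", rng)
        return params, state
    if name == "abm-column":
        params = ABMParams(geometry=TrapGeometry(width=20.0, height=20.0))
        n = 3
        st = abm.ABMState(
            x=np.full(n, 10.0),
            y=np.array([8.7, 10.0, 11.3]),
            phi=np.full(n, np.pi / 2),
            length=np.full(n, 1.4),
            birth_length=np.full(n, 0.7),
            strain=np.zeros(n, np.int8),
            species=np.zeros((n, abm.N_SPECIES)),
            f_axial=np.zeros(n),
            reduced=np.zeros(n, bool),
        )
        return params, st
    if name == "osc-cycle":
        from . import oscillator

        params = OscParams(K1=0.2, K2=0.8, n=8.0, eps=1e-3)
        series = oscillator.integrate(params, T=12.0)
        return params, series
    if name == "exp-series":
        t = np.linspace(0.0, 10.0, 101)
        f = 1.0 - 0.5 * np.exp(-0.7 * np.maximum(t - 1.0, 0.0))
        return t, f
    raise ValueError(f"unknown fixture {name!r}")
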