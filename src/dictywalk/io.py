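"""Configuration, trajectory CSV round-tripping and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemotaxis import CouplingParams
from .markov import MOVE_LABELS, ModelParams
from .simulate import MOVE_CODES, SimulationConfig, TrajectoryEnsemble


class ConfigError(ValueError):
    """Invalid or contradictory run configuration."""


#: Flat JSON config keys (also the CLI flag names, dashes for underscores).
CONFIG_KEYS = {
    "n_cells", "n_steps", "dt", "step_length", "p", "alpha", "beta",
    "epsilon", "gamma", "L", "C", "grad_c", "gradient_direction",
    "seed", "init_mode",
}

ENSEMBLE_COLUMNS = [
    "cell_id", "step", "time_min", "x_um", "y_um", "direction_index", "move_type",
]


def load_config(
    path: str | Path | None = None, **overrides
) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from JSON and/or flags.

    Flag values override file values; ``None`` overrides are ignored.
    Defaults are the homogeneous-medium study conditions: ``p = 1/7``,
    ``alpha = 0.25``, ``beta = 0.75``, 20-s steps of 6 um, cell size
    10 um.  A coupling is configured either directly with ``epsilon``
    or via the field parameters ``(gamma, C, grad_c)``.
    """
    raw: dict = {}
    if path is not None:
        try:
            raw = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as e:
            raise ConfigError(f"cannot read config {path}: {e}") from e
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a JSON object")
    raw.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(raw) - CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    try:
        alpha = float(raw.get("alpha", 0.25))
        beta = float(raw.get("beta", 1.0 - alpha))
        params = ModelParams(p=float(raw.get("p", 1.0 / 7.0)), alpha=alpha, beta=beta)
    except ValueError as e:
        raise ConfigError(str(e)) from e

    coupling = None
    field_keys = {"gamma", "C", "grad_c"} & set(raw)
    try:
        if "epsilon" in raw and float(raw["epsilon"]) > 0:
            coupling = CouplingParams(
                epsilon=float(raw["epsilon"]),
                gradient_direction=tuple(raw.get("gradient_direction", (0.0, 1.0))),
            )
        elif field_keys:
            if field_keys != {"gamma", "C", "grad_c"}:
                raise ConfigError(
                    "field coupling needs all of gamma, C and grad_c "
                    f"(got only {sorted(field_keys)})"
                )
            coupling = CouplingParams.from_field(
                gamma=float(raw["gamma"]),
                C=float(raw["C"]),
                grad_c=float(raw["grad_c"]),
                L=float(raw.get("L", 10.0)),
                gradient_direction=tuple(raw.get("gradient_direction", (0.0, 1.0))),
            )
    except ValueError as e:
        raise ConfigError(str(e)) from e

    try:
        return SimulationConfig(
            n_cells=int(raw.get("n_cells", 1)),
            n_steps=int(raw.get("n_steps", 45)),
            dt=float(raw.get("dt", 20.0)),
            step_length=float(raw.get("step_length", 6.0)),
            params=params,
            coupling=coupling,
            seed=int(raw.get("seed", 0)),
            init_mode=raw.get("init_mode", "stationary"),
        )
    except ValueError as e:
        raise ConfigError(str(e)) from e


def ensemble_to_frame(ensemble: TrajectoryEnsemble) -> pd.DataFrame:
    """Long-format table, one row per stored position.

    Step 0 is the common origin and carries no direction or move type.
    """
    n, T = ensemble.n_cells, ensemble.n_steps
    times = ensemble.times_min
    labels = np.array(MOVE_LABELS, dtype=object)
    frames = []
    for k in range(n):
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": k,
                    "step": np.arange(T + 1),
                    "time_min": times,
                    "x_um": ensemble.positions[k, :, 0],
                    "y_um": ensemble.positions[k, :, 1],
                    "direction_index": np.concatenate(
                        [[""], ensemble.directions[k].astype(str)]
                    ),
                    "move_type": np.concatenate(
                        [[""], labels[ensemble.move_types[k]]]
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_ensemble(ensemble: TrajectoryEnsemble, path: str | Path) -> None:
    """Write the trajectory CSV (positions serialized at 6 decimals)."""
    df = ensemble_to_frame(ensemble)
    df.to_csv(path, index=False, float_format="%.6f")


def read_ensemble(
    path: str | Path, config: SimulationConfig | None = None
) -> TrajectoryEnsemble:
    """Read a trajectory CSV written by :func:`write_ensemble`.

    If no config is given, a minimal one is reconstructed from the
    table (time grid and first-step length).
    """
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in ENSEMBLE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"trajectory file {path} is missing columns: {missing}")

    cells = df["cell_id"].unique()
    n = len(cells)
    steps0 = df.loc[df["cell_id"] == cells[0], "step"].to_numpy()
    if np.any(np.diff(steps0) != 1) or steps0[0] != 0:
        raise ConfigError("step index must increase by 1 from 0 within each cell")
    T = int(steps0[-1])

    positions = np.empty((n, T + 1, 2))
    directions = np.empty((n, T), dtype=np.int64)
    move_types = np.empty((n, T), dtype=np.int64)
    for k, cid in enumerate(cells):
        sub = df[df["cell_id"] == cid]
        if len(sub) != T + 1 or np.any(np.diff(sub["step"].to_numpy()) != 1):
            raise ConfigError(f"cell {cid}: non-contiguous or ragged step index")
        positions[k, :, 0] = sub["x_um"].to_numpy()
        positions[k, :, 1] = sub["y_um"].to_numpy()
        directions[k] = sub["direction_index"].to_numpy()[1:].astype(np.int64)
        try:
            move_types[k] = [MOVE_CODES[m] for m in sub["move_type"].to_numpy()[1:]]
        except KeyError as e:
            raise ConfigError(f"unknown move_type label {e.args[0]!r}") from e

    if config is None:
        t1 = float(df.loc[df["step"] == 1, "time_min"].iloc[0])
        step_len = float(np.linalg.norm(positions[0, 1] - positions[0, 0]))
        config = SimulationConfig(
            n_cells=n, n_steps=T, dt=60.0 * t1, step_length=step_len
        )
    return TrajectoryEnsemble(config, positions, directions, move_types)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    if config.coupling is not None:
        d["coupling"] = asdict(config.coupling)
    return d


def write_manifest(out_dir: str | Path, config: SimulationConfig | None, **extra) -> Path:
    """Write the run manifest (config echo, seed, artifact checksums)."""
    out_dir = Path(out_dir)
    artifacts = {
        p.name: _sha256(p)
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "config": config_dict(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
        "artifacts": artifacts,
        **extra,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
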