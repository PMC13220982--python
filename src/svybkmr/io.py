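"""Config parsing, manifests and tidy outputs for reproducible runs.

Every CLI output is written next to a config echo (JSON) sufficient to
reproduce it bit-for-bit from the same package version and master seed.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, fields, is_dataclass
from pathlib import Path

import yaml

__all__ = ["load_config", "build_dataclass", "write_config_echo",
           "write_manifest", "save_draws", "load_draws"]


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON config file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def build_dataclass(cls, params: dict, **overrides):
    """Instantiate a (frozen) dataclass from a config block, rejecting
    unknown keys so typos fail loudly."""
    params = {**(params or {}), **overrides}
    known = {f.name for f in fields(cls)}
    unknown = set(params) - known
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; "
            f"valid keys: {sorted(known)}")
    return cls(**params)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def write_config_echo(out_path: str | Path, **blocks) -> Path:
    """Write the config echo JSON alongside an output file."""
    out_path = Path(out_path)
    echo = out_path.with_name(out_path.stem + ".config.json")
    echo.write_text(json.dumps(_jsonable(blocks), indent=2, default=str))
    return echo


def save_draws(draws, prefix: str | Path) -> None:
    """Serialize retained MCMC draws: columnar CSV plus a JSON meta sidecar."""
    import pandas as pd
    prefix = Path(prefix)
    m, p = draws.m, draws.beta.shape[1]
    cols = {f"r{j + 1}": draws.r[:, j] for j in range(m)}
    cols.update({f"delta{j + 1}": draws.delta[:, j] for j in range(m)})
    cols["lam"] = draws.lam
    cols["sigma2"] = draws.sigma2
    cols.update({f"beta{j + 1}": draws.beta[:, j] for j in range(p)})
    pd.DataFrame(cols).to_csv(prefix.with_suffix(".draws.csv"), index=False)
    meta = {"z_mean": list(draws.z_mean), "z_sd": list(draws.z_sd),
            "varsel": draws.varsel, "acceptance": _jsonable(draws.acceptance),
            "config": _jsonable(draws.config) if draws.config else None}
    prefix.with_suffix(".draws.json").write_text(json.dumps(meta, indent=2))


def load_draws(prefix: str | Path):
    """Reload draws written by :func:`save_draws`."""
    import numpy as np
    import pandas as pd
    from .bkmr import BKMRConfig, PosteriorDraws
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".draws.csv"))
    meta = json.loads(prefix.with_suffix(".draws.json").read_text())
    m = len(meta["z_mean"])
    p = sum(c.startswith("beta") for c in df.columns)
    cfg = BKMRConfig(**meta["config"]) if meta.get("config") else None
    return PosteriorDraws(
        r=df[[f"r{j + 1}" for j in range(m)]].to_numpy(),
        delta=df[[f"delta{j + 1}" for j in range(m)]].to_numpy(dtype=int),
        lam=df["lam"].to_numpy(), sigma2=df["sigma2"].to_numpy(),
        beta=df[[f"beta{j + 1}" for j in range(p)]].to_numpy(),
        z_mean=np.array(meta["z_mean"]), z_sd=np.array(meta["z_sd"]),
        varsel=meta["varsel"], config=cfg,
        acceptance=meta.get("acceptance", {}))


def write_manifest(out_path: str | Path, seed: int, started: float,
                   **extra) -> Path:
    """Run provenance: master seed, package/python versions, wall-clock."""
    from . import __version__
    out_path = Path(out_path)
    manifest = {
        "seed": seed,
        "svybkmr_version": __version__,
        "python": platform.python_version(),
        "wall_clock_s": round(time.time() - started, 3),
        **_jsonable(extra),
    }
    path = out_path.with_name(out_path.stem + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
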