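"""Signal and report I/O.

Respirometry traces have no domain-standard container, so the canonical
on-disk format here is CSV with a ``time,value`` header (dt inferred from
the time column) or single-column plain text with dt given explicitly.
Impulse responses travel as JSON sidecars {dt, delay_d, support_s,
values}; every run writes its resolved configuration (seeds included)
next to its outputs so results are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ImpulseResponse, TimeGrid

__all__ = [
    "read_signal",
    "write_signal",
    "read_impulse_response",
    "write_impulse_response",
    "RunConfig",
    "write_report",
]

_UNIFORMITY_RTOL = 1e-6


def read_signal(path: str | Path, dt: float | None = None) -> tuple[np.ndarray, TimeGrid]:
    """Read a signal as (values, grid) from CSV or single-column text.

    A ``time`` column must be uniformly spaced (relative tolerance 1e-6);
    without one, ``dt`` is required.  Ragged or non-numeric rows raise a
    parse error naming the first offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse as CSV: {exc}") from exc
    # headerless single column: read_csv treats the first value as a header
    if df.shape[1] == 1 and df.columns[0] not in ("value", "values"):
        try:
            float(df.columns[0])
        except ValueError:
            pass
        else:
            df = pd.read_csv(path, header=None, names=["value"])

    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: missing/non-numeric entry at data line {bad[0] + 1}")

    if "time" in df.columns:
        t = df["time"].to_numpy(dtype=float)
        steps = np.diff(t)
        if steps.size == 0:
            raise ValueError(f"{path}: need at least two samples")
        dt_est = float(np.median(steps))
        if dt_est <= 0 or np.any(np.abs(steps - dt_est) > _UNIFORMITY_RTOL * abs(dt_est)):
            raise ValueError(f"{path}: time column is not uniformly spaced")
        if dt is not None and abs(dt - dt_est) > _UNIFORMITY_RTOL * dt_est:
            raise ValueError(
                f"{path}: explicit dt={dt} contradicts time column (dt={dt_est})"
            )
        values = df["value"].to_numpy(dtype=float)
        return values, TimeGrid(n=values.size, dt=dt_est)

    if dt is None:
        raise ValueError(f"{path}: no time column; sampling interval dt is required")
    values = df[df.columns[-1]].to_numpy(dtype=float)
    return values, TimeGrid(n=values.size, dt=float(dt))


def write_signal(path: str | Path, values: np.ndarray, grid: TimeGrid) -> None:
    pd.DataFrame({"time": grid.times[: len(values)], "value": values}).to_csv(
        path, index=False
    )


def write_impulse_response(path: str | Path, h: ImpulseResponse) -> None:
    Path(path).write_text(json.dumps(h.to_dict()))


def read_impulse_response(path: str | Path) -> ImpulseResponse:
    return ImpulseResponse.from_dict(json.loads(Path(path).read_text()))


@dataclasses.dataclass
class RunConfig:
    """Resolved parameter bundle for one CLI run; serialized next to outputs."""

    command: str
    params: dict

    def to_json(self) -> str:
        return json.dumps({"command": self.command, "params": self.params},
                          sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        unknown = set(d) - {"command", "params"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(command=d["command"], params=d["params"])

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def write_report(report, out_dir: str | Path, config: RunConfig | None = None,
                 grid: TimeGrid | None = None, prefix: str = "solution") -> dict:
    """Write solution CSV, metadata JSON, iteration history CSV, and a log.

    Returns a dict of the paths written.  ``report`` is any solver report
    with ``solution``, ``lambda_used``, ``iterations``, ``residual_norms``
    and optional ``relative_errors`` attributes.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    sol = np.asarray(report.solution)
    if grid is not None:
        write_signal(out / f"{prefix}.csv", sol, grid)
    else:
        pd.DataFrame({"value": sol}).to_csv(out / f"{prefix}.csv", index=False)
    paths["solution"] = out / f"{prefix}.csv"

    meta = {
        "version": __version__,
        "lambda_used": float(report.lambda_used),
        "iterations": int(report.iterations),
        "converged": bool(getattr(report, "converged", True)),
    }
    if config is not None:
        meta["config"] = json.loads(config.to_json())
        meta["config_hash"] = config.digest
        if "seed" in config.params:
            meta["seed"] = config.params["seed"]
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    paths["metadata"] = out / "metadata.json"

    hist = {"iter": np.arange(1, len(report.residual_norms) + 1),
            "residual_norm": report.residual_norms}
    rel = getattr(report, "relative_errors", None)
    if rel:
        hist["rel_error"] = rel
    pd.DataFrame(hist).to_csv(out / "history.csv", index=False)
    paths["history"] = out / "history.csv"

    (out / "run.log").write_text(
        f"respyro {__version__}\n"
        f"iterations={meta['iterations']} lambda={meta['lambda_used']:.6g} "
        f"converged={meta['converged']}\n"
        + (f"config_hash={meta['config_hash']}\n" if config is not None else "")
    )
    paths["log"] = out / "run.log"
    return paths
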