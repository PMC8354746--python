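"""Snapshot, metrics and probe I/O.

CSV is the canonical exchange format: one row per particle with stable
ids, so growth/death conversions are auditable across snapshots.  A
legacy-ASCII VTK point-cloud writer is provided for visual inspection of
colony morphology (phase as a scalar field); it is presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kernel import KernelSpec, wendland_value
from .particles import ParticleSystem, Phase

__all__ = ["write_snapshot", "read_snapshot", "write_metrics",
           "ProbeSeries", "extract_probe"]

SNAPSHOT_COLUMNS = ["id", "x", "y", "vx", "vy", "rho", "p", "mass", "phase", "streak"]


def snapshot_frame(system: ParticleSystem) -> pd.DataFrame:
    return pd.DataFrame({
        "id": np.arange(system.n),
        "x": system.x[:, 0], "y": system.x[:, 1],
        "vx": system.v[:, 0], "vy": system.v[:, 1],
        "rho": system.rho, "p": system.p, "mass": system.m,
        "phase": [Phase(int(ph)).name for ph in system.phase],
        "streak": system.streak,
    })


def write_snapshot(system: ParticleSystem, path, format: str = "csv",
                   config_hash: str = "") -> Path:
    """Write the particle table; the config hash rides in a header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        with open(path, "w") as fh:
            fh.write(f"# reefsph snapshot config_hash={config_hash}\n")
            snapshot_frame(system).to_csv(fh, index=False)
    elif format == "vtk":
        _write_vtk(system, path, config_hash)
    else:
        raise ValueError(f"unknown snapshot format {format!r}")
    return path


def read_snapshot(path, dx: float = 0.05,
                  bounds: Tuple[float, float, float, float] = (0, 0, 0, 0),
                  period_x: Optional[float] = None) -> ParticleSystem:
    df = pd.read_csv(path, comment="#")
    phase = np.array([int(Phase[name]) for name in df["phase"]], dtype=np.int8)
    return ParticleSystem(
        x=np.column_stack([df["x"].to_numpy(), df["y"].to_numpy()]),
        v=np.column_stack([df["vx"].to_numpy(), df["vy"].to_numpy()]),
        rho=df["rho"].to_numpy(float), p=df["p"].to_numpy(float),
        m=df["mass"].to_numpy(float), phase=phase,
        streak=df["streak"].to_numpy(np.int32),
        dx=dx, bounds=bounds, period_x=period_x,
    )


def _write_vtk(system: ParticleSystem, path: Path, config_hash: str) -> None:
    # legacy ASCII point cloud; phase encoded as a scalar field
    n = system.n
    lines = [
        "# vtk DataFile Version 3.0",
        f"reefsph snapshot config_hash={config_hash}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    lines += [f"{x:.6g} {y:.6g} 0" for x, y in system.x]
    lines += [f"POINT_DATA {n}", "SCALARS phase int 1", "LOOKUP_TABLE default"]
    lines += [str(int(p)) for p in system.phase]
    lines += ["SCALARS speed float 1", "LOOKUP_TABLE default"]
    lines += [f"{s:.6g}" for s in np.hypot(system.v[:, 0], system.v[:, 1])]
    path.write_text("\n".join(lines) + "\n")


def write_metrics(counts: pd.DataFrame, path, config_hash: str = "") -> Path:
    """Per-growth-step phase-count table (the live:dead metrics file)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# reefsph metrics config_hash={config_hash}\n")
        counts.to_csv(fh, index=False)
    return path


@dataclass
class ProbeSeries:
    """Flow-speed samples extracted at a fixed position across snapshots."""

    position: Tuple[float, float]
    samples: np.ndarray     # one speed per snapshot, m/s

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def stderr(self) -> float:
        if self.samples.size < 2:
            return 0.0
        return float(np.std(self.samples, ddof=1) / np.sqrt(self.samples.size))


def extract_probe(snapshots: Sequence[ParticleSystem],
                  position: Tuple[float, float], radius: float) -> ProbeSeries:
    """Kernel-weighted (Shepard-normalised) flow speed at a point.

    Mirrors, in silico, placing a velocimetry probe in the flow: each
    snapshot contributes one sample, the kernel-weighted mean speed of
    fluid particles within ``radius`` of the probe.
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    pos = np.asarray(position, dtype=float)
    spec = KernelSpec(radius / 2.0)   # support = radius
    samples = []
    for system in snapshots:
        xmin, xmax, ymin, ymax = system.bounds
        if not (xmin <= pos[0] <= xmax and ymin <= pos[1] <= ymax):
            raise ValueError(f"probe {tuple(pos)} outside domain bounds {system.bounds}")
        fm = system.fluid_mask
        d = system.x[fm] - pos[None, :]
        if system.period_x is not None:
            L = system.period_x
            d[:, 0] -= L * np.round(d[:, 0] / L)
        w = wendland_value(d, spec)
        speeds = np.hypot(system.v[fm, 0], system.v[fm, 1])
        wsum = w.sum()
        if wsum <= 0:
            raise ValueError("no fluid particles within probe radius")
        samples.append(float(np.sum(w * speeds) / wsum))
    return ProbeSeries(position=tuple(pos), samples=np.asarray(samples))
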