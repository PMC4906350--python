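"""Trajectory container and delimited-text readers/writers.

One representation serves both the built-in simulator and externally tracked
data (GPS logs, video tracks): a dense panel of 3D positions, optionally with
unit headings, on a uniform time grid.

Native dialect: tab-delimited text, header line
``t agent_id x y z [dx dy dz]``, one row per (time, agent), floats printed
with 15 significant digits.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "read_trajectory", "write_trajectory"]

_FLOAT_FMT = "%.15g"
_REL_DT_TOL = 1e-6


@dataclass
class Trajectory:
    """Time-indexed positions (and optional headings) of ``n`` agents in 3D.

    ``times`` is a strictly increasing, uniformly spaced vector of length
    ``T``; ``positions`` has shape ``(T, n, 3)``; ``directions`` is either
    ``None`` or an array of unit vectors with the same shape.
    """

    times: np.ndarray
    positions: np.ndarray
    directions: np.ndarray | None = None
    agent_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (T, n, 3)")
        if self.positions.shape[0] != len(self.times):
            raise ValueError("positions and times disagree on frame count")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.any(np.abs(dt - dt[0]) > _REL_DT_TOL * abs(dt[0])):
                raise ValueError("time step must be uniform (rel tol 1e-6)")
        if self.directions is not None:
            self.directions = np.asarray(self.directions, dtype=float)
            if self.directions.shape != self.positions.shape:
                raise ValueError("directions must match positions in shape")
        if self.agent_ids is None:
            self.agent_ids = [str(i) for i in range(self.positions.shape[1])]
        elif len(self.agent_ids) != self.positions.shape[1]:
            raise ValueError("agent_ids length must equal agent count")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            return 1.0
        return float(self.times[1] - self.times[0])

    def with_directions(self) -> "Trajectory":
        """Return a trajectory that has headings, deriving them from
        normalised frame-to-frame displacements if absent (the last frame
        copies the penultimate heading; zero displacement keeps the previous
        heading, seeded with +x)."""
        if self.directions is not None:
            return self
        T, n, _ = self.positions.shape
        dirs = np.zeros_like(self.positions)
        prev = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
        for t in range(T - 1):
            disp = self.positions[t + 1] - self.positions[t]
            norms = np.linalg.norm(disp, axis=1)
            ok = norms > 0
            prev = np.where(ok[:, None], disp / np.where(ok, norms, 1.0)[:, None], prev)
            dirs[t] = prev
        dirs[T - 1] = dirs[T - 2] if T > 1 else prev
        return Trajectory(self.times, self.positions, dirs, list(self.agent_ids))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the native tab-delimited dialect; direction columns are emitted
    only when the trajectory carries headings."""
    has_dir = traj.directions is not None
    cols = ["t", "agent_id", "x", "y", "z"] + (["dx", "dy", "dz"] if has_dir else [])
    buf = io.StringIO()
    buf.write("\t".join(cols) + "\n")
    for t_idx in range(traj.n_frames):
        t_str = _FLOAT_FMT % traj.times[t_idx]
        for a_idx in range(traj.n_agents):
            fields = [t_str, traj.agent_ids[a_idx]]
            fields += [_FLOAT_FMT % v for v in traj.positions[t_idx, a_idx]]
            if has_dir:
                fields += [_FLOAT_FMT % v for v in traj.directions[t_idx, a_idx]]
            buf.write("\t".join(fields) + "\n")
    Path(path).write_text(buf.getvalue())


def read_trajectory(
    path: str | Path,
    dialect: str = "native",
    cols: str | None = None,
    derive_directions: bool = True,
) -> Trajectory:
    """Read a delimited-text trajectory into a validated :class:`Trajectory`.

    Parameters
    ----------
    path:
        File to read.  Whitespace- or tab-delimited with a header for the
        native dialect; ``cols`` maps arbitrary column orders.
    dialect:
        ``"native"`` (header ``t agent_id x y z [dx dy dz]``) or
        ``"columns"`` with an explicit ``cols`` mapping such as
        ``"t,id,x,y,z"`` for headerless third-party exports.
    cols:
        Comma-separated names assigning meaning to the file's columns; must
        include ``t``, ``id``, ``x``, ``y``, ``z`` (``dx, dy, dz`` optional).
    derive_directions:
        When the file lacks heading columns, derive headings from finite
        differences of positions.

    Raises
    ------
    ValueError
        On ragged panels (an agent missing from a frame) or non-monotone /
        non-uniform times.
    """
    path = Path(path)
    if dialect == "native":
        df = pd.read_csv(path, sep=r"\s+")
        required = {"t", "agent_id", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise ValueError(f"native dialect requires columns {sorted(required)}")
        df = df.rename(columns={"agent_id": "id"})
    elif dialect == "columns":
        if cols is None:
            raise ValueError("dialect 'columns' requires a cols mapping")
        names = [c.strip() for c in cols.split(",")]
        df = pd.read_csv(path, sep=r"\s+|,", engine="python", header=None, names=names)
        # tolerate a header line in the source file
        first = df.iloc[0]
        if any(isinstance(v, str) for v in first.values):
            df = df.iloc[1:].reset_index(drop=True)
        for c in names:
            if c != "id":
                df[c] = df[c].astype(float)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not {"t", "id", "x", "y", "z"}.issubset(df.columns):
        raise ValueError("mapped columns must include t, id, x, y, z")

    df["id"] = df["id"].astype(str)
    times = np.array(sorted(df["t"].unique()), dtype=float)
    agent_ids = list(dict.fromkeys(df["id"]))  # first-appearance order
    n, T = len(agent_ids), len(times)

    counts = df.groupby("t")["id"].nunique()
    bad = counts[counts != n]
    if len(bad) or len(df) != n * T:
        frames = ", ".join(str(v) for v in bad.index[:10])
        raise ValueError(f"ragged panel: frames with missing/duplicate agents at t = {frames}")

    id_index = {a: i for i, a in enumerate(agent_ids)}
    t_index = {t: i for i, t in enumerate(times)}
    positions = np.empty((T, n, 3))
    ti = df["t"].map(t_index).to_numpy()
    ai = df["id"].map(id_index).to_numpy()
    positions[ti, ai] = df[["x", "y", "z"]].to_numpy(dtype=float)

    directions = None
    if {"dx", "dy", "dz"}.issubset(df.columns):
        directions = np.empty((T, n, 3))
        directions[ti, ai] = df[["dx", "dy", "dz"]].to_numpy(dtype=float)

    traj = Trajectory(times, positions, directions, agent_ids)
    if directions is None and derive_directions:
        traj = traj.with_directions()
    return traj
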