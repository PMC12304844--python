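"""Trajectory container with a plain-CSV store.

A :class:`Trajectory` holds an evenly spaced time series, a frames-by-CVs
matrix of collective-variable values, optionally the raw particle positions
and the per-frame metadynamics bias energy V(s(t)), plus the seed and a
config digest for provenance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    times: np.ndarray
    cv_matrix: np.ndarray  # (n_frames, n_cvs); may have 0 columns
    cv_names: list[str] = field(default_factory=list)
    positions: np.ndarray | None = None  # (n_frames, dim)
    bias_energy: np.ndarray | None = None  # (n_frames,), >= 0
    seed: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cv_matrix = np.asarray(self.cv_matrix, dtype=float)
        if self.cv_matrix.ndim == 1:
            self.cv_matrix = self.cv_matrix[:, None]
        n = self.times.shape[0]
        if n > 1:
            dt = np.diff(self.times)
            if not np.all(dt > 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
                raise ValueError("times must advance by a fixed step")
        if self.cv_matrix.shape[0] != n:
            raise ValueError("cv_matrix row count must equal frame count")
        if self.cv_names and len(self.cv_names) != self.cv_matrix.shape[1]:
            raise ValueError("cv_names length must match cv_matrix columns")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape[0] != n:
                raise ValueError("positions row count must equal frame count")
        if self.bias_energy is not None:
            self.bias_energy = np.asarray(self.bias_energy, dtype=float)
            if self.bias_energy.shape[0] != n:
                raise ValueError("bias_energy length must equal frame count")
            if np.any(self.bias_energy < -1e-9):
                raise ValueError("bias_energy must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(self.times.shape[0])

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def cv(self, name: str) -> np.ndarray:
        """Column of ``cv_matrix`` by CV name."""
        if name not in self.cv_names:
            raise KeyError(f"trajectory has no CV named {name!r}; has {self.cv_names}")
        return self.cv_matrix[:, self.cv_names.index(name)]

    def to_frame(self, include_positions: bool = False) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"time": self.times}
        names = self.cv_names or [f"cv{i}" for i in range(self.cv_matrix.shape[1])]
        for i, name in enumerate(names):
            cols[name] = self.cv_matrix[:, i]
        if self.bias_energy is not None:
            cols["bias"] = self.bias_energy
        if include_positions and self.positions is not None:
            for j in range(self.positions.shape[1]):
                cols[f"pos{j}"] = self.positions[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path_or_buf, include_positions: bool = False) -> None:
        self.to_frame(include_positions).to_csv(
            path_or_buf, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path_or_buf, seed: int = 0, provenance: str = "") -> "Trajectory":
        df = pd.read_csv(path_or_buf)
        if "time" not in df.columns:
            raise ValueError("trajectory CSV must have a 'time' column")
        pos_cols = [c for c in df.columns if c.startswith("pos")]
        cv_cols = [c for c in df.columns
                   if c not in ("time", "bias") and c not in pos_cols]
        return cls(
            times=df["time"].to_numpy(),
            cv_matrix=df[cv_cols].to_numpy() if cv_cols else np.zeros((len(df), 0)),
            cv_names=cv_cols,
            positions=df[pos_cols].to_numpy() if pos_cols else None,
            bias_energy=df["bias"].to_numpy() if "bias" in df.columns else None,
            seed=seed,
            provenance=provenance,
        )

    def csv_bytes(self) -> bytes:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue().encode()
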