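"""HILLS / COLVAR text files in the PLUMED dialect.

Files start with a ``#! FIELDS <name> ...`` header followed by
whitespace-separated numeric rows.  Values are serialized with full float
precision (``%.17g``), so a write -> read round trip reproduces every
numeric field exactly.
"""

from __future__ import annotations

import io
import math
from pathlib import Path

import numpy as np

from .metad import Hill, HillsLedger
from .thermo import ThermoContext
from .trajectory import Trajectory


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def _open_out(path_or_buf):
    if isinstance(path_or_buf, (str, Path)):
        return open(path_or_buf, "w"), True
    return path_or_buf, False


def _read_lines(path_or_buf) -> list[str]:
    if isinstance(path_or_buf, Path):
        return path_or_buf.read_text().splitlines()
    if isinstance(path_or_buf, str):
        # raw file content (the dialect always opens with "#!") vs a path
        if "\n" in path_or_buf or path_or_buf.startswith("#!"):
            return path_or_buf.splitlines()
        return Path(path_or_buf).read_text().splitlines()
    return path_or_buf.read().splitlines()


def _parse_header(lines: list[str], what: str) -> list[str]:
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise ValueError(f"{what} file must start with a '#! FIELDS' header")
    return lines[0].split()[2:]


def write_hills(ledger: HillsLedger, path_or_buf) -> None:
    """Write a ledger as a PLUMED HILLS file.

    Columns: time, one center per biased variable, one sigma per biased
    variable, height, biasf.  An empty ledger produces a header-only file.
    """
    names = ledger.biased_variables or [f"s{k}" for k in range(ledger.n_dims)]
    fields = (["time"] + list(names) + [f"sigma_{n}" for n in names]
              + ["height", "biasf"])
    f, own = _open_out(path_or_buf)
    try:
        f.write("#! FIELDS " + " ".join(fields) + "\n")
        for h in ledger.hills:
            row = ([h.time] + list(h.center) + list(h.sigma)
                   + [h.height, ledger.gamma])
            f.write(" ".join(_fmt(v) for v in row) + "\n")
    finally:
        if own:
            f.close()


def read_hills(path_or_buf, thermo: ThermoContext | None = None) -> HillsLedger:
    """Parse a PLUMED HILLS file into a :class:`HillsLedger`.

    The bias factor is taken from the ``biasf`` column; bias-at-deposit is
    not stored in the dialect and is read back as NaN.
    """
    lines = _read_lines(path_or_buf)
    fields = _parse_header(lines, "HILLS")
    if "height" not in fields:
        raise ValueError("HILLS header lacks a 'height' field")
    sig_idx = [i for i, n in enumerate(fields) if n.startswith("sigma_")]
    names = [n for n in fields
             if n not in ("time", "height", "biasf") and not n.startswith("sigma_")]
    t_i = fields.index("time")
    h_i = fields.index("height")
    b_i = fields.index("biasf") if "biasf" in fields else None
    cv_idx = [fields.index(n) for n in names]
    hills: list[Hill] = []
    gamma = math.inf
    for ln_no, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != len(fields):
            raise ValueError(
                f"HILLS line {ln_no}: expected {len(fields)} columns, got {len(parts)}")
        vals = [float(p) for p in parts]
        if b_i is not None:
            gamma = vals[b_i]
        hills.append(Hill(
            time=vals[t_i],
            center=np.array([vals[i] for i in cv_idx]),
            sigma=np.array([vals[i] for i in sig_idx]),
            height=vals[h_i],
        ))
    return HillsLedger(hills=hills, gamma=gamma,
                       thermo=thermo or ThermoContext(),
                       biased_variables=names)


def write_colvar(traj: Trajectory, path_or_buf) -> None:
    """Write a trajectory's CV (+ optional bias) series as a COLVAR file."""
    names = traj.cv_names or [f"cv{i}" for i in range(traj.cv_matrix.shape[1])]
    fields = ["time"] + list(names)
    if traj.bias_energy is not None:
        fields.append("metad.bias")
    f, own = _open_out(path_or_buf)
    try:
        f.write("#! FIELDS " + " ".join(fields) + "\n")
        for i in range(traj.n_frames):
            row = [traj.times[i]] + list(traj.cv_matrix[i])
            if traj.bias_energy is not None:
                row.append(traj.bias_energy[i])
            f.write(" ".join(_fmt(v) for v in row) + "\n")
    finally:
        if own:
            f.close()


def read_colvar(path_or_buf) -> Trajectory:
    """Parse a COLVAR file into a :class:`Trajectory` (no positions)."""
    lines = _read_lines(path_or_buf)
    fields = _parse_header(lines, "COLVAR")
    if "time" not in fields:
        raise ValueError("COLVAR header lacks a 'time' field")
    rows = []
    for ln_no, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != len(fields):
            raise ValueError(
                f"COLVAR line {ln_no}: expected {len(fields)} columns, got {len(parts)}")
        rows.append([float(p) for p in parts])
    data = np.array(rows) if rows else np.zeros((0, len(fields)))
    t_i = fields.index("time")
    bias_names = [n for n in fields if n.endswith(".bias") or n == "bias"]
    cv_names = [n for n in fields if n != "time" and n not in bias_names]
    cv_idx = [fields.index(n) for n in cv_names]
    bias = data[:, fields.index(bias_names[0])] if bias_names and len(data) else None
    return Trajectory(
        times=data[:, t_i] if len(data) else np.zeros(0),
        cv_matrix=data[:, cv_idx] if len(data) else np.zeros((0, len(cv_names))),
        cv_names=cv_names,
        bias_energy=bias,
    )
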