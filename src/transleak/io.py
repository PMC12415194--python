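"""Readers and writers for the package's tabular formats.

One tabular dialect throughout: headered CSV (UTF-8, decimal point).
Requenching tables carry the dose either as a normalized ``cp`` column
or as a lipid-to-peptide ratio ``lp`` column (converted via
``cp = lp_min / lp``, clipped to [0, 1] -- more peptide means lower L/P
and higher cp).  Free-energy profiles are two- or three-column text
(xi, F[, err]), whitespace- or comma-separated.  Reports are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .kinetics import LeakageTrace
from .landscape import FreeEnergyProfile
from .unified import RequenchCurve

__all__ = [
    "read_requench_csv",
    "write_requench_csv",
    "read_trace_csv",
    "write_traces_csv",
    "read_profile",
    "write_profile",
    "write_report",
    "lp_to_cp",
]


class TableFormatError(ValueError):
    """A tabular input failed validation; the message names the rows."""


def lp_to_cp(lp, lp_min: Optional[float] = None):
    """Map lipid-to-peptide ratios onto the normalized dose axis.

    ``cp = lp_min / lp`` clipped to [0, 1]; by default ``lp_min`` is the
    smallest (most peptide-rich) ratio observed, which maps it to
    ``cp = 1``.
    """
    lp = np.asarray(lp, dtype=float)
    if np.any(lp <= 0):
        raise ValueError("L/P ratios must be positive")
    if lp_min is None:
        lp_min = float(lp.min())
    return np.clip(lp_min / lp, 0.0, 1.0)


_REQUENCH_DEFAULTS = {"cp": "cp", "lp": "lp", "fout": "fout", "qin": "qin",
                      "qin_sd": "qin_sd"}


def read_requench_csv(
    path,
    columns: Optional[dict] = None,
    lp_min: Optional[float] = None,
) -> RequenchCurve:
    """Read a requenching table into a :class:`RequenchCurve`.

    ``columns`` remaps logical names (``cp``/``lp``, ``fout``, ``qin``,
    ``qin_sd``) onto the file's header.  Either a ``cp`` or an ``lp``
    column must be present.  Malformed cells are reported with their
    row numbers (1-based, excluding the header).
    """
    colmap = {**_REQUENCH_DEFAULTS, **(columns or {})}
    df = pd.read_csv(path)
    problems = []
    for logical in ("fout", "qin"):
        if colmap[logical] not in df.columns:
            raise TableFormatError(
                f"missing required column {colmap[logical]!r} in {path}"
            )
    has_cp = colmap["cp"] in df.columns
    has_lp = colmap["lp"] in df.columns
    if not (has_cp or has_lp):
        raise TableFormatError(f"need a {colmap['cp']!r} or {colmap['lp']!r} column")

    def numeric(logical):
        raw = df[colmap[logical]]
        vals = pd.to_numeric(raw, errors="coerce")
        for i in np.where(vals.isna() & raw.notna())[0]:
            problems.append(f"row {i + 1}: non-numeric {logical} value {raw.iloc[i]!r}")
        return vals.to_numpy(dtype=float)

    fout = numeric("fout")
    qin = numeric("qin")
    sd = numeric("qin_sd") if colmap["qin_sd"] in df.columns else None
    cp = numeric("cp") if has_cp else None
    lp = numeric("lp") if (has_lp and not has_cp) else None

    for i in range(len(df)):
        if not np.isnan(fout[i]) and not 0 <= fout[i] <= 1:
            problems.append(f"row {i + 1}: fout={fout[i]} outside [0, 1]")
        if not np.isnan(qin[i]) and not 0 < qin[i] <= 1:
            problems.append(f"row {i + 1}: qin={qin[i]} outside (0, 1]")
        if sd is not None and not np.isnan(sd[i]) and sd[i] < 0:
            problems.append(f"row {i + 1}: negative qin_sd={sd[i]}")
    if problems:
        raise TableFormatError("; ".join(problems))
    if lp is not None:
        cp = lp_to_cp(lp, lp_min)
    return RequenchCurve(fout=fout, qin=qin, sd=sd, cp=cp, source="experiment")


def write_requench_csv(curve: RequenchCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_trace_csv(
    path,
    time_col: str = "time_min",
    buffer_col: str = "buffer",
    triton_col: str = "triton",
    addition_times=(0.0,),
) -> dict[str, LeakageTrace]:
    """Read plate-reader time courses: one time column, one column per well.

    The named buffer and Triton wells provide ``f0`` and ``fmax`` (their
    time averages); every other column becomes a sample trace.
    """
    df = pd.read_csv(path)
    for col in (time_col, buffer_col, triton_col):
        if col not in df.columns:
            raise TableFormatError(f"missing column {col!r} in {path}")
    if df.isna().any().any():
        bad = sorted(set(np.where(df.isna())[0] + 1))
        raise TableFormatError(f"non-numeric or missing cells in rows {bad}")
    t = df[time_col].to_numpy(dtype=float)
    f0 = float(df[buffer_col].mean())
    fmax = float(df[triton_col].mean())
    traces = {}
    for col in df.columns:
        if col == time_col:
            continue
        traces[col] = LeakageTrace(
            time_min=t,
            fluorescence=df[col].to_numpy(dtype=float),
            f0=f0,
            fmax=fmax,
            addition_times=tuple(addition_times),
            label=col,
        )
    return traces


def write_traces_csv(traces: dict[str, LeakageTrace], path) -> None:
    first = next(iter(traces.values()))
    data = {"time_min": first.time_min}
    for name, tr in traces.items():
        data[name] = tr.fluorescence
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_profile(path, label: str = "", composition: str = "") -> FreeEnergyProfile:
    """Read a free-energy profile from 2-3 column text (xi, F[, err])."""
    path = Path(path)
    try:
        arr = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None,
                         ndmin=2)
    except ValueError:
        # fall back: maybe a CSV with a header row
        df = pd.read_csv(path)
        arr = df.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise TableFormatError("profile files need at least (xi, F) columns")
    err = arr[:, 2] if arr.shape[1] > 2 else None
    return FreeEnergyProfile(
        xi=arr[:, 0], f=arr[:, 1], err=err,
        label=label or path.stem, composition=composition,
    )


def write_profile(profile: FreeEnergyProfile, path) -> None:
    cols = [profile.xi, profile.f]
    if profile.err is not None:
        cols.append(profile.err)
    np.savetxt(path, np.column_stack(cols), fmt="%.12g")


def write_report(payload: dict, path, seed: Optional[int] = None) -> None:
    """Write a JSON report stamped with the seed and a config hash."""
    body = dict(payload)
    if seed is not None:
        body["seed"] = seed
    digest = hashlib.sha256(
        json.dumps(body, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    body["config_hash"] = digest
    Path(path).write_text(json.dumps(body, indent=2, default=str) + "\n")
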