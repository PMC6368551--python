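"""Delimited-text readers and writers for profiles, configs and peak lists.

Profiles travel as two-column CSV (depth_m, value) with ``# key=value``
metadata header lines carrying the tracer identity and units.  Transport
parameters, activity anchors and run configuration use YAML.  Peak lists are
two-column delimited text (mz, intensity) with '#' comments.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .domformula import ElementBounds, MassPeak
from .habitability import ActivityAnchor
from .transport import TracerProfile, TransportParams

__all__ = [
    "read_profile",
    "write_profile",
    "read_params_config",
    "read_anchors",
    "read_peak_list",
    "write_peak_list",
    "read_element_bounds",
]


def write_profile(profile: TracerProfile, path) -> None:
    """Write a profile as CSV with ``# tracer=`` / ``# units=`` header lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# tracer={profile.tracer}\n")
        fh.write(f"# units={profile.units}\n")
        fh.write("depth_m,value\n")
        for z, v in zip(profile.depths, profile.values):
            fh.write(f"{float(z)!r},{float(v)!r}\n")


def read_profile(path) -> TracerProfile:
    """Read a profile written by :func:`write_profile` (or compatible CSV)."""
    path = Path(path)
    meta = {"tracer": "unknown", "units": ""}
    body = []
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if "=" in stripped:
                key, _, val = stripped.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            continue
        body.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(body)))
    if not {"depth_m", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns depth_m,value, got {list(df.columns)}")
    return TracerProfile(
        tracer=meta["tracer"],
        depths=df["depth_m"].to_numpy(float),
        values=df["value"].to_numpy(float),
        units=meta["units"],
    )


_PARAM_KEYS = {"Ds", "Vs", "Rd", "C0", "Cbg"}


def _params_from_block(block: Mapping) -> TransportParams:
    unknown = set(block) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"unknown TransportParams keys: {sorted(unknown)}")
    if "Ds" not in block:
        raise ValueError("TransportParams block requires at least Ds")
    return TransportParams(**{k: float(v) for k, v in block.items()})


def read_params_config(path) -> dict[str, TransportParams]:
    """Read per-tracer transport parameters from a YAML config.

    Layout: either a flat mapping of tracer name -> parameter block, or the
    same nested under a top-level ``tracers:`` key.  Blocks may carry extra
    keys (``profile``, ``t`` ...) only in the full run config, not here.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, Mapping) or not data:
        raise ValueError(f"{path}: expected a mapping of tracer blocks")
    blocks = data.get("tracers", data)
    out = {}
    for tracer, block in blocks.items():
        if not isinstance(block, Mapping):
            raise ValueError(f"{path}: block for {tracer!r} must be a mapping")
        out[str(tracer)] = _params_from_block(block)
    return out


def read_anchors(path) -> list[ActivityAnchor]:
    """Read water-activity anchors from YAML: list of {conc, aw, source} maps."""
    data = yaml.safe_load(Path(path).read_text())
    if isinstance(data, Mapping) and "anchors" in data:
        data = data["anchors"]
    if not isinstance(data, list) or not data:
        raise ValueError(f"{path}: expected a non-empty list of anchors")
    return [
        ActivityAnchor(
            conc=float(a["conc"]), aw=float(a["aw"]), source=str(a.get("source", ""))
        )
        for a in data
    ]


def write_peak_list(peaks, path) -> None:
    """Write peaks as two-column delimited text: mz, intensity."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# mz,intensity\n")
        for p in peaks:
            fh.write(f"{float(p.mz)!r},{float(p.intensity)!r}\n")


def read_peak_list(path) -> list[MassPeak]:
    """Read a two-column (mz, intensity) delimited file; '#' lines are comments."""
    peaks = []
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = [p for p in stripped.replace("\t", ",").split(",") if p.strip()]
        if len(parts) not in (1, 2):
            raise ValueError(f"{path}: malformed peak line {line!r}")
        mz = float(parts[0])
        intensity = float(parts[1]) if len(parts) == 2 else 0.0
        peaks.append(MassPeak(mz=mz, intensity=intensity))
    if not peaks:
        raise ValueError(f"{path}: no peaks found")
    return peaks


def read_element_bounds(block: Mapping | None) -> ElementBounds:
    """Element bounds from a config mapping (missing keys keep DOM defaults)."""
    if not block:
        return ElementBounds()
    kwargs = {}
    for key in ("c", "h", "n", "o", "s"):
        if key in block:
            lo, hi = block[key]
            kwargs[key] = (int(lo), int(hi))
    for key in ("hc_range", "oc_range"):
        if key in block:
            lo, hi = block[key]
            kwargs[key] = (float(lo), float(hi))
    if "ppm_tol" in block:
        kwargs["ppm_tol"] = float(block["ppm_tol"])
    return ElementBounds(**kwargs)
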