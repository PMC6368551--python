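"""End-to-end orchestration: configuration, staged analysis, structured report.

A run config (YAML mapping) declares any subset of three stages:

``tracers``
    Per-tracer transport parameters plus a profile source, fitted singly and
    jointly for the sediment-brine contact time.
``interface``
    A halocline profile plus water-activity anchors; locates the a_w
    threshold depth and classifies each sample into layer/habitability.
``dom``
    One or two peak lists; assigns formulas and computes class statistics.

A profile source is either ``profile: <path>`` or a ``synthetic:`` block
(seeded), so the bundled demo config runs with no external data.  The report
is a plain dict (JSON-serializable); timestamps live only in the header so
report bodies are diffable across reruns.
"""

from __future__ import annotations

import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .domformula import (
    UndefinedRatioError,
    class_ratio,
    decompose_mass,
    neutral_mass_from_mz,
    sulfur_histogram,
    unique_shared_fraction,
)
from .habitability import (
    HEPHAESTUS_ANCHORS,
    ActivityAnchor,
    ThresholdNotCrossedError,
    assign_layer,
    classify_habitability,
    fit_activity_curve,
    locate_threshold_depth,
)
from .inversion import bootstrap_age_ci, fit_age
from .io import read_element_bounds, read_peak_list, read_profile
from .synthetic import make_interface_profile, preset_profile, NoiseSpec, PRESETS
from .transport import TransportParams

__all__ = ["demo_config", "run_pipeline", "load_config"]


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return dict(cfg)


def demo_config(seed: int = 1) -> dict:
    """A self-contained demo: all inputs from the bundled synthetic presets."""
    return {
        "seed": seed,
        "tracers": {
            "Mg": {"preset": "hephaestus_mg", "synthetic": {"seed": seed}},
            "Cl": {"preset": "hephaestus_cl", "synthetic": {"seed": seed + 1}},
            "dD": {"preset": "hephaestus_dD", "synthetic": {"seed": seed + 2}},
        },
        "t_bounds": [1e8, 1e12],
        "boot": 0,
        "interface": {
            "synthetic": {"shape": "logistic", "n": 31, "seed": seed + 3},
            "aw_threshold": 0.585,
        },
        "dom": {
            "synthetic": {"seed": seed + 4},
        },
    }


def _tracer_inputs(name: str, block: Mapping, default_seed):
    """Resolve one tracer block to (TracerProfile, TransportParams)."""
    if "preset" in block:
        preset = PRESETS[block["preset"]]
        params = preset.params
        t_true = preset.t
    else:
        keys = {k: float(block[k]) for k in ("Ds", "Vs", "Rd", "C0", "Cbg") if k in block}
        params = TransportParams(**keys)
        t_true = float(block.get("t", 0)) or None
    if "profile" in block:
        profile = read_profile(block["profile"])
    elif "synthetic" in block or "preset" in block:
        syn = dict(block.get("synthetic") or {})
        seed = syn.get("seed", default_seed)
        if "preset" in block:
            profile = preset_profile(
                block["preset"], seed=seed, sigma=syn.get("sigma"), t=syn.get("t")
            )
        else:
            from .synthetic import make_pore_profile

            if t_true is None:
                raise ValueError(f"tracer {name!r}: synthetic profile needs t")
            noise = NoiseSpec(
                kind=syn.get("kind", "relative-gaussian"),
                sigma=float(syn.get("sigma", 0.02)),
                seed=seed,
            )
            profile = make_pore_profile(params, t_true, noise=noise, tracer=name)
    else:
        raise ValueError(f"tracer {name!r}: needs a 'profile' path or 'synthetic' block")
    return profile, params


def _run_age_stage(cfg: Mapping, seed) -> dict:
    tracers = cfg["tracers"]
    t_bounds = tuple(float(x) for x in cfg.get("t_bounds", (1e8, 1e12)))
    n_boot = int(cfg.get("boot", 0))
    profiles, params = {}, {}
    for name, block in tracers.items():
        prof, par = _tracer_inputs(name, block, seed)
        profiles[name] = prof
        params[name] = par

    out: dict = {"per_tracer": {}, "t_bounds_s": list(t_bounds)}
    for name, prof in profiles.items():
        est = fit_age(prof, params[name], t_bounds=t_bounds)
        entry = {
            "t_seconds": est.t_seconds,
            "t_years": est.t_years,
            "rss": est.rss,
            "n_obs": est.n_obs,
        }
        if n_boot >= 2:
            lo, hi = bootstrap_age_ci(
                prof, params[name], n_boot=n_boot, seed=seed, t_bounds=t_bounds
            )
            entry["ci_years_95"] = [lo, hi]
        out["per_tracer"][name] = entry
    if len(profiles) > 1:
        joint = fit_age(list(profiles.values()), params, t_bounds=t_bounds)
        out["joint"] = {
            "t_seconds": joint.t_seconds,
            "t_years": joint.t_years,
            "rss": joint.rss,
            "n_obs": joint.n_obs,
            "per_tracer_rss": joint.per_tracer_rss,
        }
    return out


def _run_interface_stage(cfg: Mapping, seed) -> dict:
    block = cfg["interface"]
    if "profile" in block:
        profile = read_profile(block["profile"])
    else:
        syn = dict(block.get("synthetic") or {})
        noise = None
        if syn.get("sigma"):
            noise = NoiseSpec("relative-gaussian", float(syn["sigma"]), syn.get("seed", seed))
        profile = make_interface_profile(
            shape=syn.get("shape", "linear"), n=int(syn.get("n", 31)), noise=noise
        )
    anchors = block.get("anchors")
    if anchors:
        anchors = [
            ActivityAnchor(float(a["conc"]), float(a["aw"]), str(a.get("source", "")))
            for a in anchors
        ]
    else:
        anchors = HEPHAESTUS_ANCHORS
    curve = fit_activity_curve(anchors)
    threshold = float(block.get("aw_threshold", 0.585))

    out: dict = {
        "aw_threshold": threshold,
        "anchors": [{"conc": a.conc, "aw": a.aw, "source": a.source} for a in curve.anchors],
    }
    try:
        out["threshold_depth_m"] = locate_threshold_depth(profile, curve, threshold)
    except ThresholdNotCrossedError as exc:
        out["threshold_depth_m"] = None
        out["threshold_status"] = str(exc)
    samples = []
    for z, mg in zip(profile.depths, profile.values):
        res = classify_habitability(mg, curve)
        samples.append(
            {
                "depth_m": float(z),
                "mg_mM": float(mg),
                "aw": res.aw,
                "layer": assign_layer(max(mg, 0.0)),
                "status": res.status,
            }
        )
    out["samples"] = samples
    return out


# a small mixed CHNOS panel used by the synthetic DOM demo
_DEMO_FORMULAS = (
    (6, 12, 0, 6, 0), (16, 24, 0, 8, 0), (18, 34, 0, 2, 0), (12, 16, 0, 8, 0),
    (10, 15, 1, 4, 0), (14, 21, 1, 6, 0), (8, 13, 3, 2, 0),
    (10, 16, 0, 5, 1), (15, 26, 0, 6, 1), (12, 22, 0, 4, 2),
    (11, 17, 1, 5, 1), (13, 22, 2, 6, 1), (9, 15, 1, 3, 2),
)


def _run_dom_stage(cfg: Mapping, seed) -> dict:
    block = cfg["dom"]
    bounds = read_element_bounds(block.get("bounds"))
    if "peaks" in block or "peaks_a" in block:
        peaks_a = read_peak_list(block.get("peaks") or block["peaks_a"])
        peaks_b = read_peak_list(block["peaks_b"]) if "peaks_b" in block else None
    else:
        from .synthetic import make_peak_list

        syn = dict(block.get("synthetic") or {})
        peaks_a, _ = make_peak_list(
            _DEMO_FORMULAS, ppm_jitter=float(syn.get("ppm_jitter", 0.1)),
            seed=syn.get("seed", seed),
        )
        peaks_b = None

    def _assign(peaks):
        hits = []
        unassigned = 0
        for p in peaks:
            cands = decompose_mass(neutral_mass_from_mz(p.mz), bounds)
            if cands:
                hits.append((p, cands[0]))
            else:
                unassigned += 1
        return hits, unassigned

    hits, unassigned = _assign(peaks_a)
    assignments = [a for _, a in hits]
    classes: dict[str, int] = {}
    for a in assignments:
        classes[a.cls] = classes.get(a.cls, 0) + 1
    out: dict = {
        "n_peaks": len(peaks_a),
        "n_assigned": len(hits),
        "n_unassigned": unassigned,
        "class_counts": dict(sorted(classes.items())),
        "sulfur_histogram": {str(k): v for k, v in sulfur_histogram(assignments).items()},
        "ppm_tol": bounds.ppm_tol,
    }
    for num, den, key in (("CHOS", "CHO", "chos_cho"), ("CHNOS", "CHNO", "chnos_chno")):
        try:
            out[f"ratio_{key}"] = class_ratio(assignments, num, den)
        except UndefinedRatioError:
            out[f"ratio_{key}"] = None
    if peaks_b is not None:
        hits_b, _ = _assign(peaks_b)
        pct_unique, pct_shared = unique_shared_fraction(
            assignments, [a for _, a in hits_b]
        )
        out["pct_unique_between_samples"] = pct_unique
        out["pct_shared_between_samples"] = pct_shared
    return out


def run_pipeline(config: Mapping, seed: int | None = None) -> dict:
    """Execute every configured stage; report per-stage results or errors.

    Deterministic given the config (and ``seed``, which backstops any
    synthetic block that does not carry its own).  Stages without inputs are
    marked skipped; a stage failure is recorded per stage without aborting
    the others.
    """
    seed = seed if seed is not None else config.get("seed")
    report: dict = {
        "header": {
            "package": "brineage",
            "version": __version__,
            "python": platform.python_version(),
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
            "seed": seed,
        },
        "stages": {},
    }
    stages = (
        ("ages", "tracers", _run_age_stage),
        ("interface", "interface", _run_interface_stage),
        ("dom", "dom", _run_dom_stage),
    )
    for stage_name, key, runner in stages:
        if key not in config or not config[key]:
            report["stages"][stage_name] = {"skipped": "no inputs configured"}
            continue
        try:
            report["stages"][stage_name] = runner(config, seed)
        except Exception as exc:  # reported per stage, never silent
            report["stages"][stage_name] = {"error": f"{type(exc).__name__}: {exc}"}
    return report
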