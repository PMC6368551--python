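"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline's inputs end to end:

* pore-water tracer profiles from the closed-form transport model plus
  measurement noise, with presets encoding the published parameter sets of
  the Hephaestus and Discovery systems;
* interface haloclines (Mg2+ vs depth) with linear or logistic shape,
  defaulting to the observed 70 -> 4,720 mM gradient over ~3 m;
* negative-mode mass-peak lists from known CHNOS formulas with ppm jitter
  and lognormal intensities, returned together with their ground truth for
  recovery tests.

Every generator is a pure function of its arguments, including the seed.
Default noise levels (2 % relative for ion chromatography, 0.5 permil
absolute for delta-D by IRMS) are declared assumptions: replicate variances
for the real measurements were never published.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .domformula import PROTON_MASS, MassPeak, exact_neutral_mass
from .transport import TracerProfile, TransportParams, profile_curve

__all__ = [
    "NoiseSpec",
    "Preset",
    "PRESETS",
    "DEFAULT_CORE_DEPTHS",
    "make_pore_profile",
    "preset_profile",
    "make_interface_profile",
    "make_peak_list",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for synthetic profiles.

    kind 'relative-gaussian' scales sigma by the signal magnitude (ion
    chromatography); 'absolute-gaussian' adds sigma in tracer units (IRMS
    delta values).  sigma is the single-assay standard deviation; when
    ``replicates`` > 1 the reported value is the mean of that many
    independent assays, as with triplicate isotope measurements.
    sigma = 0 reproduces the noise-free model exactly.
    """

    kind: str = "relative-gaussian"
    sigma: float = 0.02
    seed: int | None = None
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("relative-gaussian", "absolute-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.sigma == 0:
            return np.asarray(values, dtype=float).copy()
        rng = np.random.default_rng(self.seed)
        values = np.asarray(values, dtype=float)
        if self.kind == "relative-gaussian":
            scale = self.sigma * np.abs(values)
        else:
            scale = np.full_like(values, self.sigma)
        noise = rng.normal(0.0, 1.0, (self.replicates,) + values.shape).mean(axis=0)
        return values + noise * scale


@dataclass(frozen=True)
class Preset:
    """A published parameter set for one tracer of one brine system."""

    params: TransportParams
    t: float
    tracer: str
    units: str
    noise: NoiseSpec


# Shared Hephaestus transport parameters: Ds = 2.4e-10 m2/s, Vs = 9.51e-11 m/s
# (delta-D uses the free-water-scaled Ds = 2.96e-10).  Boundary values are the
# brine column, backgrounds the Mediterranean seawater endmember.  Timings:
# 2.2e10 s (~700 y) for Hephaestus, 63.1e9 s (~2,000 y) for Discovery.
_ION_NOISE = NoiseSpec("relative-gaussian", 0.02)
# delta-D values are reported as the mean of three replicate assays
_DD_NOISE = NoiseSpec("absolute-gaussian", 0.5, replicates=3)

PRESETS: dict[str, Preset] = {
    "hephaestus_mg": Preset(
        TransportParams(Ds=2.4e-10, Vs=9.51e-11, C0=4720.0, Cbg=61.0),
        t=2.2e10, tracer="Mg", units="mmol/kg", noise=_ION_NOISE,
    ),
    "hephaestus_cl": Preset(
        TransportParams(Ds=2.4e-10, Vs=9.51e-11, C0=9120.0, Cbg=630.0),
        t=2.2e10, tracer="Cl", units="mmol/kg", noise=_ION_NOISE,
    ),
    "hephaestus_dD": Preset(
        TransportParams(Ds=2.96e-10, Vs=9.51e-11, C0=-16.5, Cbg=5.1),
        t=2.2e10, tracer="dD", units="permil-VSMOW", noise=_DD_NOISE,
    ),
    "discovery_cl": Preset(
        TransportParams(Ds=2.4e-10, Vs=9.51e-11, C0=10150.0, Cbg=630.0),
        t=63.1e9, tracer="Cl", units="mmol/kg", noise=_ION_NOISE,
    ),
    "discovery_mg": Preset(
        TransportParams(Ds=2.4e-10, Vs=9.51e-11, C0=5150.0, Cbg=61.0),
        t=63.1e9, tracer="Mg", units="mmol/kg", noise=_ION_NOISE,
    ),
}

#: Sampling depths of a 3.2-m core at 0.2-m resolution.
DEFAULT_CORE_DEPTHS = np.round(np.arange(0.0, 3.2001, 0.2), 10)


def make_pore_profile(
    params: TransportParams,
    t: float,
    depths: Sequence[float] | None = None,
    noise: NoiseSpec | None = None,
    tracer: str = "model",
    units: str = "",
) -> TracerProfile:
    """Forward-model a pore-water profile and add measurement noise.

    With ``noise=None`` or sigma 0 the output equals ``profile_curve``
    exactly; otherwise it is seeded and reproducible.
    """
    if depths is None:
        depths = DEFAULT_CORE_DEPTHS
    clean = profile_curve(depths, t, params, tracer=tracer, units=units)
    if noise is None:
        return clean
    return TracerProfile(
        tracer=tracer, depths=clean.depths, values=noise.apply(clean.values),
        units=units,
    )


def preset_profile(
    name: str,
    seed: int | None = None,
    depths: Sequence[float] | None = None,
    t: float | None = None,
    sigma: float | None = None,
) -> TracerProfile:
    """Generate a profile from a named preset with a fresh noise seed."""
    try:
        preset = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    noise = NoiseSpec(
        kind=preset.noise.kind,
        sigma=preset.noise.sigma if sigma is None else sigma,
        seed=seed,
        replicates=preset.noise.replicates,
    )
    return make_pore_profile(
        preset.params,
        preset.t if t is None else t,
        depths=depths,
        noise=noise,
        tracer=preset.tracer,
        units=preset.units,
    )


def make_interface_profile(
    top_mg: float = 70.0,
    bottom_mg: float = 4720.0,
    thickness: float = 3.0,
    shape: str = "linear",
    n: int = 31,
    noise: NoiseSpec | None = None,
    steepness: float = 4.0,
) -> TracerProfile:
    """Synthetic halocline: Mg2+ (mM) vs depth below the interface top.

    'linear' ramps uniformly; 'logistic' is a sigmoid centred mid-interface
    (steepness in units of 1/thickness), rescaled to hit both endpoints
    exactly.  Monotone non-decreasing with depth before noise.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if bottom_mg < top_mg:
        raise ValueError("bottom_mg must be >= top_mg (brine below seawater)")
    z = np.linspace(0.0, thickness, n)
    if shape == "linear":
        frac = z / thickness
    elif shape == "logistic":
        s = 1.0 / (1.0 + np.exp(-steepness * (2.0 * z / thickness - 1.0)))
        frac = (s - s[0]) / (s[-1] - s[0])
    else:
        raise ValueError(f"shape must be 'linear' or 'logistic', got {shape!r}")
    mg = top_mg + (bottom_mg - top_mg) * frac
    if noise is not None:
        mg = noise.apply(mg)
    return TracerProfile(tracer="Mg", depths=z, values=mg, units="mM")


def make_peak_list(
    formulas: Sequence[Sequence[int]],
    ppm_jitter: float = 0.2,
    intensity_mu: float = 10.0,
    intensity_sigma: float = 1.0,
    seed: int | None = None,
) -> tuple[list[MassPeak], pd.DataFrame]:
    """Negative-mode peak list from known formulas, with its ground truth.

    Each formula's exact [M-H]- m/z gets multiplicative mass error
    eps ~ Normal(0, ppm_jitter * 1e-6) and a lognormal intensity.  Returns
    (peaks, truth) where truth tabulates counts, exact neutral mass, exact
    and jittered m/z per row, aligned with the peak list.
    """
    if ppm_jitter < 0:
        raise ValueError("ppm_jitter must be >= 0")
    formulas = [tuple(int(x) for x in f) for f in formulas]
    if not formulas:
        raise ValueError("at least one formula is required")
    rng = np.random.default_rng(seed)
    rows = []
    peaks = []
    for counts in formulas:
        if len(counts) != 5 or any(c < 0 for c in counts):
            raise ValueError(f"formula counts must be 5 non-negative ints, got {counts}")
        neutral = exact_neutral_mass(counts)
        mz_exact = neutral - PROTON_MASS
        eps = rng.normal(0.0, ppm_jitter * 1e-6) if ppm_jitter > 0 else 0.0
        mz = mz_exact * (1.0 + eps)
        intensity = float(rng.lognormal(intensity_mu, intensity_sigma))
        peaks.append(MassPeak(mz=mz, intensity=intensity))
        rows.append(
            {
                "nC": counts[0], "nH": counts[1], "nN": counts[2],
                "nO": counts[3], "nS": counts[4],
                "neutral_mass": neutral, "mz_exact": mz_exact, "mz": mz,
                "intensity": intensity,
            }
        )
    return peaks, pd.DataFrame(rows)
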