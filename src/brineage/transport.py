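"""Closed-form 1-D advection-diffusion transport of a tracer in sediment pore water.

A dense brine ponded above the sediment acts as a constant-concentration
reservoir at the sediment-water interface (z = 0, positive downward).  The
tracer obeys Fick's second law with advection,

    dC/dt = Ds d2C/dz2 - Vs dC/dz,

with boundary condition C(0, t) = C0 and initial condition C(z, 0) = Cbg.
The classical analytical solution (Ogata-Banks form) on the
dimensionless scale F in [0, 1] is

    F(z, t) = 1/2 [ erfc((z - Vs t) / (2 sqrt(Dh t / Rd)))
                  + exp(Vs z / Dh) erfc((z + Vs t) / (2 sqrt(Dh t / Rd))) ]

with Dh = Ds for a nonreactive tracer (Rd = 1).  Concentrations are mapped
affinely onto [Cbg, C0], which lets the same solution fit tracers whose deep
background is non-zero (ions relaxing to seawater values, or delta-D relaxing
upward to seawater isotopic composition).

The exponential term overflows for depths beyond roughly a metre at typical
parameters; it is evaluated through the scaled complementary error function
erfcx(x) = exp(x^2) erfc(x), which is finite everywhere it is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erfc, erfcx

__all__ = [
    "SECONDS_PER_YEAR",
    "TransportParams",
    "TracerProfile",
    "analytic_concentration",
    "profile_curve",
    "seconds_to_years",
    "scale_diffusivity",
]

#: Julian year (365.25 d); reproduces the printed seconds <-> years pairings.
SECONDS_PER_YEAR = 3.15576e7


@dataclass(frozen=True)
class TransportParams:
    """Physical parameters of the 1-D transport model for one tracer.

    Parameters
    ----------
    Ds : float
        Effective sediment diffusion coefficient (tortuosity-corrected),
        m^2 s^-1.  Must be positive.
    Vs : float
        Average linear pore-water velocity (advection rate), m s^-1,
        positive downward.  Must be non-negative.
    Rd : float
        Retardation factor, dimensionless, >= 1.  Defaults to 1
        (nonreactive tracer); the hydrodynamic dispersion coefficient Dh
        is taken equal to Ds.
    C0 : float
        Brine-side boundary value of the tracer at z = 0, in tracer units.
    Cbg : float
        Far-field (deep background) value of the tracer, same units.
        C0 == Cbg is permitted but gives a degenerate constant profile.
    """

    Ds: float
    Vs: float = 0.0
    Rd: float = 1.0
    C0: float = 1.0
    Cbg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Ds", "Vs", "Rd", "C0", "Cbg"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.Ds <= 0:
            raise ValueError(f"Ds must be positive, got {self.Ds}")
        if self.Vs < 0:
            raise ValueError(f"Vs must be non-negative, got {self.Vs}")
        if self.Rd < 1:
            raise ValueError(f"Rd must be >= 1, got {self.Rd}")

    @property
    def span(self) -> float:
        """|C0 - Cbg|, the concentration span bridged by the profile."""
        return abs(self.C0 - self.Cbg)

    def with_(self, **kwargs) -> "TransportParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TracerProfile:
    """Depth-ordered tracer observations below the sediment-water interface.

    Depths are metres below the interface (z >= 0, strictly increasing);
    values are the tracer measurements at those depths (mmol kg^-1 for ions,
    permil vs VSMOW for delta-D).
    """

    tracer: str
    depths: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "values", values)
        if depths.ndim != 1 or values.ndim != 1:
            raise ValueError("depths and values must be 1-D")
        if depths.size != values.size:
            raise ValueError("depths and values must have equal length")
        if depths.size < 1:
            raise ValueError("profile needs at least one observation")
        if not (np.isfinite(depths).all() and np.isfinite(values).all()):
            raise ValueError("profile contains non-finite entries")
        if (depths < 0).any():
            raise ValueError("depths must be >= 0 (metres below interface)")
        if depths.size > 1 and not (np.diff(depths) > 0).all():
            raise ValueError("depths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.depths.size)


def _validate_time(t: float) -> float:
    t = float(t)
    if not np.isfinite(t) or t <= 0:
        raise ValueError(f"time must be finite and positive, got {t!r}")
    return t


def dimensionless_solution(z, t: float, params: TransportParams):
    """Dimensionless breakthrough F(z, t) in [0, 1] (F = 1 at the boundary).

    Evaluated with the erfcx identity  exp(a) erfc(b) = erfcx(b) exp(a - b^2)
    for the second term; with z >= 0, Vs >= 0 and Rd >= 1 the exponent
    a - b^2 <= 0, so the evaluation never overflows.
    """
    t = _validate_time(t)
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("depths must be finite")
    if (z < 0).any():
        raise ValueError("depths must be >= 0")

    Dh = params.Ds  # Dh ~= Ds for a nonreactive tracer
    denom = 2.0 * np.sqrt(Dh * t / params.Rd)
    a1 = (z - params.Vs * t) / denom
    a2 = (z + params.Vs * t) / denom
    expo = params.Vs * z / Dh - a2 * a2
    F = 0.5 * (erfc(a1) + erfcx(a2) * np.exp(expo))
    return np.clip(F, 0.0, 1.0)


def analytic_concentration(z, t: float, params: TransportParams):
    """Tracer concentration at depth ``z`` (m) and time ``t`` (s).

    Returns ``Cbg + (C0 - Cbg) * F(z, t)`` where F is the dimensionless
    closed-form solution; scalar in, scalar out, array in, array out.

    Raises
    ------
    ValueError
        If ``t <= 0`` or any input is non-finite or ``z < 0``.
    """
    F = dimensionless_solution(z, t, params)
    out = params.Cbg + (params.C0 - params.Cbg) * F
    if np.ndim(z) == 0:
        return float(out)
    return out


def profile_curve(
    depths,
    t: float,
    params: TransportParams,
    tracer: str = "model",
    units: str = "",
) -> TracerProfile:
    """Forward-model a whole profile: element-wise ``analytic_concentration``.

    For C0 > Cbg and Vs >= 0 the returned values are non-increasing in depth.
    """
    depths = np.asarray(depths, dtype=float)
    values = analytic_concentration(depths, t, params)
    return TracerProfile(tracer=tracer, depths=depths, values=np.asarray(values), units=units)


def seconds_to_years(t: float) -> float:
    """Convert a time in seconds to Julian years (1 yr = 3.15576e7 s)."""
    t = float(t)
    if not np.isfinite(t) or t < 0:
        raise ValueError(f"time must be finite and non-negative, got {t!r}")
    return t / SECONDS_PER_YEAR


def scale_diffusivity(Ds_ref: float, Dfree_ref: float, Dfree_target: float) -> float:
    """Scale an effective sediment diffusivity to another tracer.

    Tortuosity correction is assumed tracer-independent, so the effective
    sediment diffusion coefficient of the target tracer is the reference one
    scaled by the ratio of free-water diffusivities:

        Ds_target = Ds_ref * (Dfree_target / Dfree_ref)

    This mirrors how a water-isotope diffusivity is adapted from the ionic
    (chloride) sediment value.
    """
    for name, v in (("Ds_ref", Ds_ref), ("Dfree_ref", Dfree_ref), ("Dfree_target", Dfree_target)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be finite and positive, got {v!r}")
    return Ds_ref * (Dfree_target / Dfree_ref)
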