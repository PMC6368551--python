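"""Water-activity structure and habitability of a seawater-brine interface.

A thin (~3 m) halocline separates Mediterranean seawater (Mg2+ ~ 70 mM at
its top) from an underlying MgCl2 brine (~4,720 mM).  Samples along the
gradient are binned into the named interface fractions (UIF / MIF / LIF)
by their Mg2+ concentration; a monotone interpolation through measured
(MgCl2 concentration, water activity) anchor points maps any concentration
to an approximate water activity; and two habitability criteria are
evaluated against it:

* the recognized water-activity limit for cell division, a_w = 0.585;
* the deepest layer where metabolically active microbes were actually
  detected in this system, 2,970 mM Mg2+.

Water activity depends on the full ionic composition of the brine, not on
MgCl2 concentration alone, so anchor sets from different brine systems must
not be mixed into one curve: ``fit_activity_curve`` refuses anchors with
conflicting source labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .transport import TracerProfile

__all__ = [
    "ActivityAnchor",
    "ActivityCurve",
    "InterfaceLayer",
    "HabitabilityResult",
    "ThresholdNotCrossedError",
    "NonMonotoneAnchorsError",
    "HEPHAESTUS_ANCHORS",
    "DEFAULT_LAYERS",
    "AW_LIMIT",
    "OBSERVED_MG_LIMIT_MM",
    "assign_layer",
    "fit_activity_curve",
    "locate_threshold_depth",
    "classify_habitability",
]

#: Recognized water-activity limit for cell division (xerophile limit).
AW_LIMIT = 0.585

#: Deepest Mg2+ layer (mM) with detected metabolic activity in this system.
OBSERVED_MG_LIMIT_MM = 2970.0


class ThresholdNotCrossedError(ValueError):
    """The requested water-activity threshold is not crossed by the profile."""


class NonMonotoneAnchorsError(ValueError):
    """Anchor set implies a non-decreasing a_w vs concentration."""


@dataclass(frozen=True)
class ActivityAnchor:
    """A measured (MgCl2 concentration, water activity) calibration point.

    conc is in mol L^-1; aw is dimensionless in (0, 1]; source labels the
    brine system the measurement belongs to.
    """

    conc: float
    aw: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.aw <= 1):
            raise ValueError(f"aw must be in (0, 1], got {self.aw}")
        if self.conc < 0:
            raise ValueError(f"conc must be >= 0, got {self.conc}")


#: Sparse anchors for the Hephaestus system: seawater endmember, the deepest
#: biologically active interface layer, and the brine itself.
HEPHAESTUS_ANCHORS = (
    ActivityAnchor(0.061, 0.980, "hephaestus"),
    ActivityAnchor(2.97, 0.653, "hephaestus"),
    ActivityAnchor(4.72, 0.395, "hephaestus"),
)


class ActivityCurve:
    """Monotone-decreasing map from MgCl2 concentration (M) to water activity.

    Shape-preserving monotone cubic (PCHIP) through the anchors: exact at
    every anchor, strictly decreasing between them, no overshoot.  Queries
    outside the anchored concentration range raise, since the relation is
    empirical and extrapolation is unsupported.
    """

    def __init__(self, anchors: Sequence[ActivityAnchor]):
        anchors = sorted(anchors, key=lambda a: a.conc)
        if len(anchors) < 2:
            raise ValueError("an activity curve needs at least 2 anchors")
        conc = np.array([a.conc for a in anchors])
        aw = np.array([a.aw for a in anchors])
        if (np.diff(conc) <= 0).any():
            raise ValueError("anchor concentrations must be distinct")
        if (np.diff(aw) >= 0).any():
            raise NonMonotoneAnchorsError(
                "water activity must decrease strictly with MgCl2 concentration; "
                f"got aw={aw.tolist()} at conc={conc.tolist()} M"
            )
        sources = {a.source for a in anchors if a.source}
        if len(sources) > 1:
            raise ValueError(
                "anchors from different brine systems cannot form one curve "
                f"(a_w depends on full ion composition): sources={sorted(sources)}"
            )
        self.anchors = tuple(anchors)
        self._lo, self._hi = float(conc[0]), float(conc[-1])
        self._interp = PchipInterpolator(conc, aw, extrapolate=False)

    @property
    def conc_range(self) -> tuple[float, float]:
        return (self._lo, self._hi)

    def __call__(self, conc):
        conc = np.asarray(conc, dtype=float)
        if ((conc < self._lo) | (conc > self._hi)).any():
            raise ValueError(
                f"concentration outside anchored range [{self._lo}, {self._hi}] M"
            )
        out = self._interp(conc)
        return float(out) if out.ndim == 0 else out


def fit_activity_curve(anchors: Iterable[ActivityAnchor]) -> ActivityCurve:
    """Build a monotone activity curve through measured anchors.

    Raises ``NonMonotoneAnchorsError`` for anchor sets implying a_w rising
    with concentration and ``ValueError`` for fewer than 2 anchors,
    duplicate concentrations or mixed source labels.
    """
    return ActivityCurve(list(anchors))


@dataclass(frozen=True)
class InterfaceLayer:
    """A named interface fraction with its Mg2+ concentration range (mM)."""

    name: str
    mg_lo: float
    mg_hi: float
    lo_inclusive: bool = True
    hi_inclusive: bool = True

    def contains(self, mg: float) -> bool:
        above = mg >= self.mg_lo if self.lo_inclusive else mg > self.mg_lo
        below = mg <= self.mg_hi if self.hi_inclusive else mg < self.mg_hi
        return above and below


#: Printed layer bounds are inclusive at both ends; the unsampled intervals
#: between them are a distinct GAP class.  The 4,120-4,720 mM fraction was
#: never analysed biologically (treat BRINE-adjacent findings as unassessed,
#: not lifeless).
DEFAULT_LAYERS = (
    InterfaceLayer("SEAWATER", 0.0, 70.0, hi_inclusive=False),
    InterfaceLayer("UIF", 70.0, 1500.0),
    InterfaceLayer("GAP", 1500.0, 2080.0, lo_inclusive=False, hi_inclusive=False),
    InterfaceLayer("MIF", 2080.0, 2800.0),
    InterfaceLayer("GAP", 2800.0, 3050.0, lo_inclusive=False, hi_inclusive=False),
    InterfaceLayer("LIF", 3050.0, 4120.0),
    InterfaceLayer("BRINE", 4120.0, float("inf"), lo_inclusive=False),
)


def assign_layer(mg: float, layers: Sequence[InterfaceLayer] = DEFAULT_LAYERS) -> str:
    """Name of the interface fraction containing Mg2+ concentration ``mg`` (mM)."""
    mg = float(mg)
    if not np.isfinite(mg) or mg < 0:
        raise ValueError(f"mg must be finite and >= 0, got {mg!r}")
    for layer in layers:
        if layer.contains(mg):
            return layer.name
    raise ValueError(f"no layer covers {mg} mM")  # unreachable with defaults


def locate_threshold_depth(
    interface_profile: TracerProfile,
    curve: ActivityCurve,
    aw_threshold: float = AW_LIMIT,
) -> float:
    """Depth (m) at which water activity first drops to ``aw_threshold``.

    The profile holds Mg2+ in mM versus depth; each sample is mapped to a_w
    through the curve, and the crossing depth is found by linear
    interpolation in depth between the bracketing samples.

    Raises ``ThresholdNotCrossedError`` if the threshold lies outside the
    profile's a_w range.
    """
    depths = interface_profile.depths
    aw = np.asarray(curve(interface_profile.values / 1000.0))  # mM -> M
    if len(interface_profile) < 2:
        raise ValueError("need at least 2 samples to locate a crossing")
    for i in range(aw.size - 1):
        hi_aw, lo_aw = aw[i], aw[i + 1]
        if hi_aw >= aw_threshold >= lo_aw:
            if hi_aw == lo_aw:
                return float(depths[i])
            frac = (hi_aw - aw_threshold) / (hi_aw - lo_aw)
            return float(depths[i] + frac * (depths[i + 1] - depths[i]))
    raise ThresholdNotCrossedError(
        f"a_w={aw_threshold} not crossed: profile spans a_w "
        f"[{aw.min():.3f}, {aw.max():.3f}]"
    )


@dataclass(frozen=True)
class HabitabilityResult:
    """Joint evaluation of both habitability criteria at one Mg2+ level.

    ``status`` is the overall call: 'below-observed-limit' wherever the
    sample is deeper than the deepest observed active community, otherwise
    'below-aw-limit' if a_w is under the recognized limit, otherwise
    'active-window'.  The individual criteria are reported alongside.
    """

    status: str
    mg_mM: float
    aw: float
    below_observed_limit: bool
    below_aw_limit: bool


def classify_habitability(
    mg: float,
    curve: ActivityCurve,
    recognized_aw_limit: float = AW_LIMIT,
    observed_mg_limit: float = OBSERVED_MG_LIMIT_MM,
) -> HabitabilityResult:
    """Classify a sample at Mg2+ concentration ``mg`` (mM) against both limits."""
    mg = float(mg)
    if mg < 0:
        raise ValueError("mg must be >= 0")
    aw = float(curve(mg / 1000.0))
    below_obs = mg > observed_mg_limit
    below_aw = aw < recognized_aw_limit
    if below_obs:
        status = "below-observed-limit"
    elif below_aw:
        status = "below-aw-limit"
    else:
        status = "active-window"
    return HabitabilityResult(
        status=status, mg_mM=mg, aw=aw,
        below_observed_limit=below_obs, below_aw_limit=below_aw,
    )
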