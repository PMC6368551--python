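"""CHNOS molecular-formula assignment for ultra-high-resolution mass lists.

Negative-mode FT-ICR-MS of dissolved organic matter (DOM) yields centroided
peak lists of (m/z, intensity).  Assuming singly charged deprotonated ions
[M-H]-, each peak's neutral monoisotopic mass is the measured m/z plus one
proton mass.  An exhaustive bounded search over integer elemental
compositions C_c H_h N_n O_o S_s finds every formula whose exact mass lies
within a ppm tolerance of the neutral mass, filtered by chemical
plausibility:

* RDBE = C - H/2 + N/2 + 1 >= 0 and integer (even-electron neutral);
* H/C and O/C within the ranges typical of natural DOM.

Assignments are branded into compound classes CHO / CHNO / CHOS / CHNOS by
their heteroatom content, from which the derived products are computed:
van Krevelen coordinates (O/C vs H/C, with the O/C > 0.6 "highly
oxygenated" flag), class count ratios, sulfur-count histograms, and the
fraction of formulas unique to either of two samples.

Monoisotopic masses are IUPAC values; C is exactly 12 u by definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PROTON_MASS",
    "MONOISOTOPIC_MASS",
    "MassPeak",
    "ElementBounds",
    "FormulaAssignment",
    "UndefinedRatioError",
    "DOM_DEFAULT_BOUNDS",
    "neutral_mass_from_mz",
    "exact_neutral_mass",
    "rdbe",
    "decompose_mass",
    "classify_class",
    "class_ratio",
    "van_krevelen",
    "sulfur_histogram",
    "unique_shared_fraction",
]

PROTON_MASS = 1.00727646677  # u

MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

_ELEMENTS = ("C", "H", "N", "O", "S")

#: Refuse decompositions whose candidate grid would exceed this size.
MAX_CANDIDATES = 10_000_000


class UndefinedRatioError(ZeroDivisionError):
    """A class count ratio with an empty denominator class."""


@dataclass(frozen=True)
class MassPeak:
    """A centroided mass peak: measured m/z (u, singly charged) and intensity."""

    mz: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class ElementBounds:
    """Per-element count bounds and plausibility filters for the search.

    Each element gets an inclusive (min, max) count range; ppm_tol is the
    mass-matching tolerance; hc_range and oc_range bound the H/C and O/C
    atomic ratios.
    """

    c: tuple[int, int] = (1, 60)
    h: tuple[int, int] = (1, 120)
    n: tuple[int, int] = (0, 3)
    o: tuple[int, int] = (0, 40)
    s: tuple[int, int] = (0, 3)
    ppm_tol: float = 0.2
    hc_range: tuple[float, float] = (0.3, 2.5)
    oc_range: tuple[float, float] = (0.0, 1.2)

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s"):
            lo, hi = getattr(self, name)
            if lo < 0 or lo > hi:
                raise ValueError(f"bounds for {name.upper()} must satisfy 0 <= min <= max")
        if self.ppm_tol <= 0:
            raise ValueError("ppm_tol must be positive")

    def with_tol(self, ppm_tol: float) -> "ElementBounds":
        from dataclasses import replace

        return replace(self, ppm_tol=ppm_tol)

    @property
    def grid_size(self) -> int:
        """Candidate count of the (C, N, O, S) grid (H is solved for)."""
        n = 1
        for name in ("c", "n", "o", "s"):
            lo, hi = getattr(self, name)
            n *= hi - lo + 1
        return n


#: Bounds typical of solid-phase-extracted marine/brine DOM in ESI(-).
DOM_DEFAULT_BOUNDS = ElementBounds()


@dataclass(frozen=True)
class FormulaAssignment:
    """An elemental composition matched to an observed neutral mass.

    counts are (nC, nH, nN, nO, nS); neutral_mass is the formula's exact
    monoisotopic mass; ppm_error is signed, (exact - observed)/observed*1e6.
    """

    counts: tuple[int, int, int, int, int]
    neutral_mass: float
    ppm_error: float
    cls: str
    hc: float
    oc: float
    rdbe: float

    @property
    def formula(self) -> str:
        parts = []
        for sym, n in zip(_ELEMENTS, self.counts):
            if n == 1:
                parts.append(sym)
            elif n > 1:
                parts.append(f"{sym}{n}")
        return "".join(parts)


def neutral_mass_from_mz(mz: float, mode: str = "negative") -> float:
    """Neutral monoisotopic mass of a singly charged deprotonated ion.

    In negative mode the observed species is [M-H]-, so M = m/z + m_proton.
    """
    if mode != "negative":
        raise ValueError(f"only negative mode ([M-H]-) is supported, got {mode!r}")
    mz = float(mz)
    if mz <= PROTON_MASS:
        raise ValueError(f"mz must exceed the proton mass, got {mz}")
    return mz + PROTON_MASS


def exact_neutral_mass(counts: Sequence[int]) -> float:
    """Exact monoisotopic mass (u) of the neutral formula with given counts."""
    return float(sum(n * MONOISOTOPIC_MASS[s] for s, n in zip(_ELEMENTS, counts)))


def rdbe(counts: Sequence[int]) -> float:
    """Rings-plus-double-bond equivalents: C - H/2 + N/2 + 1."""
    nc, nh, nn, _, _ = counts
    return nc - nh / 2.0 + nn / 2.0 + 1.0


def classify_class(counts: Sequence[int]) -> str:
    """Compound class of a composition: CHO / CHNO / CHOS / CHNOS.

    All four class names contain C, H and O, so compositions lacking any of
    those are 'unclassified'.
    """
    nc, nh, nn, no, ns = counts
    if nc <= 0 or nh <= 0 or no <= 0:
        return "unclassified"
    if nn > 0 and ns > 0:
        return "CHNOS"
    if ns > 0:
        return "CHOS"
    if nn > 0:
        return "CHNO"
    return "CHO"


@lru_cache(maxsize=8)
def _candidate_grid(c, n, o, s):
    """Flattened (C, N, O, S) count grid and its base masses, cached per bounds."""
    cc, nn, oo, ss = np.meshgrid(
        np.arange(c[0], c[1] + 1),
        np.arange(n[0], n[1] + 1),
        np.arange(o[0], o[1] + 1),
        np.arange(s[0], s[1] + 1),
        indexing="ij",
    )
    cc, nn, oo, ss = (a.ravel() for a in (cc, nn, oo, ss))
    base = (
        cc * MONOISOTOPIC_MASS["C"]
        + nn * MONOISOTOPIC_MASS["N"]
        + oo * MONOISOTOPIC_MASS["O"]
        + ss * MONOISOTOPIC_MASS["S"]
    )
    return cc, nn, oo, ss, base


def decompose_mass(
    neutral: float, bounds: ElementBounds = DOM_DEFAULT_BOUNDS
) -> list[FormulaAssignment]:
    """All CHNOS compositions matching a neutral mass within the ppm tolerance.

    Exhaustive over the bounded integer grid (the hydrogen count is solved
    from the mass residual: at sub-100-ppm tolerances below 1000 u only the
    nearest integer H can match).  Matches are filtered by RDBE >= 0,
    even-electron integer RDBE, and the H/C and O/C ranges, then sorted by
    |ppm error|, ties broken by fewer heteroatoms (N+S), then by counts.

    Returns an empty list when nothing matches.  Raises ``ValueError`` if
    the bounds imply more than ``MAX_CANDIDATES`` candidate compositions.
    """
    neutral = float(neutral)
    if neutral <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral}")
    if bounds.grid_size > MAX_CANDIDATES:
        raise ValueError(
            f"bounds imply {bounds.grid_size:.3g} candidate compositions "
            f"(> {MAX_CANDIDATES:.0g}); tighten the element ranges"
        )

    cc, nn, oo, ss, base = _candidate_grid(bounds.c, bounds.n, bounds.o, bounds.s)
    mh = MONOISOTOPIC_MASS["H"]
    nh = np.rint((neutral - base) / mh)
    ok = (nh >= bounds.h[0]) & (nh <= bounds.h[1])
    nh = np.where(ok, nh, 0.0)
    mass = base + nh * mh
    ppm = (mass - neutral) / neutral * 1e6
    ok &= np.abs(ppm) <= bounds.ppm_tol
    # even-electron neutral: RDBE integer, i.e. H and N of the same parity
    dbe = cc - nh / 2.0 + nn / 2.0 + 1.0
    ok &= (dbe >= 0) & (((nh.astype(np.int64) + nn) % 2) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        hc = np.where(cc > 0, nh / cc, np.inf)
        oc = np.where(cc > 0, oo / cc, np.inf)
    ok &= (hc >= bounds.hc_range[0]) & (hc <= bounds.hc_range[1])
    ok &= (oc >= bounds.oc_range[0]) & (oc <= bounds.oc_range[1])

    idx = np.flatnonzero(ok)
    out = []
    for i in idx:
        counts = (int(cc[i]), int(nh[i]), int(nn[i]), int(oo[i]), int(ss[i]))
        out.append(
            FormulaAssignment(
                counts=counts,
                neutral_mass=float(mass[i]),
                ppm_error=float(ppm[i]),
                cls=classify_class(counts),
                hc=float(hc[i]),
                oc=float(oc[i]),
                rdbe=float(dbe[i]),
            )
        )
    out.sort(key=lambda a: (abs(a.ppm_error), a.counts[2] + a.counts[4], a.counts))
    return out


def _unique_formulas(assignments: Iterable[FormulaAssignment]):
    return {a.counts for a in assignments}


def class_ratio(
    assignments: Iterable[FormulaAssignment], num_cls: str, den_cls: str
) -> float:
    """Ratio of unique-formula counts between two compound classes.

    Counted over distinct formulas, not intensity-weighted (class panels of
    this kind report counts of elemental compositions).  Raises
    ``UndefinedRatioError`` when the denominator class is empty.
    """
    assignments = list(assignments)
    num = len({a.counts for a in assignments if a.cls == num_cls})
    den = len({a.counts for a in assignments if a.cls == den_cls})
    if den == 0:
        raise UndefinedRatioError(
            f"no unique {den_cls} formulas: {num_cls}/{den_cls} is undefined"
        )
    return num / den


def van_krevelen(
    assignments: Sequence[FormulaAssignment],
    intensities: Sequence[float] | None = None,
    oxygenated_threshold: float = 0.6,
) -> pd.DataFrame:
    """Van Krevelen table: O/C, H/C, intensity and class per assignment.

    The ``highly_oxygenated`` flag marks O/C above the threshold (0.6), the
    series depleted in biologically inactive brine DOM.
    """
    assignments = list(assignments)
    if intensities is None:
        intensities = [np.nan] * len(assignments)
    intensities = list(intensities)
    if len(intensities) != len(assignments):
        raise ValueError("intensities must match assignments in length")
    return pd.DataFrame(
        {
            "formula": [a.formula for a in assignments],
            "oc": [a.oc for a in assignments],
            "hc": [a.hc for a in assignments],
            "intensity": intensities,
            "cls": [a.cls for a in assignments],
            "highly_oxygenated": [a.oc > oxygenated_threshold for a in assignments],
        }
    )


def sulfur_histogram(assignments: Iterable[FormulaAssignment]) -> dict[int, int]:
    """Counts of formulas by sulfur atoms, over S-containing classes only."""
    hist: dict[int, int] = {}
    for counts in _unique_formulas(
        a for a in assignments if a.cls in ("CHOS", "CHNOS")
    ):
        ns = counts[4]
        hist[ns] = hist.get(ns, 0) + 1
    return dict(sorted(hist.items()))


def _as_key_set(items, match_tol_ppm):
    items = list(items)
    if not items:
        raise ValueError("both sets must be non-empty")
    first = items[0]
    if isinstance(first, FormulaAssignment):
        return {it.counts for it in items}, "formula"
    if isinstance(first, tuple):
        return set(items), "formula"
    return sorted(float(x) for x in items), "mass"


def unique_shared_fraction(
    setA, setB, match_tol_ppm: float | None = None
) -> tuple[float, float]:
    """Percent of items unique to either sample, and percent shared.

    Formula inputs (assignments or count tuples) match by exact identity;
    bare mass lists match within ``match_tol_ppm``.  Uniqueness is the
    symmetric difference over the union:

        %unique = (|A \\ B| + |B \\ A|) / |A u B| * 100

    Returns (%unique, %shared); the two always sum to 100.
    """
    a, kind_a = _as_key_set(setA, match_tol_ppm)
    b, kind_b = _as_key_set(setB, match_tol_ppm)
    if kind_a != kind_b:
        raise TypeError("both sets must hold the same kind of items")
    if kind_a == "formula":
        union = len(a | b)
        shared = len(a & b)
    else:
        if match_tol_ppm is None:
            raise ValueError("match_tol_ppm is required for bare mass lists")
        shared = 0
        j = 0
        used = [False] * len(b)
        for x in a:
            tol = x * match_tol_ppm * 1e-6
            while j < len(b) and b[j] < x - tol:
                j += 1
            k = j
            while k < len(b) and b[k] <= x + tol:
                if not used[k]:
                    used[k] = True
                    shared += 1
                    break
                k += 1
        union = len(a) + len(b) - shared
    pct_unique = (union - shared) / union * 100.0
    return (pct_unique, 100.0 - pct_unique)
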