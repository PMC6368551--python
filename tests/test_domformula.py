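"""Formula assignment: exact-mass arithmetic, decomposition, class statistics."""

import numpy as np
import pytest

from brineage import (
    DOM_DEFAULT_BOUNDS,
    ElementBounds,
    PROTON_MASS,
    class_ratio,
    classify_class,
    decompose_mass,
    exact_neutral_mass,
    neutral_mass_from_mz,
    sulfur_histogram,
    unique_shared_fraction,
    van_krevelen,
)
from brineage.domformula import FormulaAssignment, UndefinedRatioError, rdbe

from _oracles import brute_force_decompose

GLUCOSE = (6, 12, 0, 6, 0)
GLUCOSE_NEUTRAL = 180.0633881  # IUPAC monoisotopic mass of C6H12O6


def _assignment(counts, **kw):
    defaults = dict(
        counts=counts,
        neutral_mass=exact_neutral_mass(counts),
        ppm_error=0.0,
        cls=classify_class(counts),
        hc=counts[1] / counts[0] if counts[0] else float("inf"),
        oc=counts[3] / counts[0] if counts[0] else float("inf"),
        rdbe=rdbe(counts),
    )
    defaults.update(kw)
    return FormulaAssignment(**defaults)


class TestNeutralMass:
    def test_deprotonated_glucose(self):
        assert neutral_mass_from_mz(179.0561116) == pytest.approx(
            GLUCOSE_NEUTRAL, abs=2e-7
        )

    def test_tiny_but_valid_arithmetic(self):
        m = neutral_mass_from_mz(PROTON_MASS + 1e-6)
        assert m == pytest.approx(2 * PROTON_MASS + 1e-6)

    def test_below_proton_mass_rejected(self):
        with pytest.raises(ValueError):
            neutral_mass_from_mz(PROTON_MASS)

    def test_positive_mode_unsupported(self):
        with pytest.raises(ValueError):
            neutral_mass_from_mz(200.0, mode="positive")


class TestDecomposeMass:
    def test_glucose_found_at_1ppm(self):
        hits = decompose_mass(GLUCOSE_NEUTRAL, DOM_DEFAULT_BOUNDS.with_tol(1.0))
        assert GLUCOSE in [h.counts for h in hits]

    def test_glucose_unique_at_10ppb(self):
        hits = decompose_mass(GLUCOSE_NEUTRAL, DOM_DEFAULT_BOUNDS.with_tol(0.01))
        assert [h.counts for h in hits] == [GLUCOSE]

    def test_gap_mass_yields_nothing(self):
        bounds = DOM_DEFAULT_BOUNDS.with_tol(0.1)
        assert decompose_mass(180.000000, bounds) == []
        assert not brute_force_decompose(180.0, 60, 120, 3, 40, 3, 0.1)

    def test_matches_brute_force_enumeration(self):
        """Vectorized search equals naive loop enumeration on random masses."""
        bounds = ElementBounds(
            c=(1, 15), h=(1, 30), n=(0, 2), o=(0, 10), s=(0, 2), ppm_tol=5.0
        )
        rng = np.random.default_rng(2024)
        masses = rng.uniform(80.0, 420.0, size=30)
        for m in masses:
            got = {h.counts for h in decompose_mass(float(m), bounds)}
            expected = brute_force_decompose(float(m), 15, 30, 2, 10, 2, 5.0)
            assert got == expected

    def test_round_trip_recovers_every_in_bounds_formula(self):
        """Any valid formula is found again from its own exact mass."""
        rng = np.random.default_rng(7)
        bounds = DOM_DEFAULT_BOUNDS.with_tol(0.1)
        n_checked = 0
        while n_checked < 1000:
            nc = int(rng.integers(1, 61))
            nh = int(rng.integers(1, 121))
            nn = int(rng.integers(0, 4))
            no = int(rng.integers(0, 41))
            ns = int(rng.integers(0, 4))
            counts = (nc, nh, nn, no, ns)
            if rdbe(counts) < 0 or (nh + nn) % 2:
                continue
            if not (0.3 <= nh / nc <= 2.5) or not (no / nc <= 1.2):
                continue
            hits = decompose_mass(exact_neutral_mass(counts), bounds)
            assert counts in [h.counts for h in hits], counts
            n_checked += 1

    def test_ranking_by_ppm_then_parsimony(self):
        hits = decompose_mass(GLUCOSE_NEUTRAL, DOM_DEFAULT_BOUNDS.with_tol(50.0))
        ppms = [abs(h.ppm_error) for h in hits]
        assert ppms == sorted(ppms)
        assert hits[0].counts == GLUCOSE

    def test_oversized_bounds_refused(self):
        huge = ElementBounds(c=(0, 500), h=(0, 1000), n=(0, 50), o=(0, 400), s=(0, 50))
        with pytest.raises(ValueError, match="candidate"):
            decompose_mass(300.0, huge)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            decompose_mass(0.0)


class TestClassification:
    @pytest.mark.parametrize(
        "counts,cls",
        [
            ((6, 12, 0, 6, 0), "CHO"),
            ((10, 15, 1, 4, 0), "CHNO"),
            ((10, 16, 0, 5, 1), "CHOS"),
            ((10, 15, 1, 4, 1), "CHNOS"),
            ((5, 10, 0, 0, 0), "unclassified"),  # no oxygen
            ((0, 10, 0, 2, 0), "unclassified"),  # no carbon
        ],
    )
    def test_examples(self, counts, cls):
        assert classify_class(counts) == cls


class TestClassRatio:
    def test_mirrors_printed_ratio_arithmetic(self):
        chos = [_assignment((10 + i, 16, 0, 5, 1)) for i in range(211)]
        cho = [_assignment((6 + i, 12, 0, 6, 0)) for i in range(100)]
        assert class_ratio(chos + cho, "CHOS", "CHO") == pytest.approx(2.11)

    def test_small_counts(self):
        assignments = [_assignment((10 + i, 16, 0, 5, 1)) for i in range(6)]
        assignments += [_assignment((6 + i, 12, 0, 6, 0)) for i in range(3)]
        assert class_ratio(assignments, "CHOS", "CHO") == pytest.approx(2.0)

    def test_counts_unique_formulas_not_rows(self):
        dup = [_assignment((10, 16, 0, 5, 1))] * 5 + [_assignment((6, 12, 0, 6, 0))]
        assert class_ratio(dup, "CHOS", "CHO") == pytest.approx(1.0)

    def test_zero_denominator_is_explicit(self):
        chos = [_assignment((10, 16, 0, 5, 1))]
        with pytest.raises(UndefinedRatioError):
            class_ratio(chos, "CHOS", "CHO")


class TestVanKrevelen:
    def test_glucose_coordinates_flagged_oxygenated(self):
        table = van_krevelen([_assignment(GLUCOSE)])
        row = table.iloc[0]
        assert row["oc"] == pytest.approx(1.0)
        assert row["hc"] == pytest.approx(2.0)
        assert bool(row["highly_oxygenated"])

    def test_reduced_compound_not_flagged(self):
        table = van_krevelen([_assignment((10, 10, 0, 2, 0))])
        row = table.iloc[0]
        assert row["oc"] == pytest.approx(0.2)
        assert row["hc"] == pytest.approx(1.0)
        assert not bool(row["highly_oxygenated"])

    def test_empty_input_empty_table(self):
        assert len(van_krevelen([])) == 0


class TestSulfurHistogram:
    def test_sulfur_free_set_empty(self):
        assert sulfur_histogram([_assignment(GLUCOSE)]) == {}

    def test_mixed_set_matches_hand_count(self):
        assignments = [
            _assignment((10, 16, 0, 5, 1)),   # CHOS, S1
            _assignment((12, 22, 0, 4, 2)),   # CHOS, S2
            _assignment((9, 15, 1, 3, 2)),    # CHNOS, S2
            _assignment((11, 17, 1, 5, 1)),   # CHNOS, S1
            _assignment((6, 12, 0, 6, 0)),    # CHO, ignored
        ]
        assert sulfur_histogram(assignments) == {1: 2, 2: 2}


class TestUniqueSharedFraction:
    def test_identical_sets(self):
        a = [_assignment(GLUCOSE), _assignment((10, 16, 0, 5, 1))]
        assert unique_shared_fraction(a, list(a)) == (0.0, 100.0)

    def test_disjoint_sets(self):
        a = [_assignment(GLUCOSE)]
        b = [_assignment((10, 16, 0, 5, 1))]
        assert unique_shared_fraction(a, b) == (100.0, 0.0)

    def test_symmetric_difference_over_union(self):
        x, y, z, w = (
            (6, 12, 0, 6, 0), (10, 16, 0, 5, 1), (10, 15, 1, 4, 0), (12, 22, 0, 4, 2)
        )
        pct_unique, pct_shared = unique_shared_fraction(
            [x, y, z], [y, z, w]
        )
        assert pct_unique == pytest.approx(50.0)
        assert pct_shared == pytest.approx(50.0)

    def test_mass_matching_with_tolerance(self):
        a = [100.0, 200.0, 300.0]
        b = [100.0 * (1 + 0.1e-6), 400.0]
        pct_unique, _ = unique_shared_fraction(a, b, match_tol_ppm=0.5)
        assert pct_unique == pytest.approx(3 / 4 * 100)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            unique_shared_fraction([], [_assignment(GLUCOSE)])
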