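import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xlps.de import DEResult
from xlps.screens import (
    SeparationRecord,
    complete_separation_screen,
    direction_census,
    top_k_by_difference,
)


def oracle_screen(values, labels, missing, tolerance, units):
    """Exhaustive re-derivation: all pairwise comparisons, independent of the screen."""
    records = []
    labels = np.asarray(labels)
    units = np.asarray(units)
    for i in range(values.shape[0]):
        cls = {}
        for name in ("sensitive", "resilient"):
            cols = np.nonzero(labels == name)[0]
            vals = [values[i, j] for j in cols if not missing[i, j]]
            miss_units = {units[j] for j in cols if missing[i, j]}
            cls[name] = (vals, len(miss_units))
        (vs, ms), (vr, mr) = cls["sensitive"], cls["resilient"]
        if not vs or not vr:
            records.append((False, "none"))
            continue
        hi, lo = ("sensitive", "resilient") if np.mean(vs) >= np.mean(vr) else ("resilient", "sensitive")
        v_hi, m_hi = cls[hi]
        v_lo, m_lo = cls[lo]
        all_above = all(a > b for a in v_hi for b in v_lo)
        records.append((all_above and m_hi <= tolerance and m_lo == 0, hi))
    return records


class TestCompleteSeparationScreen:
    def test_clean_separation(self):
        rec = complete_separation_screen(np.array([[5.0, 6, 7, 1, 2, 3]]),
                                         ["sensitive"] * 3 + ["resilient"] * 3)
        assert rec[0].separated and rec[0].higher_class == "sensitive"
        assert rec[0].gap == pytest.approx(2.0)
        assert rec[0].rank_score == pytest.approx(4.0)

    def test_single_missing_in_higher_class_tolerated(self):
        values = np.array([[5.0, 6, 0, 1, 2, 3]])
        missing = np.array([[False, False, True, False, False, False]])
        rec = complete_separation_screen(values, ["sensitive"] * 3 + ["resilient"] * 3,
                                         missing=missing)
        assert rec[0].separated and rec[0].n_missing_higher == 1

    def test_missing_in_lower_class_never_tolerated(self):
        values = np.array([[5.0, 6, 7, 1, 2, 0]])
        missing = np.array([[False] * 5 + [True]])
        rec = complete_separation_screen(values, ["sensitive"] * 3 + ["resilient"] * 3,
                                         missing=missing)
        assert not rec[0].separated and rec[0].n_missing_lower == 1

    def test_overlap_breaks_separation(self):
        rec = complete_separation_screen(np.array([[5.0, 6, 3, 1, 2, 4]]),
                                         ["sensitive"] * 3 + ["resilient"] * 3)
        assert not rec[0].separated

    def test_tie_across_classes_breaks_separation(self):
        rec = complete_separation_screen(np.array([[5.0, 6, 3, 1, 2, 3]]),
                                         ["sensitive"] * 3 + ["resilient"] * 3)
        assert not rec[0].separated and rec[0].gap == 0.0

    def test_gene_absent_from_one_class_is_none(self):
        values = np.array([[5.0, 6, 7, 0, 0, 0]])
        missing = np.array([[False] * 3 + [True] * 3])
        rec = complete_separation_screen(values, ["sensitive"] * 3 + ["resilient"] * 3,
                                         missing=missing)
        assert not rec[0].separated and rec[0].higher_class == "none"

    def test_species_level_missing_units_count_once(self):
        # two missing columns of the same species consume one annotation unit
        values = np.array([[5.0, 6, 0, 0, 1, 2]])
        missing = np.array([[False, False, True, True, False, False]])
        units = ["sp1", "sp1", "sp2", "sp2", "sp3", "sp3"]
        rec = complete_separation_screen(values, ["sensitive"] * 4 + ["resilient"] * 2,
                                         missing=missing, units=units)
        assert rec[0].n_missing_higher == 1 and rec[0].separated

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            complete_separation_screen(np.ones((1, 2)), ["sensitive", "mystery"])

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_cols = int(rng.integers(4, 12))
        labels = rng.choice(["sensitive", "resilient"], n_cols)
        if len(set(labels)) < 2:
            labels[0], labels[1] = "sensitive", "resilient"
        values = np.round(rng.normal(0, 1, (30, n_cols)), 1)  # rounding forces ties
        missing = rng.random((30, n_cols)) < 0.15
        units = rng.choice(["u1", "u2", "u3", "u4"], n_cols)
        tol = int(rng.integers(0, 3))
        recs = complete_separation_screen(values, labels, missing, tolerance=tol, units=units)
        expected = oracle_screen(values, labels, missing, tol, units)
        for r, (sep, hi) in zip(recs, expected):
            assert r.separated == sep
            if r.higher_class != "none":
                assert r.higher_class == hi

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_tolerance_monotone_and_shift_invariant(self, seed):
        rng = np.random.default_rng(seed)
        labels = ["sensitive"] * 4 + ["resilient"] * 3
        values = rng.normal(0, 1, (25, 7))
        missing = rng.random((25, 7)) < 0.2
        sep = {}
        for tol in (0, 1, 2):
            recs = complete_separation_screen(values, labels, missing, tolerance=tol)
            sep[tol] = {r.gene_id for r in recs if r.separated}
        assert sep[0] <= sep[1] <= sep[2]
        shifted = complete_separation_screen(values + 11.5, labels, missing, tolerance=1)
        base = complete_separation_screen(values, labels, missing, tolerance=1)
        assert [(r.separated, r.higher_class) for r in shifted] == \
               [(r.separated, r.higher_class) for r in base]


def make_record(gid, score, separated=True, higher=None):
    higher = higher or ("sensitive" if score >= 0 else "resilient")
    return SeparationRecord(gid, separated, higher, 1.0, 0, 0, score)


def make_de(gid, fdr, significant):
    return DEResult(gid, 1.0, 2.0, fdr, fdr, significant, "higher_in_sensitive", 10)


class TestTopK:
    def test_orders_by_absolute_difference(self):
        recs = [make_record("a", 3.0), make_record("b", -2.0), make_record("c", 1.0)]
        assert top_k_by_difference(recs, None, 2) == ["a", "b"]

    def test_tie_breaks_lexicographically(self):
        recs = [make_record("z", 2.0), make_record("a", -2.0)]
        assert top_k_by_difference(recs, None, 2) == ["a", "z"]

    def test_short_list_not_padded(self):
        recs = [make_record("a", 3.0), make_record("b", 1.0, separated=False)]
        assert top_k_by_difference(recs, None, 5) == ["a"]

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            top_k_by_difference([make_record("a", 1.0)], None, 0)

    def test_significance_filter(self):
        recs = [make_record("a", 3.0), make_record("b", 2.0)]
        de = [make_de("a", 0.2, False), make_de("b", 0.01, True)]
        assert top_k_by_difference(recs, de, 2, require_significant=True) == ["b"]


class TestDirectionCensus:
    def test_empty_list(self):
        assert direction_census([]) == {"sensitive": 0, "resilient": 0}

    def test_counts_restricted_to_list(self):
        recs = [make_record("a", 3.0), make_record("b", -2.0), make_record("c", 1.0)]
        census = direction_census(recs, ["a", "b"])
        assert census == {"sensitive": 1, "resilient": 1}

    def test_all_resilient_construction(self):
        recs = [make_record(f"g{i}", -1.0 - i) for i in range(4)]
        assert direction_census(recs) == {"sensitive": 0, "resilient": 4}
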