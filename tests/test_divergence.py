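import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpbarcode import divergence as dv

from conftest import make_alignment

# ---------------------------------------------------------------------------
# independent brute-force oracles


def brute_classify(rows):
    """Per-column site classification by exhaustive inspection."""
    n_cols = len(rows[0])
    n_excluded = n_variable = n_informative = 0
    for c in range(n_cols):
        column = [r[c] for r in rows]
        if any(ch not in "ACGT" for ch in column):
            n_excluded += 1
            continue
        counts = {b: column.count(b) for b in set(column)}
        if len(counts) >= 2:
            n_variable += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                n_informative += 1
    return n_excluded, n_variable, n_informative


def brute_pair(a, b):
    n_compared = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n_compared += 1
        if x != y:
            if {x, y} in ({"A", "G"}, {"C", "T"}):
                ts += 1
            else:
                tv += 1
    return n_compared, ts, tv


def brute_pi(rows):
    usable = [c for c in range(len(rows[0]))
              if all(r[c] in "ACGT" for r in rows)]
    pairs = list(itertools.combinations(rows, 2))
    total = 0.0
    for a, b in pairs:
        diffs = sum(1 for c in usable if a[c] != b[c])
        total += diffs / len(usable)
    return total / len(pairs)


def random_rows(rng, n_rows, n_cols, alphabet="ACGT"):
    return ["".join(rng.choice(list(alphabet), n_cols))
            for _ in range(n_rows)]


def similar_rows(rng, n_rows, n_cols, p_mut=0.05):
    """Rows derived from one ancestor by sparse point mutations, so
    pairwise divergence stays below K2P saturation."""
    base = rng.choice(list("ACGT"), n_cols)
    rows = []
    for _ in range(n_rows):
        row = base.copy()
        for c in np.flatnonzero(rng.random(n_cols) < p_mut):
            row[c] = rng.choice(list("ACGT"))
        rows.append("".join(row))
    return rows


# ---------------------------------------------------------------------------


class TestClassifySites:
    def test_toy_hand_count(self, toy_alignment):
        cls = dv.classify_sites(toy_alignment)
        assert cls.n_variable == 3
        assert cls.n_informative == 1
        assert cls.n_excluded == 0

    def test_all_identical(self):
        cls = dv.classify_sites(make_alignment(["ACGT"] * 4))
        assert cls.n_variable == 0
        assert cls.n_informative == 0

    def test_two_rows_never_informative(self):
        rng = np.random.default_rng(0)
        aln = make_alignment(random_rows(rng, 2, 200))
        assert dv.classify_sites(aln).n_informative == 0

    def test_gap_and_ambiguity_excluded(self):
        aln = make_alignment(["AC-T", "ANGT", "ACGT"])
        cls = dv.classify_sites(aln)
        assert cls.n_excluded == 2
        assert cls.n_total == 4

    def test_matches_brute_force_on_random_alignments(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            rows = random_rows(rng, 6, 50, alphabet="ACGTN-")
            aln = make_alignment(rows)
            cls = dv.classify_sites(aln)
            exc, var, inf = brute_classify(rows)
            assert (cls.n_excluded, cls.n_variable,
                    cls.n_informative) == (exc, var, inf)

    def test_counts_consistent_with_categories(self, toy_alignment):
        cls = dv.classify_sites(toy_alignment)
        from collections import Counter
        counted = Counter(cls.categories)
        assert counted[dv.CATEGORY_INFORMATIVE] == cls.n_informative
        assert (counted[dv.CATEGORY_VARIABLE]
                + counted[dv.CATEGORY_INFORMATIVE]) == cls.n_variable


class TestPairwise:
    def test_single_transition(self):
        comp = dv.pairwise_compare("AACCGGTT", "AGCCGGTT")
        assert comp.n_compared == 8
        assert comp.n_transitions == 1
        assert comp.n_transversions == 0
        assert comp.P == pytest.approx(0.125)

    def test_identical(self):
        comp = dv.pairwise_compare("ACGT", "ACGT")
        assert comp.P == 0 and comp.Q == 0

    def test_gap_column_dropped(self):
        comp = dv.pairwise_compare("AC-T", "ACGT")
        assert comp.n_compared == 3

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = random_rows(rng, 2, 60, alphabet="ACGTN-")
            comp = dv.pairwise_compare(a, b)
            assert (comp.n_compared, comp.n_transitions,
                    comp.n_transversions) == brute_pair(a, b)

    def test_undefined_comparison(self):
        comp = dv.pairwise_compare("NN--", "ACGT")
        assert not comp.defined
        with pytest.raises(ValueError):
            dv.p_distance(comp)


class TestDistances:
    def test_k2p_closed_form(self):
        comp = dv.PairwiseComparison(8, 1, 0)
        assert dv.k2p_distance(comp) == pytest.approx(
            -0.5 * math.log(0.75), abs=1e-9)

    def test_k2p_zero(self):
        assert dv.k2p_distance(dv.PairwiseComparison(10, 0, 0)) == 0.0

    def test_k2p_saturation_is_nan(self):
        assert math.isnan(dv.k2p_distance(dv.PairwiseComparison(2, 1, 0)))

    def test_p_distance(self):
        assert dv.p_distance(dv.PairwiseComparison(8, 1, 0)) == 0.125

    def test_substitution_count(self):
        assert dv.substitution_count(dv.PairwiseComparison(8, 1, 2)) == 3

    def test_k2p_dominates_p_distance(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b = random_rows(rng, 2, 80)
            comp = dv.pairwise_compare(a, b)
            k2p = dv.k2p_distance(comp)
            if math.isnan(k2p):
                continue
            p = dv.p_distance(comp)
            assert k2p >= p - 1e-12
            if p == 0:
                assert k2p == 0


class TestDistanceMatrix:
    def test_identical_rows_zero_matrix(self):
        dm = dv.distance_matrix(make_alignment(["ACGT"] * 3))
        assert np.allclose(dm.values, 0)

    def test_matches_entrywise_brute_force(self):
        rng = np.random.default_rng(3)
        rows = similar_rows(rng, 4, 100)
        dm = dv.distance_matrix(make_alignment(rows), model="k2p")
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert dm.values[i, j] == 0
                    continue
                comp = dv.pairwise_compare(rows[i], rows[j])
                assert dm.values[i, j] == pytest.approx(
                    dv.k2p_distance(comp), abs=1e-12)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(4)
        dm = dv.distance_matrix(make_alignment(similar_rows(rng, 5, 60)))
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_undefined_entries_masked(self):
        aln = make_alignment(["ACGT", "ACGT", "NNNN"])
        dm = dv.distance_matrix(aln)
        assert dm.defined_mask[0, 1]
        assert not dm.defined_mask[0, 2]
        assert not dm.defined_mask[2, 1]


class TestPi:
    def test_hand_computation(self):
        aln = make_alignment(["ACGT", "ACGA", "ACGT"])
        assert dv.nucleotide_diversity(aln) == pytest.approx(1 / 6)

    def test_identical_rows(self):
        assert dv.nucleotide_diversity(make_alignment(["ACGT"] * 5)) == 0

    def test_two_rows_collapse_to_p_distance(self):
        rng = np.random.default_rng(5)
        rows = random_rows(rng, 2, 100)
        aln = make_alignment(rows)
        comp = dv.pairwise_compare(rows[0], rows[1])
        assert dv.nucleotide_diversity(aln) == pytest.approx(
            dv.p_distance(comp))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            rows = random_rows(rng, 5, 40, alphabet="ACGT-")
            aln = make_alignment(rows)
            try:
                got = dv.nucleotide_diversity(aln)
            except ValueError:
                continue
            assert got == pytest.approx(brute_pi(rows), abs=1e-12)

    def test_all_gapped_undefined(self):
        with pytest.raises(ValueError):
            dv.nucleotide_diversity(make_alignment(["A-", "-A"]))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_row_order_invariance_and_duplicate_row(self, seed):
        rng = np.random.default_rng(seed)
        rows = random_rows(rng, 4, 30)
        aln = make_alignment(rows)
        pi = dv.nucleotide_diversity(aln)
        shuffled = make_alignment(list(reversed(rows)))
        assert dv.nucleotide_diversity(shuffled) == pytest.approx(pi)
        # duplicating an existing row never increases pi
        dup = make_alignment(rows + [rows[0]])
        assert dv.nucleotide_diversity(dup) <= pi + 1e-12


class TestRegionDivergence:
    def test_whole_alignment_matches_global(self, toy_alignment):
        df = dv.region_divergence(toy_alignment,
                                  {"whole": (0, toy_alignment.n_cols)})
        cls = dv.classify_sites(toy_alignment)
        row = df.iloc[0]
        assert row.n_variable == cls.n_variable
        assert row.n_informative == cls.n_informative
        assert row.pi == pytest.approx(
            dv.nucleotide_diversity(toy_alignment))

    def test_counts_additive_over_halves(self):
        rng = np.random.default_rng(7)
        rows = random_rows(rng, 6, 80)
        aln = make_alignment(rows)
        df = dv.region_divergence(aln, {"left": (0, 40), "right": (40, 80)})
        cls = dv.classify_sites(aln)
        assert df.n_variable.sum() == cls.n_variable
        assert df.n_informative.sum() == cls.n_informative

    def test_percentages_use_region_length_denominator(self):
        aln = make_alignment(["AAAA", "AAAT", "AATT"])
        df = dv.region_divergence(aln, {"r": (0, 4)})
        row = df.iloc[0]
        assert row.percent_variable == pytest.approx(100 * 2 / 4)
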