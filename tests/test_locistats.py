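"""Alignment statistics, sorting, slicing, sliding and the bias diagnostic."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phyloprov as pp
from phyloprov.locistats import (
    WindowSpec,
    column_conservation,
    column_entropy,
    column_gap_score,
    five_number_summary,
    gc_content,
)


class TestColumnEntropy:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ("AAAA", 0.0),
            ("ACGT", 2.0),
            ("AAAG-", -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))),
            ("AACCGGTT", 2.0),
            ("AAAANNN-", 0.0),  # ambiguity and gaps both ignored
        ],
    )
    def test_hand_values(self, column, expected):
        assert column_entropy(column) == pytest.approx(expected, abs=1e-9)

    def test_all_gap_column_is_missing_not_zero(self):
        assert math.isnan(column_entropy("----"))
        assert math.isnan(column_entropy(""))

    @given(st.text(alphabet="ACGTN-?.", min_size=1, max_size=30))
    def test_dna_entropy_bounded(self, column):
        value = column_entropy(column)
        assert math.isnan(value) or 0.0 <= value <= 2.0

    @given(st.text(alphabet="ACGT", min_size=1, max_size=20))
    def test_zero_iff_constant(self, column):
        value = column_entropy(column)
        assert (value == 0.0) == (len(set(column)) == 1)


class TestOtherColumnStats:
    def test_gap_score_orientation(self):
        assert column_gap_score("ACGT") == 1.0  # gap-free
        assert column_gap_score("AC--") == 0.5
        assert column_gap_score("----") == 0.0

    def test_conservation_modal_frequency(self):
        assert column_conservation("AAAG") == 0.75
        assert column_conservation("AAAA") == 1.0
        assert math.isnan(column_conservation("NN--"))

    def test_gc_content_definition(self):
        assert gc_content("GGCCAATT") == 0.5
        assert gc_content("GCGC") == 1.0
        assert gc_content("GCNNAT") == 0.5  # N excluded from both sides
        assert math.isnan(gc_content("NNNN"))


class TestSummaries:
    def test_percentile_linear_interpolation(self):
        summary = five_number_summary(range(1, 101))
        assert summary["p25"] == 25.75
        assert summary["median"] == 50.5
        assert summary["p75"] == 75.25

    def test_null_box_nulls_whiskers(self):
        summary = five_number_summary([0.3] * 10)
        assert summary["p25"] == summary["median"] == summary["p75"] == 0.3
        assert summary["whisker_low"] is None and summary["whisker_high"] is None

    def test_whiskers_within_1_5_iqr(self):
        values = list(range(10)) + [1000]  # outlier beyond the fence
        summary = five_number_summary(values)
        assert summary["whisker_high"] == 9

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.random(50)
        assert five_number_summary(values) == five_number_summary(values[::-1])


class TestComputeLocusStats:
    def test_degenerate_identical_alignment(self):
        aln = pp.Alignment(
            object_id="a", locus_name="x",
            rows=[(f"r{i}", "ACGT") for i in range(4)],
        )
        stats = pp.compute_locus_stats(aln)
        assert np.all(stats.column_entropy == 0.0)
        assert np.all(stats.column_conservation == 1.0)
        assert np.all(stats.column_gap_score == 1.0)

    def test_all_gap_column_missing(self):
        aln = pp.Alignment(
            object_id="a", locus_name="x",
            rows=[("r1", "A-G"), ("r2", "A-G"), ("r3", "A-C")],
        )
        stats = pp.compute_locus_stats(aln)
        assert math.isnan(stats.column_entropy[1])
        assert stats.column_gap_score[1] == 0.0

    def test_summaries_match_brute_force(self):
        rng = np.random.default_rng(42)
        rows = [
            (f"r{i}", "".join(rng.choice(list("ACGT-"), 10))) for i in range(5)
        ]
        aln = pp.Alignment(object_id="a", locus_name="x", rows=rows)
        stats = pp.compute_locus_stats(aln)
        values = [v for v in stats.column_entropy if not math.isnan(v)]
        assert stats.summaries["entropy"]["median"] == pytest.approx(
            float(np.percentile(values, 50))
        )
        assert stats.summaries["length"]["median"] == pytest.approx(
            float(np.median([sum(c not in "-?." for c in s) for _, s in rows]))
        )


class TestSortSliceSlide:
    def test_sort_descending_matches_oracle(self, small_project):
        order = pp.sort_loci(small_project, "entropy", "median", "desc")
        medians = [
            small_project.stats[n].summaries["entropy"]["median"] for n in order
        ]
        assert medians == sorted(medians, reverse=True)

    def test_asc_is_reverse_of_desc(self, small_project):
        # value sequences are exact mirrors; ties may reorder names
        def medians(names):
            return [
                small_project.stats[n].summaries["entropy"]["median"] for n in names
            ]

        desc = pp.sort_loci(small_project, "entropy", "median", "desc")
        asc = pp.sort_loci(small_project, "entropy", "median", "asc")
        assert medians(asc) == medians(desc)[::-1]

    def test_missing_stats_error_names_locus(self, two_locus_project):
        from phyloprov.core import UnknownIdError

        with pytest.raises(UnknownIdError, match="L1"):
            pp.sort_loci(two_locus_project)

    def test_slice_counting(self, small_project):
        medians = {
            n: small_project.stats[n].summaries["entropy"]["median"]
            for n in small_project.locus_names()
        }
        cut = sorted(medians.values())[2]
        conc = pp.slice_loci(small_project, "entropy", "median", cut, math.inf)
        assert set(conc.locus_names) == {n for n, m in medians.items() if m >= cut}

    def test_slice_vacuous_bounds_selects_all(self, small_project):
        conc = pp.slice_loci(small_project, "entropy", "median", -math.inf, math.inf,
                             name="everything")
        assert len(conc.locus_names) == 6

    def test_slice_empty_range_is_error(self, small_project):
        with pytest.raises(ValueError, match="widen"):
            pp.slice_loci(small_project, "entropy", "median", 10.0, 11.0)

    def test_slice_complement_partitions_loci(self, small_project):
        cut = 1.0
        lo = pp.slice_loci(small_project, "entropy", "median", -math.inf,
                           np.nextafter(cut, -np.inf), name="lo")
        hi = pp.slice_loci(small_project, "entropy", "median", cut, math.inf,
                           name="hi")
        assert set(lo.locus_names) | set(hi.locus_names) == set(
            small_project.locus_names()
        )
        assert not set(lo.locus_names) & set(hi.locus_names)

    def test_window_offsets_enumeration(self):
        assert WindowSpec(width=4, step=3).offsets(10) == [0, 3, 6]
        assert WindowSpec(width=200, step=50).offsets(200) == [0]
        assert WindowSpec(width=200, step=50).offsets(465) == [0, 50, 100, 150, 200, 250]

    @given(
        n=st.integers(1, 300), w=st.integers(1, 300), s=st.integers(1, 50)
    )
    def test_window_count_formula(self, n, w, s):
        spec = WindowSpec(width=w, step=s)
        if w > n:
            with pytest.raises(ValueError):
                spec.offsets(n)
        else:
            offsets = spec.offsets(n)
            assert len(offsets) == (n - w) // s + 1
            assert all(off + w <= n for off in offsets)

    def test_width_above_locus_count_is_error(self, small_project):
        with pytest.raises(ValueError):
            pp.slide(small_project, WindowSpec(width=100, step=1))

    def test_slide_windows_follow_sorted_gradient(self, small_project):
        windows = pp.slide(small_project, WindowSpec(width=3, step=2))
        order = pp.sort_loci(small_project)
        assert [w.name for w in windows] == ["win_0", "win_1"]
        assert windows[0].locus_names == order[0:3]
        assert windows[1].locus_names == order[2:5]


class TestBiasDiagnostic:
    def test_perfect_monotone(self, fresh_small_project):
        # entropy vs itself is a perfectly monotone pairing
        rho, n = pp.bias_diagnostic(fresh_small_project, "entropy", "entropy")
        assert rho == pytest.approx(1.0)
        assert n == 4

    def test_constant_side_is_undefined(self, fresh_small_project):
        for stats in fresh_small_project.stats.values():
            stats.summaries["gc"]["median"] = 0.5
        rho, _ = pp.bias_diagnostic(fresh_small_project, "entropy", "gc")
        assert math.isnan(rho)

    def test_matches_scipy_free_rank_oracle(self, small_project):
        rho, _ = pp.bias_diagnostic(small_project, "entropy", "conservation")
        a = [small_project.stats[n].summaries["entropy"]["median"]
             for n in small_project.locus_names()]
        b = [small_project.stats[n].summaries["conservation"]["median"]
             for n in small_project.locus_names()]

        def ranks(values):
            order = sorted(range(len(values)), key=values.__getitem__)
            r = [0.0] * len(values)
            i = 0
            while i < len(order):
                j = i
                while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    r[order[k]] = avg
                i = j + 1
            return r

        ra, rb = ranks(a), ranks(b)
        oracle = float(np.corrcoef(ra, rb)[0, 1])
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_entropy_unbiased_by_gc_in_synthetic_world(self, small_project):
        """The entropy gradient must not be a disguised GC gradient."""
        rho, _ = pp.bias_diagnostic(small_project, "entropy", "gc")
        assert math.isnan(rho) or abs(rho) < 0.9


class TestBoxplotData:
    def test_exact_summary_numbers(self, small_project):
        data = pp.boxplot_data(small_project, "entropy")
        assert set(data) == set(small_project.locus_names())
        for summary in data.values():
            assert summary["p25"] <= summary["median"] <= summary["p75"]
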