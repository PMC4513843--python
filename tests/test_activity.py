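"""Per-variant activity statistics: fractions, ratios, gates, rankings, fits."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cleaveseq import (
    GateCriteria,
    ReadCall,
    Status,
    activation_ratio,
    build_profile,
    compare_profiles,
    enumerate_variants,
    fraction_cleaved,
    hamming_distance,
    match_pattern,
    phenotype_gate,
    rank_variants,
    tabulate,
)
from cleaveseq.reference_data import APTAZYME_J12_BENCHMARK, P4_CONSTITUTIVE


def _call(variant, status, condition="minus", library="toy2"):
    return ReadCall(
        read_id="r",
        condition=condition,
        library=library,
        status=status,
        variant=variant,
    )


class TestFractionCleaved:
    @pytest.mark.parametrize(
        "c, u, expected", [(92, 8, 0.92), (0, 500, 0.0), (13, 87, 0.13)]
    )
    def test_values(self, c, u, expected):
        assert fraction_cleaved(c, u) == pytest.approx(expected)

    def test_zero_depth_is_nan_not_error(self):
        assert math.isnan(fraction_cleaved(0, 0))


class TestActivationRatio:
    def test_equal_counts_give_unity(self):
        assert activation_ratio((40, 60), (40, 60)) == pytest.approx(1.0)

    def test_high_depth_matches_raw_fraction_quotient(self):
        # raw fractions 0.13 and 0.80: pseudo-counts barely perturb the ratio
        ratio = activation_ratio((130, 870), (800, 200))
        assert ratio == pytest.approx(0.80 / 0.13, rel=0.01)
        assert ratio == pytest.approx(6.15, abs=0.05)

    def test_zero_cleaved_off_state_stays_finite(self):
        ratio = activation_ratio((0, 1000), (500, 500))
        assert ratio == pytest.approx((500.5 / 1001) / (0.5 / 1001))
        assert math.isfinite(ratio) and ratio > 0

    def test_zero_depth_is_nan(self):
        assert math.isnan(activation_ratio((0, 0), (10, 10)))


class TestPhenotypeGate:
    @pytest.mark.parametrize(
        "f_minus, f_plus, ratio, expected",
        [
            (0.13, 0.80, 0.80 / 0.13, True),  # strong guanine-activated switch
            (0.71, 0.92, 0.92 / 0.71, False),  # constitutively active: ratio < 3
            (0.05, 0.25, 5.0, False),  # active fraction below threshold
        ],
    )
    def test_examples(self, f_minus, f_plus, ratio, expected):
        assert phenotype_gate(f_minus, f_plus, ratio) is expected

    def test_inequalities_are_strict(self):
        assert not phenotype_gate(0.1, 0.30, 10.0)
        assert not phenotype_gate(0.1, 0.9, 3.0)

    def test_benchmark_aptazymes_all_pass_default_gate(self):
        """Every benchmarked guanine-activated variant clears (0.30, 3.0)."""
        for f_minus, f_plus in APTAZYME_J12_BENCHMARK.values():
            assert phenotype_gate(f_minus, f_plus, f_plus / f_minus)
        (f_minus, f_plus) = P4_CONSTITUTIVE["AUAC"]
        assert not phenotype_gate(f_minus, f_plus, f_plus / f_minus)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        f_minus=st.floats(0, 1),
        f_plus=st.floats(0, 1),
        ratio=st.floats(0, 50),
        df=st.floats(0, 1),
        dr=st.floats(0, 10),
    )
    def test_monotone_in_thresholds(self, f_minus, f_plus, ratio, df, dr):
        """Tightening either criterion never admits a new variant."""
        loose = GateCriteria()
        tight = GateCriteria(
            f_plus_min=loose.f_plus_min + df, ratio_min=loose.ratio_min + dr
        )
        if phenotype_gate(f_minus, f_plus, ratio, tight):
            assert phenotype_gate(f_minus, f_plus, ratio, loose)


class TestTabulate:
    def test_increments_one_cell(self, toy2):
        calls = [_call("AC", Status.CLEAVED)] * 3 + [_call("AC", Status.UNCLEAVED)]
        table = tabulate(calls, [toy2])
        assert table.cell("toy2", "minus", "AC") == (3, 1)
        assert table.total_reads == 4 and table.assigned_reads == 4

    def test_empty_stream_covers_full_variant_space(self, toy2):
        table = tabulate([], [toy2])
        assert len(table.counts) == 4**toy2.k * len(toy2.conditions)
        assert table.assigned_reads == 0 and table.total_reads == 0

    def test_rejects_are_tallied_not_counted(self, toy2):
        calls = [
            _call("AC", Status.CLEAVED),
            ReadCall(read_id="x", reject_reason="bad_barcode"),
            ReadCall(read_id="y", status=Status.AMBIGUOUS, library="toy2",
                     condition="minus", reject_reason="ambiguous_status"),
        ]
        table = tabulate(calls, [toy2])
        assert table.assigned_reads == 1
        assert table.rejected_reads == 2
        assert table.total_reads == 3

    def test_unknown_library_raises(self, toy2):
        with pytest.raises(ValueError, match="unknown library"):
            tabulate([_call("AC", Status.CLEAVED, library="nope")], [toy2])


class TestRankVariants:
    def test_benchmark_ranking_puts_strongest_switch_first(self):
        by_plus = {v: fp for v, (_, fp) in APTAZYME_J12_BENCHMARK.items()}
        ranked = rank_variants(by_plus)
        assert ranked[0] == "AAGU"
        assert ranked == sorted(by_plus, key=lambda v: (-by_plus[v], v))

    def test_top_four_share_the_stem_motif(self):
        """The four most guanine-activated variants all close the 3-bp stem (xAGU)."""
        by_plus = {v: fp for v, (_, fp) in APTAZYME_J12_BENCHMARK.items()}
        ranked = rank_variants(by_plus)
        assert all(v.endswith("AGU") for v in ranked[:4])
        assert not ranked[4].endswith("AGU")

    def test_ties_break_lexicographically(self):
        ranked = rank_variants({"GG": 0.5, "AA": 0.5, "CC": 0.5})
        assert ranked == ["AA", "CC", "GG"]

    def test_is_permutation_and_depth_scale_invariant(self, toy2):
        rng = np.random.default_rng(5)
        variants = enumerate_variants(toy2)
        fractions = dict(zip(variants, rng.uniform(size=len(variants))))
        ranked = rank_variants(fractions)
        assert sorted(ranked) == sorted(variants)
        # multiplying all counts by a constant leaves fractions, hence order, unchanged
        assert ranked == rank_variants({v: f for v, f in fractions.items()})


class TestMatchPattern:
    def test_stem_motif_selects_four_benchmark_variants(self):
        hits = match_pattern(APTAZYME_J12_BENCHMARK, "NAGU")
        assert set(hits) == {"AAGU", "GAGU", "UAGU", "CAGU"}

    def test_all_n_is_identity(self):
        variants = enumerate_variants(2)
        assert match_pattern(variants, "NN") == variants

    def test_purine_wildcard_matches_brute_force(self):
        variants = enumerate_variants(2)
        expected = [v for v in variants if v[0] in "AG"]  # R = purine
        assert match_pattern(variants, "RN") == expected
        assert len(expected) == 8

    def test_invalid_iupac_letter(self):
        with pytest.raises(ValueError, match="IUPAC"):
            match_pattern(["AC"], "ZZ")


class TestHammingDistance:
    @pytest.mark.parametrize(
        "a, b, d",
        [("GUUGC", "GUUAC", 1), ("GUUAC", "GUUAC", 0), ("AUCUA", "GUUAC", 4)],
    )
    def test_values(self, a, b, d):
        assert hamming_distance(a, b) == d

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.text("ACGU", min_size=5, max_size=5), st.text("ACGU", min_size=5, max_size=5))
    def test_metric_properties(self, a, b):
        assert hamming_distance(a, b) == hamming_distance(b, a)
        assert (hamming_distance(a, b) == 0) == (a == b)

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            hamming_distance("AC", "ACG")


class TestCompareProfiles:
    def test_identity_and_scaling(self):
        x = [0.1, 0.4, 0.9, 0.2]
        fit = compare_profiles(x, x)
        assert fit.slope == pytest.approx(1.0) and fit.r_squared == pytest.approx(1.0)
        fit = compare_profiles(x, [0.5 * v for v in x])
        assert fit.slope == pytest.approx(0.5) and fit.r_squared == pytest.approx(1.0)

    def test_closed_form_three_points(self):
        fit = compare_profiles([0, 1, 2], [0, 1, 3])
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(-1 / 6)
        assert fit.r_squared == pytest.approx(27 / 28)

    def test_zero_variance_x_is_undefined_not_error(self):
        fit = compare_profiles([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert math.isnan(fit.slope)


class TestBuildProfile:
    def test_profile_from_calls(self, toy2):
        calls = []
        for cond, (c, u) in (("minus", (10, 90)), ("plus", (80, 20))):
            calls += [_call("AC", Status.CLEAVED, cond)] * c
            calls += [_call("AC", Status.UNCLEAVED, cond)] * u
        table = tabulate(calls, [toy2])
        profile = build_profile(table, min_depth=50)
        row = profile[profile["variant"] == "AC"].iloc[0]
        assert row["f_minus"] == pytest.approx(0.10)
        assert row["f_plus"] == pytest.approx(0.80)
        assert row["depth_minus"] == 100 and row["depth_plus"] == 100
        assert row["ratio"] == pytest.approx(
            (80.5 / 101) / (10.5 / 101)
        )
        assert bool(row["gate"]) is True
        assert not row["low_depth"]
        # untouched variants: zero depth, NaN fractions, flagged, never gated
        other = profile[profile["variant"] == "GG"].iloc[0]
        assert math.isnan(other["f_minus"]) and other["low_depth"]
        assert bool(other["gate"]) is False

    def test_fractions_lie_in_unit_interval(self, toy2):
        rng = np.random.default_rng(17)
        calls = []
        for v in enumerate_variants(toy2):
            for cond in ("minus", "plus"):
                c, u = rng.integers(0, 50, size=2)
                calls += [_call(v, Status.CLEAVED, cond)] * int(c)
                calls += [_call(v, Status.UNCLEAVED, cond)] * int(u)
        profile = build_profile(tabulate(calls, [toy2]), min_depth=1)
        for col in ("f_minus", "f_plus"):
            vals = profile[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()
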