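"""Frequency, use value, Shannon diversity, and attribute distributions."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kucha.indices import (
    abundance_vector,
    compute_frequencies,
    compute_use_values,
    display_percent,
    display_uv,
    family_distribution,
    mean_formulation_size,
    part_distribution,
    property_flavor_crosstab,
    round_half_even,
    shannon_diversity,
    source_distribution,
    tag_prevalence,
)
from kucha.survey_data import FrequencyTable

from conftest import make_dataset


class TestFrequencies:
    def test_counts_formulations_containing_material(self, toy_dataset):
        freq = compute_frequencies(toy_dataset)
        assert freq.counts == {"A": 3, "B": 1, "C": 1, "D": 0}
        assert freq.N == 3

    def test_unused_registry_material_counts_zero(self, toy_dataset):
        assert compute_frequencies(toy_dataset).counts["D"] == 0

    def test_total_occurrences_matches_formulation_sizes(self, toy_dataset):
        freq = compute_frequencies(toy_dataset)
        assert freq.total_occurrences == toy_dataset.total_occurrences == 5


class TestUseValue:
    @pytest.mark.parametrize("count, n, uv, shown", [
        (10, 32, 0.3125, "0.312"),   # top-ranked material of a 32-store survey
        (9, 32, 0.28125, "0.281"),
        (8, 32, 0.25, "0.25"),
        (0, 32, 0.0, "0"),
        (32, 32, 1.0, "1"),
    ])
    def test_uv_ratio_and_display(self, count, n, uv, shown):
        table = FrequencyTable(counts={"m": count}, N=n)
        values = compute_use_values(table)
        assert values["m"] == pytest.approx(uv, abs=0)
        assert display_uv(values["m"]) == shown

    def test_empty_survey_is_error(self):
        with pytest.raises(ValueError):
            compute_use_values(FrequencyTable(counts={}, N=0))

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=12))
    def test_uv_in_unit_interval_and_monotone(self, counts):
        n = max(counts) + 1
        table = FrequencyTable(
            counts={f"m{i}": c for i, c in enumerate(counts)}, N=n)
        uv = compute_use_values(table)
        assert all(0.0 <= v <= 1.0 for v in uv.values())
        ranked = sorted(table.counts, key=table.counts.__getitem__)
        for lo, hi in zip(ranked, ranked[1:]):
            assert uv[lo] <= uv[hi]


class TestRounding:
    @pytest.mark.parametrize("x, nd, want", [
        (0.3125, 3, 0.312),   # half-to-even, down
        (0.28125, 3, 0.281),
        (0.4375, 3, 0.438),   # half-to-even, up
        (0.165, 2, 0.16),
        (0.175, 2, 0.18),
    ])
    def test_half_even_ties(self, x, nd, want):
        assert round_half_even(x, nd) == want

    def test_percent_display(self):
        assert display_percent(35 / 73, decimals=0) == "48%"
        assert display_percent(11 / 73, decimals=1) == "15.1%"
        assert display_percent(33 / 71, decimals=1) == "46.5%"


class TestShannon:
    def test_uniform_counts_give_log2_s(self):
        table = FrequencyTable(counts={f"m{i}": 3 for i in range(4)}, N=10)
        assert shannon_diversity(table) == pytest.approx(2.0)

    def test_single_material_gives_zero(self):
        assert shannon_diversity(FrequencyTable(counts={"m": 5}, N=5)) == 0.0

    def test_worked_example_contribution(self):
        # one material in 10 formulations out of 183 total occurrences
        # contributes -(10/183)*log2(10/183) ≈ 0.2292 bits
        p = 10 / 183
        assert -p * math.log2(p) == pytest.approx(0.2292, abs=5e-5)
        counts = {"top": 10, "rest": 173}
        h = shannon_diversity(FrequencyTable(counts=counts, N=32))
        q = 173 / 183
        assert h == pytest.approx(-p * math.log2(p) - q * math.log2(q))

    def test_all_zero_counts_is_error(self):
        with pytest.raises(ValueError):
            shannon_diversity(FrequencyTable(counts={"m": 0}, N=3))

    def test_base_option(self):
        table = FrequencyTable(counts={"a": 1, "b": 1, "c": 1}, N=3)
        assert shannon_diversity(table, base=math.e) == pytest.approx(
            math.log(3))

    @given(st.lists(st.integers(0, 30), min_size=1, max_size=15).filter(
        lambda cs: any(cs)))
    @settings(max_examples=150)
    def test_bounds_permutation_invariance_and_zero_padding(self, counts):
        n = max(counts)
        table = FrequencyTable(
            counts={f"m{i}": c for i, c in enumerate(counts)}, N=n)
        h = shannon_diversity(table)
        s = sum(1 for c in counts if c > 0)
        assert 0.0 <= h <= math.log2(s) + 1e-12
        nonzero = [c for c in counts if c > 0]
        if len(set(nonzero)) == 1:
            assert h == pytest.approx(math.log2(s))
        # permutation invariance: relabeling materials changes nothing
        perm = FrequencyTable(
            counts={f"x{i}": c for i, c in enumerate(reversed(counts))}, N=n)
        assert shannon_diversity(perm) == pytest.approx(h)
        # a zero-count material never moves H
        padded = FrequencyTable(counts={**table.counts, "zzz": 0}, N=n)
        assert shannon_diversity(padded) == pytest.approx(h)

    @given(st.lists(st.integers(1, 30), min_size=1, max_size=15))
    def test_abundances_sum_to_one(self, counts):
        table = FrequencyTable(
            counts={f"m{i}": c for i, c in enumerate(counts)}, N=max(counts))
        abund = abundance_vector(table)
        abund.validate()
        assert sum(abund.proportions.values()) == pytest.approx(1.0, abs=1e-9)


class TestMeanSize:
    def test_survey_scale_example(self):
        # 183 occurrences over 32 formulations
        sizes = [6] * 23 + [5] * 9  # 23*6 + 9*5 = 183
        ds = make_dataset({
            f"s{i:02d}": ("north", {f"m{j}" for j in range(sz)})
            for i, sz in enumerate(sizes)})
        assert ds.total_occurrences == 183
        mean = mean_formulation_size(ds)
        assert mean == pytest.approx(5.71875)
        assert f"{round_half_even(mean, 1):g}" == "5.7"

    @pytest.mark.parametrize("spec, want", [
        ({"s1": ("north", {"a"}), "s2": ("north", {"b"})}, 1.0),
        ({"s1": ("north", {"a", "b"}), "s2": ("north", {"c"})}, 1.5),
    ])
    def test_small_cases(self, spec, want):
        assert mean_formulation_size(make_dataset(spec)) == want

    def test_exact_integer_identity(self, toy_dataset):
        ds = toy_dataset
        assert mean_formulation_size(ds) * ds.N == ds.total_occurrences


class TestFamilyDistribution:
    def test_single_family_dominates(self, toy_dataset):
        dist = family_distribution(toy_dataset)
        assert dist == {"Family01": {"species_share": 1.0,
                                     "formulation_share": 1.0}}

    def test_species_counted_by_scientific_name(self):
        # stem and leaf of one species are two materials but one species
        ds = make_dataset(
            {"s1": ("north", {"stem", "leaf"}), "s2": ("north", {"x"})},
            materials={
                "stem": {"scientific_name": "Genus one", "family": "FamA"},
                "leaf": {"scientific_name": "Genus one", "family": "FamA"},
                "x": {"scientific_name": "Genus two", "family": "FamB"},
            })
        dist = family_distribution(ds)
        assert dist["FamA"]["species_share"] == pytest.approx(0.5)
        assert dist["FamA"]["formulation_share"] == pytest.approx(0.5)
        assert dist["FamB"]["formulation_share"] == pytest.approx(0.5)

    def test_dominant_family_share_display(self):
        # 12 species of 72 -> 16.7% at one decimal
        assert display_percent(12 / 72, decimals=1) == "16.7%"

    def test_unused_family_has_zero_formulation_share(self, toy_dataset):
        # material D (never used) is the only member of its family
        ds = make_dataset(
            {"s1": ("north", {"A"})},
            materials={"D": {"family": "FamZ"}})
        assert family_distribution(ds)["FamZ"]["formulation_share"] == 0.0


class TestPartAndSource:
    def test_part_shares_sum_to_one(self):
        ds = make_dataset(
            {"s1": ("north", {"a", "b", "c"})},
            materials={"a": {"part_used": "whole_plant"},
                       "b": {"part_used": "leaf"},
                       "c": {"part_used": "leaf"}})
        dist = part_distribution(ds)
        assert sum(dist.values()) == pytest.approx(1.0)
        assert dist["leaf"] == pytest.approx(2 / 3)

    def test_whole_plant_share_display(self):
        assert display_percent(30 / 73, decimals=1) == "41.1%"

    def test_source_shares_with_overlap(self):
        flags = [(True, True)] * 4 + [(True, False)] * 2 + [(False, True)] * 3 \
            + [(False, False)]
        ds = make_dataset(
            {"s1": ("north", {f"m{i}" for i in range(10)})},
            materials={f"m{i}": {"cultivated": c, "wild": w}
                       for i, (c, w) in enumerate(flags)})
        dist = source_distribution(ds)
        assert dist == {"cultivated_share": 0.6, "wild_share": 0.7,
                        "both_share": 0.4}


class TestPropertyFlavor:
    def test_unknown_property_excluded_from_denominator(self):
        mats = {f"m{i}": {"property": "cold", "flavors": frozenset({"bitter"})}
                for i in range(33)}
        mats.update({f"c{i}": {"property": "cool"} for i in range(38)})
        mats["u1"] = {"property": "unknown"}
        mats["u2"] = {"property": "unknown"}
        ds = make_dataset({"s1": ("north", set(mats))}, materials=mats)
        ct = property_flavor_crosstab(ds)
        assert ct["n_annotated"] == 71
        assert ct["property_shares"]["cold"] == pytest.approx(33 / 71)
        assert display_percent(ct["property_shares"]["cold"]) == "46.5%"
        assert ct["flavor_shares"]["bitter"] == pytest.approx(33 / 71)
        assert ct["joint_shares"][("cold", "bitter")] == pytest.approx(33 / 71)

    def test_all_unknown_yields_empty_tables(self, caplog):
        ds = make_dataset({"s1": ("north", {"a"})},
                          materials={"a": {"property": "unknown"}})
        ct = property_flavor_crosstab(ds)
        assert ct["property_shares"] == {} and ct["flavor_shares"] == {}

    def test_single_cold_bitter_material(self):
        ds = make_dataset(
            {"s1": ("north", {"a"})},
            materials={"a": {"property": "cold",
                             "flavors": frozenset({"bitter"})}})
        ct = property_flavor_crosstab(ds)
        assert ct["joint_shares"] == {("cold", "bitter"): 1.0}


class TestTagPrevalence:
    def test_shares_over_all_materials(self):
        mats = {f"m{i}": {"function_tags": frozenset({"heat-clearing"})
                          if i < 4 else frozenset()} for i in range(16)}
        ds = make_dataset({"s1": ("north", set(mats))}, materials=mats)
        assert tag_prevalence(ds)["heat-clearing"] == pytest.approx(0.25)

    def test_tagged_denominator_option(self):
        mats = {"a": {"function_tags": frozenset({"diuresis"})},
                "b": {"function_tags": frozenset()}}
        ds = make_dataset({"s1": ("north", {"a", "b"})}, materials=mats)
        assert tag_prevalence(ds)["diuresis"] == 0.5
        assert tag_prevalence(ds, denominator="tagged")["diuresis"] == 1.0

    def test_unknown_field_is_error(self, toy_dataset):
        with pytest.raises(ValueError):
            tag_prevalence(toy_dataset, tag_field="flavor_tags")
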