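"""Family-level metric construction from species tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from natdiv.metrics import (RegionTable, SpeciesData, build_family_dataset,
                            coverage_subset_ranges, horticultural_use,
                            mean_family_range, naturalization_success,
                            species_range_size, species_zonal_range,
                            stem_diversification_rate)
from natdiv.phylo import read_newick


class TestDiversificationRate:
    def test_monotypic_rate_is_zero(self):
        for eps in (0.0, 0.5, 0.9):
            assert stem_diversification_rate(1, 10.0, eps) == 0.0

    def test_zero_extinction_closed_form(self):
        assert stem_diversification_rate(100, 50.0, 0.0) == \
            pytest.approx(math.log(100) / 50, abs=1e-15)

    def test_high_extinction_value(self):
        assert stem_diversification_rate(1000, 100.0, 0.9) == \
            pytest.approx(math.log(100.9) / 100, abs=1e-15)

    @pytest.mark.parametrize("n,t,eps", [
        (0, 10.0, 0.0), (10, 0.0, 0.0), (10, -1.0, 0.0),
        (10, 10.0, 1.0), (10, 10.0, -0.1), (2.5, 10.0, 0.0),
    ])
    def test_domain_errors(self, n, t, eps):
        with pytest.raises(ValueError):
            stem_diversification_rate(n, t, eps)

    @given(n=st.integers(2, 10**6), t=st.floats(0.1, 500),
           eps=st.floats(0.0, 0.99))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_richness_age_and_extinction(self, n, t, eps):
        r = stem_diversification_rate(n, t, eps)
        assert r > stem_diversification_rate(n, t * 1.5, eps)
        assert stem_diversification_rate(n + 1, t, eps) > r
        assert stem_diversification_rate(n, t, 0.0) >= \
            stem_diversification_rate(n, t, 0.9)

    def test_extinction_bounds_close_for_rich_families(self, small_bundle):
        # the eps = 0 and eps = 0.9 estimates stay within a modest relative
        # band once richness is large
        *_, truth = small_bundle
        rich = {f: n for f, n in truth["richness"].items() if n >= 1000}
        assert rich  # the generator produces species-rich families
        tree = small_bundle[0]
        ages = tree.stem_ages()
        for f, n in rich.items():
            r0 = stem_diversification_rate(n, ages[f], 0.0)
            r9 = stem_diversification_rate(n, ages[f], 0.9)
            assert (r0 - r9) / r0 < 0.35

    def test_continuous_in_epsilon(self):
        eps = np.linspace(0.0, 0.99, 2000)
        r = stem_diversification_rate(np.full_like(eps, 500.0), 80.0, eps)
        assert np.all(np.abs(np.diff(r)) < 1e-3)
        assert np.all(np.diff(r) < 0)  # decreasing in relative extinction


class TestRangeSizes:
    def test_single_region(self, toy_species, toy_regions):
        assert species_range_size("s1", toy_species, toy_regions) == 100.0

    def test_additivity(self, toy_species, toy_regions):
        assert species_range_size("s2", toy_species, toy_regions) == 350.5

    def test_no_records_is_zero(self, toy_species, toy_regions):
        assert species_range_size("s4", toy_species, toy_regions) == 0.0

    def test_zonal_components(self, toy_species, toy_regions):
        assert species_zonal_range("s1", toy_species, toy_regions) == (60.0, 40.0)
        assert species_zonal_range("s2", toy_species, toy_regions) == (60.0, 290.5)

    def test_zonal_sums_to_total(self, toy_species, toy_regions):
        for sid in ["s1", "s2", "s3"]:
            trop, temp = species_zonal_range(sid, toy_species, toy_regions)
            assert trop + temp == pytest.approx(
                species_range_size(sid, toy_species, toy_regions), abs=1e-9)

    def test_family_mean(self, toy_species, toy_regions):
        assert mean_family_range("fam1", toy_species, toy_regions) == \
            pytest.approx((100.0 + 350.5) / 2)
        assert mean_family_range("fam2", toy_species, toy_regions) == 100.0

    def test_family_mean_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        n_sp, n_reg = 50, 12
        regions = RegionTable(pd.DataFrame({
            "region_id": [f"r{i}" for i in range(n_reg)],
            "area_km2": rng.uniform(10, 1000, n_reg),
        }).assign(tropical_km2=lambda d: d.area_km2 * 0.3,
                  temperate_km2=lambda d: d.area_km2 * 0.7))
        species = pd.DataFrame({
            "species_id": [f"s{i}" for i in range(n_sp)],
            "family": "famX", "order": "o", "accepted": True,
            "horticultural": False, "coverage_flag": "complete"})
        occ_rows, expected = [], []
        for i in range(n_sp):
            k = int(rng.integers(1, 5))
            regs = rng.choice(n_reg, size=k, replace=False)
            occ_rows += [(f"s{i}", f"r{j}", "native") for j in regs]
            expected.append(sum(regions.frame.loc[f"r{j}", "area_km2"]
                                for j in regs))
        data = SpeciesData(species=species, occurrences=pd.DataFrame(
            occ_rows, columns=["species_id", "region_id", "status"]))
        assert mean_family_range("famX", data, regions) == \
            pytest.approx(float(np.mean(expected)), rel=1e-12)

    def test_unknown_zone(self, toy_species, toy_regions):
        with pytest.raises(ValueError, match="zone"):
            mean_family_range("fam1", toy_species, toy_regions, zone="polar")


class TestCoverageSubsets:
    def test_partition(self, toy_species, toy_regions):
        full = coverage_subset_ranges("fam1", toy_species, toy_regions, "all")
        comp = coverage_subset_ranges("fam1", toy_species, toy_regions,
                                      "global_coverage")
        part = coverage_subset_ranges("fam1", toy_species, toy_regions,
                                      "partial_coverage")
        assert sorted(full) == sorted(comp + part)
        assert comp == [100.0] and part == [350.5]

    def test_all_complete_gives_empty_partial(self, toy_species, toy_regions):
        assert coverage_subset_ranges("fam2", toy_species, toy_regions,
                                      "partial_coverage") == []

    def test_unknown_subset(self, toy_species, toy_regions):
        with pytest.raises(ValueError, match="subset"):
            coverage_subset_ranges("fam1", toy_species, toy_regions, "some")


class TestIndices:
    def test_no_naturalized_species(self):
        assert naturalization_success(0, 50, 0) == 0.0

    def test_proportion_times_records(self):
        assert naturalization_success(5, 50, 12) == pytest.approx(1.2)

    def test_linear_in_records(self):
        assert naturalization_success(5, 50, 24) == \
            pytest.approx(2 * naturalization_success(5, 50, 12))

    def test_consistency_errors(self):
        with pytest.raises(ValueError):
            naturalization_success(51, 50, 60)
        with pytest.raises(ValueError):
            naturalization_success(5, 50, 3)

    def test_horticultural_use(self):
        assert horticultural_use(0, 100) == 0.0
        assert horticultural_use(100, 100) == 1.0
        assert horticultural_use(25, 200) == 0.125
        with pytest.raises(ValueError):
            horticultural_use(10, 5)

    def test_index_from_toy_table(self, toy_species, toy_regions):
        # fam1: s1 naturalized in 2 regions out of 2 accepted species
        tree = read_newick("(fam1:10,fam2:10);")
        ds, _ = build_family_dataset(toy_species, toy_regions, tree,
                                     min_richness=1)
        row = ds.set_index("family").loc["fam1"]
        assert row["n_species"] == 2  # unaccepted s4 not counted
        assert row["n_naturalized"] == 1
        assert row["naturalized_region_records"] == 2
        assert row["nat_success"] == pytest.approx((1 / 2) * 2)
        assert row["hort_prop"] == pytest.approx(0.5)


class TestBuildFamilyDataset:
    @pytest.fixture
    def designed_tables(self):
        """Families engineered to hit each exclusion criterion."""
        regions = RegionTable(pd.DataFrame({
            "region_id": ["r1"], "area_km2": [100.0],
            "tropical_km2": [100.0], "temperate_km2": [0.0]}))
        rows, occ = [], []
        spec_of = {"keep_a": 50, "keep_b": 60, "too_small": 49,
                   "not_in_tree": 55, "no_age": 52, "no_ranges": 51}
        for fam, n in spec_of.items():
            for i in range(n):
                sid = f"{fam}_{i}"
                rows.append((sid, fam, "o1", True, False, "complete"))
                if fam != "no_ranges":
                    occ.append((sid, "r1", "native"))
        data = SpeciesData(
            species=pd.DataFrame(rows, columns=[
                "species_id", "family", "order", "accepted",
                "horticultural", "coverage_flag"]),
            occurrences=pd.DataFrame(occ, columns=[
                "species_id", "region_id", "status"]))
        tree = read_newick(
            "((keep_a:10,keep_b:10):5,(too_small:8,(no_age:4,no_ranges:4):4):7);")
        ages = {f: 10.0 for f in spec_of if f != "no_age"}
        return data, regions, tree, ages

    def test_designed_exclusions(self, designed_tables):
        data, regions, tree, ages = designed_tables
        ds, excl = build_family_dataset(data, regions, tree, stem_ages=ages,
                                        min_richness=50)
        assert sorted(ds["family"]) == ["keep_a", "keep_b"]
        reasons = dict(zip(excl["family"], excl["reason"]))
        assert reasons == {"too_small": "min_richness",
                           "not_in_tree": "no_phylogeny",
                           "no_age": "no_stem_age",
                           "no_ranges": "no_range_data"}

    def test_empty_result_raises(self, designed_tables):
        data, regions, tree, ages = designed_tables
        with pytest.raises(ValueError, match="no family"):
            build_family_dataset(data, regions, tree, stem_ages=ages,
                                 min_richness=10_000)

    def test_epsilon_columns(self, designed_tables):
        data, regions, tree, ages = designed_tables
        ds, _ = build_family_dataset(data, regions, tree, stem_ages=ages,
                                     epsilon=0.9)
        row = ds.set_index("family").loc["keep_a"]
        assert row["div_rate"] == pytest.approx(
            stem_diversification_rate(50, 10.0, 0.9))
        assert row["div_rate_eps0"] == pytest.approx(np.log(50) / 10.0)
        assert row["div_rate_eps0"] >= row["div_rate"]
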