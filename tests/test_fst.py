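"""The nested-ANOVA Fst estimator against analytic limits and the
gamete-expansion brute-force oracle."""

from __future__ import annotations

import numpy as np
import pytest

from fstscan.dataset import MISSING, GenotypeDataset, Individual
from fstscan.fst import (Grouping, GroupingError, InsufficientPopulationsError,
                         compute_nc, fst_locus, fst_scan, merge_grouping,
                         pop_locus_stats)
from fstscan.simulate import SimConfig, simulate_dataset

from _oracles import gamete_expansion_fst
from conftest import dataset_from_pop_dosages, random_small_dataset


class TestNc:
    def test_equal_sizes_give_nc_equal_s(self):
        assert compute_nc([10, 10, 10]) == pytest.approx(10.0)

    def test_two_singletons(self):
        assert compute_nc([1, 1]) == pytest.approx(1.0)

    def test_nine_breed_sample_sizes(self):
        # S1 = 235, S2 = 6523 -> (235 - 6523/235)/8
        nc = compute_nc([35, 22, 23, 25, 24, 40, 18, 26, 22])
        assert nc == pytest.approx(25.905319148936, abs=1e-9)

    def test_empty_groups_dropped(self):
        assert compute_nc([10, 0, 10, 0, 10]) == pytest.approx(10.0)

    def test_fewer_than_two_groups_raises(self):
        with pytest.raises(InsufficientPopulationsError):
            compute_nc([5, 0])


class TestPopLocusStats:
    def test_direct_counts(self):
        ds = dataset_from_pop_dosages([[0, 1, 1], [2, 2, 1]])
        stats = pop_locus_stats(ds, Grouping.all_populations(ds.breeds), 0)
        assert stats.p[0] == pytest.approx(2 / 6)
        assert stats.h[0] == pytest.approx(2 / 3)
        assert stats.p[1] == pytest.approx(5 / 6)

    def test_fully_missing_population_dropped(self):
        ds = dataset_from_pop_dosages([[0, 1], [MISSING, MISSING], [2, 2]])
        stats = pop_locus_stats(ds, Grouping.all_populations(ds.breeds), 0)
        assert stats.n_pops == 2

    def test_mixed_missingness_hand_tally(self):
        ds = dataset_from_pop_dosages([[0, MISSING, 1, 2], [MISSING, 1, 1]])
        stats = pop_locus_stats(ds, Grouping.all_populations(ds.breeds), 0)
        assert stats.sizes.tolist() == [3, 2]
        assert stats.p[0] == pytest.approx(3 / 6)
        assert stats.h[1] == pytest.approx(1.0)

    def test_single_population_with_data_raises(self):
        ds = dataset_from_pop_dosages([[0, 1], [MISSING, MISSING]])
        with pytest.raises(InsufficientPopulationsError):
            pop_locus_stats(ds, Grouping.all_populations(ds.breeds), 0)


class TestAnalyticLimits:
    def test_fixed_difference_fst_is_one_exactly(self):
        ds = dataset_from_pop_dosages([[0, 0, 0], [2, 2, 2]])
        rec = fst_locus(ds, Grouping.all_populations(ds.breeds), 0)
        assert rec.msi == 0.0 and rec.msg == 0.0
        assert rec.fst == 1.0

    def test_all_heterozygote_fst_is_zero_exactly(self):
        ds = dataset_from_pop_dosages([[1, 1, 1], [1, 1, 1, 1]])
        rec = fst_locus(ds, Grouping.all_populations(ds.breeds), 0)
        assert rec.msg == pytest.approx(0.5)
        assert rec.fst == 0.0

    def test_monomorphic_locus_undefined(self):
        ds = dataset_from_pop_dosages([[0, 0, 0], [0, 0]])
        rec = fst_locus(ds, Grouping.all_populations(ds.breeds), 0)
        assert not rec.defined

    def test_all_singleton_populations_undefined(self):
        ds = dataset_from_pop_dosages([[1], [2]])
        rec = fst_locus(ds, Grouping.all_populations(ds.breeds), 0)
        assert not rec.defined


class TestOracleEquivalence:
    def test_worked_two_population_example(self):
        pops = [[0, 1, 1], [2, 2, 1]]
        ds = dataset_from_pop_dosages(pops)
        rec = fst_locus(ds, Grouping.all_populations(ds.breeds), 0)
        oracle = gamete_expansion_fst(pops)
        assert rec.msp == pytest.approx(oracle["msp"], abs=1e-12)
        assert rec.msi == pytest.approx(oracle["msi"], abs=1e-12)
        assert rec.msg == pytest.approx(oracle["msg"], abs=1e-12)
        assert rec.fst == pytest.approx(oracle["fst"], abs=1e-12)

    def test_agreement_on_200_random_datasets(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(200):
            ds = random_small_dataset(rng)
            grouping = Grouping.all_populations(ds.breeds)
            table = fst_scan(ds, grouping)
            pop = grouping.labels_for(ds)
            for j in range(ds.n_markers):
                col = ds.calls[:, j]
                pops = [col[(pop == g) & (col != MISSING)].tolist()
                        for g in range(grouping.n_pops)]
                oracle = gamete_expansion_fst(pops)
                rec = fst_locus(ds, grouping, j)
                if np.isnan(oracle["fst"]):
                    assert not rec.defined
                    assert np.isnan(table.fst[j])
                else:
                    assert rec.fst == pytest.approx(oracle["fst"], abs=1e-12)
                    assert table.fst[j] == pytest.approx(oracle["fst"],
                                                         abs=1e-12)
                checked += 1
        assert checked >= 200


class TestInvariances:
    def test_population_label_permutation(self, rng):
        ds = random_small_dataset(rng)
        grouping = Grouping.all_populations(ds.breeds)
        labels = sorted(set(ds.breeds))
        perm = {b: labels[(i + 1) % len(labels)] for i, b in enumerate(labels)}
        renamed = GenotypeDataset(
            [Individual(i.individual_id, perm[i.breed]) for i in ds.individuals],
            ds.markers, ds.calls,
        )
        t1 = fst_scan(ds, grouping)
        t2 = fst_scan(renamed, Grouping.all_populations(renamed.breeds))
        np.testing.assert_allclose(t1.fst, t2.fst, atol=1e-12)

    def test_allele_swap_invariance(self, rng):
        ds = random_small_dataset(rng)
        swapped = GenotypeDataset(
            ds.individuals, ds.markers,
            np.where(ds.calls == MISSING, MISSING, 2 - ds.calls).astype(np.int8),
        )
        g = Grouping.all_populations(ds.breeds)
        np.testing.assert_allclose(fst_scan(ds, g).fst,
                                   fst_scan(swapped, g).fst, atol=1e-12)

    def test_deleting_missing_individual_changes_nothing(self):
        ds = dataset_from_pop_dosages([[0, 1, MISSING], [2, 2, 1]])
        g = Grouping.all_populations(ds.breeds)
        rec_full = fst_locus(ds, g, 0)
        pruned = GenotypeDataset(
            [i for k, i in enumerate(ds.individuals) if k != 2],
            ds.markers, np.delete(ds.calls, 2, axis=0),
        )
        rec_pruned = fst_locus(pruned, g, 0)
        assert rec_full.fst == pytest.approx(rec_pruned.fst, abs=1e-15)

    def test_defined_fst_bounded_by_one(self, rng):
        for _ in range(30):
            ds = random_small_dataset(rng)
            t = fst_scan(ds, Grouping.all_populations(ds.breeds))
            assert np.all(t.defined_fst <= 1.0 + 1e-12)


class TestScanAndSummary:
    def test_parameter_recovery_under_drift(self):
        cfg = SimConfig(n_loci=5000, drift_F=0.2, n_selected=0, n_unmapped=0,
                        n_low_maf=0, n_low_callrate=0, seed=5)
        ds, _ = simulate_dataset(cfg)
        table = fst_scan(ds, Grouping.all_populations(ds.breeds))
        assert abs(table.mean_fst - 0.2) <= 0.02

    def test_no_differentiation_limit(self):
        cfg = SimConfig(n_loci=2000, drift_F=0.001, n_selected=0, n_unmapped=0,
                        n_low_maf=0, n_low_callrate=0, seed=6)
        ds, _ = simulate_dataset(cfg)
        table = fst_scan(ds, Grouping.all_populations(ds.breeds))
        assert abs(table.mean_fst) <= 0.01

    def test_undefined_loci_excluded_from_summary(self):
        ds = dataset_from_pop_dosages([[0, 0, 1], [2, 2, 1]], n_markers=2)
        ds.calls[:, 1] = 0  # monomorphic second locus
        table = fst_scan(ds, Grouping.all_populations(ds.breeds))
        assert np.isnan(table.fst[1])
        assert table.mean_fst == pytest.approx(table.fst[0])


class TestMergeGrouping:
    def test_merged_pool_sizes(self):
        sizes = {"TC": 35, "BM": 22, "LW": 23, "WZS": 25, "NX": 24,
                 "LC": 40, "Landrace": 18, "LargeWhite": 26, "YT": 22}
        gmap = {"LW": "North", "LC": "South", "WZS": "South", "BM": "South"}
        breeds = [b for b, n in sizes.items() for _ in range(n) if b in gmap]
        grouping = merge_grouping(breeds, gmap, name="NORTH_VS_SOUTH")
        assert grouping.n_pops == 2
        south = sum(1 for b in breeds if gmap[b] == "South")
        assert south == 40 + 25 + 22

    def test_identity_map_reproduces_allpop(self):
        breeds = ["A", "B", "C", "A"]
        ident = merge_grouping(breeds, {b: b for b in breeds})
        allpop = Grouping.all_populations(breeds)
        assert ident.assignment == allpop.assignment
        assert ident.n_pops == allpop.n_pops

    def test_excluded_breeds_take_no_part(self):
        ds = dataset_from_pop_dosages([[0, 0, 1], [2, 2, 1], [1, 1, 1]])
        two_pop = merge_grouping(ds.breeds,
                                 {"P0": "a", "P1": "b", "P2": None})
        assert two_pop.n_pops == 2
        pruned = dataset_from_pop_dosages([[0, 0, 1], [2, 2, 1]])
        rec_full = fst_locus(ds, two_pop, 0)
        rec_pruned = fst_locus(
            pruned, merge_grouping(pruned.breeds, {"P0": "a", "P1": "b"}), 0)
        assert rec_full.fst == pytest.approx(rec_pruned.fst, abs=1e-15)

    def test_missing_breed_named_in_error(self):
        with pytest.raises(GroupingError, match="'C'"):
            merge_grouping(["A", "B", "C"], {"A": "g1", "B": "g2"})

    def test_merged_groups_amplify_between_group_loci(self):
        cfg = SimConfig(n_loci=400, drift_F=0.1, n_selected=20,
                        n_unmapped=0, n_low_maf=0, n_low_callrate=0, seed=9)
        ds, truth = simulate_dataset(cfg)
        allpop = fst_scan(ds, Grouping.all_populations(ds.breeds))
        split = {name: ("EURO" if name in cfg.group_split else "CHN")
                 for name in cfg.pop_names}
        merged = fst_scan(ds, merge_grouping(ds.breeds, split, "CHN_VS_EURO"))
        sel = truth.frame["is_selected"].to_numpy()
        assert np.nanmean(merged.fst[sel]) > np.nanmean(allpop.fst[sel])
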