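"""Empirical-quantile outlier thresholds, tracks, and distance correlation."""

from __future__ import annotations

import numpy as np
import pytest

from fstscan.fst import Grouping, fst_scan
from fstscan.scan import (ScanConfig, empirical_threshold,
                          fst_distance_correlation, per_chromosome_track,
                          select_outliers)
from fstscan.simulate import SimConfig, simulate_dataset

from _oracles import brute_force_outliers


class TestEmpiricalThreshold:
    def test_values_1_to_100_at_99(self):
        vals = np.arange(1, 101, dtype=float)
        assert empirical_threshold(vals, 0.99) == 99.0
        assert (vals > 99.0).sum() == 1

    def test_values_1_to_100_at_975(self):
        vals = np.arange(1, 101, dtype=float)
        assert empirical_threshold(vals, 0.975) == 98.0
        assert (vals > 98.0).sum() == 2

    def test_ties_at_top_yield_zero_outliers(self):
        vals = np.array(list(range(1, 99)) + [98.0, 98.0])
        thr, n_out = brute_force_outliers(vals.tolist(), 0.975)
        assert empirical_threshold(vals, 0.975) == thr
        assert n_out == 0

    def test_agrees_with_enumeration_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 400))
            vals = np.round(rng.normal(size=n), 2)  # rounding induces ties
            q = float(rng.uniform(0.5, 0.999))
            thr, n_out = brute_force_outliers(vals.tolist(), q)
            assert empirical_threshold(vals, q) == thr
            assert (vals > thr).sum() == n_out

    def test_threshold_is_member_of_value_set(self, rng):
        vals = rng.normal(size=501)
        for q in (0.5, 0.9, 0.975, 0.99):
            assert empirical_threshold(vals, q) in vals

    def test_44652_distinct_values_give_446_outliers(self):
        vals = np.arange(44_652, dtype=float)
        thr = empirical_threshold(vals, 0.99)
        assert (vals > thr).sum() == 446

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            empirical_threshold(np.array([]), 0.99)


class TestSelectOutliers:
    def _table(self, fst_values):
        from fstscan.fst import FstTable
        n = len(fst_values)
        return FstTable(
            grouping_name="T", marker_ids=np.array([f"m{i}" for i in range(n)],
                                                   dtype=object),
            chrom=np.array(["1"] * n, dtype=object),
            pos_bp=np.arange(1, n + 1, dtype=np.int64) * 1000,
            msp=np.zeros(n), msi=np.zeros(n), msg=np.zeros(n),
            n_c=np.full(n, 2.0), fst=np.asarray(fst_values, dtype=float),
            n_pops_used=np.full(n, 2, dtype=np.int64),
        )

    def test_all_equal_values_give_zero_outliers(self):
        res = select_outliers(self._table([0.3] * 50))
        assert res.n_outliers == 0

    def test_undefined_loci_never_flagged(self):
        vals = list(np.linspace(0, 1, 99)) + [np.nan]
        res = select_outliers(self._table(vals))
        assert not res.outlier_flags[-1]
        assert res.n_defined == 99

    def test_monotone_in_quantile(self, rng):
        vals = rng.normal(size=2000)
        counts = []
        for q in (0.9, 0.95, 0.975, 0.99, 0.995):
            cfg = ScanConfig(quantiles=(q,), selection_quantile=q)
            counts.append(select_outliers(self._table(vals), cfg).n_outliers)
        assert counts == sorted(counts, reverse=True)

    def test_flags_invariant_under_marker_permutation(self, rng):
        vals = rng.normal(size=500)
        res = select_outliers(self._table(vals))
        perm = rng.permutation(500)
        res_p = select_outliers(self._table(vals[perm]))
        assert set(np.flatnonzero(res.outlier_flags)) == \
            set(perm[np.flatnonzero(res_p.outlier_flags)])
        assert res.thresholds == res_p.thresholds

    def test_planted_fixed_difference_loci_recovered(self):
        cfg = SimConfig(n_loci=44_652, n_unmapped=0, n_low_maf=0,
                        n_low_callrate=0, n_selected=100, drift_F=0.2, seed=17)
        ds, truth = simulate_dataset(cfg)
        table = fst_scan(ds, Grouping.all_populations(ds.breeds))
        res = select_outliers(table, ScanConfig())
        planted = truth.frame["is_selected"].to_numpy()
        assert res.outlier_flags[planted].sum() >= 95


class TestTrack:
    def test_track_sorted_within_chromosome_with_mb_units(self):
        cfg = SimConfig(n_loci=500, n_unmapped=20, n_low_maf=0,
                        n_low_callrate=0, n_selected=5, drift_F=0.2, seed=2)
        ds, _ = simulate_dataset(cfg)
        table = fst_scan(ds, Grouping.all_populations(ds.breeds))
        res = select_outliers(table)
        track = per_chromosome_track(table, res)
        # unmapped markers excluded
        assert len(track) == 480
        for _, grp in track.groupby("chrom"):
            assert grp["pos_mb"].is_monotonic_increasing
        # Mb conversion
        one = track.iloc[0]
        marker = next(m for m in ds.markers if m.marker_id == one["marker_id"])
        assert one["pos_mb"] == pytest.approx(marker.pos_bp / 1e6)
        assert "threshold_q0.99" in track.columns

    def test_planted_high_fst_block_localized(self):
        # one-chromosome layout with divergent loci planted in 40-80 Mb
        cfg = SimConfig(n_loci=2000, n_unmapped=0, n_low_maf=0,
                        n_low_callrate=0, n_selected=0, drift_F=0.1,
                        chrom_layout=(("X", 140_000_000),), seed=13)
        ds, truth = simulate_dataset(cfg)
        pos = np.array([m.pos_bp for m in ds.markers])
        # fixed differences planted in a narrow (sub-1%) slice of 40-80 Mb
        block = (pos >= 40e6) & (pos <= 41e6)
        ds.calls[:, block] = 0
        high = np.array([i.breed in ("Landrace", "LargeWhite")
                         for i in ds.individuals])
        ds.calls[np.ix_(high, block)] = 2
        table = fst_scan(ds, Grouping.all_populations(ds.breeds))
        res = select_outliers(table)
        # every planted locus is flagged, and the longest contiguous flagged
        # run sits inside the planted interval (stray singleton background
        # outliers are expected from a 1% rule)
        assert res.outlier_flags[block].all()
        flags = res.outlier_flags
        runs, start = [], None
        for i, f in enumerate(flags):
            if f and start is None:
                start = i
            if not f and start is not None:
                runs.append((i - start, start))
                start = None
        if start is not None:
            runs.append((len(flags) - start, start))
        length, start = max(runs)
        run_pos = pos[start:start + length]
        assert length == block.sum()
        assert run_pos.min() >= 40e6 and run_pos.max() <= 80e6


class TestDistanceCorrelation:
    def test_independent_loci_have_near_zero_correlation(self):
        cfg = SimConfig(n_loci=44_652, n_unmapped=0, n_low_maf=0,
                        n_low_callrate=0, n_selected=0, drift_F=0.2,
                        ld_block_size=1, seed=23)
        ds, _ = simulate_dataset(cfg)
        table = fst_scan(ds, Grouping.all_populations(ds.breeds))
        corr = fst_distance_correlation(
            table, ScanConfig(max_pairs_per_bin=50_000), seed=1)
        full_bins = corr.n_pairs >= 10_000
        assert full_bins.any()
        assert np.all(np.abs(corr.correlation[full_bins]) <= 0.05)

    def test_ld_blocks_induce_correlation_decay(self):
        cfg = SimConfig(n_loci=20_000, n_unmapped=0, n_low_maf=0,
                        n_low_callrate=0, n_selected=0, drift_F=0.2,
                        ld_block_size=10, seed=29)
        ds, _ = simulate_dataset(cfg)
        table = fst_scan(ds, Grouping.all_populations(ds.breeds))
        corr = fst_distance_correlation(table, ScanConfig(), seed=1)
        defined = ~np.isnan(corr.correlation)
        first = corr.correlation[defined][0]
        last = corr.correlation[defined][-1]
        assert first > last
        assert first > 0.3

    def test_degenerate_two_identical_loci_bin_empty(self):
        from fstscan.fst import FstTable
        table = FstTable(
            grouping_name="T",
            marker_ids=np.array(["a", "b"], dtype=object),
            chrom=np.array(["1", "1"], dtype=object),
            pos_bp=np.array([1000, 2000], dtype=np.int64),
            msp=np.zeros(2), msi=np.zeros(2), msg=np.zeros(2),
            n_c=np.full(2, 2.0), fst=np.array([0.5, 0.5]),
            n_pops_used=np.full(2, 2, dtype=np.int64),
        )
        corr = fst_distance_correlation(table, ScanConfig(), seed=0)
        assert np.all(np.isnan(corr.correlation))
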