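import numpy as np
import pytest
from scipy import stats

import chipmeta as cm


def _grid(values, step=7, start=0, dataset_id="g"):
    return cm.GridTrack(dataset_id, {"chr1": (start, step, np.asarray(values, float))})


class TestInterpolation:
    def test_hand_computed_linear_value(self, tiny_track):
        g = cm.interpolate_to_grid(tiny_track, 35)
        start, step, vals = g.data["chr1"]
        assert start == 105 and step == 35
        assert vals.tolist() == [pytest.approx(2.0 + 5 / 35 * 2.0)]

    def test_gap_rule_blocks_distant_probes(self):
        t = cm.ScoreTrack("x", "p", {"chr1": (np.array([100, 300]), np.array([1.0, 2.0]))},
                          resolution=35, max_interp_dist=50)
        g = cm.interpolate_to_grid(t, 35)
        start, step, vals = g.data["chr1"]
        # no grid point strictly between the probes is filled
        inner = vals[(start + step * np.arange(vals.size) > 100)
                     & (start + step * np.arange(vals.size) < 300)]
        assert np.all(np.isnan(inner))

    def test_single_probe_fills_only_coincident_point(self):
        t = cm.ScoreTrack("x", "p", {"chr1": (np.array([70]), np.array([3.5]))},
                          resolution=7, max_interp_dist=10)
        g = cm.interpolate_to_grid(t, 7)
        start, step, vals = g.data["chr1"]
        assert start == 70 and vals.tolist() == [3.5]

    def test_probe_coincident_points_exact_and_no_extrapolation(self):
        rng = np.random.default_rng(3)
        pos = np.arange(35, 3500, 35)
        sc = rng.normal(size=pos.size)
        t = cm.ScoreTrack("x", "p", {"chr1": (pos, sc)}, resolution=35, max_interp_dist=50)
        g = cm.interpolate_to_grid(t, 7)
        start, step, vals = g.data["chr1"]
        grid_pos = start + step * np.arange(vals.size)
        on_probe = np.isin(grid_pos, pos)
        np.testing.assert_array_equal(vals[on_probe], sc)  # bit-exact at probes
        # filled values lie within the flanking probe scores
        filled = np.isfinite(vals) & ~on_probe
        for gp, v in zip(grid_pos[filled], vals[filled]):
            j = np.searchsorted(pos, gp)
            lo, hi = sorted((sc[j - 1], sc[j]))
            assert lo <= v <= hi

    def test_bad_step_rejected(self, tiny_track):
        with pytest.raises(ValueError):
            cm.interpolate_to_grid(tiny_track, 0)


class TestNullModel:
    def test_recovers_normal_parameters(self):
        rng = np.random.default_rng(11)
        null = cm.estimate_null(rng.normal(2, 3, 100_000))
        assert 1.9 <= null.mu0 <= 2.1
        assert 2.85 <= null.sigma0 <= 3.15

    def test_robust_to_heavy_right_tail(self):
        rng = np.random.default_rng(12)
        values = np.concatenate([rng.normal(0, 1, 95_000), rng.normal(6, 1, 5_000)])
        null = cm.estimate_null(values)
        assert -0.1 <= null.mu0 <= 0.1
        assert 0.9 <= null.sigma0 <= 1.1

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError, match="degenerate|spread"):
            cm.estimate_null(np.full(200, 1.5))

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="100"):
            cm.estimate_null(np.random.default_rng(0).normal(size=99))

    def test_shift_equivariance(self):
        """Adding a constant to all scores shifts the null median and leaves
        the Z-scores unchanged."""
        rng = np.random.default_rng(13)
        vals = rng.standard_t(5, 5_000)
        g1 = _grid(vals)
        g2 = _grid(vals + 10.0)
        z1 = cm.to_zscores(g1, cm.estimate_null(vals))
        z2 = cm.to_zscores(g2, cm.estimate_null(vals + 10.0))
        np.testing.assert_allclose(z1.data["chr1"][2], z2.data["chr1"][2], atol=1e-9)


class TestZScores:
    def test_standardization_and_missing_propagation(self):
        null = cm.NullModel(mu0=2.0, sigma0=3.0)
        z = cm.to_zscores(_grid([2.0, 5.0, np.nan]), null)
        vals = z.data["chr1"][2]
        assert vals[0] == 0.0 and vals[1] == pytest.approx(1.0)
        assert np.isnan(vals[2])


class TestStouffer:
    cfg = cm.ChipChipConfig(target_step=7)

    def test_unit_weight_reduction(self):
        grids = [_grid([1.0], dataset_id=f"g{i}") for i in range(4)]
        comp = cm.combine_stouffer(grids, self.cfg)
        assert comp.data["chr1"][2][0] == pytest.approx(2.0)  # 4/sqrt(4)

    def test_single_dataset_identity(self):
        comp = cm.combine_stouffer([_grid([0.3, -1.2])], self.cfg)
        np.testing.assert_allclose(comp.data["chr1"][2], [0.3, -1.2])

    def test_k_copies_scale_by_sqrt_k(self):
        vals = np.array([0.5, -0.5, 2.0])
        grids = [_grid(vals, dataset_id=f"g{i}") for i in range(3)]
        comp = cm.combine_stouffer(grids, self.cfg)
        np.testing.assert_allclose(comp.data["chr1"][2], np.sqrt(3) * vals)

    def test_weighted_form_preserves_null_variance(self):
        rng = np.random.default_rng(21)
        grids = [_grid(rng.normal(size=50_000), dataset_id=f"g{i}") for i in range(2)]
        cfg = cm.ChipChipConfig(target_step=7, weights={"g0": 3.0, "g1": 1.0})
        comp = cm.combine_stouffer(grids, cfg)
        assert np.std(comp.data["chr1"][2]) == pytest.approx(1.0, abs=0.02)

    def test_partial_coverage_uses_nonmissing_subset(self):
        g1 = _grid([1.0, np.nan])
        g2 = _grid([1.0, 2.0], dataset_id="g2")
        comp = cm.combine_stouffer([g1, g2], self.cfg)
        vals, k = comp.data["chr1"][2], comp.data["chr1"][3]
        assert vals[0] == pytest.approx(2 / np.sqrt(2))
        assert vals[1] == pytest.approx(2.0) and k.tolist() == [2, 1]

    def test_min_datasets_gates_points(self):
        g1 = _grid([1.0, np.nan])
        g2 = _grid([1.0, 2.0], dataset_id="g2")
        cfg = cm.ChipChipConfig(target_step=7, min_datasets=2)
        comp = cm.combine_stouffer([g1, g2], cfg)
        assert np.isnan(comp.data["chr1"][2][1])

    def test_mismatched_steps_rejected(self):
        with pytest.raises(ValueError, match="step"):
            cm.combine_stouffer([_grid([1.0], step=7), _grid([1.0], step=5, dataset_id="b")],
                                self.cfg)

    def test_null_tail_calibration(self):
        """Composite of independent standard-normal tracks has the standard
        normal's one-sided 5% tail."""
        rng = np.random.default_rng(31)
        grids = [_grid(rng.normal(size=100_000), dataset_id=f"g{i}") for i in range(3)]
        comp = cm.combine_stouffer(grids, self.cfg)
        frac = np.mean(comp.data["chr1"][2] > stats.norm.isf(0.05))
        assert 0.045 <= frac <= 0.055


class TestCompositePeaks:
    def test_all_below_cutoff_gives_empty(self):
        comp = cm.CompositeTrack(data={"chr1": (0, 7, np.zeros(100), np.ones(100, int))})
        assert cm.call_peaks_composite(comp, cm.ChipChipConfig()) == []

    def test_single_run_score_and_pvalue(self):
        vals = np.zeros(200)
        vals[50:108] = 5.0  # 58 points * 7 bp > min_peak_len
        comp = cm.CompositeTrack(data={"chr1": (0, 7, vals, np.ones(200, int))})
        cfg = cm.ChipChipConfig(pvalue_cutoff=0.05)
        peaks = cm.call_peaks_composite(comp, cfg)
        assert len(peaks) == 1
        pk = peaks[0]
        assert pk.score == pytest.approx(5.0)
        assert pk.pvalue == pytest.approx(stats.norm.sf(5.0))
        assert pk.start == 50 * 7 and pk.end == 108 * 7
        assert pk.summit == 50 * 7  # leftmost maximum

    def test_merge_rule_joins_nearby_runs(self):
        vals = np.zeros(100)
        vals[10:20] = 5.0
        vals[22:32] = 5.0  # 2-point gap = 14 bp <= merge_gap (14)
        comp = cm.CompositeTrack(data={"chr1": (0, 7, vals, np.ones(100, int))})
        cfg = cm.ChipChipConfig(pvalue_cutoff=0.05, merge_gap=14)
        assert len(cm.call_peaks_composite(comp, cfg)) == 1
        cfg2 = cm.ChipChipConfig(pvalue_cutoff=0.05, merge_gap=7)
        assert len(cm.call_peaks_composite(comp, cfg2)) == 2

    def test_short_runs_discarded(self):
        vals = np.zeros(100)
        vals[10:12] = 5.0  # 14 bp < default min_peak_len 28
        comp = cm.CompositeTrack(data={"chr1": (0, 7, vals, np.ones(100, int))})
        assert cm.call_peaks_composite(comp, cm.ChipChipConfig(pvalue_cutoff=0.05)) == []


class TestSignFlipEfdr:
    def _comp_with_runs(self, n_pos, n_neg):
        blocks = []
        for _ in range(n_pos):
            blocks += [5.0] * 6 + [0.0] * 10
        for _ in range(n_neg):
            blocks += [-5.0] * 6 + [0.0] * 10
        vals = np.asarray(blocks)
        return cm.CompositeTrack(data={"chr1": (0, 7, vals, np.ones(vals.size, int))})

    def test_ratio_arithmetic(self):
        cfg = cm.ChipChipConfig(pvalue_cutoff=0.05, merge_gap=7, min_peak_len=28)
        comp = self._comp_with_runs(100, 5)
        assert cm.efdr_signflip(comp, cfg) == pytest.approx(0.05)

    def test_no_negative_peaks_gives_zero(self):
        cfg = cm.ChipChipConfig(pvalue_cutoff=0.05, merge_gap=7, min_peak_len=28)
        assert cm.efdr_signflip(self._comp_with_runs(10, 0), cfg) == 0.0

    def test_no_positive_peaks_is_not_defined(self):
        cfg = cm.ChipChipConfig(pvalue_cutoff=0.05, merge_gap=7, min_peak_len=28)
        assert cm.efdr_signflip(self._comp_with_runs(0, 3), cfg) is None

    def test_capped_at_one(self):
        cfg = cm.ChipChipConfig(pvalue_cutoff=0.05, merge_gap=7, min_peak_len=28)
        assert cm.efdr_signflip(self._comp_with_runs(2, 10), cfg) == 1.0


class TestPipeline:
    def test_composite_outranks_individual_platforms(self, spikein_benchmark):
        """Combining platforms must not rank truth regions worse than the best
        single platform does (ROC AUC, window-level)."""
        _, tracks, truth = spikein_benchmark
        cfg = cm.ChipChipConfig(target_step=7)
        aucs = []
        z_grids = []
        for tr in tracks:
            g = cm.interpolate_to_grid(tr, cfg.target_step)
            vals = np.concatenate([v for (_, _, v) in g.data.values()])
            zg = cm.to_zscores(g, cm.estimate_null(vals))
            z_grids.append(zg)
            cands = cm.baselines.windowed_candidates(zg.data, 500)
            aucs.append(cm.roc_curve(cands, truth)[2])
        comp = cm.combine_stouffer(z_grids, cfg)
        comp_cands = cm.baselines.windowed_candidates(comp.data, 500)
        auc_comp = cm.roc_curve(comp_cands, truth)[2]
        assert auc_comp >= max(aucs) - 0.01

    def test_pipeline_annotates_efdr_and_sorts_by_pvalue(self, spikein_benchmark):
        _, tracks, _ = spikein_benchmark
        peaks, efdr, _ = cm.chipchip_pipeline(tracks, cm.ChipChipConfig())
        assert peaks
        pv = [p.pvalue for p in peaks]
        assert pv == sorted(pv)
        if efdr is not None:
            assert all(p.efdr == pytest.approx(efdr) for p in peaks)
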