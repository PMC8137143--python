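import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adscreen.activation_quant import (BinTable, ControlModel,
                                       activation_from_bins,
                                       corrected_multivector_rate,
                                       enhancement_factor,
                                       estimate_fragment_cells,
                                       fit_control_model, normalize_bins,
                                       quantify_screen)


def _table(counts, cells=None, events=(1000.0, 1000.0), bin_means=None):
    df = pd.DataFrame(counts, columns=BinTable.BIN_COLUMNS)
    df.index = [f"f{i}" for i in range(len(df))]
    df["input"] = 0
    if cells is None:
        cells = np.full(8, 1000.0)
    if bin_means is None:
        bin_means = np.linspace(1.5, 4.8, 8)
    return BinTable(df, cells, events, bin_means)


class TestNormalizeBins:
    def test_equal_events_unchanged(self):
        t = _table([[10] * 8])
        out = normalize_bins(t)
        assert np.allclose(out.cells_sorted, t.cells_sorted)

    def test_ratio_two_doubles_high_bins(self):
        t = _table([[10] * 8], events=(2000.0, 1000.0))
        out = normalize_bins(t)
        assert np.allclose(out.cells_sorted[:4], 1000)
        assert np.allclose(out.cells_sorted[4:], 2000)

    def test_idempotent(self):
        t = _table([[10] * 8], events=(1700.0, 600.0))
        once = normalize_bins(t)
        twice = normalize_bins(once)
        assert np.allclose(once.cells_sorted, twice.cells_sorted)

    def test_zero_events_rejected(self):
        t = _table([[10] * 8], events=(0.0, 100.0))
        with pytest.raises(ValueError):
            normalize_bins(t)


class TestEstimateFragmentCells:
    def test_single_fragment_receives_all_cells(self):
        t = _table([[5, 1, 7, 2, 9, 4, 3, 8]])
        cells = estimate_fragment_cells(t)
        assert np.allclose(cells.to_numpy(), t.cells_sorted)

    def test_read_proportionality(self):
        t = _table([[1] * 8, [3] * 8])
        cells = estimate_fragment_cells(t)
        assert np.allclose(cells.loc["f0"], 250)
        assert np.allclose(cells.loc["f1"], 750)

    def test_zero_read_fragment_gets_zero_cells(self):
        t = _table([[1] * 8, [0] * 8])
        cells = estimate_fragment_cells(t)
        assert np.allclose(cells.loc["f1"], 0)

    def test_bin_with_cells_but_no_reads_rejected(self):
        t = _table([[0, 1, 1, 1, 1, 1, 1, 1]])
        with pytest.raises(ValueError):
            estimate_fragment_cells(t)


class TestActivationFromBins:
    control = ControlModel(mu=2.0, sigma=0.35)

    def test_degenerate_distribution(self):
        # all cells in one bin two log10 units above the control mean
        cells = np.array([0, 0, 0, 100, 0, 0, 0, 0.0])
        logg = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
        est = activation_from_bins(cells, logg, self.control)
        assert est.fold_activation == pytest.approx(100.0)
        assert est.sd_log_gfp == 0.0
        assert est.passed_filters

    def test_weighted_mean_of_two_bins(self):
        cells = np.array([50, 0, 50, 0, 0, 0, 0, 0.0])
        logg = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
        est = activation_from_bins(cells, logg, self.control)
        assert est.mean_log_gfp == pytest.approx(2.0)
        assert est.fold_activation == pytest.approx(1.0)

    def test_significance_cutoff_is_3_09(self):
        # the p<0.001 significance rule corresponds to Z>3.09
        assert round(float(stats.norm.isf(0.001)), 2) == 3.09

    def test_min_cells_filter(self):
        cells = np.array([0, 0, 0, 9, 0, 0, 0, 0.0])
        logg = np.linspace(1, 8, 8)
        est = activation_from_bins(cells, logg, self.control)
        assert not est.passed_filters

    def test_scale_invariance_of_mean(self):
        cells = np.array([5, 10, 20, 5, 3, 0, 1, 2.0])
        logg = np.linspace(1, 8, 8)
        a = activation_from_bins(cells, logg, self.control)
        b = activation_from_bins(cells * 7.3, logg, self.control)
        assert a.mean_log_gfp == pytest.approx(b.mean_log_gfp)

    def test_p_monotone_in_z(self):
        logg = np.linspace(1, 8, 8)
        ests = [
            activation_from_bins(np.eye(8)[i] * 100, logg, self.control)
            for i in range(8)
        ]
        zs = [e.z for e in ests]
        ps = [e.p for e in ests]
        assert all(z2 > z1 for z1, z2 in zip(zs, zs[1:]))
        assert all(p2 < p1 for p1, p2 in zip(ps, ps[1:]))
        for e in ests:
            assert (e.fold_activation > 1) == (e.z > 0)


class TestControlModel:
    def test_external_passthrough(self):
        m = fit_control_model([], mode="external", external_mu=2.0, external_sigma=0.3)
        assert m.mu == 2.0 and m.sigma == 0.3

    def test_single_far_outlier_excluded(self):
        # 19 tight controls plus one far outlier (the batch 3-sd rule needs
        # n >= 11 before any single point can exceed 3 sd of the full set)
        means = [2.0 + 0.01 * i for i in range(19)] + [8.0]
        ids = [f"c{i}" for i in range(20)]
        m = fit_control_model(means, mode="internal", control_ids=ids)
        assert m.excluded_ids == ("c19",)

    def test_equal_controls_pool_within_spread(self):
        m = fit_control_model(
            [2.0] * 5, mode="internal",
            control_sds=[0.3] * 5, control_cells=[100] * 5,
        )
        assert m.mu == pytest.approx(2.0)
        assert m.sigma == pytest.approx(0.3)

    def test_planted_outliers_match_stepwise_oracle(self, rng):
        # 50 controls, 3 planted far outliers; compare against an independent
        # one-at-a-time exclusion oracle on the same instance
        means = list(rng.normal(2.0, 0.05, 47)) + [3.5, 4.0, -1.0]
        ids = [f"c{i}" for i in range(50)]

        def oracle(values):
            vals = dict(zip(ids, values))
            while True:
                arr = np.array(list(vals.values()))
                m, s = arr.mean(), arr.std()
                worst = max(vals, key=lambda k: abs(vals[k] - m))
                if abs(vals[worst] - m) > 3 * s:
                    del vals[worst]
                else:
                    return set(ids) - set(vals)

        model = fit_control_model(means, mode="internal", control_ids=ids)
        assert set(model.excluded_ids) == oracle(means) == {"c47", "c48", "c49"}

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            fit_control_model([1.0, 2.0], mode="internal")


class TestMultivectorCorrection:
    @pytest.mark.parametrize(
        "distinct,colonies,n,expected",
        [(2, 15, 3, 0.20), (1, 24, 3, 0.0625), (0, 10, 3, 0.0)],
    )
    def test_examples(self, distinct, colonies, n, expected):
        assert corrected_multivector_rate(distinct, colonies, n) == pytest.approx(expected)

    def test_impossible_rate_flagged(self):
        with pytest.raises(ValueError):
            corrected_multivector_rate(10, 10, 2)


class TestEnhancementFactor:
    @pytest.mark.parametrize(
        "tandem,a,b,expected", [(6.0, 2.0, 3.0, 1.0), (8.0, 2.0, 2.0, 2.0)]
    )
    def test_examples(self, tandem, a, b, expected):
        assert enhancement_factor(tandem, a, b) == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            enhancement_factor(1.0, 0.0, 1.0)


def test_quantify_screen_recovers_simulated_folds(rng):
    """Estimated log10 fold tracks truth on a synthetic screen."""
    from adscreen import synthetic_data as sd

    proteome = sd.generate_proteome(n_proteins=10, ad_frequency=0.6, rng_seed=4)
    tiles = sd.tile_proteome(proteome)
    cfg = sd.ScreenSimulationConfig(rng_seed=5)
    table, truth = sd.simulate_screen(proteome, tiles, cfg)
    control = ControlModel(cfg.background_mean_log_gfp, cfg.population_sd_log_gfp)
    act = quantify_screen(table, control)
    mask = act["passed_filters"]
    est = np.log10(act.loc[mask, "fold_activation"])
    tru = np.log10(truth.loc[est.index, "true_fold"])
    r = stats.pearsonr(est, tru)[0]
    assert r**2 > 0.95
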