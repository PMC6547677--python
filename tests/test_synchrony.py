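"""Synchrony model outputs: BLUP slopes, EMMs, slope-variance LRT, and
the pseudo-dyad surrogate null."""

import numpy as np
import pandas as pd
import pytest

from dyadsync.config import SimConfig
from dyadsync.simulate import generate_epoch_panel
from dyadsync.synchrony import (extract_dyad_slopes, fit_synchrony_model,
                                make_directed_frame, pseudo_dyad_null,
                                repair_participants)
from dyadsync.synchrony import test_random_slope as slope_variance_lrt

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


@pytest.fixture(scope="module")
def fitted_67():
    cfg = SimConfig(n_dyads=67, seed=42)
    panel = generate_epoch_panel(cfg)
    directed = make_directed_frame(panel.data)
    fit = fit_synchrony_model(directed, compute_ci=False)
    return cfg, panel, directed, fit


class TestDirectedFrame:
    def test_condition_codes_survive(self, fitted_67):
        _, panel, directed, _ = fitted_67
        assert set(directed["talk"]) == {-1, 1}
        merged = directed.drop_duplicates("dyad_id").merge(
            panel.dyad_truth, on="dyad_id")
        assert (merged["talk"] == merged["talk_code"]).all()

    def test_lag_is_previous_epoch_of_target(self, fitted_67):
        _, panel, directed, _ = fitted_67
        one = directed[(directed["dyad_id"] == 0)].sort_values(["target_id", "epoch"])
        first_target = one[one["target_id"] == one["target_id"].iloc[0]]
        series = panel.data[
            (panel.data["dyad_id"] == 0)
            & (panel.data["participant_id"] == first_target["target_id"].iloc[0])
        ].sort_values("epoch")["reactivity"].to_numpy()
        assert np.allclose(first_target["lag"].to_numpy(), series[:-1])
        assert np.allclose(first_target["y"].to_numpy(), series[1:])


class TestFitOutputs:
    def test_fixed_table_invariants(self, fitted_67):
        *_, fit = fitted_67
        tab = fit.fixed
        from scipy import stats
        tcrit = stats.t.ppf(0.975, tab["df"])
        assert np.allclose(tab["ci_lower"], tab["b"] - tcrit * tab["se"], atol=1e-9)
        assert np.allclose(tab["ci_upper"], tab["b"] + tcrit * tab["se"], atol=1e-9)
        r_check = tab["t_value"] / np.sqrt(tab["t_value"] ** 2 + tab["df"])
        assert np.allclose(tab["r"], r_check, atol=1e-12)
        assert np.all(np.sign(tab["r"]) == np.sign(tab["t_value"]))

    def test_variance_components_nonnegative_and_phi_bounded(self, fitted_67):
        *_, fit = fitted_67
        assert (fit.variance_components["variance"].dropna() >= 0).all()
        assert abs(fit.ar1_phi) < 1

    def test_recovers_truth_roughly(self, fitted_67):
        cfg, *_ , fit = fitted_67
        assert fit.lmm.beta["sync"] == pytest.approx(cfg.beta_sync, abs=0.15)
        assert fit.ar1_phi == pytest.approx(cfg.phi_ar1, abs=0.15)
        assert fit.lmm.beta["lag"] == pytest.approx(cfg.rho_lag, abs=0.12)

    def test_dyad_slope_count_matches_dyads(self, fitted_67):
        *_, fit = fitted_67
        assert len(fit.dyad_slopes) == 67
        # BLUP deviations sum to approximately zero
        assert abs(fit.dyad_slopes["deviation"].mean()) < 0.02

    def test_emm_equals_sum_of_condition_coefficients(self, fitted_67):
        *_, fit = fitted_67
        b = fit.lmm.beta
        cell = fit.emm[(fit.emm["talk"] == 1) & (fit.emm["coop"] == 1)].iloc[0]
        expect = b["intercept"] + b["talk"] + b["coop"] + b["talk_coop"]
        assert cell["emmean"] == pytest.approx(expect, abs=1e-9)
        assert cell["df"] == 63


class TestDyadSlopes:
    def test_zero_variance_data_shrinks_to_fixed_slope(self):
        cfg = SimConfig(n_dyads=30, sigma_sync=0.0, seed=6)
        d = make_directed_frame(generate_epoch_panel(cfg).data)
        fit = fit_synchrony_model(d, compute_ci=False)
        slopes = extract_dyad_slopes(fit.lmm)
        resid_sd = np.sqrt(fit.lmm.sigma2["resid"])
        assert slopes["slope"].std() < 0.1 * resid_sd

    def test_predicted_slopes_track_truth(self):
        # BLUP-truth correlation at sigma_sync=0.2, 67 dyads. The
        # information ceiling is sqrt(reliability) ~ 0.52 here: each
        # dyad's slope is estimated from ~6 effective epochs (T=9,
        # phi=0.5), giving per-dyad SE ~ 0.4 against a true slope SD of
        # 0.2; no estimator can correlate with truth above that.
        rs = []
        for seed in (13, 14, 15):
            cfg = SimConfig(n_dyads=67, sigma_sync=0.2, seed=seed)
            panel = generate_epoch_panel(cfg)
            d = make_directed_frame(panel.data)
            fit = fit_synchrony_model(d, compute_ci=False)
            merged = fit.dyad_slopes.merge(panel.dyad_truth, on="dyad_id")
            rs.append(np.corrcoef(merged["slope"], merged["s_true"])[0, 1])
        assert np.mean(rs) > 0.45


class TestRandomSlopeLRT:
    def test_df_bookkeeping_sympathetic_vs_parasympathetic(self):
        cfg = SimConfig(n_dyads=20, seed=3)
        d = make_directed_frame(generate_epoch_panel(cfg).data)
        assert slope_variance_lrt(d, branch="sns")["df"] == 2
        assert slope_variance_lrt(d, branch="pns")["df"] == 3

    def test_detects_real_slope_variance(self):
        cfg = SimConfig(n_dyads=67, sigma_sync=0.3, seed=17)
        d = make_directed_frame(generate_epoch_panel(cfg).data)
        res = slope_variance_lrt(d)
        assert res["p_value"] < 0.05


class TestPseudoDyad:
    def test_repairing_is_deterministic_given_seed(self, fitted_67):
        _, panel, *_ = fitted_67
        a = repair_participants(panel.data, np.random.default_rng(5))
        b = repair_participants(panel.data, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_no_one_keeps_their_true_partner(self, fitted_67):
        _, panel, *_ = fitted_67
        true_pairs = set()
        for _, grp in panel.data.drop_duplicates("participant_id").groupby("dyad_id"):
            pids = sorted(grp["participant_id"])
            true_pairs.add(tuple(pids))
        shuffled = repair_participants(panel.data, np.random.default_rng(2))
        for _, grp in shuffled.drop_duplicates("participant_id").groupby("dyad_id"):
            pids = tuple(sorted(grp["participant_id"]))
            assert pids not in true_pairs

    def test_strata_respected(self, fitted_67):
        _, panel, *_ = fitted_67
        people = panel.data.drop_duplicates("participant_id").set_index("participant_id")
        shuffled = repair_participants(panel.data, np.random.default_rng(3))
        for _, grp in shuffled.drop_duplicates("participant_id").groupby("dyad_id"):
            rows = people.loc[grp["participant_id"]]
            assert rows["sex"].nunique() == 1
            assert rows["talk_code"].nunique() == 1
            assert rows["coop_code"].nunique() == 1

    def test_single_dyad_stratum_skipped(self):
        cfg = SimConfig(n_dyads=12, seed=1)
        panel = generate_epoch_panel(cfg)
        data = panel.data.copy()
        data["sex"] = "F"
        # give one dyad a unique sex so its stratum cannot be re-paired
        data.loc[data["dyad_id"] == 0, "sex"] = "X"
        shuffled = repair_participants(data, np.random.default_rng(0))
        assert ("X", 1, 1) in shuffled.attrs["skipped_strata"]
        assert not shuffled["participant_id"].isin(["p000", "p001"]).any()

    def test_shared_stimulus_inflates_repaired_slope_variance(self):
        # a common task-driven signal loading on every participant makes
        # even random re-pairings look synchronised — the diagnostic's
        # purpose is to expose exactly this shared-environment artifact
        cfg = SimConfig(n_dyads=40, sigma_sync=0.0, beta_sync=0.0,
                        rho_lag=0.0, seed=30)
        panel = generate_epoch_panel(cfg)
        rng = np.random.default_rng(1)
        common = rng.normal(0, 1.2, cfg.epochs_per_task)
        codes = (panel.data["participant_id"].astype("category")
                 .cat.codes.to_numpy().astype(np.int64))
        # strong vs weak responders: pseudo-pairs then differ in how
        # coupled they appear, i.e. genuine slope variance
        loadings = np.where(codes % 2 == 0, 1.8, 0.1)
        spiked = panel.data.copy()
        spiked["reactivity"] = (spiked["reactivity"].to_numpy()
                                + loadings * common[spiked["epoch"].to_numpy()])
        base = pseudo_dyad_null(panel.data, n_repairings=3, seed=9)
        spik = pseudo_dyad_null(spiked, n_repairings=3, seed=9)
        assert (spik.results["sigma2_sync"].mean()
                > base.results["sigma2_sync"].mean() + 0.015)


def test_pseudo_dyad_null_reduces_slope_variance(fitted_67):
    """Breaking real pairings removes the dyad-specific part of the
    slope variance; what remains is the model's baseline inflation on
    panels whose regressors are other rows' outcomes."""
    _, panel, _, fit = fitted_67
    res = pseudo_dyad_null(panel.data, n_repairings=5, seed=11)
    assert res.n_repairings == 5
    true_v = fit.lmm.re_variances["sync"]
    assert res.results["sigma2_sync"].mean() < true_v
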