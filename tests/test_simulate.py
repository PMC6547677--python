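"""Synthetic-dyad generator: ground-truth recovery by independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from dyadsync.config import SimConfig
from dyadsync.ibi import segment_epochs
from dyadsync.indices import compute_log_rsa
from dyadsync.simulate import (assign_dyads, generate_affiliation_outcomes,
                               generate_dyad_ibi, generate_epoch_panel)
from dyadsync.synchrony import make_directed_frame


def dyad_ols_slopes(panel, rho=None):
    """Oracle: per-dyad OLS of the quasi-differenced outcome on the partner.

    Regressing ``y_t - rho_true * y_{t-1}`` on the partner's concurrent
    value isolates the coupling slope with a strictly exogenous
    regressor (the residual is independent of the whole partner path by
    construction), so the estimate is unbiased even at nine usable
    epochs. Estimating the lag freely instead would re-introduce
    short-series dynamic-regression bias into the oracle.
    """
    if rho is None:
        rho = panel.params["rho_lag"]
    d = make_directed_frame(panel.data)
    slopes = {}
    for dyad, grp in d.groupby("dyad_id"):
        per_direction = []
        for _, gg in grp.groupby("target_id"):
            X = gg[["intercept", "sync"]].to_numpy()
            y = (gg["y"] - rho * gg["lag"]).to_numpy()
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            per_direction.append(beta[1])
        # each direction is conditionally unbiased on its own; pooling
        # the two into one regression is a ratio of summed quadratics
        # and picks up a large small-T bias under serial correlation
        slopes[dyad] = float(np.mean(per_direction))
    return pd.Series(slopes)


class TestEpochPanel:
    def test_noiseless_degenerate_panel_is_flat(self):
        cfg = SimConfig(n_dyads=4, beta_sync=0.0, sigma_sync=0.0, rho_lag=0.0,
                        phi_ar1=0.0, sigma_resid=0.0, b0=1.7,
                        cond_effects={"talk": 0, "coop": 0, "talk:coop": 0}, seed=0)
        panel = generate_epoch_panel(cfg)
        assert np.allclose(panel.data["reactivity"], 1.7)

    def test_panel_shape_and_lag_bookkeeping(self):
        cfg = SimConfig(n_dyads=67, seed=1)
        panel = generate_epoch_panel(cfg)
        assert len(panel.data) == 67 * 2 * 10
        directed = make_directed_frame(panel.data)
        # one lag is lost per directed series
        assert len(directed) == 67 * 2 * 9

    def test_per_dyad_ols_recovers_mean_slope(self):
        # rho_lag=0 keeps the partner value strictly exogenous, making
        # the per-dyad OLS oracle unbiased even at nine usable epochs
        # (with own-lag feedback every short-series regression carries
        # O(1/T) dynamic bias and no longer qualifies as an oracle)
        cfg = SimConfig(n_dyads=67, beta_sync=0.3, sigma_sync=0.2,
                        rho_lag=0.0, seed=1)
        panel = generate_epoch_panel(cfg)
        slopes = dyad_ols_slopes(panel)
        se = slopes.std(ddof=1) / math.sqrt(len(slopes))
        assert abs(slopes.mean() - 0.3) < 3 * se

    def test_per_dyad_ols_unbiased_for_each_dyad_slope(self):
        # under symmetric coupling residual scale and partner variation
        # shrink together, so per-dyad estimates keep an O(1/sqrt(T))
        # error at any noise level; averaging long series removes it
        cfg = SimConfig(n_dyads=8, epochs_per_task=2000, sigma_sync=0.15,
                        rho_lag=0.0, seed=4)
        panel = generate_epoch_panel(cfg)
        slopes = dyad_ols_slopes(panel)
        truth = panel.dyad_truth.set_index("dyad_id")["s_true"]
        # per-dyad OLS sampling SD ~ sqrt((1-s^2)/T_eff) ~ 0.03 here
        assert np.allclose(slopes.sort_index(), truth.sort_index(), atol=0.09)
        assert abs((slopes.sort_index() - truth.sort_index()).mean()) < 0.02

    def test_slope_variance_matches_sigma_sync_at_large_n(self):
        cfg = SimConfig(n_dyads=2000, sigma_sync=0.2, seed=11)
        panel = generate_epoch_panel(cfg)
        sd = panel.dyad_truth["s_true"].std(ddof=1)
        # stability clipping shaves a few percent off the nominal SD
        assert sd == pytest.approx(0.2, rel=0.10)

    def test_residual_autocorrelation_matches_phi(self):
        # ground-truth residuals (true coefficients imposed, not re-fit:
        # a free lag coefficient would absorb the serial structure)
        cfg = SimConfig(n_dyads=1, epochs_per_task=10_000, phi_ar1=0.5,
                        sigma_sync=0.0, seed=3)
        panel = generate_epoch_panel(cfg)
        d = make_directed_frame(panel.data)
        grp = d[d["target_id"] == d["target_id"].iloc[0]].sort_values("epoch")
        truth = panel.dyad_truth.iloc[0]
        ce = cfg.cond_effects
        c = (ce["talk"] * truth["talk_code"] + ce["coop"] * truth["coop_code"]
             + ce["talk:coop"] * truth["talk_code"] * truth["coop_code"])
        resid = (grp["y"] - c - cfg.rho_lag * grp["lag"]
                 - truth["s_true"] * grp["sync"]).to_numpy()
        acf1 = np.corrcoef(resid[1:], resid[:-1])[0, 1]
        assert acf1 == pytest.approx(0.5, abs=0.05)

    def test_seed_fixed_runs_identical(self):
        cfg = SimConfig(n_dyads=5, seed=9)
        a = generate_epoch_panel(cfg)
        b = generate_epoch_panel(cfg)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(a.dyad_truth, b.dyad_truth)

    def test_condition_codes_are_plus_minus_one(self):
        meta = assign_dyads(67, np.random.default_rng(0))
        assert set(meta["talk_code"]) == {-1, 1}
        assert set(meta["coop_code"]) == {-1, 1}
        # cell sizes follow the emulated 2x2 participant counts
        counts = meta.groupby(["talk_code", "coop_code"]).size()
        assert counts[(1, 1)] == 16 and counts[(-1, -1)] == 20

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(phi_ar1=1.0)
        with pytest.raises(ValueError):
            SimConfig(epochs_per_task=1)
        with pytest.raises(ValueError):
            SimConfig(rsa_freq_hz=0.05)
        with pytest.raises(ValueError):
            SimConfig(resid_corr=[[1, 2, 0], [2, 1, 0], [0, 0, 1]])
        with pytest.raises(ValueError, match="unknown"):
            SimConfig(outcome_effects={"friendship": {"bogus_term": 1.0}})


class TestDyadIBI:
    def test_zero_amplitude_gives_constant_series(self):
        cfg = SimConfig(n_dyads=1, rsa_amp_ms=1e-9, ibi_noise_ms=0.0, seed=0,
                        sigma_resid=0.0, beta_sync=0.0, sigma_sync=0.0)
        series = generate_dyad_ibi(cfg)
        beats = next(iter(series.values()))
        assert np.allclose(beats.ibis_ms, beats.ibis_ms[0], atol=1e-6)

    def test_downstream_log_rsa_matches_target(self):
        # 40 ms modulation at 0.25 Hz -> logRSA log(800) on every task epoch
        cfg = SimConfig(n_dyads=1, rsa_amp_ms=40.0, ibi_noise_ms=0.0,
                        sigma_resid=0.0, beta_sync=0.0, sigma_sync=0.0,
                        cond_effects={"talk": 0, "coop": 0, "talk:coop": 0}, seed=0)
        series = generate_dyad_ibi(cfg)
        beats = next(iter(series.values()))
        segs = segment_epochs(beats, (0.0, 300.0), 30.0, 12.0)
        vals = [compute_log_rsa(s) for s in segs]
        assert np.allclose(vals, math.log(800.0), atol=0.1)

    def test_two_seeds_differ_but_cover_same_window(self):
        base = dict(n_dyads=1, ibi_noise_ms=2.0)
        s1 = next(iter(generate_dyad_ibi(SimConfig(seed=1, **base)).values()))
        s2 = next(iter(generate_dyad_ibi(SimConfig(seed=2, **base)).values()))
        assert not np.array_equal(s1.ibis_ms[:50], s2.ibis_ms[:50])
        assert s1.t0_s == s2.t0_s
        assert abs(s1.duration_s - s2.duration_s) < 2.0

    def test_amplitude_exceeding_base_rejected(self):
        with pytest.raises(ValueError, match="base_ibi_ms"):
            SimConfig(base_ibi_ms=70.0, rsa_amp_ms=40.0)


class TestAffiliationOutcomes:
    def test_null_effects_recovered_near_zero(self):
        cfg = SimConfig(
            n_dyads=300, seed=21,
            outcome_effects={o: {"intercept": 4.0} for o in
                             ("similarity", "friendship", "negative_affect")},
        )
        panel = generate_epoch_panel(cfg)
        table = generate_affiliation_outcomes(panel, cfg)
        import statsmodels.api as sm

        from dyadsync.simulate import affiliation_design_row
        X = np.stack([
            affiliation_design_row(r.talk_code, r.coop_code, r.react, r.sync)
            for r in table.itertuples()
        ])
        fit = sm.OLS(table["friendship"], X).fit()
        assert (np.abs(fit.params.iloc[1:]) < 3 * fit.bse.iloc[1:]).mean() > 0.9

    def test_planted_three_way_recovered_by_ols(self):
        cfg = SimConfig(n_dyads=500, seed=22)
        cfg.outcome_effects["friendship"]["talk:react:sync"] = 4.2
        panel = generate_epoch_panel(cfg)
        table = generate_affiliation_outcomes(panel, cfg)
        import statsmodels.api as sm

        from dyadsync.config import AFFILIATION_TERMS
        from dyadsync.simulate import affiliation_design_row
        X = np.stack([
            affiliation_design_row(r.talk_code, r.coop_code, r.react, r.sync)
            for r in table.itertuples()
        ])
        fit = sm.OLS(table["friendship"], X).fit()
        k = AFFILIATION_TERMS.index("talk:react:sync")
        assert abs(fit.params.iloc[k] - 4.2) < 3 * fit.bse.iloc[k]

    def test_identity_resid_corr_gives_uncorrelated_residuals(self):
        cfg = SimConfig(
            n_dyads=400, seed=23, resid_corr=np.eye(3).tolist(),
            outcome_dyad_sd={"similarity": 0.0, "friendship": 0.0, "negative_affect": 0.0},
            outcome_effects={o: {"intercept": 4.0} for o in
                             ("similarity", "friendship", "negative_affect")},
        )
        panel = generate_epoch_panel(cfg)
        table = generate_affiliation_outcomes(panel, cfg)
        corr = table[["similarity", "friendship", "negative_affect"]].corr()
        off = corr.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.12)
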