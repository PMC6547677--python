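"""Residualized-change reactivity scores.

Reactivity is operationalised as residualized change: per autonomic
branch, task-epoch index values are regressed on the participant's
baseline summary pooled across the whole sample, and the residual is
the reactivity score. Pooling (rather than residualizing within
condition) deliberately leaves condition effects in the scores — they
are what the synchrony model estimates. When the sample has no baseline
variance the regression is degenerate and simple change scores are used
instead, with a logged warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)


def residualized_change(task_panel: pd.DataFrame, baseline: pd.DataFrame,
                        value_col: str, baseline_col: str = "baseline"
                        ) -> tuple[pd.DataFrame, dict]:
    """Residualize task-epoch index values on participant baselines.

    Parameters
    ----------
    task_panel:
        Long table with ``participant_id``, ``epoch`` and ``value_col``.
    baseline:
        One row per participant: ``participant_id`` and ``baseline_col``
        (mean index over the baseline epochs).

    Returns the panel with a ``reactivity`` column plus a dict recording
    the pooled slope/intercept (or the change-score fallback).
    """
    merged = task_panel.merge(baseline[["participant_id", baseline_col]],
                              on="participant_id", how="left", validate="many_to_one")
    if merged[baseline_col].isna().any():
        missing = merged.loc[merged[baseline_col].isna(), "participant_id"].unique()
        raise ValueError(f"participants without baseline: {list(missing)[:5]}")
    ok = merged[value_col].notna()
    b = merged.loc[ok, baseline_col].to_numpy(dtype=float)
    y = merged.loc[ok, value_col].to_numpy(dtype=float)
    if np.std(b) < 1e-12:
        log.warning("zero baseline variance: falling back to simple change scores")
        merged["reactivity"] = merged[value_col] - merged[baseline_col]
        info = {"method": "change_score", "slope": 1.0, "intercept": 0.0}
        return merged, info
    X = sm.add_constant(b)
    fit = sm.OLS(y, X).fit()
    merged["reactivity"] = merged[value_col] - (
        fit.params[0] + fit.params[1] * merged[baseline_col]
    )
    info = {"method": "residualized_change", "intercept": float(fit.params[0]),
            "slope": float(fit.params[1])}
    return merged, info


def baseline_condition_check(baseline: pd.DataFrame, baseline_col: str = "baseline",
                             code_col: str = "talk_code") -> dict:
    """Between-condition contrast on baseline levels (confound check).

    Regresses the participant baseline on the +/-1 condition code; the
    slope is half the between-condition mean difference. Returns
    estimate, SE, t, df and p.
    """
    b = baseline[baseline_col].to_numpy(dtype=float)
    code = baseline[code_col].to_numpy(dtype=float)
    if np.allclose(b, b[0]):
        return {"estimate": 0.0, "se": 0.0, "t_value": 0.0,
                "df": len(b) - 2, "p_value": 1.0}
    fit = sm.OLS(b, sm.add_constant(code)).fit()
    t_val = float(fit.tvalues[1])
    df = float(fit.df_resid)
    return {
        "estimate": float(fit.params[1]),
        "se": float(fit.bse[1]),
        "t_value": t_val,
        "df": df,
        "p_value": float(2 * stats.t.sf(abs(t_val), df)),
    }
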