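"""The dyadic synchrony mixed model and its diagnostics.

For one autonomic branch, each member of a dyad serves in turn as the
modelled "partner": their per-epoch reactivity is regressed on their own
lag-1 value, the other member's concurrent reactivity (the synchrony
term), the two +/-1 condition codes, and all their interactions with
synchrony, in a 3-level model (epochs in participants in dyads) with a
dyad-level random synchrony slope and AR(1) epoch residuals. The
reliability of between-dyad slope differences is tested by a likelihood
ratio on the slope (co)variance; a pseudo-dyad surrogate analysis
re-pairs participants within sex x condition strata to check that the
slope variance vanishes when partners never actually interacted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import (LMMFit, LMMSpec, effect_size_r, fit_lmm,
                  likelihood_ratio_test, profile_ci)

FIXED_TERMS = [
    "intercept", "lag", "sync", "talk", "coop",
    "sync_talk", "sync_coop", "talk_coop", "sync_talk_coop",
]

DISPLAY_NAMES = {
    "intercept": "Intercept",
    "lag": "Lagged Partner",
    "sync": "Synchrony",
    "talk": "Talking/No Talking",
    "coop": "Cooperative/Competitive",
    "sync_talk": "Synchrony x Talking/No Talking",
    "sync_coop": "Synchrony x Cooperative/Competitive",
    "talk_coop": "Talking/No Talking x Cooperative/Competitive",
    "sync_talk_coop": "Synchrony x Talking/No Talking x Cooperative/Competitive",
}


def make_directed_frame(panel: pd.DataFrame, value_col: str = "reactivity") -> pd.DataFrame:
    """Both directed observations per dyad with within-series lags.

    For each dyad and each ordering (actor -> target), the target's
    epoch value is the outcome, the target's previous epoch value is
    ``lag``, and the actor's concurrent value is ``sync``; the first
    epoch of each series is dropped. Condition codes are +/-1 as coded
    in the panel.
    """
    needed = {"dyad_id", "participant_id", "epoch", "talk_code", "coop_code", value_col}
    missing = needed - set(panel.columns)
    if missing:
        raise ValueError(f"panel lacks columns {sorted(missing)}")
    meta = panel.drop_duplicates("dyad_id").set_index("dyad_id")
    rows = []
    for dyad_id, sub in panel.groupby("dyad_id", sort=True):
        grp = sub.pivot_table(index="epoch", columns="participant_id",
                              values=value_col, sort=True).sort_index()
        pids = list(grp.columns)
        if len(pids) != 2:
            raise ValueError(f"dyad {dyad_id} does not have exactly two participants")
        talk = int(meta.loc[dyad_id, "talk_code"])
        coop = int(meta.loc[dyad_id, "coop_code"])
        sex = meta.loc[dyad_id, "sex"] if "sex" in meta.columns else ""
        epochs = grp.index.to_numpy()
        for target, actor in ((pids[0], pids[1]), (pids[1], pids[0])):
            y = grp[target].to_numpy(dtype=float)
            x = grp[actor].to_numpy(dtype=float)
            for k in range(1, len(epochs)):
                rows.append(
                    {
                        "dyad_id": dyad_id,
                        "target_id": target,
                        "actor_id": actor,
                        "epoch": int(epochs[k]),
                        "y": y[k],
                        "lag": y[k - 1],
                        "sync": x[k],
                        "talk": talk,
                        "coop": coop,
                        "sex": sex,
                    }
                )
    out = pd.DataFrame(rows).dropna(subset=["y", "lag", "sync"]).reset_index(drop=True)
    out["intercept"] = 1.0
    out["sync_talk"] = out["sync"] * out["talk"]
    out["sync_coop"] = out["sync"] * out["coop"]
    out["talk_coop"] = out["talk"] * out["coop"]
    out["sync_talk_coop"] = out["sync"] * out["talk"] * out["coop"]
    return out


def _spec(random_lag: bool, ar1: bool = True) -> LMMSpec:
    re = ["intercept", "sync"] + (["lag"] if random_lag else [])
    return LMMSpec(
        y="y", x=list(FIXED_TERMS), cluster="dyad_id", re=re,
        subject="target_id", ar1=ar1, series="target_id", time="epoch",
    )


@dataclass
class SynchronyFit:
    """Full synchrony-model output for one branch."""

    branch: str
    lmm: LMMFit
    fixed: pd.DataFrame
    variance_components: pd.DataFrame
    ar1_phi: float | None
    phi_ci: tuple[float, float] | None
    dyad_slopes: pd.DataFrame
    emm: pd.DataFrame


def fit_synchrony_model(directed: pd.DataFrame, branch: str = "sns",
                        random_lag: bool | None = None, ar1: bool = True,
                        compute_ci: bool = False) -> SynchronyFit:
    """Fit the 3-level synchrony model on a directed frame.

    ``random_lag`` adds a dyad-level random slope for the lagged own
    value (the parasympathetic specification); by default it is on for
    ``branch="pns"``. ``compute_ci`` turns on profile-likelihood
    intervals for phi and the variance components (slow; meant for a
    single headline fit, not replicate studies).
    """
    if random_lag is None:
        random_lag = branch == "pns"
    spec = _spec(random_lag, ar1)
    fit = fit_lmm(directed, spec)

    fixed = fit.fixed.copy()
    fixed.index = [DISPLAY_NAMES.get(t, t) for t in fixed.index]

    comps = []
    ci_map = {}
    if compute_ci:
        for col in spec.re:
            ci_map[col] = profile_ci(fit, f"log_sd({col})")
        ci_map["_subject"] = profile_ci(fit, f"log_sd({spec.subject})")
        ci_map["_resid"] = profile_ci(fit, "log_sigma(resid)")
    for col, label in (("intercept", "Dyad Intercept"), ("sync", "Synchrony"),
                       ("lag", "Lagged Partner")):
        if col in spec.re:
            lo, hi = ci_map.get(col, (np.nan, np.nan))
            comps.append({"component": label, "variance": fit.re_variances[col],
                          "ci_lower": lo, "ci_upper": hi})
    lo, hi = ci_map.get("_subject", (np.nan, np.nan))
    comps.append({"component": "Participant Intercept", "variance": fit.tau2,
                  "ci_lower": lo, "ci_upper": hi})
    lo, hi = ci_map.get("_resid", (np.nan, np.nan))
    comps.append({"component": "Residual", "variance": fit.sigma2["resid"],
                  "ci_lower": lo, "ci_upper": hi})
    variance_components = pd.DataFrame(comps).set_index("component")

    phi_ci = None
    if ar1 and compute_ci:
        phi_ci = profile_ci(fit, "atanh_phi")

    dyad_slopes = extract_dyad_slopes(fit)
    emm = condition_emms(fit)
    return SynchronyFit(
        branch=branch, lmm=fit, fixed=fixed,
        variance_components=variance_components,
        ar1_phi=fit.phi, phi_ci=phi_ci, dyad_slopes=dyad_slopes, emm=emm,
    )


def extract_dyad_slopes(fit: LMMFit) -> pd.DataFrame:
    """Per-dyad synchrony coefficient: fixed slope + BLUP deviation."""
    if "b(sync)" not in fit.blups.columns:
        raise ValueError("fit has no dyad-level synchrony random slope")
    out = fit.blups[[fit.spec.cluster, "b(sync)"]].copy()
    out = out.rename(columns={"b(sync)": "deviation"})
    out["slope"] = fit.beta["sync"] + out["deviation"]
    return out


def condition_emms(fit: LMMFit) -> pd.DataFrame:
    """Estimated marginal reactivity means per condition cell (at sync = lag = 0)."""
    rows = []
    df_cond = float(fit.df_by_term["talk"])
    for talk in (1, -1):
        for coop in (1, -1):
            w = {"intercept": 1.0, "talk": float(talk), "coop": float(coop),
                 "talk_coop": float(talk * coop)}
            c = fit.contrast(w, df=df_cond)
            rows.append({"talk": talk, "coop": coop, "emmean": c["estimate"],
                         "se": c["se"], "ci_lower": c["ci_lower"],
                         "ci_upper": c["ci_upper"], "t_value": c["t_value"],
                         "df": c["df"], "p_value": c["p_value"]})
    return pd.DataFrame(rows)


def test_random_slope(directed: pd.DataFrame, branch: str = "sns",
                      random_lag: bool | None = None, ar1: bool = True,
                      full_fit: LMMFit | None = None) -> dict:
    """LRT for the dyad-level synchrony slope (co)variance.

    Removing the slope drops its variance plus its covariances with the
    other dyad-level effects: 2 parameters for the sympathetic
    specification, 3 for the parasympathetic one.
    """
    if random_lag is None:
        random_lag = branch == "pns"
    full = full_fit if full_fit is not None else fit_lmm(directed, _spec(random_lag, ar1))
    reduced_re = [c for c in full.spec.re if c != "sync"]
    reduced_spec = LMMSpec(**{**full.spec.__dict__, "re": reduced_re})
    reduced = fit_lmm(directed, reduced_spec, compute_blups=False)
    res = likelihood_ratio_test(full, reduced)
    res["sigma2_sync"] = full.re_variances.get("sync", 0.0)
    return res


# ---------------------------------------------------------------------------
# pseudo-dyad surrogate null
# ---------------------------------------------------------------------------

@dataclass
class PseudoDyadResult:
    n_repairings: int
    results: pd.DataFrame  # one row per re-pairing: sigma2_sync, chi2, df, p
    skipped_strata: list

    @property
    def prop_nonsignificant(self) -> float:
        return float((self.results["lrt_p"] > 0.05).mean())


def repair_participants(panel: pd.DataFrame, rng: np.random.Generator
                        ) -> pd.DataFrame | None:
    """One random re-pairing within sex x condition strata.

    Participants are paired uniformly at random without replacement
    inside each stratum, never with their true partner; a stratum with
    a single dyad cannot be re-paired and is skipped. Returns a panel
    with pseudo dyad ids, or None if no stratum could be re-paired.
    """
    people = panel.drop_duplicates("participant_id")[
        ["participant_id", "dyad_id", "sex", "talk_code", "coop_code"]
    ]
    pieces = []
    next_id = 0
    skipped = []
    for (sex, talk, coop), grp in people.groupby(["sex", "talk_code", "coop_code"], sort=True):
        pids = grp["participant_id"].tolist()
        true_dyad = dict(zip(grp["participant_id"], grp["dyad_id"]))
        if len(set(true_dyad.values())) < 2:
            skipped.append((sex, talk, coop))
            continue
        for _ in range(200):
            order = list(rng.permutation(pids))
            pairs = [(order[2 * k], order[2 * k + 1]) for k in range(len(order) // 2)]
            if all(true_dyad[a] != true_dyad[b] for a, b in pairs):
                break
        else:  # pragma: no cover - vanishingly unlikely with >= 2 dyads
            skipped.append((sex, talk, coop))
            continue
        for a, b in pairs:
            sub = panel[panel["participant_id"].isin([a, b])].copy()
            sub["dyad_id"] = next_id
            sub["talk_code"], sub["coop_code"] = talk, coop
            pieces.append(sub)
            next_id += 1
    if not pieces:
        return None
    out = pd.concat(pieces, ignore_index=True)
    out.attrs["skipped_strata"] = skipped
    return out


def pseudo_dyad_null(panel: pd.DataFrame, n_repairings: int = 20,
                     seed: int | np.random.Generator = 0, branch: str = "sns",
                     random_lag: bool | None = None, ar1: bool = True) -> PseudoDyadResult:
    """Re-pair, refit and test the slope variance, ``n_repairings`` times."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    skipped: list = []
    for k in range(n_repairings):
        shuffled = repair_participants(panel, rng)
        if shuffled is None:
            warnings.warn("no stratum could be re-paired; returning empty result")
            break
        skipped = shuffled.attrs.get("skipped_strata", [])
        directed = make_directed_frame(shuffled)
        res = test_random_slope(directed, branch=branch, random_lag=random_lag, ar1=ar1)
        rows.append(
            {"repairing": k, "sigma2_sync": res["sigma2_sync"],
             "lrt_chi2": res["chi2"], "lrt_df": res["df"], "lrt_p": res["p_value"]}
        )
    return PseudoDyadResult(
        n_repairings=len(rows), results=pd.DataFrame(rows), skipped_strata=skipped
    )


__all__ = [
    "FIXED_TERMS", "DISPLAY_NAMES", "SynchronyFit", "PseudoDyadResult",
    "make_directed_frame", "fit_synchrony_model", "extract_dyad_slopes",
    "condition_emms", "test_random_slope", "repair_participants",
    "pseudo_dyad_null", "effect_size_r",
]
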