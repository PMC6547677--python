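"""Multivariate multilevel models linking synchrony to affiliation.

The three affiliation outcomes (perceived similarity, friendship
interest, negative affect) are stacked into one long response and
modelled jointly: each outcome gets its own full set of fixed effects —
conditions x reactivity x synchrony up to the 4-way product — its own
residual variance, and a dyad-level random intercept; the three dyad
intercepts are allowed to correlate, which is what makes the model
multivariate. Simple effects are probed at +/-1 SD of the continuous
moderators within condition cells, with Tukey-adjusted p-values over
each family of pairwise comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

from .config import AFFILIATION_TERMS, OUTCOMES
from .lmm import LMMFit, LMMSpec, fit_lmm
from .simulate import affiliation_design_row

TERM_DISPLAY = {
    "intercept": "Intercept",
    "talk": "Talking/No Talking",
    "coop": "Cooperative/Competitive",
    "react": "Reactivity",
    "sync": "Synchrony",
    "talk:coop": "Talking/No Talking x Cooperative/Competitive",
    "talk:react": "Talking/No Talking x Reactivity",
    "coop:react": "Cooperative/Competitive x Reactivity",
    "talk:sync": "Talking/No Talking x Synchrony",
    "coop:sync": "Cooperative/Competitive x Synchrony",
    "react:sync": "Reactivity x Synchrony",
    "talk:coop:react": "Talking/No Talking x Cooperative/Competitive x Reactivity",
    "talk:coop:sync": "Talking/No Talking x Cooperative/Competitive x Synchrony",
    "talk:react:sync": "Talking/No Talking x Reactivity x Synchrony",
    "coop:react:sync": "Cooperative/Competitive x Reactivity x Synchrony",
    "talk:coop:react:sync":
        "Talking/No Talking x Cooperative/Competitive x Reactivity x Synchrony",
}


def stack_outcomes(table: pd.DataFrame, outcomes=OUTCOMES) -> pd.DataFrame:
    """Long format: one row per participant x outcome, with the full
    outcome-specific fixed-effect design and outcome indicator columns."""
    needed = {"participant_id", "dyad_id", "talk_code", "coop_code", "react", "sync"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"affiliation table lacks columns {sorted(missing)}")
    rows = []
    for rec in table.itertuples(index=False):
        x = affiliation_design_row(rec.talk_code, rec.coop_code, rec.react, rec.sync)
        for o in outcomes:
            row = {
                "participant_id": rec.participant_id,
                "dyad_id": rec.dyad_id,
                "outcome": o,
                "value": getattr(rec, o),
            }
            for oo in outcomes:
                ind = 1.0 if oo == o else 0.0
                row[f"re[{oo}]"] = ind
                for k, term in enumerate(AFFILIATION_TERMS):
                    row[f"{term}[{oo}]"] = ind * x[k]
            rows.append(row)
    return pd.DataFrame(rows)


def _x_cols(outcomes=OUTCOMES) -> list[str]:
    return [f"{term}[{o}]" for o in outcomes for term in AFFILIATION_TERMS]


@dataclass
class AffiliationFit:
    branch: str
    lmm: LMMFit
    tables: dict[str, pd.DataFrame]      # per-outcome fixed-effect tables
    dyad_corr: pd.DataFrame              # cross-outcome random-intercept correlations
    resid_var: dict[str, float]
    moderator_sd: dict[str, float]
    fallback: bool


def fit_multivariate_affiliation(table: pd.DataFrame, branch: str = "sns",
                                 outcomes=OUTCOMES,
                                 re_structure: str = "unstructured") -> AffiliationFit:
    """Fit the stacked multivariate model for one autonomic branch.

    Random intercepts per outcome are nested in dyads and correlated;
    residual variances are outcome-specific. If the unstructured
    random-intercept covariance cannot be estimated the fit falls back
    to a diagonal structure and is flagged.
    """
    long = stack_outcomes(table, outcomes)
    # REML: with 48 fixed effects in ~400 rows the ML variance bias
    # (factor (n-p)/n ~ 0.88) would make every test anticonservative;
    # no variance-component LRT is run on this model, so REML is safe
    spec = LMMSpec(
        y="value", x=_x_cols(outcomes), cluster="dyad_id",
        re=[f"re[{o}]" for o in outcomes], var_group="outcome",
        re_structure=re_structure, method="reml",
    )
    fit = fit_lmm(long, spec)
    fallback = fit.spec.re_structure == "diagonal" and re_structure == "unstructured"

    tables = {}
    for o in outcomes:
        rows = []
        for term in AFFILIATION_TERMS:
            rec = fit.fixed.loc[f"{term}[{o}]"]
            rows.append({"term": TERM_DISPLAY[term], **rec.to_dict()})
        tables[o] = pd.DataFrame(rows).set_index("term")

    G = fit.G0.to_numpy()
    sd = np.sqrt(np.clip(np.diag(G), 1e-300, None))
    corr = G / np.outer(sd, sd)
    dyad_corr = pd.DataFrame(corr, index=list(outcomes), columns=list(outcomes))
    moderator_sd = {
        "react": float(table["react"].std(ddof=1)),
        "sync": float(table["sync"].std(ddof=1)),
        "react_mean": float(table["react"].mean()),
        "sync_mean": float(table["sync"].mean()),
    }
    return AffiliationFit(
        branch=branch, lmm=fit, tables=tables, dyad_corr=dyad_corr,
        resid_var={o: fit.sigma2[o] for o in outcomes},
        moderator_sd=moderator_sd, fallback=fallback,
    )


def tukey_adjust(t_value: float, k: int, df: float) -> float:
    """Tukey HSD adjusted p for one of the pairwise contrasts among k means.

    Uses the studentized range: p = P(Q_{k,df} > sqrt(2)|t|). For k = 2
    this equals the unadjusted two-sided t probability.
    """
    if k < 2:
        raise ValueError("need at least two means in the family")
    q = math_sqrt2 * abs(t_value)
    return float(studentized_range.sf(q, k, df))


math_sqrt2 = float(np.sqrt(2.0))


def probe_simple_effects(fit: AffiliationFit, outcome: str,
                         moderators: list[str] = ("talk",),
                         at_sd: float = 1.0) -> dict[str, pd.DataFrame]:
    """EMMs and Tukey-adjusted pairwise contrasts for one outcome.

    Cells are every combination of the requested condition moderators
    (+/-1) with reactivity and synchrony at mean -/+ ``at_sd`` sample
    SDs; condition factors not probed are averaged over (set to 0).
    Only adjusted p-values are reported for the contrasts.
    """
    for m in moderators:
        if m not in ("talk", "coop"):
            raise ValueError(f"moderator {m!r} is not in the model")
    sds = fit.moderator_sd
    react_pts = [sds["react_mean"] - at_sd * sds["react"],
                 sds["react_mean"] + at_sd * sds["react"]]
    sync_pts = [sds["sync_mean"] - at_sd * sds["sync"],
                sds["sync_mean"] + at_sd * sds["sync"]]
    cond_levels = [(-1, 1)] * len(moderators)

    cells = []
    for combo in itertools.product(*cond_levels, react_pts, sync_pts):
        conds = dict(zip(moderators, combo[: len(moderators)]))
        react, sync = combo[-2], combo[-1]
        talk = float(conds.get("talk", 0.0))
        coop = float(conds.get("coop", 0.0))
        x = affiliation_design_row(talk, coop, react, sync)
        weights = {
            f"{term}[{outcome}]": x[k] for k, term in enumerate(AFFILIATION_TERMS)
        }
        cells.append({"label": _cell_label(conds, react, sync, sds),
                      "weights": weights, **conds, "react": react, "sync": sync})

    df_contrast = float(min(fit.lmm.df_by_term[f"{t}[{outcome}]"]
                            for t in AFFILIATION_TERMS))
    emm_rows = []
    for cell in cells:
        c = fit.lmm.contrast(cell["weights"], df=df_contrast)
        emm_rows.append({"cell": cell["label"], "emmean": c["estimate"],
                         "se": c["se"], "df": c["df"],
                         "ci_lower": c["ci_lower"], "ci_upper": c["ci_upper"]})
    emms = pd.DataFrame(emm_rows).set_index("cell")

    k = len(cells)
    rows = []
    for a, b in itertools.combinations(cells, 2):
        w = {key: a["weights"].get(key, 0.0) - b["weights"].get(key, 0.0)
             for key in set(a["weights"]) | set(b["weights"])}
        c = fit.lmm.contrast(w, df=df_contrast)
        rows.append(
            {
                "contrast": f"{a['label']} - {b['label']}",
                "estimate": c["estimate"],
                "se": c["se"],
                "t_value": c["t_value"],
                "df": c["df"],
                "p_adjusted": tukey_adjust(c["t_value"], k, c["df"]),
            }
        )
    return {"emmeans": emms, "contrasts": pd.DataFrame(rows)}


def _cell_label(conds: dict, react: float, sync: float, sds: dict) -> str:
    parts = []
    for key, val in conds.items():
        name = {"talk": ("Talking", "No Talking"), "coop": ("Cooperative", "Competitive")}[key]
        parts.append(name[0] if val > 0 else name[1])
    parts.append("react+1SD" if react > sds["react_mean"] else "react-1SD")
    parts.append("sync+1SD" if sync > sds["sync_mean"] else "sync-1SD")
    return ", ".join(parts)
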