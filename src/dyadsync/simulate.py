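"""Synthetic dyads with known ground truth.

Two entry points at different levels of rawness:

* :func:`generate_epoch_panel` draws epoch-level reactivity values whose
  statistical structure is exactly the one the downstream synchrony
  model assumes. Within a dyad the two partners' per-epoch innovations
  are jointly Gaussian with cross-correlation equal to the dyad's
  coupling slope ``s_d = beta_sync + u_d`` and evolve as a vector AR(1)
  in ``phi_ar1``; the conditional expectation of either member's value
  given the partner's is then ``b0 + rho_lag * own lag + s_d * partner +
  condition terms`` for *both* directed orderings, with homoscedastic
  AR(1) residuals of SD ``sigma_resid``. This is the unique Gaussian
  construction under which the directed regression is correctly
  specified in both directions, so the generator's parameters are the
  estimands of the fitted model.

* :func:`generate_dyad_ibi` emulates the raw interbeat-interval series
  feeding the QC/index stages: a base heart period with sinusoidal
  respiratory modulation inside 0.12-0.40 Hz whose per-epoch amplitude
  tracks the dyad's target logRSA trajectory, plus white measurement
  jitter.

:func:`inject_artifacts` plants beat splits (a spuriously detected extra
R wave turns one interval into two short ones) with ground-truth
bookkeeping, and :func:`generate_affiliation_outcomes` draws correlated
affiliation outcomes from per-dyad synchrony slopes and per-participant
mean reactivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import AFFILIATION_TERMS, OUTCOMES, SimConfig, spawn_seed
from .ibi import BeatSeries

BURN_IN = 30

# participant-count pattern of the 2x2 between-dyad design: dyad counts
# 16/16/15/20 across (talk, coop) cells reproduce 32/32/30/40 participants
CELL_DYADS = {(1, 1): 16, (1, -1): 16, (-1, 1): 15, (-1, -1): 20}


@dataclass
class EpochPanel:
    """Long per-epoch panel plus the ground truth that generated it."""

    data: pd.DataFrame
    dyad_truth: pd.DataFrame
    participant_truth: pd.DataFrame
    params: dict

    @property
    def n_dyads(self) -> int:
        return self.data["dyad_id"].nunique()


def assign_dyads(n_dyads: int, rng: np.random.Generator) -> pd.DataFrame:
    """Dyad metadata: condition cell, sex label, participant ids.

    Cells follow the 2x2 pattern of the emulated design scaled to
    ``n_dyads``; roughly 70% of dyads are female pairs.
    """
    cells = list(CELL_DYADS)
    weights = np.array([CELL_DYADS[c] for c in cells], dtype=float)
    counts = np.floor(weights / weights.sum() * n_dyads).astype(int)
    while counts.sum() < n_dyads:
        counts[int(np.argmax(weights / weights.sum() * n_dyads - counts))] += 1
    rows = []
    d = 0
    for (talk, coop), c in zip(cells, counts):
        for _ in range(c):
            rows.append(
                {
                    "dyad_id": d,
                    "talk_code": talk,
                    "coop_code": coop,
                    "sex": "F" if (d % 10) < 7 else "M",
                    "participant_a": f"p{2 * d:03d}",
                    "participant_b": f"p{2 * d + 1:03d}",
                }
            )
            d += 1
    return pd.DataFrame(rows)


def _dyad_slope(cfg: SimConfig, u: float, talk: int, coop: int) -> float:
    s = cfg.beta_sync + u
    mod = cfg.sync_cond_effects
    s += mod.get("talk", 0.0) * talk + mod.get("coop", 0.0) * coop
    s += mod.get("talk:coop", 0.0) * talk * coop
    # keep the coupled mean recursion stationary: its spectral radius is
    # |rho|/(1-|s|), so |s| must stay below 1-|rho| (with margin)
    bound = min(0.95, 0.93 * (1.0 - abs(cfg.rho_lag)))
    return float(np.clip(s, -bound, bound))


def generate_epoch_panel(config: SimConfig, branch: str = "sns",
                         rng: np.random.Generator | None = None) -> EpochPanel:
    """Draw the epoch-level reactivity panel for one autonomic branch.

    Returns one row per participant x epoch (``n_dyads * 2 *
    epochs_per_task`` rows) with condition codes, plus dyad- and
    participant-level ground truth.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(spawn_seed(cfg.seed, "panel", branch))
    meta = assign_dyads(cfg.n_dyads, rng)
    T = cfg.epochs_per_task
    phi = cfg.phi_ar1
    rho = cfg.rho_lag
    ce = cfg.cond_effects

    data_rows = []
    dyad_rows = []
    part_rows = []
    for row in meta.itertuples(index=False):
        talk, coop = int(row.talk_code), int(row.coop_code)
        u = rng.normal(0.0, cfg.sigma_sync)
        s = _dyad_slope(cfg, u, talk, coop)
        g = rng.normal(0.0, cfg.sd_dyad_intercept)
        p_a = rng.normal(0.0, cfg.sd_participant_intercept)
        p_b = rng.normal(0.0, cfg.sd_participant_intercept)
        cond_shift = (
            ce.get("talk", 0.0) * talk
            + ce.get("coop", 0.0) * coop
            + ce.get("talk:coop", 0.0) * talk * coop
        )
        c = np.array([cfg.b0 + g + p_a + cond_shift, cfg.b0 + g + p_b + cond_shift])

        # mixing matrix of the simultaneous conditional system
        M = np.array([[1.0, s], [s, 1.0]]) / (1.0 - s * s)
        # participants are exchangeable: every series has the same
        # marginal innovation variance (anchored so the mean dyad's
        # directed residual SD is sigma_resid); residual variance then
        # varies mildly with the dyad's coupling strength
        sigma_a2 = cfg.sigma_resid**2 / (1.0 - cfg.beta_sync**2)
        S_a = sigma_a2 * np.array([[1.0, s], [s, 1.0]])
        S_w = (1.0 - phi * phi) * S_a
        Lw = np.linalg.cholesky(S_w) if cfg.sigma_resid > 0 else np.zeros((2, 2))
        La = np.linalg.cholesky(S_a) if cfg.sigma_resid > 0 else np.zeros((2, 2))

        # stationary mean as burn-in start
        try:
            y = np.linalg.solve(np.eye(2) - rho * M, M @ c)
        except np.linalg.LinAlgError:
            y = c.copy()
        a = La @ rng.normal(size=2)
        kept = np.empty((T, 2))
        for t in range(-BURN_IN, T):
            if t == 1:
                # epoch 0 only seeds the lag; restarting the innovation
                # chain keeps the first modelled residual independent of
                # it, exactly as the fitted model assumes of its initial
                # (conditioned-on) lag value
                a = La @ rng.normal(size=2)
            else:
                a = phi * a + Lw @ rng.normal(size=2)
            y = M @ (c + rho * y) + a
            if t >= 0:
                kept[t] = y

        dyad_rows.append(
            {
                "dyad_id": row.dyad_id,
                "s_true": s,
                "u_true": u,
                "dyad_intercept": g,
                "talk_code": talk,
                "coop_code": coop,
                "sex": row.sex,
            }
        )
        for which, pid, partner, p_eff in (
            (0, row.participant_a, row.participant_b, p_a),
            (1, row.participant_b, row.participant_a, p_b),
        ):
            part_rows.append(
                {"participant_id": pid, "dyad_id": row.dyad_id, "participant_intercept": p_eff}
            )
            for t in range(T):
                data_rows.append(
                    {
                        "dyad_id": row.dyad_id,
                        "participant_id": pid,
                        "partner_id": partner,
                        "epoch": t,
                        "branch": branch,
                        "talk_code": talk,
                        "coop_code": coop,
                        "sex": row.sex,
                        "reactivity": kept[t, which],
                    }
                )

    return EpochPanel(
        data=pd.DataFrame(data_rows),
        dyad_truth=pd.DataFrame(dyad_rows),
        participant_truth=pd.DataFrame(part_rows),
        params={"branch": branch, **cfg.to_dict()},
    )


# ---------------------------------------------------------------------------
# Raw IBI emulation
# ---------------------------------------------------------------------------

def _ibi_series_for_participant(cfg: SimConfig, targets_log_rsa: np.ndarray,
                                rng: np.random.Generator, pad_s: float = 14.0
                                ) -> BeatSeries:
    """One participant's IBI series spanning baseline + task (+ margins).

    ``targets_log_rsa`` gives the per-task-epoch logRSA trajectory; the
    sinusoidal amplitude within task epoch t is ``sqrt(2*exp(target_t))``
    so the band-limited variance of the modulation matches the target.
    """
    task_s = cfg.epochs_per_task * cfg.epoch_s
    start = -(cfg.baseline_s + pad_s)
    end = task_s + pad_s
    base_amp = cfg.rsa_amp_ms
    amps = np.sqrt(2.0 * np.exp(targets_log_rsa))

    def amp_at(t: float) -> float:
        if t < 0:
            return base_amp
        k = min(int(t // cfg.epoch_s), len(amps) - 1)
        return float(amps[k])

    ibis = []
    t = start
    f = cfg.rsa_freq_hz
    while t < end:
        ibi = cfg.base_ibi_ms + amp_at(t) * math.sin(2 * math.pi * f * (t - start))
        ibi += cfg.ibi_noise_ms * rng.normal()
        ibi = max(ibi, 0.25 * cfg.base_ibi_ms)
        ibis.append(ibi)
        t += ibi / 1000.0
    return BeatSeries(np.asarray(ibis), t0_s=start, provenance="raw")


def generate_dyad_ibi(config: SimConfig, panel: EpochPanel | None = None,
                      rng: np.random.Generator | None = None
                      ) -> dict[tuple[int, str], BeatSeries]:
    """Raw IBI series for every participant (two BeatSeries per dyad).

    When ``panel`` is given (a parasympathetic-branch epoch panel), each
    participant's per-epoch sinusoid amplitude is modulated so the
    downstream logRSA trajectory tracks the baseline level plus that
    participant's panel reactivity; otherwise the amplitude is constant.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(spawn_seed(cfg.seed, "ibi"))
    base_log_rsa = math.log(cfg.rsa_amp_ms**2 / 2.0)
    if panel is None:
        panel = generate_epoch_panel(cfg, branch="pns",
                                     rng=np.random.default_rng(spawn_seed(cfg.seed, "panel", "pns")))
    out: dict[tuple[int, str], BeatSeries] = {}
    for (dyad_id, pid), grp in panel.data.groupby(["dyad_id", "participant_id"], sort=True):
        targets = base_log_rsa + grp.sort_values("epoch")["reactivity"].to_numpy()
        series = _ibi_series_for_participant(cfg, targets, rng)
        out[(int(dyad_id), str(pid))] = replace(series, dyad_id=int(dyad_id),
                                                participant_id=str(pid))
    return out


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

@dataclass
class InjectionResult:
    """Artifact-planted series plus ground truth for QC evaluation."""

    beats: BeatSeries
    split_indices: np.ndarray  # index (output coordinates) of each first fragment
    original: BeatSeries


def inject_artifacts(beats: BeatSeries, rate: float,
                     rng: np.random.Generator | int | None = None) -> InjectionResult:
    """Split a proportion ``rate`` of beats in two (extra-R-wave analog).

    Each selected interval of length x becomes two fragments ``u*x`` and
    ``x - u*x`` with ``u ~ U(0.4, 0.6)``, so the pair sums to the
    original exactly and both fragments are short enough for the 0.6
    ratio rule to catch the second one against the following beat.
    """
    if not (0 <= rate < 0.5):
        raise ValueError("rate must lie in [0, 0.5)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: list[float] = []
    split_at: list[int] = []
    for x in beats.ibis_ms:
        if rate > 0 and rng.random() < rate:
            u = rng.uniform(0.4, 0.6)
            first = u * x
            split_at.append(len(out))
            out.append(first)
            out.append(x - first)
        else:
            out.append(float(x))
    new = replace(beats, ibis_ms=np.asarray(out), flags=None, provenance="raw")
    return InjectionResult(beats=new, split_indices=np.asarray(split_at, dtype=int),
                           original=beats)


def restoration_rate(original: BeatSeries, corrected: BeatSeries,
                     tol_ms: float = 1e-6) -> float:
    """Fraction of original intervals reproduced, in order, by the corrected series."""
    a, b = original.ibis_ms, corrected.ibis_ms
    i = j = hits = 0
    ca = cb = 0.0
    while i < a.size and j < b.size:
        if abs(a[i] - b[j]) <= tol_ms:
            hits += 1
            ca += a[i]
            cb += b[j]
            i += 1
            j += 1
        elif ca + a[i] <= cb + b[j]:
            ca += a[i]
            i += 1
        else:
            cb += b[j]
            j += 1
    return hits / a.size


# ---------------------------------------------------------------------------
# Affiliation outcomes
# ---------------------------------------------------------------------------

def affiliation_design_row(talk: float, coop: float, react: float, sync: float) -> np.ndarray:
    """Design vector over :data:`AFFILIATION_TERMS` for one participant."""
    vals = {"talk": talk, "coop": coop, "react": react, "sync": sync}
    out = np.empty(len(AFFILIATION_TERMS))
    for k, term in enumerate(AFFILIATION_TERMS):
        if term == "intercept":
            out[k] = 1.0
        else:
            prod = 1.0
            for part in term.split(":"):
                prod *= vals[part]
            out[k] = prod
    return out


def generate_affiliation_outcomes(panel: EpochPanel, config: SimConfig,
                                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Three correlated affiliation outcomes per participant.

    Outcomes are linear in the dyad's true synchrony slope, the
    participant's mean reactivity, the condition codes, and the
    interactions named in ``config.outcome_effects``. Dyad-level
    intercepts (shared by both members) and participant-level residuals
    are both correlated across outcomes via ``config.resid_corr`` with
    outcome-specific scales. Values are continuous on the questionnaire
    scale; no truncation is applied.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(spawn_seed(cfg.seed, "affiliation"))
    corr = np.asarray(cfg.resid_corr, dtype=float)
    L_corr = np.linalg.cholesky(corr)
    d_dyad = np.array([cfg.outcome_dyad_sd[o] for o in OUTCOMES])
    d_res = np.array([cfg.outcome_resid_sd[o] for o in OUTCOMES])
    coef = np.zeros((len(OUTCOMES), len(AFFILIATION_TERMS)))
    for oi, o in enumerate(OUTCOMES):
        for term, val in cfg.outcome_effects.get(o, {}).items():
            coef[oi, AFFILIATION_TERMS.index(term)] = val

    react = (
        panel.data.groupby(["dyad_id", "participant_id"], sort=True)["reactivity"]
        .mean()
        .rename("react")
        .reset_index()
    )
    truth = panel.dyad_truth.set_index("dyad_id")
    rows = []
    for dyad_id, grp in react.groupby("dyad_id", sort=True):
        t = truth.loc[dyad_id]
        dyad_eff = d_dyad * (L_corr @ rng.normal(size=3))
        for r in grp.itertuples(index=False):
            x = affiliation_design_row(t["talk_code"], t["coop_code"], r.react, t["s_true"])
            resid = d_res * (L_corr @ rng.normal(size=3))
            vals = coef @ x + dyad_eff + resid
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "dyad_id": int(dyad_id),
                    "talk_code": int(t["talk_code"]),
                    "coop_code": int(t["coop_code"]),
                    "sync": float(t["s_true"]),
                    "react": float(r.react),
                    **{o: float(vals[i]) for i, o in enumerate(OUTCOMES)},
                }
            )
    return pd.DataFrame(rows)
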