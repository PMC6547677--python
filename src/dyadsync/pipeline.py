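"""End-to-end orchestration: simulate -> qc -> indices -> reactivity ->
synchrony -> pseudo-dyad null -> affiliation, with file handoff between
stages, a JSON manifest and a human-readable report.

All stage outputs are long-format delimited text, diffable and
language-neutral. Every stochastic stage derives its stream from the
single top-level seed, so a config + seed pair reproduces the run
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .affiliation import fit_multivariate_affiliation, probe_simple_effects
from .config import OUTCOMES, RunConfig, SimConfig, spawn_seed
from .ibi import (correct_flagged, flag_improbable_ibis, qc_report,
                  read_ibi, segment_epochs, write_ibi)
from .indices import index_panel
from .reactivity import baseline_condition_check, residualized_change
from .simulate import (generate_affiliation_outcomes, generate_dyad_ibi,
                       generate_epoch_panel, inject_artifacts)
from .synchrony import (fit_synchrony_model, make_directed_frame,
                        pseudo_dyad_null, test_random_slope)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    param_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "dyadsync_version": __version__,
        "versions": _lib_versions(),
        "seed": config.seed,
        "parameter_hash": param_hash,
        "config": cfg_dict,
        "stages": [],
        "outputs": [],
    }
    config.to_yaml(out / "config.yaml")

    state: dict = {}
    for stage in config.stages:
        fn = _STAGES.get(stage)
        if fn is None:
            raise StageError(stage, ValueError("unknown stage"))
        try:
            log.info("running stage %s", stage)
            outputs = fn(config, out, state)
        except Exception as exc:  # halt, keep partial outputs
            manifest["failed_stage"] = stage
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise StageError(stage, exc) from exc
        manifest["stages"].append(stage)
        manifest["outputs"].extend(outputs)

    report = render_report(out, config)
    (out / "report.txt").write_text(report)
    manifest["outputs"].append("report.txt")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _lib_versions() -> dict:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _sim_config(config: RunConfig) -> SimConfig:
    sim = SimConfig.from_dict({**config.sim.to_dict(), "seed": spawn_seed(config.seed, "sim")})
    return sim


def stage_simulate(config: RunConfig, out: Path, state: dict) -> list[str]:
    sim = _sim_config(config)
    outputs = []
    for branch in config.branches:
        panel = generate_epoch_panel(sim, branch=branch)
        state[f"panel_{branch}"] = panel
        _write(panel.data, out / f"panel_{branch}.csv")
        _write(panel.dyad_truth, out / f"truth_dyads_{branch}.csv")
        _write(panel.participant_truth, out / f"truth_participants_{branch}.csv")
        outputs += [f"panel_{branch}.csv", f"truth_dyads_{branch}.csv",
                    f"truth_participants_{branch}.csv"]
    outcomes = generate_affiliation_outcomes(
        state[f"panel_{config.branches[0]}"], sim
    )
    state["outcomes"] = outcomes
    _write(outcomes, out / "outcomes.csv")
    outputs.append("outcomes.csv")

    if config.from_raw_ibi:
        pns = state.get("panel_pns") or state[f"panel_{config.branches[0]}"]
        series = generate_dyad_ibi(sim, panel=pns)
        rng = np.random.default_rng(spawn_seed(config.seed, "artifacts"))
        ibi_dir = out / "ibi"
        ibi_dir.mkdir(exist_ok=True)
        meta_rows = []
        for (dyad_id, pid), beats in series.items():
            if config.artifact_rate > 0:
                beats = inject_artifacts(beats, config.artifact_rate, rng).beats
            write_ibi(ibi_dir / f"{pid}.tsv", beats)
            meta_rows.append({"dyad_id": dyad_id, "participant_id": pid,
                              "t0_s": beats.t0_s})
        meta = pns.data.drop_duplicates("participant_id")[
            ["participant_id", "dyad_id", "sex", "talk_code", "coop_code"]
        ].merge(pd.DataFrame(meta_rows)[["participant_id", "t0_s"]], on="participant_id")
        _write(meta, out / "ibi_meta.csv")
        outputs.append("ibi_meta.csv")
        state["ibi_meta"] = meta
    return outputs


def _load_ibi(config: RunConfig, out: Path) -> dict:
    meta = pd.read_csv(out / "ibi_meta.csv")
    series = {}
    for rec in meta.itertuples(index=False):
        beats = read_ibi(out / "ibi" / f"{rec.participant_id}.tsv",
                         t0_s=float(rec.t0_s), dyad_id=int(rec.dyad_id),
                         participant_id=str(rec.participant_id))
        series[(int(rec.dyad_id), str(rec.participant_id))] = beats
    return series


def stage_qc(config: RunConfig, out: Path, state: dict) -> list[str]:
    if not config.from_raw_ibi:
        return []  # epoch-level path: nothing to clean
    series = state.get("ibi_series") or _load_ibi(config, out)
    reports = []
    cleaned = {}
    for key, beats in series.items():
        flagged = flag_improbable_ibis(beats, config.ratio_threshold)
        reports.append(qc_report(flagged).assign(dyad_id=key[0]))
        cleaned[key] = correct_flagged(flagged, config.qc_strategy)
    state["ibi_series"] = cleaned
    rep = pd.concat(reports, ignore_index=True) if reports else pd.DataFrame()
    _write(rep, out / "qc_report.csv")
    return ["qc_report.csv"]


def stage_indices(config: RunConfig, out: Path, state: dict) -> list[str]:
    if not config.from_raw_ibi:
        return []
    series = state.get("ibi_series") or _load_ibi(config, out)
    sim = _sim_config(config)
    task_s = sim.epochs_per_task * config.epoch_s
    task_segments = {}
    base_segments = {}
    for key, beats in series.items():
        task_segments[key] = segment_epochs(beats, (0.0, task_s),
                                            config.epoch_s, config.pad_s)
        base_segments[key] = segment_epochs(beats, (-sim.baseline_s, 0.0),
                                            config.epoch_s, config.pad_s)
    panel = index_panel(task_segments, config.band_hz, config.fs_hz,
                        config.interpolation, config.min_beats)
    basepanel = index_panel(base_segments, config.band_hz, config.fs_hz,
                            config.interpolation, config.min_beats)
    baseline = (
        basepanel.groupby(["dyad_id", "participant_id"], as_index=False)[["csi", "log_rsa"]]
        .mean()
        .rename(columns={"csi": "baseline_csi", "log_rsa": "baseline_log_rsa"})
    )
    state["index_panel"] = panel
    state["baseline"] = baseline
    _write(panel, out / "indices.csv")
    _write(baseline, out / "baseline.csv")
    return ["indices.csv", "baseline.csv"]


_BRANCH_INDEX = {"sns": "csi", "pns": "log_rsa"}


def stage_reactivity(config: RunConfig, out: Path, state: dict) -> list[str]:
    outputs = []
    meta_cols = ["dyad_id", "participant_id", "epoch", "talk_code", "coop_code", "sex"]
    for branch in config.branches:
        if config.from_raw_ibi:
            idx_col = _BRANCH_INDEX[branch]
            panel = state["index_panel"].rename(columns={idx_col: "value"})
            baseline = state["baseline"].rename(
                columns={f"baseline_{idx_col}": "baseline"})
            rx, info = residualized_change(panel, baseline, "value")
            meta = pd.read_csv(out / "ibi_meta.csv")[
                ["participant_id", "talk_code", "coop_code", "sex"]]
            rx = rx.merge(meta, on="participant_id")
            check = baseline_condition_check(
                baseline.merge(meta, on="participant_id"))
        else:
            panel_obj = state.get(f"panel_{branch}")
            data = (panel_obj.data if panel_obj is not None
                    else pd.read_csv(out / f"panel_{branch}.csv"))
            rx = data.copy()
            info = {"method": "direct_epoch_panel", "slope": float("nan"),
                    "intercept": float("nan")}
            check = None
        rx = rx[[c for c in meta_cols if c in rx.columns] + ["reactivity"]]
        state[f"reactivity_{branch}"] = rx
        _write(rx, out / f"reactivity_{branch}.csv")
        payload = {"fit": info}
        if check is not None:
            payload["baseline_condition_check"] = check
        (out / f"reactivity_{branch}.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True))
        outputs += [f"reactivity_{branch}.csv", f"reactivity_{branch}.json"]
    return outputs


def _reactivity_panel(config: RunConfig, out: Path, state: dict, branch: str) -> pd.DataFrame:
    key = f"reactivity_{branch}"
    if key not in state:
        state[key] = pd.read_csv(out / f"{key}.csv")
    return state[key]


def stage_synchrony(config: RunConfig, out: Path, state: dict) -> list[str]:
    outputs = []
    for branch in config.branches:
        panel = _reactivity_panel(config, out, state, branch)
        directed = make_directed_frame(panel)
        fit = fit_synchrony_model(directed, branch=branch, compute_ci=config.compute_ci)
        lrt = test_random_slope(directed, branch=branch, full_fit=fit.lmm)
        state[f"synchrony_{branch}"] = fit
        _write(fit.fixed.reset_index(), out / f"synchrony_{branch}_fixed.csv")
        _write(fit.variance_components.reset_index(),
               out / f"synchrony_{branch}_varcomp.csv")
        _write(fit.dyad_slopes, out / f"synchrony_{branch}_slopes.csv")
        _write(fit.emm, out / f"synchrony_{branch}_emm.csv")
        (out / f"synchrony_{branch}_phi.json").write_text(json.dumps({
            "phi": fit.ar1_phi,
            "phi_ci": list(fit.phi_ci) if fit.phi_ci else None,
            "slope_lrt": {k: v for k, v in lrt.items()},
        }, indent=2, sort_keys=True))
        outputs += [f"synchrony_{branch}_{s}.csv"
                    for s in ("fixed", "varcomp", "slopes", "emm")]
        outputs.append(f"synchrony_{branch}_phi.json")
    return outputs


def stage_null(config: RunConfig, out: Path, state: dict) -> list[str]:
    outputs = []
    for branch in config.branches:
        panel = _reactivity_panel(config, out, state, branch)
        res = pseudo_dyad_null(panel, n_repairings=config.n_repairings,
                               seed=spawn_seed(config.seed, "null", branch),
                               branch=branch)
        _write(res.results, out / f"null_{branch}.csv")
        outputs.append(f"null_{branch}.csv")
    return outputs


def stage_affiliation(config: RunConfig, out: Path, state: dict) -> list[str]:
    outcomes = state.get("outcomes")
    if outcomes is None:
        outcomes = pd.read_csv(out / "outcomes.csv")
    outputs = []
    for branch in config.branches:
        table = outcomes.drop(columns=["sync", "react"], errors="ignore")
        sfit = state.get(f"synchrony_{branch}")
        if sfit is not None:
            slopes = sfit.dyad_slopes[["dyad_id", "slope"]].rename(columns={"slope": "sync"})
        else:
            slopes = pd.read_csv(out / f"synchrony_{branch}_slopes.csv")[
                ["dyad_id", "slope"]].rename(columns={"slope": "sync"})
        rx = _reactivity_panel(config, out, state, branch)
        react = (rx.groupby("participant_id", as_index=False)["reactivity"].mean()
                 .rename(columns={"reactivity": "react"}))
        table = table.merge(slopes, on="dyad_id").merge(react, on="participant_id")
        fit = fit_multivariate_affiliation(table, branch=branch)
        for o in OUTCOMES:
            _write(fit.tables[o].reset_index(), out / f"affiliation_{branch}_{o}.csv")
            outputs.append(f"affiliation_{branch}_{o}.csv")
        probe = probe_simple_effects(fit, "friendship",
                                     moderators=list(config.probe_moderators))
        _write(probe["contrasts"], out / f"affiliation_{branch}_probe.csv")
        outputs.append(f"affiliation_{branch}_probe.csv")
        state[f"affiliation_{branch}"] = fit
    return outputs


_STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "indices": stage_indices,
    "reactivity": stage_reactivity,
    "synchrony": stage_synchrony,
    "null": stage_null,
    "affiliation": stage_affiliation,
}


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _fmt_fixed_table(df: pd.DataFrame, title: str) -> str:
    lines = [title, "-" * len(title)]
    header = f"{'Term':<62}{'b':>9}{'CI_lo':>9}{'CI_hi':>9}{'SE':>8}{'t':>8}{'df':>7}{'p':>8}{'r':>8}"
    lines.append(header)
    for _, row in df.iterrows():
        lines.append(
            f"{str(row.iloc[0]):<62}"
            f"{row['b']:>9.3f}{row['ci_lower']:>9.3f}{row['ci_upper']:>9.3f}"
            f"{row['se']:>8.3f}{row['t_value']:>8.3f}{row['df']:>7.0f}"
            f"{row['p_value']:>8.3f}{row['r']:>8.3f}"
        )
    return "\n".join(lines)


def render_report(out: Path, config: RunConfig) -> str:
    """Assemble the per-branch model tables into one text report."""
    chunks = [f"dyadsync run report (seed={config.seed})", ""]
    for branch in config.branches:
        name = {"sns": "Sympathetic", "pns": "Parasympathetic"}.get(branch, branch)
        fx = out / f"synchrony_{branch}_fixed.csv"
        if fx.exists():
            chunks.append(_fmt_fixed_table(pd.read_csv(fx),
                                           f"Model Predicting {name} Synchrony"))
            vc = pd.read_csv(out / f"synchrony_{branch}_varcomp.csv")
            chunks.append("Random effects (variance, 95% CI):")
            for _, row in vc.iterrows():
                ci = ""
                if np.isfinite(row.get("ci_lower", np.nan)):
                    ci = f"  [{row['ci_lower']:.3f}, {row['ci_upper']:.3f}]"
                chunks.append(f"  {row.iloc[0]:<24}{row['variance']:.3f}{ci}")
            phi = json.loads((out / f"synchrony_{branch}_phi.json").read_text())
            if phi.get("phi") is not None:
                ci = phi.get("phi_ci")
                ci_txt = f", 95% CI [{ci[0]:.3f}, {ci[1]:.3f}]" if ci else ""
                chunks.append(f"AR(1) phi = {phi['phi']:.3f}{ci_txt}")
            lrt = phi.get("slope_lrt")
            if lrt:
                chunks.append(
                    f"Synchrony slope variance LRT: chi2({lrt['df']}) = "
                    f"{lrt['chi2']:.3f}, p = {lrt['p_value']:.3f}"
                )
            chunks.append("")
        for o in OUTCOMES:
            af = out / f"affiliation_{branch}_{o}.csv"
            if af.exists():
                chunks.append(_fmt_fixed_table(
                    pd.read_csv(af),
                    f"Multivariate Model ({name}): {o.replace('_', ' ').title()}"))
                chunks.append("")
    return "\n".join(chunks) + "\n"
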