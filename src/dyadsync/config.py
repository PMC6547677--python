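"""Configuration objects for simulation and pipeline runs.

``SimConfig`` holds every parameter of the synthetic dyad generator; its
defaults are the study conditions the rest of the package is exercised
under (67 dyads, ten 30-s epochs, respiratory modulation inside the
0.12-0.40 Hz band, AR(1) epoch noise). ``RunConfig`` wraps a SimConfig
plus the processing/model options for an end-to-end pipeline run and
round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

#: fixed effect terms accepted by the affiliation outcome generator
AFFILIATION_TERMS = (
    "intercept",
    "talk",
    "coop",
    "react",
    "sync",
    "talk:coop",
    "talk:react",
    "coop:react",
    "talk:sync",
    "coop:sync",
    "react:sync",
    "talk:coop:react",
    "talk:coop:sync",
    "talk:react:sync",
    "coop:react:sync",
    "talk:coop:react:sync",
)

OUTCOMES = ("similarity", "friendship", "negative_affect")


def _default_cond_effects() -> dict[str, float]:
    # mean reactivity shifts for the +/-1 coded 2x2 design
    return {"talk": 0.20, "coop": 0.14, "talk:coop": 0.035}


def _default_outcome_effects() -> dict[str, dict[str, float]]:
    # modest affiliation effects: synchrony slope -> similarity, a 3-way
    # talking x reactivity x synchrony interaction -> friendship interest
    return {
        "similarity": {"intercept": 4.4, "sync": 2.0, "react": 0.48, "talk:react": 0.46},
        "friendship": {"intercept": 4.8, "react": 0.69, "talk:react": 0.60,
                       "talk:react:sync": 4.2, "coop:react:sync": -4.3},
        "negative_affect": {"intercept": 1.3},
    }


def _default_resid_corr() -> list[list[float]]:
    return [[1.0, 0.5, -0.2], [0.5, 1.0, -0.2], [-0.2, -0.2, 1.0]]


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic dyad generator.

    The epoch-level process for each dyad couples the two partners'
    reactivity series so that, for both directed orderings, the
    conditional expectation of one member's epoch value given the
    other's is ``b0 + rho_lag * own_lag + (beta_sync + u_d) * partner +
    condition terms`` with AR(1)(``phi_ar1``) residuals of standard
    deviation ``sigma_resid``.
    """

    n_dyads: int = 67
    epochs_per_task: int = 10
    epoch_s: float = 30.0
    baseline_s: float = 300.0

    # raw IBI emulation
    base_ibi_ms: float = 800.0
    rsa_freq_hz: float = 0.25
    rsa_amp_ms: float = 40.0
    ibi_noise_ms: float = 2.0

    # epoch-level coupling dynamics
    b0: float = 0.0
    beta_sync: float = 0.30
    sigma_sync: float = 0.20
    rho_lag: float = -0.25
    phi_ar1: float = 0.50
    sigma_resid: float = 0.805  # sqrt(0.648), residual SD of the directed equation
    # optional level heterogeneity; the default generator couples pure
    # fluctuations (reactivity scores are residualized, mean ~ 0)
    sd_dyad_intercept: float = 0.0
    sd_participant_intercept: float = 0.0
    cond_effects: dict[str, float] = field(default_factory=_default_cond_effects)
    # optional moderation of the coupling slope by condition (defaults off:
    # no moderation of synchrony by condition is assumed)
    sync_cond_effects: dict[str, float] = field(default_factory=dict)

    # affiliation outcomes
    outcome_effects: dict[str, dict[str, float]] = field(default_factory=_default_outcome_effects)
    resid_corr: list[list[float]] = field(default_factory=_default_resid_corr)
    outcome_resid_sd: dict[str, float] = field(
        default_factory=lambda: {"similarity": 0.9, "friendship": 1.0, "negative_affect": 0.45}
    )
    outcome_dyad_sd: dict[str, float] = field(
        default_factory=lambda: {"similarity": 0.35, "friendship": 0.4, "negative_affect": 0.15}
    )

    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs_per_task < 2:
            raise ValueError("epochs_per_task must be >= 2")
        if not abs(self.phi_ar1) < 1:
            raise ValueError("phi_ar1 must lie strictly inside (-1, 1)")
        if self.sigma_sync < 0:
            raise ValueError("sigma_sync must be non-negative")
        if not (0.12 <= self.rsa_freq_hz <= 0.40):
            raise ValueError("rsa_freq_hz must lie in the respiratory band [0.12, 0.40] Hz")
        if self.base_ibi_ms <= 2 * self.rsa_amp_ms:
            raise ValueError("base_ibi_ms must exceed twice rsa_amp_ms")
        corr = np.asarray(self.resid_corr, dtype=float)
        if corr.shape != (len(OUTCOMES),) * 2 or not np.allclose(corr, corr.T):
            raise ValueError("resid_corr must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("resid_corr must be positive-definite")
        for out, eff in self.outcome_effects.items():
            if out not in OUTCOMES:
                raise ValueError(f"unknown outcome {out!r}")
            unknown = set(eff) - set(AFFILIATION_TERMS)
            if unknown:
                raise ValueError(f"unknown affiliation terms for {out!r}: {sorted(unknown)}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        return cls(**d)


@dataclass
class RunConfig:
    """Full pipeline configuration: one seed, all stage parameters."""

    sim: SimConfig = field(default_factory=SimConfig)
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "qc", "indices", "reactivity", "synchrony", "null", "affiliation",
        ]
    )
    ratio_threshold: float = 0.6
    qc_strategy: str = "merge_adjacent"
    artifact_rate: float = 0.0
    epoch_s: float = 30.0
    pad_s: float = 12.0
    band_hz: tuple[float, float] = (0.12, 0.40)
    fs_hz: float = 10.0
    interpolation: str = "cubic"
    min_beats: int = 20
    n_repairings: int = 20
    branches: list[str] = field(default_factory=lambda: ["sns", "pns"])
    probe_moderators: list[str] = field(default_factory=lambda: ["talk"])
    compute_ci: bool = True
    from_raw_ibi: bool = False
    seed: int = 0
    outdir: str = "dyadsync_out"

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["band_hz"] = list(self.band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def spawn_seed(seed: int, *keys: str) -> int:
    """Derive a deterministic child seed (< 2**31) from a top-level seed."""
    import hashlib

    digests = [
        int.from_bytes(hashlib.sha256(k.encode()).digest()[:4], "little") for k in keys
    ]
    ss = np.random.SeedSequence([int(seed)] + digests)
    return int(ss.generate_state(1)[0] % (2**31))
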