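"""Per-segment autonomic indices: Cardiac Sympathetic Index and logRSA.

CSI is the ratio of the longitudinal to the transverse axis of the
Poincaré (Lorenz) plot of successive interbeat intervals — the axes are
4 standard deviations along and across the identity line, so the 4s
cancel and CSI = SD2/SD1. For a stationary Gaussian series with lag-1
autocorrelation rho, CSI = sqrt((1+rho)/(1-rho)).

logRSA is the natural log of the variance of the heart-period signal
band-limited to the adult respiratory range (0.12-0.40 Hz): the IBI
sequence is interpolated against beat time, resampled at 10 Hz,
band-pass filtered with a zero-phase Butterworth filter, and the first
and last 12 s of the filtered segment are discarded before taking the
variance, removing filter edge transients. A pure sinusoidal modulation
of amplitude A (ms) therefore yields logRSA ~= log(A^2/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate as sp_interp
from scipy import signal

from .ibi import EpochSegment

#: logRSA below this is numerically degenerate and reported missing
LOG_RSA_FLOOR = -20.0
MIN_BEATS = 20


class DegenerateGeometryError(ValueError):
    """Poincaré points are collinear; the transverse axis has zero length."""


@dataclass
class IndexValue:
    """CSI and logRSA for one participant-epoch."""

    dyad_id: int | None
    participant_id: str | None
    epoch_index: int
    csi: float
    log_rsa: float
    n_beats_used: int
    missing: bool = False
    reason: str = ""


def poincare_axes(ibis_ms: np.ndarray) -> tuple[float, float]:
    """Lengths (L, T) of the Poincaré-plot axes: 4*SD along / across identity.

    The point set is (IBI_n, IBI_{n+1}); rotating 45 degrees maps the
    identity axis to (x+y)/sqrt(2) and the transverse axis to
    (y-x)/sqrt(2).
    """
    x = np.asarray(ibis_ms, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 intervals for a Poincaré plot")
    a, b = x[:-1], x[1:]
    along = (a + b) / math.sqrt(2.0)
    across = (b - a) / math.sqrt(2.0)
    return 4.0 * float(np.std(along, ddof=1)), 4.0 * float(np.std(across, ddof=1))


def csi_from_ibis(ibis_ms: np.ndarray) -> float:
    """CSI = L/T; raises :class:`DegenerateGeometryError` when T == 0."""
    L, T = poincare_axes(ibis_ms)
    if not np.isfinite(T) or T <= 1e-9 * max(L, 1.0):
        raise DegenerateGeometryError("successive-IBI points are collinear (T = 0)")
    return L / T


def compute_csi(segment: EpochSegment, min_beats: int = MIN_BEATS) -> float:
    if segment.ibis_ms.size < min_beats:
        raise ValueError(
            f"epoch {segment.epoch_index}: only {segment.ibis_ms.size} beats (< {min_beats})"
        )
    return csi_from_ibis(segment.ibis_ms)


def _bandpass_sos(band_hz: tuple[float, float], fs_hz: float, order: int = 4):
    lo, hi = band_hz
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")


def heart_period_signal(ibis_ms: np.ndarray, beat_times_s: np.ndarray,
                        fs_hz: float = 10.0, interpolation: str = "cubic"
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Evenly resampled heart-period signal over the segment's beat span.

    Interpolates IBI against the terminating beat time (piecewise cubic
    by default, linear as fallback) and samples at ``fs_hz``.
    """
    t = np.asarray(beat_times_s, dtype=float)
    y = np.asarray(ibis_ms, dtype=float)
    grid = np.arange(t[0], t[-1], 1.0 / fs_hz)
    if interpolation == "cubic" and t.size >= 4:
        f = sp_interp.CubicSpline(t, y)
    elif interpolation in ("cubic", "linear"):
        f = sp_interp.interp1d(t, y, kind="linear")
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return grid, np.asarray(f(grid), dtype=float)


def compute_log_rsa(segment: EpochSegment, band_hz: tuple[float, float] = (0.12, 0.40),
                    fs_hz: float = 10.0, trunc_s: float = 12.0,
                    interpolation: str = "cubic", min_beats: int = MIN_BEATS,
                    log_base: str = "e") -> float:
    """Natural log of band-limited heart-period variance over the central window.

    Returns ``nan`` (missing) when the segment is too sparse or the
    band-limited variance is numerically zero (logRSA below the floor).
    """
    if segment.ibis_ms.size < min_beats:
        return float("nan")
    grid, hp = heart_period_signal(segment.ibis_ms, segment.beat_times_s, fs_hz, interpolation)
    n_trunc = int(round(trunc_s * fs_hz))
    if hp.size <= 2 * n_trunc + 8:
        return float("nan")
    sos = _bandpass_sos(band_hz, fs_hz)
    filtered = signal.sosfiltfilt(sos, hp - hp.mean())
    core = filtered[n_trunc: hp.size - n_trunc]
    var = float(np.var(core))
    if var <= 0:
        return float("nan")
    val = math.log(var) if log_base == "e" else math.log10(var)
    if val < LOG_RSA_FLOOR:
        return float("nan")
    return val


def index_panel(segments_by_participant: dict, band_hz=(0.12, 0.40), fs_hz=10.0,
                interpolation: str = "cubic", min_beats: int = MIN_BEATS) -> pd.DataFrame:
    """Compute per-epoch indices for many participants.

    ``segments_by_participant`` maps (dyad_id, participant_id) to a list
    of :class:`EpochSegment`. Returns a long table keyed by dyad,
    participant, epoch with ``csi`` and ``log_rsa`` columns; degenerate
    epochs yield NaN rather than raising.
    """
    rows = []
    for (dyad_id, pid), segments in segments_by_participant.items():
        for seg in segments:
            try:
                csi = compute_csi(seg, min_beats=min_beats)
            except (ValueError, DegenerateGeometryError):
                csi = float("nan")
            lrsa = compute_log_rsa(seg, band_hz=band_hz, fs_hz=fs_hz,
                                   interpolation=interpolation, min_beats=min_beats)
            rows.append(
                {
                    "dyad_id": dyad_id,
                    "participant_id": pid,
                    "epoch": seg.epoch_index,
                    "csi": csi,
                    "log_rsa": lrsa,
                    "n_beats_used": int(seg.ibis_ms.size),
                }
            )
    return pd.DataFrame(rows)
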