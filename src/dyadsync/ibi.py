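"""Interbeat-interval containers, artifact QC, and epoch segmentation.

A :class:`BeatSeries` is one participant's ordered sequence of interbeat
intervals (IBI, ms). The QC stage flags improbably short intervals with a
ratio rule (an interval no longer than 0.6 times its successor is the
signature of a spuriously detected extra R wave) and repairs them; the
segmentation stage cuts the recording into overlapping 54-s windows whose
central 30 s tile the task, matching index software that truncates 12 s
of filter transient from each end of its input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

DEFAULT_RATIO = 0.6


@dataclass
class BeatSeries:
    """One participant's IBI sequence anchored to task-relative time.

    Parameters
    ----------
    ibis_ms:
        Positive interbeat intervals in milliseconds, in temporal order.
    t0_s:
        Task-relative time (s) at which the first interval begins; the
        task itself starts at 0.
    flags:
        Per-interval artifact markers (True = questionable).
    provenance:
        ``"raw"`` or ``"corrected"``.
    """

    ibis_ms: np.ndarray
    t0_s: float = 0.0
    flags: np.ndarray | None = None
    provenance: str = "raw"
    dyad_id: int | None = None
    participant_id: str | None = None

    def __post_init__(self) -> None:
        self.ibis_ms = np.asarray(self.ibis_ms, dtype=float)
        if self.ibis_ms.ndim != 1 or self.ibis_ms.size == 0:
            raise ValueError("ibis_ms must be a non-empty 1-D sequence")
        if np.any(self.ibis_ms <= 0):
            raise ValueError("all interbeat intervals must be positive")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape != self.ibis_ms.shape:
                raise ValueError("flags must align with ibis_ms")

    @property
    def n_beats(self) -> int:
        return int(self.ibis_ms.size)

    @property
    def beat_end_times_s(self) -> np.ndarray:
        """Task-relative end time (s) of each interval."""
        return self.t0_s + np.cumsum(self.ibis_ms) / 1000.0

    @property
    def duration_s(self) -> float:
        return float(np.sum(self.ibis_ms) / 1000.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beat": np.arange(self.n_beats), "ibi_ms": self.ibis_ms})


def write_ibi(path, beats: BeatSeries) -> None:
    """Write the two-column text format (beat index, IBI ms)."""
    beats.to_frame().to_csv(path, sep="\t", index=False)


def read_ibi(path, t0_s: float = 0.0, **meta) -> BeatSeries:
    df = pd.read_csv(path, sep="\t")
    return BeatSeries(df["ibi_ms"].to_numpy(), t0_s=t0_s, **meta)


# ---------------------------------------------------------------------------
# QC: flagging and correction
# ---------------------------------------------------------------------------

def flag_improbable_ibis(beats: BeatSeries, ratio_threshold: float = DEFAULT_RATIO) -> BeatSeries:
    """Flag intervals that are improbably short relative to their successor.

    Interval ``k`` is flagged iff ``ibis[k] <= ratio_threshold * ibis[k+1]``.
    The last interval has no successor and is never flagged. Flags are
    scale-invariant: rescaling all intervals leaves them unchanged.
    """
    ibis = beats.ibis_ms
    flags = np.zeros(ibis.size, dtype=bool)
    flags[:-1] = ibis[:-1] <= ratio_threshold * ibis[1:]
    return replace(beats, flags=flags)


def qc_report(beats: BeatSeries) -> pd.DataFrame:
    """Tabulate flag positions and their task-relative times."""
    if beats.flags is None:
        raise ValueError("run flag_improbable_ibis first")
    idx = np.flatnonzero(beats.flags)
    times = beats.beat_end_times_s
    return pd.DataFrame(
        {
            "participant_id": beats.participant_id,
            "interval_index": idx,
            "ibi_ms": beats.ibis_ms[idx],
            "time_s": times[idx],
        }
    )


def correct_flagged(beats: BeatSeries, strategy: str = "merge_adjacent",
                    tol: float = 0.2, median_window: int = 15) -> BeatSeries:
    """Repair flagged intervals.

    ``merge_adjacent`` sums a flagged interval with a neighbour when the
    merged interval is within ``tol`` (default 20%) of the local median —
    the successor is tried first, then the predecessor (a beat split in
    two flags the *second* fragment, whose true mate precedes it).
    Cumulative duration is conserved exactly. ``interpolate`` replaces a
    flagged interval by the mean of its unflagged neighbours; ``drop``
    removes flagged intervals.
    """
    if strategy not in {"merge_adjacent", "interpolate", "drop"}:
        raise ValueError(f"unknown correction strategy {strategy!r}")
    if beats.flags is None or not beats.flags.any():
        return replace(beats, provenance="corrected")

    ibis = beats.ibis_ms.copy()
    flags = beats.flags.copy()

    if strategy == "drop":
        keep = ~flags
        return replace(beats, ibis_ms=ibis[keep], flags=None, provenance="corrected")

    if strategy == "interpolate":
        out = ibis.copy()
        good = np.flatnonzero(~flags)
        for k in np.flatnonzero(flags):
            left = good[good < k]
            right = good[good > k]
            neigh = []
            if left.size:
                neigh.append(ibis[left[-1]])
            if right.size:
                neigh.append(ibis[right[0]])
            out[k] = float(np.mean(neigh)) if neigh else ibis[k]
        return replace(beats, ibis_ms=out, flags=None, provenance="corrected")

    # merge_adjacent: walk the series, merging greedily; the local median
    # is taken over intervals away from any flag so split fragments do
    # not drag it down
    clean = ~(flags | np.roll(flags, 1) | np.roll(flags, -1))
    merged: list[float] = []
    pending_flags = list(flags)
    vals = list(ibis)
    i = 0
    half = median_window // 2
    while i < len(vals):
        if not pending_flags[i]:
            merged.append(vals[i])
            i += 1
            continue
        lo, hi = max(0, i - half), min(len(vals), i + half + 1)
        ref = beats.ibis_ms[lo:hi][clean[lo:hi]]
        if ref.size == 0:
            ref = beats.ibis_ms[clean] if clean.any() else beats.ibis_ms
        local_med = float(np.median(ref))
        if i + 1 < len(vals) and abs(vals[i] + vals[i + 1] - local_med) <= tol * local_med:
            merged.append(vals[i] + vals[i + 1])
            i += 2
        elif merged and abs(vals[i] + merged[-1] - local_med) <= tol * local_med:
            merged[-1] = merged[-1] + vals[i]
            i += 1
        else:
            merged.append(vals[i])  # unrepairable: keep as-is
            i += 1
    return replace(beats, ibis_ms=np.asarray(merged), flags=None, provenance="corrected")


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

class MarginError(ValueError):
    """Recording does not cover a segment's padded window."""


@dataclass
class EpochSegment:
    """IBIs falling in one padded epoch window.

    The window spans ``[k*epoch_s - pad_s, (k+1)*epoch_s + pad_s)``
    relative to the analysis window start; after the downstream 12-s
    truncation the effective span is the central ``epoch_s`` seconds.
    An interval belongs to the segment iff its terminating beat time
    lies in the half-open window.
    """

    epoch_index: int
    window: tuple[float, float]
    ibis_ms: np.ndarray
    beat_times_s: np.ndarray
    epoch_s: float = 30.0
    dyad_id: int | None = None
    participant_id: str | None = None

    @property
    def pad_s(self) -> float:
        return (self.window[1] - self.window[0] - self.epoch_s) / 2.0

    @property
    def effective_window(self) -> tuple[float, float]:
        return (self.window[0] + self.pad_s, self.window[1] - self.pad_s)


def segment_epochs(beats: BeatSeries, task_window: tuple[float, float],
                   epoch_s: float = 30.0, pad_s: float = 12.0) -> list[EpochSegment]:
    """Cut an analysis window into overlapping padded epoch segments.

    A 300-s window with ``epoch_s=30`` and ``pad_s=12`` yields ten 54-s
    segments whose effective 30-s centres tile the window; adjacent
    segments overlap by ``2*pad_s``. Raises :class:`MarginError` (naming
    the epoch) if the recording does not cover a padded window.
    """
    start, end = task_window
    n_epochs = (end - start) / epoch_s
    if abs(n_epochs - round(n_epochs)) > 1e-9:
        raise ValueError("task window length must be divisible by epoch_s")
    n_epochs = int(round(n_epochs))

    times = beats.beat_end_times_s
    rec_start = beats.t0_s
    rec_end = times[-1]
    segments = []
    for k in range(n_epochs):
        w0 = start + k * epoch_s - pad_s
        w1 = start + (k + 1) * epoch_s + pad_s
        if w0 < rec_start - 1e-9 or w1 > rec_end + 1e-9:
            raise MarginError(
                f"epoch {k}: padded window [{w0:.1f}, {w1:.1f}) s not covered by "
                f"recording [{rec_start:.1f}, {rec_end:.1f}] s"
            )
        sel = (times >= w0) & (times < w1)
        segments.append(
            EpochSegment(
                epoch_index=k,
                window=(w0, w1),
                ibis_ms=beats.ibis_ms[sel],
                beat_times_s=times[sel],
                epoch_s=epoch_s,
                dyad_id=beats.dyad_id,
                participant_id=beats.participant_id,
            )
        )
    return segments
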