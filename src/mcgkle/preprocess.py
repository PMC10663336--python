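"""Beat averaging into the common averaged-map format and gamma-normalization.

Every recording, whatever the acquisition device, is reduced to a common
format: a map ``B`` of 36 measurement positions x 1,000 samples at 1,000 Hz
with the R peak at sample 333 (1-based; 0-based index 332).  The field
strength of each map is then normalized by the factor

    gamma = (1/36) * sum_i (1/t_QRS) * sum_{t in QRS} |B_t^i|

i.e. the mean absolute field over the QRS window across all positions,
which cancels fluctuations in sensor-to-heart distance between subjects.
The QRS window is the closed interval [onset, end] (both samples included),
so t_QRS = end - onset + 1 samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .synth import BEAT_SAMPLES, R_PEAK_INDEX, CmfmRecording

__all__ = ["AveragedMap", "average_beats", "gamma_factor", "normalize_map"]

logger = logging.getLogger(__name__)

_CURSOR_KEYS = ("qrs_onset", "qrs_end", "stt_onset", "stt_end")
#: samples before the R peak in the averaged window (R included)
_PRE_R = R_PEAK_INDEX
_POST_R = BEAT_SAMPLES - R_PEAK_INDEX  # samples from R (exclusive) to window end


@dataclass(frozen=True)
class AveragedMap:
    """Averaged cardiac magnetic field map in the common format."""

    subject_id: str
    B: np.ndarray  # (n_positions, n_samples)
    cursors: dict  # sample indices into B, closed-interval convention
    fs_hz: float = 1000.0
    r_index: int = R_PEAK_INDEX
    gamma: float | None = None
    normalized: bool = False
    group: str | None = None

    def __post_init__(self) -> None:
        B = np.asarray(self.B, dtype=float)
        if B.ndim != 2:
            raise ValueError("B must be 2-D (positions x samples)")
        object.__setattr__(self, "B", B)
        missing = [k for k in _CURSOR_KEYS if k not in self.cursors]
        if missing:
            raise ValueError(f"missing cursors: {missing}")
        c = self.cursors
        n = B.shape[1]
        if not (0 < c["qrs_onset"] < c["qrs_end"] <= c["stt_onset"]
                < c["stt_end"] <= n):
            raise ValueError(f"cursor ordering violated: {c}")
        if not (c["qrs_onset"] < self.r_index < c["qrs_end"]):
            raise ValueError("R peak must lie inside the QRS window")
        if self.normalized:
            if self.gamma is None:
                raise ValueError("normalized map must carry its gamma")
            g = _gamma(B, c["qrs_onset"], c["qrs_end"])
            if abs(g - 1.0) > 1e-9:
                raise ValueError("normalized map must have recomputed gamma == 1")

    @property
    def n_positions(self) -> int:
        return self.B.shape[0]

    @property
    def n_samples(self) -> int:
        return self.B.shape[1]

    def segment_cursors(self, name: str) -> tuple[int, int]:
        """(onset, end) sample indices (closed interval) for ``QRS`` or ``STT``."""
        key = name.lower()
        if key not in ("qrs", "stt"):
            raise ValueError(f"unknown segment {name!r}")
        return int(self.cursors[f"{key}_onset"]), int(self.cursors[f"{key}_end"])


def cursors_ms_to_samples(cursors_ms: dict, r_index: int = R_PEAK_INDEX) -> dict:
    """Convert cursors from ms-relative-to-R (file convention) to samples."""
    return {k: r_index + int(round(float(cursors_ms[k]))) for k in _CURSOR_KEYS}


def cursors_samples_to_ms(cursors: dict, r_index: int = R_PEAK_INDEX) -> dict:
    return {k: float(cursors[k] - r_index) for k in _CURSOR_KEYS}


def _resample_to_1khz(rec: CmfmRecording) -> CmfmRecording:
    """Linear interpolation of the recording onto the 1,000 Hz grid."""
    if rec.fs_hz == 1000.0:
        return rec
    n = rec.signal.shape[1]
    duration_ms = (n - 1) / rec.fs_hz * 1000.0
    n_new = int(round(duration_ms)) + 1
    t_old = np.arange(n) / rec.fs_hz * 1000.0
    t_new = np.arange(n_new, dtype=float)
    try:
        signal = np.vstack([np.interp(t_new, t_old, ch) for ch in rec.signal])
    except Exception as exc:  # pragma: no cover - defensive
        raise ValueError(f"resampling to 1000 Hz failed: {exc}") from exc
    r_peaks = np.round(rec.r_peaks / rec.fs_hz * 1000.0).astype(int)
    return CmfmRecording(subject_id=rec.subject_id, group=rec.group,
                         signal=signal, fs_hz=1000.0, r_peaks=r_peaks,
                         true_cursors_ms=rec.true_cursors_ms)


def average_beats(rec: CmfmRecording, cursors_ms: dict | None = None,
                  baseline_correction: bool = True,
                  baseline_window: int = 100) -> AveragedMap:
    """Average beat windows aligned on the R peak into an ``AveragedMap``.

    Each usable beat contributes the window of 333 samples up to and
    including R plus 667 samples after it (1,000 samples at 1,000 Hz);
    windows extending past the recording edge are dropped with a logged
    count, never zero-padded.  Input at other sampling rates is first
    interpolated linearly onto the 1,000 Hz grid.  Cursors come from the
    recording's ground truth unless supplied explicitly (imported data),
    in ms relative to the R peak.

    When ``baseline_correction`` is on, the per-channel mean over the first
    ``baseline_window`` samples of the averaged map (a pre-QRS quiet zone)
    is subtracted.
    """
    rec = _resample_to_1khz(rec)
    n = rec.signal.shape[1]
    starts = rec.r_peaks - _PRE_R
    usable = (starts >= 0) & (starts + BEAT_SAMPLES <= n)
    dropped = int(np.sum(~usable))
    if dropped:
        logger.info("subject %s: dropped %d beat(s) overlapping the recording edge",
                    rec.subject_id, dropped)
    starts = starts[usable]
    if len(starts) < 2:
        raise ValueError(
            f"subject {rec.subject_id}: need >= 2 usable beats, got {len(starts)}")

    windows = np.stack([rec.signal[:, s:s + BEAT_SAMPLES] for s in starts])
    B = windows.mean(axis=0)

    if baseline_correction:
        if not (0 < baseline_window <= BEAT_SAMPLES):
            raise ValueError("baseline_window out of range")
        B = B - B[:, :baseline_window].mean(axis=1, keepdims=True)

    cursors_ms = cursors_ms if cursors_ms is not None else rec.true_cursors_ms
    cursors = cursors_ms_to_samples(cursors_ms)
    return AveragedMap(subject_id=rec.subject_id, B=B, cursors=cursors,
                       group=rec.group)


def _gamma(B: np.ndarray, qrs_onset: int, qrs_end: int) -> float:
    # closed interval [onset, end]; t_QRS = end - onset + 1 samples
    if qrs_end <= qrs_onset:
        raise ValueError("degenerate QRS window (qrs_end <= qrs_onset)")
    window = B[:, qrs_onset:qrs_end + 1]
    return float(np.mean(np.mean(np.abs(window), axis=1)))


def gamma_factor(amap: AveragedMap) -> float:
    """Normalization factor: mean |B| over the closed QRS window and all positions."""
    if amap.normalized:
        raise ValueError("map is already normalized")
    on, end = amap.segment_cursors("QRS")
    return _gamma(amap.B, on, end)


def normalize_map(amap: AveragedMap) -> AveragedMap:
    """Divide the map by its gamma factor; idempotent, scale invariant.

    A map that is already normalized is returned unchanged.  A zero gamma
    (identically-zero QRS window) is an error.
    """
    if amap.normalized:
        return amap
    g = gamma_factor(amap)
    if g == 0.0:
        raise ValueError(
            f"subject {amap.subject_id}: gamma is zero (empty/zero QRS window)")
    return replace(amap, B=amap.B / g, gamma=g, normalized=True)
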