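"""QRS and STT analysis-window extraction.

Two variants are supported, mirroring the two analysis configurations:

* ``fixed`` — an excerpt of fixed duration from the segment onset: 80 ms
  for QRS, 250 ms for STT (at 1,000 Hz, one sample per ms);
* ``resampled`` — the full cursor-to-cursor segment length-normalized by
  linear interpolation onto a fixed number of samples: 20 for QRS, 40 for
  STT.  Length normalization removes inter-subject differences in wave
  duration and, by reducing the sample count, limits the correlation
  between within-segment features (the discriminant analysis assumes
  weakly dependent inputs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .preprocess import AveragedMap
from .stats import MannWhitneyResult, mann_whitney_u

__all__ = [
    "FIXED_N_OUT",
    "RESAMPLED_N_OUT",
    "SegmentMaps",
    "extract_fixed",
    "extract_resampled",
    "intersample_correlation",
    "segment_length_test",
]

logger = logging.getLogger(__name__)

#: fixed-excerpt lengths in samples (= ms at 1,000 Hz)
FIXED_N_OUT = {"QRS": 80, "STT": 250}
#: length-normalized sample counts
RESAMPLED_N_OUT = {"QRS": 20, "STT": 40}


@dataclass(frozen=True)
class SegmentMaps:
    """Per-subject time slices of one analysis window (36 x n_out)."""

    subject_id: str
    name: str  # "QRS" | "STT"
    mode: str  # "fixed" | "resampled"
    maps: np.ndarray
    native_length_ms: float
    group: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "maps", np.asarray(self.maps, dtype=float))
        if self.name not in ("QRS", "STT"):
            raise ValueError(f"unknown segment name {self.name!r}")
        if self.mode not in ("fixed", "resampled"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_out(self) -> int:
        return self.maps.shape[1]


def _check_ready(amap: AveragedMap) -> None:
    if not amap.normalized:
        raise ValueError("segments must be extracted from a normalized map")


def extract_fixed(amap: AveragedMap, name: str,
                  n_out: int | None = None) -> SegmentMaps:
    """Fixed-duration excerpt starting at the segment onset (pure slice)."""
    _check_ready(amap)
    name = name.upper()
    n_out = n_out if n_out is not None else FIXED_N_OUT[name]
    onset, end = amap.segment_cursors(name)
    if onset + n_out > amap.n_samples:
        raise ValueError(
            f"{name} fixed window [{onset}, {onset + n_out}) exceeds map length "
            f"{amap.n_samples}")
    maps = amap.B[:, onset:onset + n_out].copy()
    return SegmentMaps(subject_id=amap.subject_id, name=name, mode="fixed",
                       maps=maps, native_length_ms=float(end - onset),
                       group=amap.group)


def extract_resampled(amap: AveragedMap, name: str, n_out: int | None = None,
                      kind: str = "linear") -> SegmentMaps:
    """Length-normalized segment: cursor-to-cursor, interpolated to n_out samples.

    The closed native interval [onset, end] is mapped onto ``n_out``
    equispaced points including both endpoints.  Interpolation is linear by
    default (``kind="cubic"`` is available but never the default).
    """
    _check_ready(amap)
    name = name.upper()
    n_out = n_out if n_out is not None else RESAMPLED_N_OUT[name]
    onset, end = amap.segment_cursors(name)
    if end - onset + 1 < 2:
        raise ValueError(f"{name}: degenerate segment (fewer than 2 samples)")
    x_native = np.arange(onset, end + 1, dtype=float)
    x_new = np.linspace(onset, end, n_out)
    seg = amap.B[:, onset:end + 1]
    if kind == "linear":
        maps = np.vstack([np.interp(x_new, x_native, ch) for ch in seg])
    elif kind == "cubic":
        maps = CubicSpline(x_native, seg, axis=1)(x_new)
    else:
        raise ValueError(f"unknown interpolation kind {kind!r}")
    return SegmentMaps(subject_id=amap.subject_id, name=name, mode="resampled",
                       maps=maps, native_length_ms=float(end - onset),
                       group=amap.group)


def intersample_correlation(segments_or_features, summary=None) -> float:
    """Maximum |Pearson correlation| between distinct within-segment time points.

    Accepts either a ready feature matrix (subjects x time points) or a list
    of :class:`SegmentMaps` together with a ``summary`` callable that
    scalarizes each time point (e.g. the KL-entropy feature extractor).
    Zero-variance time points cannot be correlated; the pairs involving
    them are excluded with a logged warning.  This is a diagnostic of the
    published sample-count choice (20 QRS / 40 STT keeps it below 0.2), not
    an automatic re-selection.
    """
    if summary is not None:
        segs = list(segments_or_features)
        if len(segs) < 3:
            raise ValueError("need >= 3 subjects")
        if len({(s.name, s.mode, s.n_out) for s in segs}) != 1:
            raise ValueError("all segments must share name/mode/n_out")
        features = np.vstack([np.asarray(summary(s), dtype=float) for s in segs])
    else:
        features = np.asarray(segments_or_features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 3:
        raise ValueError("need a (subjects x time points) matrix with >= 3 rows")

    sd = features.std(axis=0)
    defined = sd > 0
    if not np.all(defined):
        logger.warning("excluding %d zero-variance time point(s) from the "
                       "correlation diagnostic", int(np.sum(~defined)))
    f = features[:, defined]
    if f.shape[1] < 2:
        raise ValueError("fewer than 2 time points with variance; "
                         "correlation undefined")
    corr = np.corrcoef(f, rowvar=False)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    return float(np.max(np.abs(off)))


def segment_length_test(lengths_healthy, lengths_pathology) -> dict:
    """Between-group comparison of native segment lengths.

    Two-sided Mann-Whitney U on the per-subject cursor-to-cursor lengths,
    plus per-group median/IQR summaries for a boxplot-style report.  A
    significant difference would indicate a segment-length confound in any
    downstream topology comparison.
    """
    lx = np.asarray(lengths_healthy, dtype=float)
    ly = np.asarray(lengths_pathology, dtype=float)
    if len(lx) == 0 or len(ly) == 0:
        raise ValueError("both groups must be non-empty")
    res: MannWhitneyResult = mann_whitney_u(lx, ly)

    def _summary(v):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {"median": float(med), "iqr": float(q3 - q1), "n": int(len(v))}

    return {
        "u": res.u,
        "p_value": res.p_value,
        "method": res.method,
        "healthy": _summary(lx),
        "pathology": _summary(ly),
    }
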