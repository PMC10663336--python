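"""Kullback-Leibler entropy of field-map topology against a group reference.

At each time point within an analysis window, the 36 sensor readings of a
subject's normalized map are converted into a discrete probability
distribution P over measurement positions, the group-average reference map
is converted into Q the same way, and their divergence

    KL(P, Q) = sum_i P_i * ln(P_i / Q_i)        (natural log, nats)

is the subject's feature for that time point.  KL is non-negative (Gibbs
inequality), zero iff P == Q, and asymmetric: it is a statistical distance,
not a metric.

The conversion from a signed field column to a distribution is not unique;
the default ``abs`` strategy normalizes epsilon-smoothed absolute values,
which preserves the two-pole topology of a dipolar map and keeps KL finite.
``square`` and ``minshift`` are available alternatives; results should
always report the strategy used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segments import SegmentMaps

__all__ = [
    "EPS_REL",
    "ReferenceMap",
    "KleFeatures",
    "to_distribution",
    "kl_entropy",
    "build_reference",
    "kle_features",
]

#: epsilon-smoothing scale, relative to the column maximum (scale invariant)
EPS_REL = 1e-6

_STRATEGIES = ("abs", "square", "minshift")


@dataclass(frozen=True)
class ReferenceMap:
    """Group-average segment maps: the Q of the divergence, with provenance."""

    name: str
    mode: str
    Q: np.ndarray  # (36, n_out) field values (not yet distributions)
    built_from: tuple
    group_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "Q", np.asarray(self.Q, dtype=float))
        object.__setattr__(self, "built_from", tuple(self.built_from))
        if len(self.built_from) == 0:
            raise ValueError("built_from must be non-empty")

    @property
    def n_out(self) -> int:
        return self.Q.shape[1]


@dataclass(frozen=True)
class KleFeatures:
    """Per-time-point KL entropies of one subject's segment (length n_out)."""

    subject_id: str
    name: str
    mode: str
    values: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("KLE features must be finite")
        object.__setattr__(self, "values", v)


def _weights(values: np.ndarray, strategy: str) -> np.ndarray:
    if strategy == "abs":
        return np.abs(values)
    if strategy == "square":
        return np.square(values)
    if strategy == "minshift":
        return values - np.min(values, axis=-1, keepdims=True)
    raise ValueError(f"unknown distribution strategy {strategy!r}; "
                     f"choose one of {_STRATEGIES}")


def to_distribution(values, strategy: str = "abs",
                    eps_rel: float = EPS_REL) -> np.ndarray:
    """Convert one map column (36 field values) into a probability vector.

    p_i = (w_i + eps) / sum_j (w_j + eps) with w the non-negative weights of
    the chosen strategy and eps = ``eps_rel`` * max_j w_j, so the result is
    invariant to a global rescaling of the column.  All entries are strictly
    positive and sum to 1.  An all-zero column is degenerate and raises.
    """
    v = np.asarray(values, dtype=float)
    w = _weights(v, strategy)
    m = float(np.max(w))
    if m == 0.0:
        raise ValueError("degenerate map slice: all weights are zero")
    w = w + eps_rel * m
    return w / np.sum(w)


def kl_entropy(P, Q) -> float:
    """KL(P, Q) = sum_i P_i ln(P_i/Q_i) in nats; >= 0, zero iff P == Q."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 1:
        raise ValueError("P and Q must be 1-D of equal length")
    if abs(P.sum() - 1.0) > 1e-9 or abs(Q.sum() - 1.0) > 1e-9:
        raise ValueError("P and Q must each sum to 1 (within 1e-9)")
    if np.any(P <= 0) or np.any(Q <= 0):
        raise ValueError("P and Q must be strictly positive")
    return float(np.sum(P * (np.log(P) - np.log(Q))))


def build_reference(segments: list[SegmentMaps],
                    group_label: str | None = None) -> ReferenceMap:
    """Element-wise mean of the reference group's segment maps."""
    if len(segments) < 2:
        raise ValueError("need >= 2 subjects to build a reference map")
    keys = {(s.name, s.mode, s.maps.shape) for s in segments}
    if len(keys) != 1:
        raise ValueError(f"mixed segment name/mode/shape in reference group: {keys}")
    first = segments[0]
    Q = np.mean([s.maps for s in segments], axis=0)
    label = group_label or (first.group or "unknown")
    return ReferenceMap(name=first.name, mode=first.mode, Q=Q,
                        built_from=tuple(s.subject_id for s in segments),
                        group_label=label)


def _column_distributions(maps: np.ndarray, strategy: str,
                          eps_rel: float) -> np.ndarray:
    """Vectorized ``to_distribution`` over the time axis.

    maps: (..., n_positions, n_out) -> distributions of the same shape,
    normalized per column (over positions).
    """
    w = _weights(np.moveaxis(maps, -1, -2), strategy)  # (..., n_out, n_pos)
    m = np.max(w, axis=-1, keepdims=True)
    if np.any(m == 0.0):
        bad = np.argwhere(m[..., 0] == 0.0)
        raise ValueError(f"degenerate map slice (all-zero column) at time "
                         f"point(s) {bad[:, -1].tolist()}")
    w = w + eps_rel * m
    p = w / np.sum(w, axis=-1, keepdims=True)
    return np.moveaxis(p, -1, -2)


def kle_features(subject: SegmentMaps, ref: ReferenceMap,
                 strategy: str = "abs", eps_rel: float = EPS_REL) -> KleFeatures:
    """Per-time-point KL entropy of a subject's segment against the reference.

    For each of the n_out time points, the subject's column and the
    reference's column are converted to distributions and their divergence
    computed, yielding the n_out-vector of classifier inputs.
    """
    if (subject.name, subject.mode) != (ref.name, ref.mode):
        raise ValueError("subject and reference segment name/mode mismatch")
    if subject.maps.shape != ref.Q.shape:
        raise ValueError("subject and reference shapes differ")
    P = _column_distributions(subject.maps, strategy, eps_rel)
    Q = _column_distributions(ref.Q, strategy, eps_rel)
    values = np.sum(P * (np.log(P) - np.log(Q)), axis=0)
    return KleFeatures(subject_id=subject.subject_id, name=subject.name,
                       mode=subject.mode, values=values, group=subject.group)
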