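"""Synthetic magnetocardiogram cohorts with controllable group structure.

The heart's magnetic field is emulated by a single equivalent point dipole
whose moment traces a beat-shaped trajectory: a fast, large-moment rotation
during the QRS complex and a slower, smaller-moment deflection during the
STT interval (ventricular repolarization).  The field component
perpendicular to a planar 6 x 6 sensor grid is sampled, beats are
concatenated with heart-period jitter, and i.i.d. Gaussian sensor noise is
added, producing recordings with the same statistical structure the
downstream analysis assumes:

* healthy subjects are small, i.i.d. perturbations of one canonical beat,
  so their averaged field maps form a tight cluster;
* pathology subjects additionally receive a subject-specific distortion of
  the repolarization interval (a random rotation and displacement of the
  dipole), so their maps differ from healthy maps *and from each other*.

Units are arbitrary linear field units; the downstream gamma-normalization
removes absolute scale, so no attempt is made at calibrated picotesla
output.  No volume-conductor effects are modelled: the analysis needs
plausible rotating-map topology, not biophysical fidelity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.spatial.transform import Rotation

__all__ = [
    "BEAT_SAMPLES",
    "R_PEAK_INDEX",
    "DipoleTrajectory",
    "SensorGrid",
    "GroupTiming",
    "CohortSpec",
    "BeatTemplate",
    "CmfmRecording",
    "forward_field",
    "synth_beat_template",
    "synth_recording",
    "generate_cohort",
    "derive_subject_seed",
]

#: samples per averaged-map beat window at 1000 Hz
BEAT_SAMPLES = 1000
#: 0-based index of the R peak inside the beat window (printed convention:
#: "sample 333", 1-based)
R_PEAK_INDEX = 332

# Global field scale: chosen once so that peak |Bz| of the canonical beat is
# of order 10 field units at the default grid geometry.
_FIELD_SCALE = 0.01

# Canonical beat shape (arbitrary units / radians).  QRS: fast rotation of a
# large moment; STT: slow drift of a smaller moment at a different angle.
_QRS_AMPLITUDE = 1.0
_QRS_SWEEP_RAD = 2.5
_QRS_MZ_FRAC = 0.2
_STT_AMPLITUDE = 0.35
_STT_DRIFT_RAD = 0.4
_STT_MZ_FRAC = 0.1
_BASE_ANGLE_RAD = 0.6
_T_ANGLE_OFFSET_RAD = 0.9
# fraction of the QRS interval preceding the R peak
_QRS_R_FRACTION = 0.45

# Pathology distortion: the rotation axis scatters around a
# disease-typical axis and the rotation angle (x effect_size) is bounded
# away from zero, so every patient deviates from the healthy topology but
# each in an individual direction.  The group is therefore heterogeneous
# around a displaced centre rather than around the healthy topology.
_DISEASE_AXIS = np.array([0.36, 0.48, 0.80])
_DISEASE_AXIS_SPREAD = 1.0
_DISEASE_ANGLE_MID_RAD = 1.4
_DISEASE_ANGLE_HALF_RANGE_RAD = 0.5
_DISEASE_DISP_DIR = np.array([0.8, -0.36, 0.48])
_DISEASE_WARP_HALF_RANGE = 0.35


@dataclass(frozen=True)
class DipoleTrajectory:
    """Time-parametrized point dipole: position and moment per time stamp.

    positions are metres in a heart-centred frame, moments are in scaled
    arbitrary units, times in milliseconds from beat onset.
    """

    positions: np.ndarray  # (n, 3)
    moments: np.ndarray  # (n, 3)
    times: np.ndarray  # (n,) ms, strictly increasing

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        mom = np.asarray(self.moments, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if not (len(pos) == len(mom) == len(t)):
            raise ValueError("positions, moments and times must have equal length")
        if len(t) < 2:
            raise ValueError("a trajectory needs at least two time points")
        if pos.shape[1] != 3 or mom.shape[1] != 3:
            raise ValueError("positions and moments must be 3-vectors")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "moments", mom)
        object.__setattr__(self, "times", t)

    @property
    def span_ms(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class SensorGrid:
    """Planar rectangular magnetometer grid above the dipole frame."""

    n_rows: int
    n_cols: int
    extent_m: float
    positions: np.ndarray  # (n_rows*n_cols, 3)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (self.n_rows * self.n_cols, 3):
            raise ValueError("positions must have n_rows*n_cols rows of 3-vectors")
        if np.ptp(pos[:, 2]) > 1e-12:
            raise ValueError("all sensors must be coplanar (constant z)")
        object.__setattr__(self, "positions", pos)

    @property
    def n_sensors(self) -> int:
        return self.n_rows * self.n_cols

    @classmethod
    def default(cls, n_rows: int = 6, n_cols: int = 6, extent_m: float = 0.20,
                height_m: float = 0.10) -> "SensorGrid":
        """6 x 6 grid over 20 cm x 20 cm, 10 cm above the heart centre."""
        xs = np.linspace(-extent_m / 2, extent_m / 2, n_cols)
        ys = np.linspace(-extent_m / 2, extent_m / 2, n_rows)
        gx, gy = np.meshgrid(xs, ys)
        pos = np.column_stack([gx.ravel(), gy.ravel(),
                               np.full(n_rows * n_cols, height_m)])
        return cls(n_rows=n_rows, n_cols=n_cols, extent_m=extent_m, positions=pos)


class GroupTiming(BaseModel):
    """Per-group heart-rate and segment-length distributions (means +/- SD)."""

    model_config = ConfigDict(extra="forbid")

    hr_mean_bpm: float = Field(70.0, gt=0)
    hr_sd_bpm: float = Field(5.0, ge=0)
    qrs_len_mean_ms: float = Field(90.0, gt=0)
    qrs_len_sd_ms: float = Field(8.0, ge=0)
    stt_len_mean_ms: float = Field(300.0, gt=0)
    stt_len_sd_ms: float = Field(25.0, ge=0)


class CohortSpec(BaseModel):
    """Study conditions for one synthetic cohort.

    With ``effect_size == 0`` the two groups are statistically exchangeable
    by construction; the default timing distributions are identical between
    groups so that segment lengths overlap and heart rate is not a
    confound.
    """

    model_config = ConfigDict(extra="forbid")

    n_healthy: int = Field(57, ge=0)
    n_path: int = Field(40, ge=0)
    effect_size: float = Field(1.0, ge=0)
    healthy_jitter: float = Field(0.05, ge=0)
    beat_noise_sd: float = Field(6.0, ge=0)
    n_beats: int = Field(30, ge=2)
    healthy: GroupTiming = Field(default_factory=GroupTiming)
    pathology: GroupTiming = Field(default_factory=GroupTiming)
    pathology_phase: str = Field("stt", pattern="^(stt|qrs)$")
    pathology_scatter: float = Field(1.0, ge=0)
    fs_hz: float = Field(1000.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if self.n_beats < 2:
            raise ValueError("n_beats must be >= 2 (averaging undefined otherwise)")
        return self


@dataclass(frozen=True)
class BeatTemplate:
    """A subject's noiseless beat: dipole trajectory plus ground truth."""

    trajectory: DipoleTrajectory
    cursors_ms: dict  # qrs_onset/qrs_end/stt_onset/stt_end, ms relative to R
    hr_bpm: float
    group: str
    subject_seed: int


@dataclass(frozen=True)
class CmfmRecording:
    """Raw multi-beat, multi-channel magnetic time series with R annotations."""

    subject_id: str
    group: str  # "healthy" | "pathology"
    signal: np.ndarray  # (n_channels, n_samples), field units
    fs_hz: float
    r_peaks: np.ndarray  # strictly increasing sample indices
    true_cursors_ms: dict  # qrs_onset/qrs_end/stt_onset/stt_end rel. to R

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        peaks = np.asarray(self.r_peaks, dtype=int)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if sig.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if len(peaks) and not np.all(np.diff(peaks) > 0):
            raise ValueError("r_peaks must be strictly increasing")
        if len(peaks) and (peaks.min() < 0 or peaks.max() >= sig.shape[1]):
            raise ValueError("r_peaks must lie within the signal")
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "r_peaks", peaks)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    def mean_heart_rate_bpm(self) -> float:
        """Mean heart rate from R-R intervals, in beats per minute."""
        if len(self.r_peaks) < 2:
            raise ValueError(f"subject {self.subject_id}: need >= 2 R peaks")
        rr_ms = np.diff(self.r_peaks) / self.fs_hz * 1000.0
        return 60000.0 / float(np.mean(rr_ms))


def derive_subject_seed(master_seed: int, subject_id: str) -> int:
    """Stable per-subject seed < 2**31 from the master seed and subject id.

    Hash-based so cohorts are extensible without reshuffling existing
    subjects.
    """
    digest = hashlib.sha256(f"{master_seed}:{subject_id}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _dipole_bz(positions: np.ndarray, moments: np.ndarray,
               sensors: np.ndarray) -> np.ndarray:
    """Perpendicular (z) field of a point dipole at each sensor.

    B(r) = k * (3 n (n.m) - m) / |r - r0|^3 with n the unit vector from the
    dipole to the sensor; only the z component is returned.  Vectorized over
    leading time axis: positions/moments (t, 3), sensors (s, 3) -> (t, s).
    """
    rel = sensors[None, :, :] - positions[:, None, :]  # (t, s, 3)
    dist = np.linalg.norm(rel, axis=2)  # (t, s)
    n = rel / dist[..., None]
    n_dot_m = np.einsum("tsk,tk->ts", n, moments)
    bz = _FIELD_SCALE * (3.0 * n[..., 2] * n_dot_m - moments[:, None, 2]) / dist**3
    return bz


def forward_field(trajectory: DipoleTrajectory, grid: SensorGrid,
                  t_ms: float) -> np.ndarray:
    """Perpendicular field of the trajectory's dipole at time ``t_ms``.

    Position and moment are interpolated linearly between trajectory knots.
    Raises ``ValueError`` if ``t_ms`` lies outside the trajectory span.
    """
    lo, hi = trajectory.span_ms
    if not (lo <= t_ms <= hi):
        raise ValueError(f"t={t_ms} ms outside trajectory span [{lo}, {hi}] ms")
    pos = np.array([np.interp(t_ms, trajectory.times, trajectory.positions[:, k])
                    for k in range(3)])
    mom = np.array([np.interp(t_ms, trajectory.times, trajectory.moments[:, k])
                    for k in range(3)])
    return _dipole_bz(pos[None, :], mom[None, :], grid.positions)[0]


def _raised_sine(u: np.ndarray) -> np.ndarray:
    # small plateau keeps the field non-zero at the wave's cursor samples,
    # as in measured data where cursors never land on an exactly-zero field
    return 0.02 + 0.98 * np.sin(np.pi * u) ** 2


def synth_beat_template(group: str, subject_seed: int,
                        spec: CohortSpec) -> BeatTemplate:
    """Draw one subject's noiseless beat trajectory.

    Healthy subjects perturb the canonical beat by i.i.d. jitter of scale
    ``spec.healthy_jitter`` (angles, amplitudes, dipole position).
    Pathology subjects additionally rotate and displace the dipole during
    the pathology interval (STT by default) by a subject-specific random
    direction of magnitude ``spec.effect_size``; with ``effect_size == 0``
    the same seed yields the identical trajectory as a healthy subject.
    """
    if group not in ("healthy", "pathology"):
        raise ValueError(f"unknown group {group!r}")
    timing = spec.healthy if group == "healthy" else spec.pathology
    rng = np.random.default_rng(subject_seed)

    # Draw order is fixed so healthy and pathology subjects with the same
    # seed share the common (non-pathological) draws.
    # whole-ms segment lengths so cursors land exactly on samples
    qrs_len = float(np.round(np.clip(rng.normal(timing.qrs_len_mean_ms,
                                                timing.qrs_len_sd_ms),
                                     60.0, 130.0)))
    stt_len = float(np.round(np.clip(rng.normal(timing.stt_len_mean_ms,
                                                timing.stt_len_sd_ms),
                                     200.0, 400.0)))
    hr_bpm = float(np.clip(rng.normal(timing.hr_mean_bpm, timing.hr_sd_bpm),
                           40.0, 140.0))

    j = spec.healthy_jitter
    base_angle = _BASE_ANGLE_RAD + rng.normal(0.0, j)
    qrs_sweep = _QRS_SWEEP_RAD * (1.0 + rng.normal(0.0, j))
    qrs_amp = _QRS_AMPLITUDE * (1.0 + rng.normal(0.0, j))
    t_angle = base_angle + _T_ANGLE_OFFSET_RAD + rng.normal(0.0, j)
    stt_amp = _STT_AMPLITUDE * (1.0 + rng.normal(0.0, j))
    base_pos = rng.normal(0.0, 0.02 * j, size=3)

    t = np.arange(float(BEAT_SAMPLES))  # 1 ms resolution
    qrs_on = float(np.round(R_PEAK_INDEX - _QRS_R_FRACTION * qrs_len))
    qrs_end = qrs_on + qrs_len
    stt_on = qrs_end
    stt_end = stt_on + stt_len

    moments = np.zeros((BEAT_SAMPLES, 3))
    positions = np.tile(base_pos, (BEAT_SAMPLES, 1))

    qrs_mask = (t >= qrs_on) & (t <= qrs_end)
    u = (t[qrs_mask] - qrs_on) / qrs_len
    env = qrs_amp * _raised_sine(u)
    phi = base_angle - qrs_sweep / 2 + qrs_sweep * u
    moments[qrs_mask, 0] = env * np.cos(phi)
    moments[qrs_mask, 1] = env * np.sin(phi)
    moments[qrs_mask, 2] = _QRS_MZ_FRAC * env

    stt_mask = (t > stt_on) & (t <= stt_end)
    u = (t[stt_mask] - stt_on) / stt_len
    stt_warp = 1.0
    if group == "pathology":
        # subject-specific repolarization timing skew (see below); drawn
        # here so the envelope warp applies before the rotation
        stt_warp = float(np.exp(
            spec.effect_size * spec.pathology_scatter
            * rng.uniform(-_DISEASE_WARP_HALF_RANGE, _DISEASE_WARP_HALF_RANGE)))
    env = stt_amp * _raised_sine(u ** stt_warp)
    phi = t_angle + _STT_DRIFT_RAD * u
    moments[stt_mask, 0] = env * np.cos(phi)
    moments[stt_mask, 1] = env * np.sin(phi)
    moments[stt_mask, 2] = _STT_MZ_FRAC * env

    if group == "pathology":
        # Distortion of the pathology interval: one dipole rotation whose
        # angle grows strictly with effect_size (every patient deviates)
        # and whose axis scatters around a disease-typical axis (every
        # patient deviates in their own way), plus a dipole displacement
        # with a disease-typical direction and subject scatter.
        # ``pathology_scatter`` scales every subject-specific component:
        # at 0 the group collapses onto one coherent displaced topology;
        # at the default 1 it is heterogeneous around a displaced centre
        # rather than around the healthy topology, so the group-average
        # map represents no individual patient.  Everything is scaled by
        # effect_size so the null (effect_size == 0) is an exact no-op.
        mask = stt_mask if spec.pathology_phase == "stt" else qrs_mask
        het = spec.pathology_scatter
        axis = (_DISEASE_AXIS
                + het * _DISEASE_AXIS_SPREAD * rng.normal(size=3))
        axis /= np.linalg.norm(axis)
        theta = spec.effect_size * (
            _DISEASE_ANGLE_MID_RAD
            + het * rng.uniform(-_DISEASE_ANGLE_HALF_RANGE_RAD,
                                _DISEASE_ANGLE_HALF_RANGE_RAD))
        disp_dir = _DISEASE_DISP_DIR + het * rng.normal(size=3)
        disp_dir /= np.linalg.norm(disp_dir)
        disp = (spec.effect_size * 0.02
                * (1.0 + het * rng.uniform(-0.5, 0.5)) * disp_dir)
        if theta != 0.0:
            moments[mask] = Rotation.from_rotvec(theta * axis).apply(
                moments[mask])
        positions[mask] += disp

    traj = DipoleTrajectory(positions=positions, moments=moments, times=t)
    cursors = {
        "qrs_onset": qrs_on - R_PEAK_INDEX,
        "qrs_end": qrs_end - R_PEAK_INDEX,
        "stt_onset": stt_on - R_PEAK_INDEX,
        "stt_end": stt_end - R_PEAK_INDEX,
    }
    return BeatTemplate(trajectory=traj, cursors_ms=cursors, hr_bpm=hr_bpm,
                        group=group, subject_seed=subject_seed)


def template_field(template: BeatTemplate,
                   grid: SensorGrid | None = None) -> np.ndarray:
    """Noiseless beat field sampled at the trajectory knots (channels x samples)."""
    grid = grid or SensorGrid.default()
    traj = template.trajectory
    return _dipole_bz(traj.positions, traj.moments, grid.positions).T


def synth_recording(subject_id: str, group: str, spec: CohortSpec,
                    grid: SensorGrid | None = None) -> CmfmRecording:
    """Generate one subject's multi-beat recording.

    ``spec.n_beats`` copies of the subject's beat template are laid down at
    R-R intervals drawn from the subject's heart-rate distribution, then
    i.i.d. Gaussian sensor noise of SD ``spec.beat_noise_sd`` is added.
    Ground-truth R peaks and segment cursors are recorded.  Deterministic
    for a fixed (spec.seed, subject_id).
    """
    if spec.n_beats < 2:
        raise ValueError("n_beats must be >= 2 (averaging undefined otherwise)")
    grid = grid or SensorGrid.default()
    subject_seed = derive_subject_seed(spec.seed, subject_id)
    template = synth_beat_template(group, subject_seed, spec)
    beat = template_field(template, grid)  # (channels, BEAT_SAMPLES)

    timing = spec.healthy if group == "healthy" else spec.pathology
    rng = np.random.default_rng(derive_subject_seed(spec.seed, subject_id + ":rec"))
    # Per-beat heart-period jitter around the subject's mean rate; exactly
    # zero jitter when hr_sd_bpm is zero so the noiseless limit is exact.
    if timing.hr_sd_bpm > 0:
        hr_beats = rng.normal(template.hr_bpm, 0.5 * timing.hr_sd_bpm,
                              size=spec.n_beats - 1)
        hr_beats = np.clip(hr_beats, 40.0, 140.0)
    else:
        hr_beats = np.full(spec.n_beats - 1, template.hr_bpm)
    rr_samples = np.round(60000.0 / hr_beats * spec.fs_hz / 1000.0).astype(int)

    lead_in = int(round(0.5 * spec.fs_hz))
    tail = int(round(0.7 * spec.fs_hz))
    scale = spec.fs_hz / 1000.0
    r_first = lead_in + int(round(R_PEAK_INDEX * scale))
    r_peaks = r_first + np.concatenate([[0], np.cumsum(rr_samples)])
    beat_len = int(round(BEAT_SAMPLES * scale))
    n_samples = int(r_peaks[-1]) + (beat_len - int(round(R_PEAK_INDEX * scale))) + tail

    if spec.fs_hz == 1000.0:
        beat_resampled = beat
    else:
        t_native = np.arange(BEAT_SAMPLES)
        t_new = np.arange(beat_len) / scale
        beat_resampled = np.vstack([np.interp(t_new, t_native, ch) for ch in beat])

    signal = np.zeros((grid.n_sensors, n_samples))
    r_in_beat = int(round(R_PEAK_INDEX * scale))
    for r in r_peaks:
        start = int(r) - r_in_beat
        signal[:, start:start + beat_len] += beat_resampled

    if spec.beat_noise_sd > 0:
        signal += rng.normal(0.0, spec.beat_noise_sd, size=signal.shape)

    return CmfmRecording(
        subject_id=subject_id,
        group=group,
        signal=signal,
        fs_hz=spec.fs_hz,
        r_peaks=r_peaks,
        true_cursors_ms=dict(template.cursors_ms),
    )


def generate_cohort(spec: CohortSpec,
                    grid: SensorGrid | None = None) -> list[CmfmRecording]:
    """Generate the full cohort: healthy subjects H001.. then pathology P001.."""
    grid = grid or SensorGrid.default()
    recs = []
    for i in range(spec.n_healthy):
        recs.append(synth_recording(f"H{i + 1:03d}", "healthy", spec, grid))
    for i in range(spec.n_path):
        recs.append(synth_recording(f"P{i + 1:03d}", "pathology", spec, grid))
    return recs
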