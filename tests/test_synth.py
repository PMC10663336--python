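"""Synthetic cohort generator: forward model, templates, recordings."""

import numpy as np
import pytest

from mcgkle import (CmfmRecording, CohortSpec, DipoleTrajectory, GroupTiming,
                    SensorGrid, average_beats, forward_field,
                    mann_whitney_u, synth_beat_template, synth_recording)
from mcgkle.synth import (R_PEAK_INDEX, derive_subject_seed, template_field)


def static_trajectory(moment, position=(0.0, 0.0, 0.0)):
    return DipoleTrajectory(
        positions=np.tile(position, (2, 1)),
        moments=np.tile(moment, (2, 1)),
        times=np.array([0.0, 1.0]),
    )


class TestForwardField:
    def test_zero_moment_reads_zero_everywhere(self):
        grid = SensorGrid.default()
        traj = static_trajectory((0.0, 0.0, 0.0))
        assert np.all(forward_field(traj, grid, 0.5) == 0.0)

    def test_linearity_in_moment(self):
        grid = SensorGrid.default()
        b1 = forward_field(static_trajectory((0.3, -0.2, 0.5)), grid, 0.0)
        b2 = forward_field(static_trajectory((0.6, -0.4, 1.0)), grid, 0.0)
        np.testing.assert_allclose(b2, 2.0 * b1, rtol=1e-12)

    def test_matches_closed_form_dipole_equation(self):
        # Independent hand evaluation of Bz = k (3 nz (n.m) - mz) / d^3 for
        # a tangential moment m = (m, 0, 0) and a sensor at (x, 0, z).
        from mcgkle.synth import _FIELD_SCALE
        m_val, x, z = 0.7, 0.06, 0.10
        grid = SensorGrid(n_rows=1, n_cols=1, extent_m=0.0,
                          positions=np.array([[x, 0.0, z]]))
        d = (x**2 + z**2) ** 0.5
        nz, nx = z / d, x / d
        expected = _FIELD_SCALE * (3.0 * nz * (nx * m_val)) / d**3
        got = forward_field(static_trajectory((m_val, 0.0, 0.0)), grid, 0.0)
        np.testing.assert_allclose(got[0], expected, rtol=1e-12)

    def test_time_outside_span_raises(self):
        with pytest.raises(ValueError, match="outside"):
            forward_field(static_trajectory((1, 0, 0)), SensorGrid.default(), 2.0)


class TestBeatTemplate:
    def test_same_seed_reproduces_trajectory(self):
        spec = CohortSpec(n_healthy=2, n_path=2, seed=0)
        a = synth_beat_template("pathology", 123, spec)
        b = synth_beat_template("pathology", 123, spec)
        np.testing.assert_array_equal(a.trajectory.moments, b.trajectory.moments)
        np.testing.assert_array_equal(a.trajectory.positions, b.trajectory.positions)

    def test_null_effect_makes_groups_identical_per_seed(self):
        spec = CohortSpec(n_healthy=2, n_path=2, effect_size=0.0, seed=0)
        h = synth_beat_template("healthy", 99, spec)
        p = synth_beat_template("pathology", 99, spec)
        np.testing.assert_array_equal(h.trajectory.moments, p.trajectory.moments)
        np.testing.assert_array_equal(h.trajectory.positions,
                                      p.trajectory.positions)

    def test_pathology_maps_differ_from_each_other(self):
        # group structure: at large effect size, two pathology subjects are
        # further apart at the T peak than typical healthy pairs are
        spec = CohortSpec(n_healthy=8, n_path=2, effect_size=1.5, seed=5)
        grid = SensorGrid.default()

        def t_peak_map(group, seed):
            tpl = synth_beat_template(group, seed, spec)
            c = tpl.cursors_ms
            t_peak = R_PEAK_INDEX + (c["stt_onset"] + c["stt_end"]) / 2.0
            field = template_field(tpl, grid)
            col = field[:, int(round(t_peak))]
            return col / np.linalg.norm(col)

        healthy = [t_peak_map("healthy", s) for s in range(8)]
        path = [t_peak_map("pathology", s) for s in (100, 101)]
        hh = [np.linalg.norm(a - b) for i, a in enumerate(healthy)
              for b in healthy[i + 1:]]
        pp = np.linalg.norm(path[0] - path[1])
        assert pp > np.median(hh)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            synth_beat_template("sick", 1, CohortSpec())


class TestRecording:
    def test_noiseless_limit_every_beat_identical(self):
        timing = GroupTiming(hr_sd_bpm=0.0)
        spec = CohortSpec(n_healthy=1, n_path=0, beat_noise_sd=0.0, n_beats=4,
                          healthy=timing, seed=3)
        rec = synth_recording("H001", "healthy", spec)
        wins = [rec.signal[:, r - 332:r + 668] for r in rec.r_peaks]
        for w in wins[1:]:
            np.testing.assert_array_equal(w, wins[0])
        # averaging recovers any single beat window exactly
        amap = average_beats(rec, baseline_correction=False)
        np.testing.assert_allclose(amap.B, wins[0], rtol=0, atol=1e-12)

    def test_fixed_seed_reproduces_recording(self):
        spec = CohortSpec(n_healthy=1, n_path=0, n_beats=4, seed=11)
        a = synth_recording("H001", "healthy", spec)
        b = synth_recording("H001", "healthy", spec)
        np.testing.assert_array_equal(a.signal, b.signal)
        np.testing.assert_array_equal(a.r_peaks, b.r_peaks)

    def test_averaging_noise_shrinks_as_sqrt_n(self):
        # Monte-Carlo: SD of the beat-averaged map ~ beat_noise_sd / sqrt(n)
        n_beats, sd = 16, 2.0
        timing = GroupTiming(hr_sd_bpm=0.0)
        maps = []
        for k in range(80):
            spec = CohortSpec(n_healthy=1, n_path=0, beat_noise_sd=sd,
                              n_beats=n_beats, healthy=timing, seed=50_000 + k)
            rec = synth_recording("H001", "healthy", spec)
            maps.append(average_beats(rec, baseline_correction=False).B)
        observed = np.stack(maps).std(axis=0).mean()
        expected = sd / np.sqrt(n_beats)
        assert abs(observed - expected) / expected < 0.15

    def test_too_few_beats_rejected(self):
        with pytest.raises(Exception):
            CohortSpec(n_healthy=1, n_path=0, n_beats=1)

    def test_r_peaks_monotone_and_in_range(self, small_cohort):
        for rec in small_cohort["recordings"]:
            assert np.all(np.diff(rec.r_peaks) > 0)
            assert rec.r_peaks[-1] < rec.signal.shape[1]

    def test_seed_derivation_stable_and_bounded(self):
        s1 = derive_subject_seed(7, "H001")
        assert s1 == derive_subject_seed(7, "H001")
        assert s1 != derive_subject_seed(7, "H002")
        assert 0 <= s1 < 2**31


def test_null_cohort_exchangeability_rejection_rate():
    """With effect_size=0, a Mann-Whitney test on a T-peak map summary
    between groups rejects at roughly the nominal 5% rate."""
    grid = SensorGrid.default()
    n_rep, alpha = 200, 0.05
    rejections = 0
    for rep in range(n_rep):
        spec = CohortSpec(n_healthy=8, n_path=8, effect_size=0.0,
                          seed=90_000 + rep)
        summaries = {"healthy": [], "pathology": []}
        for group, n in (("healthy", 8), ("pathology", 8)):
            for i in range(n):
                seed = derive_subject_seed(spec.seed, f"{group}{i}")
                tpl = synth_beat_template(group, seed, spec)
                c = tpl.cursors_ms
                t_peak = int(round(R_PEAK_INDEX
                                   + (c["stt_onset"] + c["stt_end"]) / 2.0))
                field = template_field(tpl, grid)
                summaries[group].append(float(np.abs(field[:, t_peak]).mean()))
        p = mann_whitney_u(summaries["healthy"], summaries["pathology"]).p_value
        rejections += p < alpha
    rate = rejections / n_rep
    assert abs(rate - alpha) <= 0.03
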