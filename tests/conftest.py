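import numpy as np
import pytest

from mcgkle import AveragedMap, CohortSpec, cohort_segment_sets
from mcgkle.synth import R_PEAK_INDEX


def make_map(B, qrs=(292, 382), stt=(382, 682), subject_id="S01",
             normalized=False, gamma=None, group=None, r_index=R_PEAK_INDEX):
    """Construct a valid AveragedMap around an arbitrary B array."""
    cursors = {"qrs_onset": qrs[0], "qrs_end": qrs[1],
               "stt_onset": stt[0], "stt_end": stt[1]}
    return AveragedMap(subject_id=subject_id, B=np.asarray(B, dtype=float),
                       cursors=cursors, normalized=normalized, gamma=gamma,
                       group=group, r_index=r_index)


def make_normalized_map(rng=None, n_pos=36, n_samples=1000, **kwargs):
    """A random but valid normalized map (gamma of B equals 1)."""
    rng = rng or np.random.default_rng(0)
    B = rng.normal(size=(n_pos, n_samples))
    amap = make_map(B, **kwargs)
    from mcgkle import gamma_factor, normalize_map
    return normalize_map(amap)


@pytest.fixture(scope="session")
def small_cohort():
    """A small separable cohort shared across tests (12 healthy, 10 pathology)."""
    spec = CohortSpec(n_healthy=12, n_path=10, n_beats=8, effect_size=1.05,
                      seed=424242)
    recordings, segment_sets = cohort_segment_sets(spec)
    return {"spec": spec, "recordings": recordings, "segments": segment_sets}
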