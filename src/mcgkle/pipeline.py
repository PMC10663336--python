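"""End-to-end pipeline: simulate -> average -> segment -> KLE -> classify.

Every stage persists its artefacts (recordings, averaged maps, feature
table, classification reports) under the output directory, each carrying
the configuration fingerprint; rerunning with identical inputs reproduces
byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .classify import heart_rate_test, loocv
from .io import (PipelineConfig, atomic_write_text, read_manifest,
                 read_recording, write_averaged_map, write_feature_table,
                 write_manifest, write_recording)
from .kle import build_reference, kle_features
from .preprocess import average_beats, normalize_map
from .segments import (extract_fixed, extract_resampled,
                       intersample_correlation, segment_length_test)
from .synth import SensorGrid, generate_cohort

__all__ = ["PipelineError", "run_pipeline", "simulate_to_dir",
           "segments_from_maps", "classification_reports"]

logger = logging.getLogger(__name__)

SEGMENT_COMBOS = {"qrs": ("QRS",), "stt": ("STT",), "qrs_stt": ("QRS", "STT")}


class PipelineError(RuntimeError):
    """A stage failure, annotated with stage name and subject id."""


def _stage(stage: str, subject: str | None = None):
    def _wrap(exc: Exception) -> PipelineError:
        where = f"stage {stage}" + (f", subject {subject}" if subject else "")
        return PipelineError(f"{where}: {exc}")
    return _wrap


def simulate_to_dir(config: PipelineConfig, out_dir) -> Path:
    """Generate the synthetic cohort and write recordings plus manifest."""
    out_dir = Path(out_dir)
    rec_dir = out_dir / "recordings"
    fingerprint = config.fingerprint()
    rows = []
    grid = SensorGrid.default()
    try:
        recordings = generate_cohort(config.cohort, grid)
    except Exception as exc:
        raise _stage("simulate")(exc) from exc
    for rec in recordings:
        rel = f"recordings/{rec.subject_id}.h5"
        write_recording(out_dir / rel, rec, fingerprint)
        rows.append({
            "subject_id": rec.subject_id,
            "group": rec.group,
            "recording_path": rel,
            "fs_hz": rec.fs_hz,
            "system_tag": "synthetic",
            **{f"{k}_ms": rec.true_cursors_ms[k] for k in
               ("qrs_onset", "qrs_end", "stt_onset", "stt_end")},
        })
    manifest_path = out_dir / "manifest.csv"
    write_manifest(manifest_path, rows)
    return manifest_path


def _load_recordings(manifest_path):
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    recs = []
    for _, row in df.iterrows():
        recs.append(read_recording(manifest_path.parent / row["recording_path"]))
    return recs


def segments_from_maps(norm_maps, config: PipelineConfig) -> dict:
    """Extract QRS and STT SegmentMaps (configured mode) for every map."""
    out = {"QRS": [], "STT": []}
    for amap in norm_maps:
        for name in ("QRS", "STT"):
            try:
                if config.mode == "fixed":
                    seg = extract_fixed(amap, name, config.n_out(name))
                else:
                    seg = extract_resampled(amap, name, config.n_out(name),
                                            kind=config.interpolation)
            except Exception as exc:
                raise _stage("segments", amap.subject_id)(exc) from exc
            out[name].append(seg)
    return out


def classification_reports(segment_sets: dict, config: PipelineConfig) -> dict:
    """LOOCV reports for QRS-only, STT-only and joint QRS+STT features."""
    reports = {}
    for key, names in SEGMENT_COMBOS.items():
        subset = {n: segment_sets[n] for n in names}
        try:
            reports[key] = loocv(
                subset, regularization=config.lda_ridge,
                strategy=config.distribution_strategy, eps_rel=config.eps_rel,
                reference_group=config.reference_group,
                config={"fingerprint": config.fingerprint(),
                        "mode": config.mode})
        except Exception as exc:
            raise _stage(f"classify[{key}]")(exc) from exc
    return reports


def _report_to_dict(report) -> dict:
    return {
        "subjects": list(report.subjects),
        "y_true": report.y_true.tolist(),
        "y_pred": report.y_pred.tolist(),
        "scores": [f"{s:.17g}" for s in report.scores],
        "confusion": {"tp": report.tp, "fn": report.fn,
                      "tn": report.tn, "fp": report.fp},
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "accuracy": report.accuracy,
        "config": report.config,
    }


def run_pipeline(config: PipelineConfig, out_dir,
                 manifest_path=None) -> dict:
    """Run every stage in order, persisting all intermediates.

    Without a manifest the synthetic cohort defined by ``config.cohort`` is
    generated first.  Returns a summary dict with the three classification
    reports, the segment-length and heart-rate confound tests, and the
    intersample-correlation diagnostics.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fingerprint = config.fingerprint()

    if manifest_path is None:
        manifest_path = simulate_to_dir(config, out_dir)
    recordings = _load_recordings(manifest_path)

    maps_dir = out_dir / "maps"
    norm_maps = []
    for rec in recordings:
        try:
            amap = average_beats(rec,
                                 baseline_correction=config.baseline_correction,
                                 baseline_window=config.baseline_window)
            amap = normalize_map(amap)
        except Exception as exc:
            raise _stage("preprocess", rec.subject_id)(exc) from exc
        write_averaged_map(maps_dir, amap, fingerprint)
        norm_maps.append(amap)

    segment_sets = segments_from_maps(norm_maps, config)

    feature_rows = []
    corr = {}
    for name, segs in segment_sets.items():
        healthy = [s for s in segs if s.group == "healthy"]
        try:
            ref = build_reference(healthy, group_label="healthy")
        except Exception as exc:
            raise _stage(f"features[{name}]")(exc) from exc
        feats = [kle_features(s, ref, strategy=config.distribution_strategy,
                              eps_rel=config.eps_rel) for s in segs]
        for s, f in zip(segs, feats):
            feature_rows.append({
                "subject_id": s.subject_id, "group": s.group, "segment": name,
                "mode": s.mode, "native_length_ms": s.native_length_ms,
                "values": f.values,
            })
        corr[name] = intersample_correlation(
            np.vstack([f.values for f in feats]))
        if corr[name] > config.correlation_warn_threshold:
            logger.warning("%s: max intersample correlation %.3f exceeds "
                           "threshold %.2f", name, corr[name],
                           config.correlation_warn_threshold)
    write_feature_table(out_dir / "features.csv", feature_rows)

    reports = classification_reports(segment_sets, config)

    lengths = {g: [s.native_length_ms for s in segment_sets["STT"]
                   if s.group == g] for g in ("healthy", "pathology")}
    summary = {
        "config_fingerprint": fingerprint,
        "reports": {k: _report_to_dict(r) for k, r in reports.items()},
        "intersample_correlation": corr,
        "heart_rate_test": heart_rate_test(recordings),
        "stt_length_test": segment_length_test(lengths["healthy"],
                                               lengths["pathology"]),
    }
    atomic_write_text(out_dir / "report.json",
                      json.dumps(summary, indent=1, sort_keys=True))
    return {"summary": summary, "reports": reports,
            "segment_sets": segment_sets, "recordings": recordings}
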