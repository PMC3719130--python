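"""Batch driver: spectrogram -> ROIs -> per-model detection over a
directory of WAV recordings.

Recordings are processed independently and in sorted filename order, so
the batch output equals the concatenation of single-recording runs and
re-running on the same inputs reproduces identical outputs.  A failure
on one recording is logged (naming the recording) and skipped; the run
reports whether any recording failed.
"""

from __future__ import annotations

import logging
import re
from datetime import datetime
from pathlib import Path
from zoneinfo import ZoneInfo

import pandas as pd

from .audio import read_wav
from .config import ProjectConfig
from .hmm import SpeciesModel, detect
from .roi import find_rois, rois_to_frame
from .spectrogram import compute_spectrogram

__all__ = ["process_recording", "run_batch", "timestamp_from_name",
           "BatchResult"]

logger = logging.getLogger("roihmm")

#: filenames of the form <site>_YYYYMMDD-HHMMSS.wav carry their start time
_NAME_RE = re.compile(r"_(\d{8})-(\d{6})$")


def timestamp_from_name(stem: str, time_zone: str) -> datetime | None:
    m = _NAME_RE.search(stem)
    if not m:
        return None
    naive = datetime.strptime(m.group(1) + m.group(2), "%Y%m%d%H%M%S")
    return naive.replace(tzinfo=ZoneInfo(time_zone))


def process_recording(
    wav_path: str | Path,
    config: ProjectConfig,
    models: list[SpeciesModel],
    timestamp: datetime | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the full per-recording pipeline; returns (roi table, detections)."""
    wav_path = Path(wav_path)
    if timestamp is None:
        timestamp = timestamp_from_name(wav_path.stem, config.site.time_zone)
    clip = read_wav(wav_path, start_time=timestamp, site_id=config.site.site_id)
    spec = compute_spectrogram(clip, config.window_size, config.hop)
    rois = find_rois(spec, factor=config.roi_factor,
                     connectivity=config.connectivity,
                     min_cells=config.min_cells,
                     exclude_dc=config.exclude_dc)
    table = rois_to_frame(rois, spec, recording_id=clip.recording_id)
    detections = []
    for model in models:
        rec = detect(model, table, recording_id=clip.recording_id,
                     timestamp=timestamp)
        detections.append({
            "recording_id": rec.recording_id,
            "timestamp": timestamp.isoformat() if timestamp else "",
            "species": rec.species,
            "score": rec.score,
            "present": int(rec.present),
        })
    return table, detections


class BatchResult:
    def __init__(self, detections: pd.DataFrame, n_processed: int,
                 failed: list[str]):
        self.detections = detections
        self.n_processed = n_processed
        self.failed = failed

    @property
    def ok(self) -> bool:
        return not self.failed


def run_batch(
    config: ProjectConfig,
    wav_dir: str | Path,
    models: list[SpeciesModel],
    manifest: pd.DataFrame | None = None,
) -> BatchResult:
    """Apply every model to every WAV under ``wav_dir``.

    ``manifest`` (recording_id, timestamp) overrides filename-derived
    timestamps when given.

    Raises
    ------
    ValueError
        If no models are supplied (before any audio is read) or the
        directory contains no WAV files.
    """
    if not models:
        raise ValueError("no species models supplied")
    wav_dir = Path(wav_dir)
    wav_paths = sorted(wav_dir.glob("*.wav"))
    if not wav_paths:
        raise ValueError(f"no WAV files found in {wav_dir}")

    ts_by_id: dict[str, datetime] = {}
    if manifest is not None:
        for rec_id, ts in zip(manifest["recording_id"], manifest["timestamp"]):
            ts_by_id[str(rec_id)] = pd.Timestamp(ts).to_pydatetime()

    rows: list[dict] = []
    failed: list[str] = []
    for path in wav_paths:
        try:
            _, detections = process_recording(
                path, config, models, timestamp=ts_by_id.get(path.stem))
            rows.extend(detections)
            logger.info("processed %s", path.name)
        except Exception:
            logger.exception("failed on recording %s; skipping", path.name)
            failed.append(path.name)
    det = pd.DataFrame(rows, columns=["recording_id", "timestamp", "species",
                                      "score", "present"])
    det = det.sort_values(["recording_id", "species"], kind="stable",
                          ignore_index=True)
    return BatchResult(det, n_processed=len(wav_paths) - len(failed),
                       failed=failed)
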