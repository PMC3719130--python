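"""Region-of-interest (ROI) detection on a spectrogram.

The detector estimates the background-noise level of every frequency
band as the mean magnitude of that row across the whole recording,
keeps only the cells strictly greater than 10% above their band mean
(the retained cells form a compressed-sparse-row "event" matrix), and
grows neighbourhoods of retained cells into ROIs by depth-first search.
Each ROI is summarised by its bounding box in physical units: minimum
and maximum frequency, bandwidth, duration, and maximum intensity —
the five features consumed by the species models.

Two clustering engines produce the identical partition:

``engine="label"`` (default)
    connected-component labelling via :func:`scipy.ndimage.label`;
    C-speed, used for full-length recordings.
``engine="dfs"``
    an explicit-stack (iterative, no recursion limit) depth-first
    search over the sparse events; the direct transcription of the
    neighbourhood-growing procedure, kept as a readable reference.

Connectivity is 8 by default: frequency-modulated sweeps trace diagonal
pixel runs that 4-connectivity would fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage, sparse

from .spectrogram import Spectrogram

__all__ = [
    "EventSet",
    "ROI",
    "band_thresholds",
    "extract_events",
    "cluster_rois",
    "roi_features",
    "find_rois",
    "rois_to_frame",
    "ROI_COLUMNS",
]

#: column order of the exported ROI table
ROI_COLUMNS = [
    "recording_id", "roi_index", "t_start_s", "t_end_s",
    "min_freq_hz", "max_freq_hz", "bandwidth_hz", "duration_s",
    "max_intensity",
]


@dataclass
class EventSet:
    """Above-threshold spectrogram cells in CSR organisation."""

    events: sparse.csr_array  # retained magnitudes; zero elsewhere
    shape: tuple[int, int]

    @property
    def n_events(self) -> int:
        return int(self.events.nnz)

    def cells(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (bins, frames, magnitudes) of the retained cells."""
        coo = self.events.tocoo()
        return coo.coords[0], coo.coords[1], coo.data


@dataclass
class ROI:
    """One connected neighbourhood of retained cells.

    ``cells`` is an ``(n, 2)`` array of (bin, frame) pairs; the bounds
    are tight over the members.
    """

    cells: np.ndarray
    min_bin: int
    max_bin: int
    first_frame: int
    last_frame: int
    max_intensity: float

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]


def band_thresholds(spec: Spectrogram, factor: float = 1.10) -> np.ndarray:
    """Per-frequency-band detection thresholds.

    ``threshold[b] = factor * mean(magnitude[b, :])`` — the band's mean
    intensity over the whole recording, raised by 10% by default.
    """
    if spec.n_frames == 0:
        raise ValueError("spectrogram has no frames")
    return factor * spec.magnitude.mean(axis=1)


def extract_events(
    spec: Spectrogram,
    thresholds: np.ndarray,
    exclude_dc: bool = True,
) -> EventSet:
    """Keep cells whose magnitude strictly exceeds their band threshold.

    The DC row (bin 0) is excluded by default: offsets there are
    recording-chain artefacts, not acoustic events.

    Raises
    ------
    ValueError
        If ``thresholds`` does not have one entry per frequency bin.
    """
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.shape != (spec.n_bins,):
        raise ValueError(
            f"thresholds shape {thresholds.shape} does not match "
            f"{spec.n_bins} frequency bins")
    mask = spec.magnitude > thresholds[:, None]
    if exclude_dc:
        mask[0, :] = False
    events = sparse.csr_array(np.where(mask, spec.magnitude, 0.0))
    return EventSet(events=events, shape=spec.magnitude.shape)


_STRUCTURE = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}

_NEIGHBORS = {
    4: ((-1, 0), (1, 0), (0, -1), (0, 1)),
    8: tuple((db, df) for db in (-1, 0, 1) for df in (-1, 0, 1)
             if (db, df) != (0, 0)),
}


def cluster_rois(
    events: EventSet,
    connectivity: int = 8,
    engine: str = "label",
) -> list[ROI]:
    """Partition the retained cells into connected ROIs.

    Every retained cell belongs to exactly one ROI.  The result is
    ordered by (first frame, lowest bin) so downstream observation
    sequences are reproducible.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    if engine == "label":
        labels, cells, mags = _label_components(events, connectivity)
    elif engine == "dfs":
        labels, cells, mags = _dfs_components(events, connectivity)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    if cells.shape[0] == 0:
        return []

    order = np.argsort(labels, kind="stable")
    labels, cells, mags = labels[order], cells[order], mags[order]
    starts = np.flatnonzero(np.diff(labels, prepend=labels[0] - 1))
    ends = np.append(starts[1:], labels.size)

    rois: list[ROI] = []
    bins_col, frames_col = cells[:, 0], cells[:, 1]
    min_b = np.minimum.reduceat(bins_col, starts)
    max_b = np.maximum.reduceat(bins_col, starts)
    min_f = np.minimum.reduceat(frames_col, starts)
    max_f = np.maximum.reduceat(frames_col, starts)
    max_i = np.maximum.reduceat(mags, starts)
    for k, (s, e) in enumerate(zip(starts, ends)):
        rois.append(ROI(cells=cells[s:e], min_bin=int(min_b[k]),
                        max_bin=int(max_b[k]), first_frame=int(min_f[k]),
                        last_frame=int(max_f[k]),
                        max_intensity=float(max_i[k])))
    rois.sort(key=lambda r: (r.first_frame, r.min_bin))
    return rois


def _label_components(events: EventSet, connectivity: int):
    dense = events.events.toarray()
    mask = dense > 0
    labeled, n = ndimage.label(mask, structure=_STRUCTURE[connectivity])
    cells = np.argwhere(mask)
    labels = labeled[mask]
    mags = dense[mask]
    return labels, cells, mags


def _dfs_components(events: EventSet, connectivity: int):
    """Explicit-stack depth-first search over the sparse event cells."""
    bins, frames, mags = events.cells()
    remaining = {(int(b), int(f)): float(m)
                 for b, f, m in zip(bins, frames, mags)}
    offsets = _NEIGHBORS[connectivity]
    out_cells: list[tuple[int, int]] = []
    out_labels: list[int] = []
    out_mags: list[float] = []
    label = 0
    # iterate seeds in CSR (row-major) order for determinism
    for seed in zip(bins.tolist(), frames.tolist()):
        if seed not in remaining:
            continue
        label += 1
        stack = [seed]
        mag = remaining.pop(seed)
        out_cells.append(seed)
        out_labels.append(label)
        out_mags.append(mag)
        while stack:
            b, f = stack.pop()
            for db, df in offsets:
                nb = (b + db, f + df)
                if nb in remaining:
                    out_cells.append(nb)
                    out_labels.append(label)
                    out_mags.append(remaining.pop(nb))
                    stack.append(nb)
    return (np.array(out_labels, dtype=np.int64),
            np.array(out_cells, dtype=np.int64).reshape(-1, 2),
            np.array(out_mags, dtype=np.float64))


def roi_features(roi: ROI, spec: Spectrogram) -> dict[str, float]:
    """Bounding-box features of one ROI in physical units.

    A single cell has non-zero extent: bandwidth counts inclusive bins
    (``(max_bin - min_bin + 1) * bin_width_hz``) and duration inclusive
    frames, so a 1x1 ROI spans one bin width and one hop.
    """
    if roi.n_cells == 0:
        raise ValueError("cannot compute features of an empty ROI")
    bw = spec.bin_width_hz
    hs = spec.hop_s
    return {
        "t_start_s": roi.first_frame * hs,
        "t_end_s": (roi.last_frame + 1) * hs,
        "min_freq_hz": roi.min_bin * bw,
        "max_freq_hz": roi.max_bin * bw,
        "bandwidth_hz": (roi.max_bin - roi.min_bin + 1) * bw,
        "duration_s": (roi.last_frame - roi.first_frame + 1) * hs,
        "max_intensity": roi.max_intensity,
    }


def find_rois(
    spec: Spectrogram,
    factor: float = 1.10,
    connectivity: int = 8,
    min_cells: int = 1,
    exclude_dc: bool = True,
    engine: str = "label",
) -> list[ROI]:
    """Threshold, extract events, and cluster in one call."""
    thresholds = band_thresholds(spec, factor=factor)
    events = extract_events(spec, thresholds, exclude_dc=exclude_dc)
    rois = cluster_rois(events, connectivity=connectivity, engine=engine)
    if min_cells > 1:
        rois = [r for r in rois if r.n_cells >= min_cells]
    return rois


def rois_to_frame(
    rois: Iterable[ROI],
    spec: Spectrogram,
    recording_id: str = "",
) -> pd.DataFrame:
    """ROI table in the exported CSV layout (:data:`ROI_COLUMNS`)."""
    rows = []
    for i, roi in enumerate(rois):
        feats = roi_features(roi, spec)
        rows.append({"recording_id": recording_id, "roi_index": i, **feats})
    frame = pd.DataFrame(rows, columns=ROI_COLUMNS)
    return frame
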