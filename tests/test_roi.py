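"""ROI detection: thresholds, event extraction, clustering, features."""

import numpy as np
import pytest
from scipy import sparse

from roihmm.audio import AudioClip
from roihmm.roi import (EventSet, band_thresholds, cluster_rois,
                        extract_events, find_rois, roi_features,
                        rois_to_frame)
from roihmm.spectrogram import Spectrogram, compute_spectrogram


def make_spec(matrix, sample_rate=44100):
    matrix = np.asarray(matrix, dtype=float)
    window = 2 * (matrix.shape[0] - 1)
    return Spectrogram(matrix, sample_rate=sample_rate,
                       window_size=window, hop=window // 2)


def events_from_bool(mask, mags=None):
    mask = np.asarray(mask, dtype=bool)
    data = np.where(mask, 1.0 if mags is None else mags, 0.0)
    return EventSet(sparse.csr_array(data), mask.shape)


# -- thresholds and event extraction -------------------------------------

def test_band_threshold_hand_example():
    spec = make_spec(np.array([[1.0, 1.0, 1.0, 1.0, 10.0],
                               [2.0, 2.0, 2.0, 2.0, 2.0]]))
    th = band_thresholds(spec)
    assert th[0] == pytest.approx(1.1 * 2.8)  # mean 2.8 -> 3.08
    assert th[1] == pytest.approx(2.2)        # constant band c -> 1.1c


def test_all_zero_band_threshold_zero():
    spec = make_spec(np.zeros((3, 4)))
    assert np.all(band_thresholds(spec) == 0.0)


def test_only_outlier_cell_survives_threshold():
    spec = make_spec(np.array([[0.0, 0.0], [1.0, 1.0],
                               [1.0, 1.0], [1.0, 10.0]]))
    events = extract_events(spec, band_thresholds(spec))
    assert events.n_events == 1
    bins, frames, mags = events.cells()
    assert (bins[0], frames[0], mags[0]) == (3, 1, 10.0)


def test_constant_matrix_yields_no_events():
    spec = make_spec(np.full((4, 6), 2.5))
    assert extract_events(spec, band_thresholds(spec)).n_events == 0


def test_zero_matrix_yields_no_events():
    spec = make_spec(np.zeros((4, 6)))
    assert extract_events(spec, band_thresholds(spec)).n_events == 0


def test_threshold_shape_mismatch_rejected():
    spec = make_spec(np.zeros((4, 6)))
    with pytest.raises(ValueError, match="thresholds"):
        extract_events(spec, np.zeros(3))


def test_dc_row_excluded_by_default():
    m = np.zeros((3, 4))
    m[0, 1] = 5.0  # only energy is in the DC row
    spec = make_spec(m)
    assert extract_events(spec, band_thresholds(spec)).n_events == 0
    kept = extract_events(spec, band_thresholds(spec), exclude_dc=False)
    assert kept.n_events == 1


def test_raising_factor_never_adds_cells(rng):
    spec = make_spec(rng.random((12, 30)))
    counts = [extract_events(spec, band_thresholds(spec, f)).n_events
              for f in (1.0, 1.1, 1.3, 1.8, 2.5)]
    assert counts == sorted(counts, reverse=True)


# -- clustering -----------------------------------------------------------

def flood_fill_labels(mask, connectivity):
    """Independent brute-force oracle: repeated whole-grid label sweeps."""
    mask = np.asarray(mask, dtype=bool)
    labels = -np.ones(mask.shape, dtype=int)
    if connectivity == 4:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1)
                if (a, b) != (0, 0)]
    current = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and labels[i, j] < 0:
                labels[i, j] = current
                changed = True
                while changed:  # naive propagation until stable
                    changed = False
                    for a in range(mask.shape[0]):
                        for b in range(mask.shape[1]):
                            if labels[a, b] == current:
                                for da, db in offs:
                                    na, nb = a + da, b + db
                                    if (0 <= na < mask.shape[0]
                                            and 0 <= nb < mask.shape[1]
                                            and mask[na, nb]
                                            and labels[na, nb] < 0):
                                        labels[na, nb] = current
                                        changed = True
                current += 1
    return labels


def partition_sets(rois):
    sets = [frozenset((int(a), int(b)) for a, b in r.cells) for r in rois]
    return sorted(sets, key=sorted)


def oracle_sets(labels):
    out = []
    for lab in range(labels.max() + 1):
        out.append(frozenset((int(a), int(b))
                             for a, b in np.argwhere(labels == lab)))
    return sorted(out, key=sorted)


@pytest.mark.parametrize("connectivity", [4, 8])
@pytest.mark.parametrize("engine", ["label", "dfs"])
def test_clustering_matches_flood_fill_oracle(connectivity, engine):
    rng = np.random.default_rng(7)
    for _ in range(60):
        shape = (rng.integers(1, 15), rng.integers(1, 15))
        mask = rng.random(shape) < 0.35
        rois = cluster_rois(events_from_bool(mask), connectivity, engine)
        assert partition_sets(rois) == oracle_sets(
            flood_fill_labels(mask, connectivity))


def test_diagonal_cells_split_by_connectivity():
    mask = np.array([[1, 0], [0, 1]], dtype=bool)
    assert len(cluster_rois(events_from_bool(mask), connectivity=8)) == 1
    assert len(cluster_rois(events_from_bool(mask), connectivity=4)) == 2


def test_well_separated_cells_always_two_rois():
    mask = np.zeros((6, 6), dtype=bool)
    mask[0, 0] = mask[4, 4] = True
    for conn in (4, 8):
        assert len(cluster_rois(events_from_bool(mask), conn)) == 2


def test_single_cell_roi_bounds():
    mask = np.zeros((5, 5), dtype=bool)
    mask[2, 3] = True
    (roi,) = cluster_rois(events_from_bool(mask))
    assert (roi.min_bin, roi.max_bin) == (2, 2)
    assert (roi.first_frame, roi.last_frame) == (3, 3)
    assert roi.n_cells == 1


def test_partition_property(rng):
    mask = rng.random((20, 20)) < 0.4
    rois = cluster_rois(events_from_bool(mask))
    all_cells = [tuple(c) for r in rois for c in r.cells]
    assert len(all_cells) == len(set(all_cells)) == mask.sum()
    assert set(all_cells) == set(map(tuple, np.argwhere(mask)))


def test_roi_ordering_deterministic(rng):
    mask = rng.random((15, 25)) < 0.3
    a = cluster_rois(events_from_bool(mask))
    b = cluster_rois(events_from_bool(mask))
    assert [(r.first_frame, r.min_bin) for r in a] == \
           [(r.first_frame, r.min_bin) for r in b]
    keys = [(r.first_frame, r.min_bin) for r in a]
    assert keys == sorted(keys)


# -- features -------------------------------------------------------------

def test_feature_arithmetic_inclusive_convention():
    m = np.zeros((30, 30))
    m[10:21, 5:16] = 7.0
    spec = make_spec(m, sample_rate=44100)
    events = events_from_bool(m > 0, m)
    (roi,) = cluster_rois(events)
    feats = roi_features(roi, spec)
    bw = spec.bin_width_hz
    hs = spec.hop_s
    assert feats["min_freq_hz"] == pytest.approx(10 * bw)
    assert feats["max_freq_hz"] == pytest.approx(20 * bw)
    assert feats["bandwidth_hz"] == pytest.approx(11 * bw)
    assert feats["duration_s"] == pytest.approx(11 * hs)
    assert feats["max_intensity"] == 7.0


def test_single_cell_has_one_bin_one_hop_extent():
    m = np.zeros((8, 8))
    m[3, 4] = 2.0
    spec = make_spec(m)
    (roi,) = cluster_rois(events_from_bool(m > 0, m))
    feats = roi_features(roi, spec)
    assert feats["bandwidth_hz"] == pytest.approx(spec.bin_width_hz)
    assert feats["duration_s"] == pytest.approx(spec.hop_s)


def test_max_intensity_is_global_max_when_roi_covers_it(rng):
    m = rng.random((10, 10)) + 0.5
    m[4, 4] = 50.0
    spec = make_spec(m)
    rois = find_rois(spec, factor=1.1, exclude_dc=True)
    best = max(r.max_intensity for r in rois)
    assert best == pytest.approx(50.0)


def test_roi_table_layout(noise_clip):
    spec = compute_spectrogram(noise_clip)
    rois = find_rois(spec, min_cells=3)
    frame = rois_to_frame(rois, spec, recording_id="rec1")
    assert list(frame.columns) == [
        "recording_id", "roi_index", "t_start_s", "t_end_s", "min_freq_hz",
        "max_freq_hz", "bandwidth_hz", "duration_s", "max_intensity"]
    assert (frame["bandwidth_hz"] > 0).all()
    assert (frame["t_end_s"] > frame["t_start_s"]).all()
    assert (frame["recording_id"] == "rec1").all()
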