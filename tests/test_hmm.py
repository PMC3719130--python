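"""Discrete HMM: codebook, initialisation, Baum-Welch, forward, detection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from roihmm.hmm import (Codebook, HMMParams, ObservationSequence,
                        apply_filter, assemble_sequences, baum_welch,
                        build_codebook, detect, init_model, log_likelihood,
                        train_model)


def record_frame(rows):
    return pd.DataFrame(rows, columns=["recording_id", "roi_index",
                                       "t_start_s", "t_end_s", "min_freq_hz",
                                       "max_freq_hz", "bandwidth_hz",
                                       "duration_s", "max_intensity"])


def feature_rows(specs):
    """specs: list of (t_start, min_freq, bandwidth, duration)."""
    return record_frame([
        ("r", i, t, t + d, f, f + b, b, d, 10.0)
        for i, (t, f, b, d) in enumerate(specs)])


def random_params(rng, n, m):
    a = rng.random((n, n)) + 0.1
    a /= a.sum(axis=1, keepdims=True)
    b = rng.random((n, m)) + 0.1
    b /= b.sum(axis=1, keepdims=True)
    pi = rng.random(n) + 0.1
    pi /= pi.sum()
    return HMMParams(a, b, pi)


def brute_force_likelihood(params, seq):
    n = params.n_states
    total = 0.0
    for path in itertools.product(range(n), repeat=len(seq)):
        p = params.pi[path[0]] * params.b[path[0], seq[0]]
        for t in range(1, len(seq)):
            p *= params.a[path[t - 1], path[t]] * params.b[path[t], seq[t]]
        total += p
    return np.log(total) if total > 0 else -np.inf


# -- codebook -------------------------------------------------------------

def test_codebook_uniform_edge_spacing():
    recs = feature_rows([(0.0, 100.0, 50.0, 0.1), (1.0, 900.0, 150.0, 0.3)])
    cb = build_codebook(recs, bins_per_feature=(8, 4, 4))
    np.testing.assert_allclose(np.diff(cb.edges[0]), 100.0)
    assert cb.n_symbols == 8 * 4 * 4


def test_single_record_degenerate_codebook_still_encodes():
    recs = feature_rows([(0.0, 500.0, 100.0, 0.2)])
    cb = build_codebook(recs)
    sym = cb.encode(recs)
    assert sym.shape == (1,)
    assert 0 <= sym[0] < cb.n_symbols


def test_identical_records_share_symbol():
    recs = feature_rows([(0.0, 500.0, 100.0, 0.2)] * 5)
    cb = build_codebook(recs)
    assert len(set(cb.encode(recs))) == 1


def test_out_of_range_values_clip_into_outer_bins():
    recs = feature_rows([(0.0, 100.0, 50.0, 0.1), (1.0, 900.0, 150.0, 0.3)])
    cb = build_codebook(recs)
    outside = feature_rows([(0.0, -1e4, 1e5, 99.0)])
    sym = cb.encode(outside)
    assert 0 <= sym[0] < cb.n_symbols


def test_empty_training_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        build_codebook(feature_rows([]))


# -- sequence assembly ----------------------------------------------------

def test_sequences_sorted_by_time_and_filtered():
    recs = feature_rows([(3.0, 500.0, 100.0, 0.2),
                         (1.0, 600.0, 100.0, 0.2),
                         (2.0, 5000.0, 100.0, 0.2)])  # filtered out
    cb = build_codebook(recs)
    seqs = assemble_sequences(recs, cb,
                              candidate_filter={"min_freq_hz": (400, 1000)})
    seq = seqs["r"]
    assert len(seq) == 2
    # order follows start time (1.0 before 3.0), not table order
    expected = cb.encode(recs.iloc[[1, 0]])
    np.testing.assert_array_equal(seq.symbols, expected)


def test_filter_excluding_everything_gives_empty_sequence():
    recs = feature_rows([(0.0, 500.0, 100.0, 0.2)])
    cb = build_codebook(recs)
    seqs = assemble_sequences(recs, cb,
                              candidate_filter={"min_freq_hz": (1e4, 2e4)})
    assert len(seqs["r"]) == 0


def test_inverted_filter_range_rejected():
    recs = feature_rows([(0.0, 500.0, 100.0, 0.2)])
    with pytest.raises(ValueError, match="low"):
        apply_filter(recs, {"min_freq_hz": (100.0, 50.0)})


# -- initialisation -------------------------------------------------------

def test_single_state_init_is_smoothed_frequencies():
    seqs = [np.array([0, 1, 1]), np.array([2])]
    p = init_model(1, seqs, n_symbols=3)
    np.testing.assert_allclose(p.a, [[1.0]])
    np.testing.assert_allclose(p.pi, [1.0])
    np.testing.assert_allclose(p.b, [[2 / 7, 3 / 7, 2 / 7]])  # counts+1 / (4+3)


def test_two_state_uniform_alignment_counts():
    # every length-2 sequence contributes one 0->1 transition before smoothing
    seqs = [np.array([0, 1])] * 4
    p = init_model(2, seqs, n_symbols=2)
    # row 0 counts: 0->0: 0+1, 0->1: 4+1 -> [1/6, 5/6]
    np.testing.assert_allclose(p.a[0], [1 / 6, 5 / 6])
    np.testing.assert_allclose(p.a[1], [0.0, 1.0])  # last state self-loop only
    np.testing.assert_allclose(p.pi, [1.0, 0.0])


def test_init_rows_are_stochastic(rng):
    seqs = [rng.integers(0, 5, rng.integers(1, 12)) for _ in range(6)]
    p = init_model(3, seqs, n_symbols=5)
    np.testing.assert_allclose(p.a.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(p.b.sum(axis=1), 1.0, atol=1e-12)
    assert p.pi.sum() == pytest.approx(1.0)


def test_init_rejects_empty_and_out_of_range():
    with pytest.raises(ValueError, match="empty"):
        init_model(2, [np.array([], dtype=int)], 4)
    with pytest.raises(ValueError, match="range"):
        init_model(2, [np.array([5])], 4)


# -- forward --------------------------------------------------------------

def test_forward_matches_brute_force_enumeration(rng):
    for _ in range(40):
        n = int(rng.integers(1, 4))
        m = int(rng.integers(2, 5))
        params = random_params(rng, n, m)
        seq = rng.integers(0, m, int(rng.integers(1, 7)))
        assert log_likelihood(params, seq) == pytest.approx(
            brute_force_likelihood(params, seq), abs=1e-10)


def test_length_one_closed_form(rng):
    params = random_params(rng, 3, 4)
    for k in range(4):
        expected = np.log(np.sum(params.pi * params.b[:, k]))
        assert log_likelihood(params, np.array([k])) == pytest.approx(expected)


def test_deterministic_model_scores_zero():
    params = HMMParams(np.array([[0.0, 1.0], [0.0, 1.0]]),
                       np.array([[1.0, 0.0], [0.0, 1.0]]),
                       np.array([1.0, 0.0]))
    assert log_likelihood(params, np.array([0, 1, 1])) == pytest.approx(0.0)


def test_impossible_sequence_scores_minus_inf():
    params = HMMParams(np.array([[1.0]]), np.array([[1.0, 0.0]]),
                       np.array([1.0]))
    assert log_likelihood(params, np.array([1])) == -np.inf


def test_forward_rejects_empty_and_bad_symbols(rng):
    params = random_params(rng, 2, 3)
    with pytest.raises(ValueError, match="empty"):
        log_likelihood(params, np.array([], dtype=int))
    with pytest.raises(ValueError, match="range"):
        log_likelihood(params, np.array([3]))


def test_forward_agrees_with_reference_implementation(rng):
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    for _ in range(10):
        n, m = int(rng.integers(2, 5)), int(rng.integers(2, 6))
        params = random_params(rng, n, m)
        seq = rng.integers(0, m, int(rng.integers(3, 40)))
        ref = hmmlearn.CategoricalHMM(n_components=n)
        ref.startprob_ = params.pi
        ref.transmat_ = params.a
        ref.emissionprob_ = params.b
        expected = ref.score(seq.reshape(-1, 1))
        assert log_likelihood(params, seq) == pytest.approx(expected, abs=1e-6)


# -- Baum-Welch -----------------------------------------------------------

def test_monotone_log_likelihood(rng):
    for _ in range(30):
        n, m = int(rng.integers(1, 4)), int(rng.integers(2, 6))
        params = random_params(rng, n, m)
        seqs = [rng.integers(0, m, int(rng.integers(2, 20)))
                for _ in range(4)]
        _, history = baum_welch(params, seqs, tol=0.0, max_iter=20)
        assert np.all(np.diff(history) >= -1e-8)


def test_rows_stay_stochastic_after_reestimation(rng):
    params = random_params(rng, 3, 4)
    seqs = [rng.integers(0, 4, 15) for _ in range(5)]
    fit, _ = baum_welch(params, seqs, max_iter=10)
    np.testing.assert_allclose(fit.a.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(fit.b.sum(axis=1), 1.0, atol=1e-9)
    assert fit.pi.sum() == pytest.approx(1.0, abs=1e-9)


def test_single_state_reaches_empirical_frequencies():
    seqs = [np.array([0, 1, 1, 2]), np.array([2, 2])]
    p0 = init_model(1, seqs, 3)
    fit, history = baum_welch(p0, seqs, tol=0.0, max_iter=3)
    np.testing.assert_allclose(fit.b, [[1 / 6, 2 / 6, 3 / 6]], atol=1e-12)
    # single-state model converges immediately: likelihood flat after step 1
    assert history[-1] == pytest.approx(history[1], abs=1e-12)


def test_converged_params_are_fixed_point():
    seqs = [np.array([0, 1, 1, 2]), np.array([2, 2])]
    fit, _ = baum_welch(init_model(1, seqs, 3), seqs, max_iter=5)
    again, _ = baum_welch(fit, seqs, max_iter=1, tol=0.0)
    np.testing.assert_allclose(again.b, fit.b, atol=1e-9)
    np.testing.assert_allclose(again.a, fit.a, atol=1e-9)


def test_state_relabeling_permutes_recovered_matrices(rng):
    m = 4
    params = random_params(rng, 2, m)
    seqs = [rng.integers(0, m, 20) for _ in range(5)]
    fit, _ = baum_welch(params, seqs, max_iter=5, tol=0.0)
    perm = [1, 0]
    permuted = HMMParams(params.a[np.ix_(perm, perm)], params.b[perm],
                         params.pi[perm])
    fit_p, _ = baum_welch(permuted, seqs, max_iter=5, tol=0.0)
    np.testing.assert_allclose(fit_p.a, fit.a[np.ix_(perm, perm)], atol=1e-8)
    np.testing.assert_allclose(fit_p.b, fit.b[perm], atol=1e-8)


def test_bad_symbol_rejected(rng):
    params = random_params(rng, 2, 3)
    with pytest.raises(ValueError, match="range"):
        baum_welch(params, [np.array([0, 3])])


# -- training and detection ----------------------------------------------

def three_note_examples(n=6, jitter=0.0):
    rng = np.random.default_rng(0)
    out = []
    for _ in range(n):
        j = jitter * rng.standard_normal(3)
        out.append(feature_rows([
            (1.0, 3000.0 + j[0], 400.0, 0.10),
            (1.3, 3000.0 + j[1], 400.0, 0.10),
            (1.6, 3500.0 + j[2], 900.0, 0.25),
        ]))
    return out


def test_trained_model_detects_its_own_training_call():
    model = train_model(three_note_examples(), n_states=3, species="sp")
    rec = detect(model, three_note_examples(1)[0], recording_id="x")
    assert rec.present
    assert rec.species == "sp"


def test_recording_with_no_candidates_is_absent():
    model = train_model(three_note_examples(), n_states=3)
    empty = feature_rows([])
    rec = detect(model, empty, recording_id="x")
    assert not rec.present
    assert rec.score == -np.inf


def test_out_of_band_rois_are_absent():
    model = train_model(three_note_examples(), n_states=3)
    other = feature_rows([(0.5, 900.0, 200.0, 0.12),
                          (0.8, 900.0, 200.0, 0.12),
                          (1.1, 900.0, 200.0, 0.12)])
    rec = detect(model, other, recording_id="x")
    assert not rec.present


def test_model_json_roundtrip(tmp_path):
    from roihmm.hmm import SpeciesModel
    model = train_model(three_note_examples(), n_states=3, species="sp",
                        emission_floor=0.1, intensity_floor_factor=0.5)
    path = tmp_path / "model.json"
    model.save(path)
    back = SpeciesModel.load(path)
    np.testing.assert_allclose(back.params.a, model.params.a)
    np.testing.assert_allclose(back.params.b, model.params.b)
    assert back.candidate_filter == model.candidate_filter
    assert back.decision_threshold == model.decision_threshold
    assert (back.min_window, back.max_window) == (model.min_window,
                                                  model.max_window)
    rec1 = detect(model, three_note_examples(1)[0], recording_id="x")
    rec2 = detect(back, three_note_examples(1)[0], recording_id="x")
    assert rec1.score == pytest.approx(rec2.score)
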