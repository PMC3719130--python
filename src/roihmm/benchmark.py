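"""End-to-end synthetic benchmark: plant calls, train, detect, score.

This module wires the whole pipeline together on a synthetic corpus
with known truth: two stock species with disjoint frequency bands and
distinct note grammars are planted in scheduled clips over background
noise and broadband transients; models are trained from ROI series
selected the way an expert would (one ROI per note of a known call) and
then applied to an independent evaluation corpus; the result is scored
against the planted presence truth.

The default experiment — 30 training clips, 200 evaluation clips of
10 s at roughly 45 dB per-call band SNR, species independently present
in half the clips — is the package's standing stand-in for a field
validation campaign.  All randomness derives from the single seed.

Analysis settings used here (and their reasons):

- band-threshold factor 2.0 (not the 1.10 default): against the
  benchmark's stationary Gaussian background the 10%-above-mean rule
  retains ~39% of pure-noise cells — almost exactly the 8-connectivity
  site-percolation threshold — so noise clusters grow heavy-tailed
  tendrils that attach to call ROIs and wreck their bounding boxes.
  Raising the factor to 2.0 drops retention to ~4% and leaves call
  features stable; tightening detector parameters against a validation
  set is part of the modelling workflow this package supports, and the
  1.10 default is used everywhere outside this benchmark.
- ``min_cells=8``: single-cell noise specks are overwhelming even at
  4% retention; genuine note ROIs at benchmark SNR have tens of cells.
- training examples are kept when note selection recovers at least
  ``n_notes - 1`` ROIs, then robustly curated (median +- 5 MAD per
  feature): a transient can bridge notes or wreck a bounding box, and
  an expert would discard such picks.  Candidate-filter ranges still
  come from the full uncurated pool (margin 0.25, plus an intensity
  floor at half the faintest training note) so the filter stays
  tolerant of feature jitter while the emission statistics stay clean.
- (6, 2, 2) codebook — fine in minimum frequency to separate species
  bands, coarse in bandwidth/duration which jitter most — with
  emission floor 0.1 so one degraded note dents a window's score
  instead of vetoing it.
- decision threshold: lower decile of normalised training scores,
  extended by a one-degraded-note allowance, minus one standard
  deviation (see ``train_model``).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .evaluate import ConfusionCounts, Percent, accuracy, confusion, precision
from .hmm import SpeciesModel, detect, train_model
from .roi import find_rois, rois_to_frame
from .spectrogram import compute_spectrogram
from .synth import (CallGrammar, SceneSpec, build_scene, iter_rendered_clips,
                    select_call_rois, two_species_grammars)

__all__ = ["SpeciesResult", "ExperimentResult", "collect_training_examples",
           "curate_examples", "train_from_scene", "evaluate_on_scene",
           "two_species_experiment"]

MIN_CELLS = 8
ROI_FACTOR = 2.0


@dataclass
class SpeciesResult:
    species: str
    counts: ConfusionCounts
    accuracy: Percent
    precision: Percent


@dataclass
class ExperimentResult:
    models: dict[str, SpeciesModel]
    per_species: dict[str, SpeciesResult]
    detections: pd.DataFrame
    truth: pd.DataFrame


def _roi_frame(clip, min_cells: int = MIN_CELLS,
               factor: float = ROI_FACTOR) -> pd.DataFrame:
    spec = compute_spectrogram(clip)
    rois = find_rois(spec, factor=factor, min_cells=min_cells)
    return rois_to_frame(rois, spec, recording_id=clip.recording_id)


def collect_training_examples(
    scene: SceneSpec,
    min_cells: int = MIN_CELLS,
    min_notes_missing: int = 1,
) -> dict[str, list[pd.DataFrame]]:
    """Expert-style training data from a scene with known call placement.

    For every planted call, one ROI per note is selected from the
    detected ROI table; examples missing more than ``min_notes_missing``
    notes (e.g. a call largely destroyed by a transient) are discarded,
    as an expert would discard an unusable example.
    """
    examples: dict[str, list[pd.DataFrame]] = {sp: [] for sp in scene.grammars}
    for plan, clip in iter_rendered_clips(scene):
        frame = _roi_frame(clip, min_cells)
        for call in plan.calls:
            grammar = scene.grammars[call.species]
            ex = select_call_rois(frame, call.onset_s, grammar)
            if len(ex) >= grammar.n_notes - min_notes_missing and len(ex) >= 1:
                examples[call.species].append(ex)
    return examples


def curate_examples(
    examples: list[pd.DataFrame],
    k: float = 5.0,
) -> list[pd.DataFrame]:
    """Drop training examples containing outlier features.

    Occasionally a note's bounding box is wrecked by an attached noise
    cluster or transient (e.g. its minimum frequency drops by a couple
    of kilohertz); an expert reviewing training picks would discard
    such an example.  An example is dropped when any of its
    (min_freq_hz, bandwidth_hz, duration_s) values falls outside
    median +- ``k`` * MAD of the pooled training values for that
    feature.  At least half the examples are always kept.
    """
    import numpy as np

    if len(examples) < 4:
        return examples
    pooled = pd.concat(examples, ignore_index=True)
    stats = {}
    for feat in ("min_freq_hz", "bandwidth_hz", "duration_s"):
        v = pooled[feat].to_numpy(float)
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        stats[feat] = (med, max(mad, 1e-3 * max(abs(med), 1.0)))
    # robust z of an example = worst feature deviation of any of its ROIs
    zs = []
    for ex in examples:
        z = max(np.max(np.abs(ex[f].to_numpy(float) - med)) / mad
                for f, (med, mad) in stats.items())
        zs.append(z)
    zs = np.asarray(zs)
    order = np.argsort(zs, kind="stable")
    keep_n = max(int(np.sum(zs <= k)), (len(examples) + 1) // 2)
    return [examples[i] for i in sorted(order[:keep_n])]


def train_from_scene(
    scene: SceneSpec,
    bins_per_feature=(6, 2, 2),
    filter_margin: float = 0.25,
    emission_floor: float = 0.1,
    intensity_floor_factor: float = 0.5,
    threshold_sds: float = 1.0,
    min_cells: int = MIN_CELLS,
) -> dict[str, SpeciesModel]:
    """Train one model per species of ``scene`` from its planted calls."""
    import numpy as np

    examples = collect_training_examples(scene, min_cells)
    models: dict[str, SpeciesModel] = {}
    for sp, grammar in scene.grammars.items():
        if not examples[sp]:
            raise ValueError(f"no usable training examples for {sp!r}")
        # candidate ranges from the FULL training pool (wide, tolerant of
        # bounding-box jitter); emissions and threshold from the curated
        # examples (clean symbol statistics)
        pooled = pd.concat(examples[sp], ignore_index=True)
        filt = {}
        for feat in ("min_freq_hz", "bandwidth_hz", "duration_s"):
            v = pooled[feat].to_numpy(float)
            lo, hi = float(v.min()), float(v.max())
            pad = filter_margin * max(hi - lo, 1e-9)
            filt[feat] = (lo - pad, hi + pad)
        filt["max_intensity"] = (
            intensity_floor_factor * float(pooled["max_intensity"].min()),
            np.inf)
        models[sp] = train_model(
            curate_examples(examples[sp]),
            n_states=grammar.n_notes,
            species=sp,
            bins_per_feature=bins_per_feature,
            emission_floor=emission_floor,
            candidate_filter=filt,
            threshold_sds=threshold_sds,
        )
    return models


def evaluate_on_scene(
    models: dict[str, SpeciesModel],
    scene: SceneSpec,
    min_cells: int = MIN_CELLS,
) -> ExperimentResult:
    """Apply models to every clip of ``scene``; score vs planted truth."""
    truth: dict[str, dict[str, bool]] = {sp: {} for sp in models}
    calls: dict[str, dict[str, bool]] = {sp: {} for sp in models}
    det_rows, truth_rows = [], []
    for plan, clip in iter_rendered_clips(scene):
        frame = _roi_frame(clip, min_cells)
        present = {c.species for c in plan.calls}
        for sp, model in models.items():
            rec = detect(model, frame, recording_id=plan.recording_id,
                         timestamp=plan.timestamp)
            truth[sp][plan.recording_id] = sp in present
            calls[sp][plan.recording_id] = rec.present
            det_rows.append({"recording_id": plan.recording_id,
                             "timestamp": plan.timestamp.isoformat(),
                             "species": sp, "score": rec.score,
                             "present": int(rec.present)})
            truth_rows.append({"recording_id": plan.recording_id,
                               "species": sp,
                               "present": int(sp in present)})
    per_species = {}
    for sp in models:
        c = confusion(truth[sp], calls[sp])
        per_species[sp] = SpeciesResult(sp, c, accuracy(c), precision(c))
    return ExperimentResult(models=models, per_species=per_species,
                            detections=pd.DataFrame(det_rows),
                            truth=pd.DataFrame(truth_rows))


def two_species_experiment(
    seed: int,
    n_train_clips: int = 30,
    n_eval_clips: int = 200,
    clip_duration_s: float = 10.0,
    grammars: dict[str, CallGrammar] | None = None,
) -> ExperimentResult:
    """The standing two-species benchmark (see module docstring).

    Training and evaluation corpora use disjoint seed streams derived
    from ``seed``; species are independently present in half the
    evaluation clips.
    """
    grammars = grammars or two_species_grammars()
    train_scene = build_scene(grammars, n_clips=n_train_clips,
                              seed=seed * 2 + 1, presence_prob=0.8,
                              clip_duration_s=clip_duration_s)
    eval_scene = build_scene(grammars, n_clips=n_eval_clips,
                             seed=seed * 2 + 2, presence_prob=0.5,
                             clip_duration_s=clip_duration_s)
    models = train_from_scene(train_scene)
    return evaluate_on_scene(models, eval_scene)
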