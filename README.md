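# roihmm

Spectrogram region-of-interest (ROI) detection and trainable
hidden-Markov species-vocalization models for passive acoustic
monitoring.

Unattended recording stations produce enormous audio archives — a
station recording 1 min of audio every 10 min collects 144 clips per
day, over 50,000 per year.  Ecologists need per-recording
presence/absence calls for focal species to turn that archive into
activity patterns and population trends.  `roihmm` implements the full
analysis chain as a tested Python library with a thin CLI:

1. **Spectrogram** — each recording (stereo collapsed to mono, PCM
   rescaled to [-1, 1]) is framed with a 512-sample Hann window at hop
   256 and transformed; at 44,100 samples/s each cell spans 86 Hz by
   5.8 ms.
2. **ROI detection** — per frequency band *b* the background level is
   the mean magnitude of that row; cells with
   `M[b,t] > factor * mean_t M[b,t]` (default factor 1.10, "10% above
   the mean") are kept as sparse acoustic events and grown into
   connected neighbourhoods by depth-first search (8-connectivity by
   default).  Each ROI is summarised by minimum/maximum frequency,
   bandwidth, duration, and maximum intensity.
3. **Species models** — a vocalization is a left-to-right discrete HMM
   λ = (A, B, π) over symbols obtained by quantizing each candidate
   ROI's (min frequency, bandwidth, duration).  Initial probabilities
   come from uniformly aligning user-selected example ROI series
   (e.g. *two chirps followed by a shrill*) across the states;
   Baum–Welch then re-estimates A′, B′, π′.  A recording is scored by
   the best length-normalised forward log-likelihood
   `max_w log P(O_w | λ) / |w|` over admissible candidate-ROI windows,
   and called present above a decision threshold derived from the
   training scores.
4. **Validation** — detections vs expert annotations yield the
   confusion matrix and `precision = TP/(TP+FP)`,
   `accuracy = (TP+TN)/total`, printed as integer percents.
5. **Activity** — presence calls aggregate into detection frequency
   (positive recordings / total recordings) by hour of day or calendar
   month, in site-local time.
6. **Synthetic soundscapes** — a deterministic generator plants
   multi-note tonal calls into noise (white + 1/f) with broadband
   transient bursts, emitting WAVs and ground-truth tables, so the
   entire pipeline is testable without field data.

## Worked example

```python
from roihmm import build_scene, two_species_grammars
from roihmm.benchmark import train_from_scene, evaluate_on_scene

grammars = two_species_grammars()          # "whistler" and "croaker"
train = build_scene(grammars, n_clips=30, seed=3, presence_prob=0.8,
                    clip_duration_s=10.0)
models = train_from_scene(train)           # expert-style note selection
test = build_scene(grammars, n_clips=60, seed=4, presence_prob=0.5,
                   clip_duration_s=10.0)
result = evaluate_on_scene(models, test)
for sp, r in result.per_species.items():
    print(sp, r.counts, "accuracy", r.accuracy.rounded,
          "precision", r.precision.rounded)
```

prints

```
whistler ConfusionCounts(tp=31, fp=0, tn=27, fn=2) accuracy 97 precision 100
croaker ConfusionCounts(tp=33, fp=0, tn=26, fn=1) accuracy 98 precision 100
```

i.e. on 60 unseen 10-s clips the trained whistler model recovered 31 of
33 planted calls with no false alarms (97% accuracy, 100% precision);
the croaker model missed 1 of 34.  Misses are clips where a broadband
transient or an attached noise cluster wrecked a note's bounding box.
The `examples/` directory holds one short narrative script per
capability (spectrogram/ROIs, training and detection, validation
statistics, activity patterns, corpus synthesis).

## Command line

```sh
roihmm spectrogram clip.wav --png spec.png
roihmm rois clip.wav --factor 1.10 --out rois.csv
roihmm train --rois rois.csv --labels labels.csv --states 3 --out model.json
roihmm detect --model model.json --rois rois.csv --out detections.csv
roihmm validate --detections detections.csv --truth validation.csv --out report.csv
roihmm activity --detections detections.csv --by hour --tz America/Puerto_Rico
roihmm synth --spec scene.yaml --out corpus/
roihmm batch corpus/ --model model.json --out detections.csv
```

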