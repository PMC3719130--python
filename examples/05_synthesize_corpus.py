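"""Render a labelled synthetic corpus to disk.

Writes WAV clips on a fixed recording schedule plus the truth tables the
rest of the pipeline consumes: a recordings manifest, per-recording
species presence (validation format), and call-level onset/frequency
truth.  The same seed always renders byte-identical files.
"""

import tempfile
from pathlib import Path

import pandas as pd

from roihmm import build_scene, render_scene, two_species_grammars

out = Path(tempfile.mkdtemp(prefix="roihmm_corpus_"))
grammars = two_species_grammars()
scene = build_scene(grammars, n_clips=6, seed=42, presence_prob=0.5,
                    clip_duration_s=10.0)
paths = render_scene(scene, out)

print(f"rendered {len(scene.clips)} clips to {out}")
print("presence truth:")
print(pd.read_csv(paths["presence"]).to_string(index=False))
print("planted calls:")
print(pd.read_csv(paths["calls"]).round(2).to_string(index=False))
# Each clip is 10 s of background noise (white + low-frequency rumble)
# with occasional broadband transients; 'present' rows say which species
# actually call in each clip, and calls.csv gives their onsets and bands.
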