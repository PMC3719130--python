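"""Deterministic synthetic soundscapes with ground truth.

Field recordings cannot ship with a library, so every stage is
exercised on synthetic corpora that emulate the salient structure of a
tropical soundscape: tonal multi-note species calls (each species a
:class:`CallGrammar` of notes with centre frequency, optional linear
sweep, duration and gaps), background noise (white Gaussian plus a
1/f-weighted low-frequency component, the generic rumble of wind and
habitat), and occasional broadband transient bursts standing in for
rain, wind gusts and thunder — the classic sources of false positives.
A :class:`SceneSpec` fixes a recording schedule (canonically 1-min
clips every 10 min, 144 per day), which species call in which clip and
when, and a mandatory seed: the same spec renders a byte-identical
corpus every time.

Per-call SNR is defined as the peak call magnitude over the RMS noise
magnitude within the call's frequency band (see :func:`call_band_snr_db`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
import yaml

from .audio import AudioClip, write_wav
from .spectrogram import compute_spectrogram

__all__ = [
    "Note", "CallGrammar", "PlantedCall", "ClipPlan", "NoiseModel",
    "SceneSpec", "render_call", "render_clip", "render_scene",
    "iter_rendered_clips", "build_scene", "two_species_grammars",
    "call_band_snr_db", "select_call_rois", "load_scene_yaml",
    "save_scene_yaml",
]

_FADE_S = 0.005  # raised-cosine edge fade applied to every note


@dataclass
class Note:
    """One tonal element: a pure tone or linear sweep."""

    freq_hz: float
    duration_s: float
    amplitude: float = 0.3
    sweep_hz_per_s: float = 0.0
    gap_s: float = 0.05  # silence after the note

    @property
    def end_freq_hz(self) -> float:
        return self.freq_hz + self.sweep_hz_per_s * self.duration_s


@dataclass
class CallGrammar:
    """An ordered series of notes, optionally repeated, for one species."""

    species: str
    notes: list[Note]
    repeats: int = 1

    def __post_init__(self) -> None:
        if not self.notes:
            raise ValueError("a call grammar needs at least one note")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        for n in self.notes:
            if n.duration_s <= 0:
                raise ValueError("note durations must be positive")

    @property
    def duration_s(self) -> float:
        per = sum(n.duration_s + n.gap_s for n in self.notes)
        return per * self.repeats

    @property
    def n_notes(self) -> int:
        return len(self.notes) * self.repeats

    def freq_bounds_hz(self) -> tuple[float, float]:
        los = [min(n.freq_hz, n.end_freq_hz) for n in self.notes]
        his = [max(n.freq_hz, n.end_freq_hz) for n in self.notes]
        return min(los), max(his)

    def note_boxes(self) -> list[tuple[float, float, float, float]]:
        """Per rendered note: (t_start, t_end, f_lo, f_hi) relative to call onset."""
        boxes = []
        t = 0.0
        for _ in range(self.repeats):
            for n in self.notes:
                lo = min(n.freq_hz, n.end_freq_hz)
                hi = max(n.freq_hz, n.end_freq_hz)
                boxes.append((t, t + n.duration_s, lo, hi))
                t += n.duration_s + n.gap_s
        return boxes


@dataclass
class PlantedCall:
    species: str
    onset_s: float


@dataclass
class ClipPlan:
    recording_id: str
    timestamp: datetime
    calls: list[PlantedCall] = field(default_factory=list)


@dataclass
class NoiseModel:
    """Background noise: white floor plus 1/f-weighted low-frequency rumble."""

    white_rms: float = 0.01
    pink_rms: float = 0.01


@dataclass
class SceneSpec:
    """Full description of a synthetic corpus; ``seed`` is mandatory."""

    grammars: dict[str, CallGrammar]
    clips: list[ClipPlan]
    seed: int
    sample_rate: int = 44100
    clip_duration_s: float = 60.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    transient_rate: float = 0.5       # expected broadband bursts per clip
    transient_amplitude: float = 0.2
    site_id: str = "synth"

    def __post_init__(self) -> None:
        nyquist = self.sample_rate / 2
        for g in self.grammars.values():
            lo, hi = g.freq_bounds_hz()
            if hi >= nyquist:
                raise ValueError(
                    f"grammar {g.species!r} reaches {hi} Hz >= Nyquist {nyquist} Hz")
        for plan in self.clips:
            for call in plan.calls:
                dur = self.grammars[call.species].duration_s
                if call.onset_s < 0 or call.onset_s + dur > self.clip_duration_s:
                    raise ValueError(
                        f"call onset {call.onset_s}s in {plan.recording_id} "
                        "falls outside the clip")


def render_call(grammar: CallGrammar, sample_rate: int) -> np.ndarray:
    """Render a grammar to a waveform: tones, sweeps, gaps, edge fades."""
    nyquist = sample_rate / 2
    lo, hi = grammar.freq_bounds_hz()
    if hi >= nyquist:
        raise ValueError(f"call frequency {hi} Hz >= Nyquist {nyquist} Hz")
    pieces: list[np.ndarray] = []
    for _ in range(grammar.repeats):
        for note in grammar.notes:
            n = int(round(note.duration_s * sample_rate))
            t = np.arange(n) / sample_rate
            inst_freq = note.freq_hz + note.sweep_hz_per_s * t
            phase = 2 * np.pi * np.cumsum(inst_freq) / sample_rate
            tone = note.amplitude * np.sin(phase)
            nf = min(int(round(_FADE_S * sample_rate)), n // 2)
            if nf > 0:
                ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nf) / nf))
                tone[:nf] *= ramp
                tone[-nf:] *= ramp[::-1]
            pieces.append(tone)
            pieces.append(np.zeros(int(round(note.gap_s * sample_rate))))
    return np.concatenate(pieces)


def _noise(n: int, model: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(n)
    if model.white_rms > 0:
        out += rng.normal(0.0, model.white_rms, n)
    if model.pink_rms > 0:
        # shape white noise by 1/sqrt(f) in the frequency domain
        white = rng.normal(0.0, 1.0, n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n)
        weight = np.zeros_like(f)
        weight[1:] = 1.0 / np.sqrt(f[1:])
        pink = np.fft.irfft(spec * weight, n)
        rms = np.sqrt(np.mean(pink ** 2))
        if rms > 0:
            out += pink * (model.pink_rms / rms)
    return out


def _transients(n: int, sample_rate: int, rate: float, amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """Broadband noise bursts (rain / wind / thunder surrogates)."""
    out = np.zeros(n)
    for _ in range(rng.poisson(rate)):
        dur = rng.uniform(0.05, 0.3)
        nb = int(dur * sample_rate)
        start = rng.integers(0, max(n - nb, 1))
        envelope = np.hanning(nb)
        out[start:start + nb] += amplitude * envelope * rng.normal(0.0, 1.0, nb)
    return out


def _clip_rng(spec: SceneSpec, clip_index: int) -> np.random.Generator:
    # per-clip stream independent of render order
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(clip_index,)))


def render_clip(spec: SceneSpec, clip_index: int) -> np.ndarray:
    """Render one scheduled clip (noise + transients + planted calls)."""
    plan = spec.clips[clip_index]
    n = int(round(spec.clip_duration_s * spec.sample_rate))
    rng = _clip_rng(spec, clip_index)
    samples = _noise(n, spec.noise, rng)
    samples += _transients(n, spec.sample_rate, spec.transient_rate,
                           spec.transient_amplitude, rng)
    for call in plan.calls:
        wave = render_call(spec.grammars[call.species], spec.sample_rate)
        start = int(round(call.onset_s * spec.sample_rate))
        samples[start:start + wave.size] += wave[:max(n - start, 0)]
    return np.clip(samples, -1.0, 1.0)


def iter_rendered_clips(spec: SceneSpec):
    """Yield (plan, AudioClip) pairs without touching the filesystem."""
    for i, plan in enumerate(spec.clips):
        samples = render_clip(spec, i)
        yield plan, AudioClip(samples, spec.sample_rate,
                              start_time=plan.timestamp,
                              site_id=spec.site_id,
                              recording_id=plan.recording_id)


def render_scene(spec: SceneSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the corpus: WAV per clip plus manifest and truth tables.

    Outputs in ``out_dir``:

    - one 16-bit PCM WAV per scheduled clip,
    - ``recordings.csv`` — recording_id, path, timestamp (ISO 8601),
    - ``presence.csv`` — per-recording species presence in the
      validation format (recording_id, species, present),
    - ``calls.csv`` — call-level truth: onset, duration and frequency
      bounds of every planted call.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, presence, calls = [], [], []
    species_list = sorted(spec.grammars)
    for plan, clip in iter_rendered_clips(spec):
        wav_path = out_dir / f"{plan.recording_id}.wav"
        write_wav(wav_path, clip.samples, spec.sample_rate)
        manifest.append({"recording_id": plan.recording_id,
                         "path": wav_path.name,
                         "timestamp": plan.timestamp.isoformat()})
        present_here = {c.species for c in plan.calls}
        for sp in species_list:
            presence.append({"recording_id": plan.recording_id,
                             "species": sp,
                             "present": int(sp in present_here)})
        for c in plan.calls:
            g = spec.grammars[c.species]
            lo, hi = g.freq_bounds_hz()
            calls.append({"recording_id": plan.recording_id,
                          "species": c.species, "onset_s": c.onset_s,
                          "duration_s": g.duration_s,
                          "min_freq_hz": lo, "max_freq_hz": hi})
    paths = {"recordings": out_dir / "recordings.csv",
             "presence": out_dir / "presence.csv",
             "calls": out_dir / "calls.csv"}
    pd.DataFrame(manifest).to_csv(paths["recordings"], index=False)
    pd.DataFrame(presence).to_csv(paths["presence"], index=False)
    pd.DataFrame(calls, columns=["recording_id", "species", "onset_s",
                                 "duration_s", "min_freq_hz", "max_freq_hz"]
                 ).to_csv(paths["calls"], index=False)
    return paths


def two_species_grammars() -> dict[str, CallGrammar]:
    """Two stock species with disjoint bands and distinct note grammars.

    ``whistler``: a high-low-high triplet of tonal whistles around
    3-3.6 kHz.  ``croaker``: four descending tones, 1.2 kHz down to
    0.9 kHz.
    """
    whistler = CallGrammar("whistler", [
        Note(3600.0, 0.15, 0.3, 0.0, 0.15),
        Note(3000.0, 0.15, 0.3, 0.0, 0.15),
        Note(3600.0, 0.15, 0.3, 0.0, 0.15),
    ])
    croaker = CallGrammar("croaker", [
        Note(1200.0, 0.12, 0.3, 0.0, 0.15),
        Note(1100.0, 0.12, 0.3, 0.0, 0.15),
        Note(1000.0, 0.12, 0.3, 0.0, 0.15),
        Note(900.0, 0.12, 0.3, 0.0, 0.15),
    ])
    return {"whistler": whistler, "croaker": croaker}


def build_scene(
    grammars: dict[str, CallGrammar],
    n_clips: int,
    seed: int,
    presence_prob: float = 0.5,
    clip_duration_s: float = 60.0,
    period_s: float = 600.0,
    start: datetime | None = None,
    sample_rate: int = 44100,
    noise: NoiseModel | None = None,
    transient_rate: float = 0.5,
    site_id: str = "synth",
) -> SceneSpec:
    """Random scene on a fixed schedule: each species independently
    present in each clip with ``presence_prob``, one call at a random
    admissible onset.  Fully determined by ``seed``."""
    if start is None:
        start = datetime(2021, 3, 1, 0, 0, tzinfo=ZoneInfo("America/Puerto_Rico"))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(1,)))
    clips: list[ClipPlan] = []
    for i in range(n_clips):
        ts = start + timedelta(seconds=i * period_s)
        rec_id = f"{site_id}_{ts.strftime('%Y%m%d-%H%M%S')}"
        plan = ClipPlan(rec_id, ts)
        for sp in sorted(grammars):
            if rng.random() < presence_prob:
                dur = grammars[sp].duration_s
                margin = 0.25
                hi = clip_duration_s - dur - margin
                onset = float(rng.uniform(margin, hi))
                plan.calls.append(PlantedCall(sp, onset))
        clips.append(plan)
    return SceneSpec(grammars=grammars, clips=clips, seed=seed,
                     sample_rate=sample_rate, clip_duration_s=clip_duration_s,
                     noise=noise or NoiseModel(),
                     transient_rate=transient_rate, site_id=site_id)


def call_band_snr_db(grammar: CallGrammar, spec: SceneSpec) -> float:
    """Per-call SNR: peak call magnitude over RMS noise magnitude in the
    call's frequency band, in dB, measured on spectrograms of the call
    and the noise rendered separately."""
    sr = spec.sample_rate
    wave = render_call(grammar, sr)
    pad = np.zeros(512)
    call_clip = AudioClip(np.concatenate([pad, wave, pad]), sr)
    call_spec = compute_spectrogram(call_clip)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed,
                                                       spawn_key=(2,)))
    noise = _noise(sr * 2, spec.noise, rng)
    noise_spec = compute_spectrogram(AudioClip(noise, sr))
    lo, hi = grammar.freq_bounds_hz()
    b_lo = int(lo / call_spec.bin_width_hz)
    b_hi = int(np.ceil(hi / call_spec.bin_width_hz)) + 1
    peak = call_spec.magnitude[b_lo:b_hi].max()
    noise_rms = np.sqrt(np.mean(noise_spec.magnitude[b_lo:b_hi] ** 2))
    return 20.0 * np.log10(peak / noise_rms)


def select_call_rois(
    roi_frame: pd.DataFrame,
    onset_s: float,
    grammar: CallGrammar,
    freq_margin_hz: float = 100.0,
    time_margin_s: float = 0.05,
) -> pd.DataFrame:
    """Pick the ROIs of one planted call from a recording's ROI table.

    Emulates the expert clicking the ROI of each note of a known
    vocalization when building training data: for every note of the
    grammar, among the ROIs overlapping that note's time span and
    frequency band (small margins), the brightest (highest
    max_intensity) is selected.  Duplicates — notes bridged into one ROI
    by intervening noise — are kept once.  Result is in time order.
    """
    t_end = roi_frame["t_end_s"].to_numpy()
    t_start = roi_frame["t_start_s"].to_numpy()
    f_hi = roi_frame["max_freq_hz"].to_numpy()
    f_lo = roi_frame["min_freq_hz"].to_numpy()
    intensity = roi_frame["max_intensity"].to_numpy()
    picked: list[int] = []
    for (nt0, nt1, nf_lo, nf_hi) in grammar.note_boxes():
        box_t0 = onset_s + nt0 - time_margin_s
        box_t1 = onset_s + nt1 + time_margin_s
        overlap = ((t_end > box_t0) & (t_start < box_t1)
                   & (f_hi > nf_lo - freq_margin_hz)
                   & (f_lo < nf_hi + freq_margin_hz))
        idx = np.flatnonzero(overlap)
        if idx.size == 0:
            continue
        best = idx[np.argmax(intensity[idx])]
        if best not in picked:
            picked.append(best)
    sel = roi_frame.iloc[picked]
    return sel.sort_values(["t_start_s", "min_freq_hz"], kind="stable")


# -- YAML round trip for scene specs -------------------------------------

def save_scene_yaml(spec: SceneSpec, path: str | Path) -> None:
    doc = {
        "seed": spec.seed,
        "sample_rate": spec.sample_rate,
        "clip_duration_s": spec.clip_duration_s,
        "site_id": spec.site_id,
        "transient_rate": spec.transient_rate,
        "transient_amplitude": spec.transient_amplitude,
        "noise": asdict(spec.noise),
        "grammars": {
            name: {"repeats": g.repeats,
                   "notes": [asdict(n) for n in g.notes]}
            for name, g in spec.grammars.items()
        },
        "clips": [
            {"recording_id": p.recording_id,
             "timestamp": p.timestamp.isoformat(),
             "calls": [{"species": c.species, "onset_s": c.onset_s}
                       for c in p.calls]}
            for p in spec.clips
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scene_yaml(path: str | Path) -> SceneSpec:
    doc = yaml.safe_load(Path(path).read_text())
    grammars = {
        name: CallGrammar(name, [Note(**n) for n in g["notes"]],
                          repeats=g.get("repeats", 1))
        for name, g in doc["grammars"].items()
    }
    clips = [
        ClipPlan(p["recording_id"], datetime.fromisoformat(p["timestamp"]),
                 [PlantedCall(c["species"], float(c["onset_s"]))
                  for c in p.get("calls", [])])
        for p in doc["clips"]
    ]
    return SceneSpec(
        grammars=grammars, clips=clips, seed=int(doc["seed"]),
        sample_rate=int(doc.get("sample_rate", 44100)),
        clip_duration_s=float(doc.get("clip_duration_s", 60.0)),
        noise=NoiseModel(**doc.get("noise", {})),
        transient_rate=float(doc.get("transient_rate", 0.5)),
        transient_amplitude=float(doc.get("transient_amplitude", 0.2)),
        site_id=doc.get("site_id", "synth"),
    )
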