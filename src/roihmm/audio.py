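"""WAV reading and the in-memory audio clip container.

Recordings from unattended monitoring stations arrive as RIFF PCM WAV
files (canonically 1-min clips at 44,100 samples/s, but any length and
rate is accepted).  Stereo recordings are collapsed to mono by averaging
the channels sample-wise, and integer PCM is rescaled to the unit
interval so that all downstream magnitude arithmetic is format-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioClip", "AudioReadError", "read_wav", "write_wav"]


class AudioReadError(IOError):
    """Raised when a WAV file cannot be read or decoded."""


#: full-scale divisor per integer sample width (scipy returns 24-bit PCM
#: left-justified in int32, so the int32 divisor applies to it too)
_INT_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


@dataclass
class AudioClip:
    """A mono audio recording with optional provenance metadata.

    ``samples`` are floats in [-1, 1]; ``start_time`` is a time-zone-aware
    timestamp when known (needed only for activity aggregation).
    """

    samples: np.ndarray
    sample_rate: int
    start_time: datetime | None = None
    site_id: str | None = None
    recording_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip samples must be one-dimensional (mono)")
        if self.samples.size == 0:
            raise ValueError("AudioClip samples must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioClip samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def scaled(self, factor: float) -> "AudioClip":
        """Return a copy with samples multiplied by ``factor``."""
        return AudioClip(self.samples * factor, self.sample_rate,
                         self.start_time, self.site_id, self.recording_id)


def read_wav(
    path: str | Path,
    *,
    start_time: datetime | None = None,
    site_id: str | None = None,
    recording_id: str | None = None,
) -> AudioClip:
    """Read a PCM or float WAV file into a mono :class:`AudioClip`.

    Multi-channel audio is averaged across channels.  Integer PCM is
    scaled by its full-scale value (e.g. a full-scale positive 16-bit
    sample becomes 32767/32768); unsigned 8-bit is first re-centred.

    Raises
    ------
    AudioReadError
        If the file is missing, unreadable, or not a supported encoding.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError as exc:
        raise AudioReadError(f"audio file not found: {path}") from exc
    except Exception as exc:  # wavfile raises bare ValueError on bad RIFF
        raise AudioReadError(f"cannot read WAV file {path}: {exc}") from exc

    if data.size == 0:
        raise AudioReadError(f"WAV file contains no samples: {path}")

    samples = np.asarray(data)
    if samples.dtype == np.uint8:
        samples = (samples.astype(np.float64) - 128.0) / 128.0
    elif samples.dtype in _INT_SCALE:
        samples = samples.astype(np.float64) / _INT_SCALE[samples.dtype]
    elif np.issubdtype(samples.dtype, np.floating):
        samples = samples.astype(np.float64)
    else:
        raise AudioReadError(
            f"unsupported WAV sample format {samples.dtype} in {path}")

    if samples.ndim == 2:  # stereo (or more) -> mono by channel mean
        samples = samples.mean(axis=1)

    rec_id = recording_id if recording_id is not None else path.stem
    return AudioClip(samples, int(rate), start_time=start_time,
                     site_id=site_id, recording_id=rec_id)


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int) -> None:
    """Write mono float samples in [-1, 1] as 16-bit PCM WAV."""
    samples = np.asarray(samples, dtype=np.float64)
    quantized = np.clip(np.round(samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(sample_rate), quantized)
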