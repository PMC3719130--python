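"""Short-time Fourier transform of a recording into a frequency-time matrix.

Each recording is framed with a periodic Hann window (default 512
samples, hop 256, i.e. 50% overlap) and transformed; the linear
magnitude of the non-negative-frequency bins is kept.  At the canonical
44,100 samples/s this gives cells of 44100/512 = 86.13 Hz by
256/44100 = 5.8 ms.  Linear magnitude (not power or dB) is the default
cell value because the downstream region-of-interest threshold is
multiplicative ("10% above the band mean"), which is only well-posed on
a non-negative linear scale; a power scale is available via ``scale``.

Trailing samples that do not fill a complete window are dropped (no
zero-padding), so the number of frames is
``floor((n_samples - window_size) / hop) + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann

from .audio import AudioClip

__all__ = ["Spectrogram", "compute_spectrogram"]


@dataclass
class Spectrogram:
    """Non-negative magnitude matrix ``[n_bins x n_frames]`` with geometry.

    Row ``b`` covers frequencies around ``b * bin_width_hz``; column ``t``
    starts at ``t * hop_s`` seconds from the start of the recording.
    """

    magnitude: np.ndarray
    sample_rate: int
    window_size: int
    hop: int

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        if self.magnitude.ndim != 2:
            raise ValueError("magnitude must be a 2-D [n_bins x n_frames] matrix")
        if self.magnitude.shape[0] != self.window_size // 2 + 1:
            raise ValueError(
                f"expected {self.window_size // 2 + 1} frequency rows for a "
                f"{self.window_size}-sample window, got {self.magnitude.shape[0]}")
        if np.any(self.magnitude < 0) or not np.all(np.isfinite(self.magnitude)):
            raise ValueError("magnitudes must be finite and non-negative")

    @property
    def n_bins(self) -> int:
        return self.magnitude.shape[0]

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[1]

    @property
    def bin_width_hz(self) -> float:
        """Hz per frequency row (sample_rate / window_size)."""
        return self.sample_rate / self.window_size

    @property
    def hop_s(self) -> float:
        """Seconds per time column (hop / sample_rate)."""
        return self.hop / self.sample_rate

    @property
    def bin_freqs_hz(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width_hz

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.hop_s

    def to_csv(self, path: str | Path) -> None:
        """Dump the dense matrix, one frequency row per line, columns = frames."""
        np.savetxt(str(path), self.magnitude, delimiter=",", fmt="%.8g")

    def to_png(self, path: str | Path) -> None:
        """Render an inspection image (log-compressed, dark = quiet)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 4))
        ax.imshow(np.log1p(self.magnitude), origin="lower", aspect="auto",
                  extent=(0.0, self.n_frames * self.hop_s,
                          0.0, self.n_bins * self.bin_width_hz),
                  cmap="magma")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        fig.tight_layout()
        fig.savefig(str(path), dpi=100)
        plt.close(fig)


def compute_spectrogram(
    clip: AudioClip,
    window_size: int = 512,
    hop: int = 256,
    scale: str = "magnitude",
) -> Spectrogram:
    """Compute the framed, Hann-windowed magnitude spectrogram of ``clip``.

    Parameters
    ----------
    clip : AudioClip
        Mono audio; must contain at least ``window_size`` samples.
    window_size, hop : int
        Frame length and stride in samples.
    scale : {"magnitude", "power"}
        Cell value: linear magnitude (default) or squared magnitude.

    Raises
    ------
    ValueError
        If the clip is shorter than one window or parameters are invalid.
    """
    if window_size < 2:
        raise ValueError(f"window_size must be >= 2, got {window_size}")
    if hop < 1:
        raise ValueError(f"hop must be >= 1, got {hop}")
    if scale not in ("magnitude", "power"):
        raise ValueError(f"scale must be 'magnitude' or 'power', got {scale!r}")
    n = clip.samples.size
    if n < window_size:
        raise ValueError(
            f"clip has {n} samples, shorter than one {window_size}-sample window")

    window = hann(window_size, sym=False)  # periodic Hann, standard for STFT
    frames = sliding_window_view(clip.samples, window_size)[::hop]
    spectrum = np.fft.rfft(frames * window, axis=1)
    mag = np.abs(spectrum).T  # -> [n_bins x n_frames]
    if scale == "power":
        mag = mag ** 2
    return Spectrogram(mag, sample_rate=clip.sample_rate,
                       window_size=window_size, hop=hop)
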