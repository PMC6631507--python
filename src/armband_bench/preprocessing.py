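"""Signal-to-example transforms: high-pass filtering, windowing, spectrograms.

The latency budget is 250 ms, so raw examples are 250 ms windows
(8×50 at 200 sps, 10×250 at 1000 sps).  Spectrogram examples are built per
channel with 100 ms Hann windows and 50 ms overlap and arranged as
time-frames × channels × frequency-bins (4×8×11 and 4×10×51 for the two
built-in profiles).  Filtering is causal single-pass: the pipeline is meant
to be implementable in real time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.signal.windows import hann

__all__ = [
    "StftConfig",
    "WindowExample",
    "WindowingConfig",
    "butterworth_highpass",
    "extract_windows",
    "spectrogram_tensor",
]


@dataclass(frozen=True)
class WindowingConfig:
    window_ms: float = 250.0
    stride_ms: float = 250.0
    label_rule: str = "majority"  # or "center"

    def __post_init__(self) -> None:
        if self.window_ms > 250.0 + 1e-9:
            raise ValueError("window exceeds the 250 ms latency budget")
        if self.stride_ms <= 0:
            raise ValueError("stride must be positive")
        if self.label_rule not in ("majority", "center"):
            raise ValueError("label_rule must be 'majority' or 'center'")


@dataclass(frozen=True)
class StftConfig:
    win_ms: float = 100.0
    overlap_ms: float = 50.0
    log_compress: bool = False  # magnitude by default

    def __post_init__(self) -> None:
        if self.overlap_ms >= self.win_ms:
            raise ValueError("overlap must be smaller than the STFT window")


@dataclass
class WindowExample:
    """One labeled example in one of three modalities.

    payload shapes: raw — (channels, samples); spectrogram —
    (frames, channels, bins); htd — (4 * channels,).
    """

    modality: str
    payload: np.ndarray
    label: int
    rate: float


def butterworth_highpass(x: np.ndarray, rate: float, order: int = 4,
                         cutoff_hz: float = 20.0) -> np.ndarray:
    """Causal 4th-order Butterworth high-pass (−3 dB at the cutoff)."""
    if cutoff_hz >= rate / 2:
        raise ValueError("cutoff must be below Nyquist")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=rate, output="sos")
    return signal.sosfilt(sos, np.asarray(x, dtype=float), axis=-1)


def _segments(labels: np.ndarray):
    """Yield (label, start, stop) for contiguous label runs."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [labels.size]])
    for a, b in zip(starts, stops):
        yield int(labels[a]), int(a), int(b)


def extract_windows(samples: np.ndarray, labels: np.ndarray, rate: float,
                    config: WindowingConfig = WindowingConfig()) -> list[WindowExample]:
    """Slice a cycle into fixed-length raw windows.

    Windows are cut inside contiguous label segments (ramp-up samples carry
    the gesture's label, so they are part of the segment); per segment of
    length L the count is floor((L − W)/S) + 1.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError("samples must be a nonempty (channels, time) array")
    w = int(round(config.window_ms * rate / 1000.0))
    s = int(round(config.stride_ms * rate / 1000.0))
    if x.shape[1] < w:
        raise ValueError("cycle shorter than one window")
    out: list[WindowExample] = []
    for lab, a, b in _segments(labels):
        n = (b - a - w) // s + 1
        for i in range(max(n, 0)):
            start = a + i * s
            win = x[:, start:start + w]
            if config.label_rule == "center":
                lab_i = int(labels[start + w // 2])
            else:
                vals, cnt = np.unique(labels[start:start + w], return_counts=True)
                lab_i = int(vals[np.argmax(cnt)])
            out.append(WindowExample("raw", win, lab_i, rate))
    return out


def spectrogram_tensor(window, stft: StftConfig = StftConfig(),
                       rate: float | None = None) -> WindowExample:
    """Magnitude STFT of one raw window, as frames × channels × bins.

    Per channel: symmetric Hann window of ``win_ms``, hop of
    ``win_ms − overlap_ms``, magnitude of the one-sided DFT.  Frame count is
    floor((W − win)/hop) + 1; bin count is win_samples//2 + 1.
    """
    if isinstance(window, WindowExample):
        x, rate, label = window.payload, window.rate, window.label
    else:
        if rate is None:
            raise ValueError("rate is required when passing a bare array")
        x, label = np.asarray(window, dtype=float), -1
    nwin = int(round(stft.win_ms * rate / 1000.0))
    hop = nwin - int(round(stft.overlap_ms * rate / 1000.0))
    if nwin > x.shape[1]:
        raise ValueError("STFT window longer than the example")
    w = hann(nwin, sym=True)
    frames = np.lib.stride_tricks.sliding_window_view(x, nwin, axis=1)[:, ::hop, :]
    spec = np.abs(np.fft.rfft(frames * w, axis=-1))     # (ch, frames, bins)
    spec = np.transpose(spec, (1, 0, 2))                # (frames, ch, bins)
    if stft.log_compress:
        spec = np.log1p(spec)
    return WindowExample("spectrogram", spec, label, rate)
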