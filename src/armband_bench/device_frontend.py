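"""Parameterized sEMG acquisition chains.

Renders a master signal through the signal path of one armband: analog
band-limiting (one-pole high-pass and low-pass), oversampled delta-sigma
conversion represented by its decimation filtering and effective
resolution, input-referred noise, and uniform quantization.

Two fidelities are provided:

* ``full`` — the oversampled-domain chain for short validation segments:
  upsample to ``out_rate * osr``, analog one-pole filters, fourth-order CIC
  decimation, passband-droop compensation, noise, quantization.
* ``fast`` — a baseband-equivalent chain at the master rate (FIR emulation
  of the compensated CIC magnitude, polyphase resampling), for session-scale
  simulation.  The two agree on band-limited tones.

The delta-sigma modulator itself is not bit-level simulated: the converter
is characterized by its oversampling ratio, effective number of bits and
input-referred noise, which is exactly what the chain here reproduces.

A note on the CIC corner: a bare fourth-order CIC at R=50 has its −3 dB
point near 0.23×Fdecim, far below the chain's advertised ~460 Hz corner.
Real designs flatten the droop with an inverse-sinc compensation FIR after
decimation; ``acquire`` does the same (see ``cic_compensator``).  The bare
``cic_decimate`` operation remains the textbook sinc^N filter.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from importlib import resources

import numpy as np
from scipy import signal

from .synthetic_semg import MasterSignal

__all__ = [
    "AcquiredRecording",
    "DeviceProfile",
    "acquire",
    "builtin_profile",
    "cic_decimate",
    "cic_frequency_response",
    "cic_compensator",
    "dequantize",
    "quantize",
]

log = logging.getLogger(__name__)

_FULL_FIDELITY_MAX_S = 60.0


# --------------------------------------------------------------------------
# device profile
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DeviceProfile:
    """Acquisition-chain parameters of one armband."""

    name: str
    n_channels: int
    out_rate: int                  # decimated sample rate, sps
    enob: int                      # effective number of bits
    full_scale_pp: float           # peak-to-peak input span, volts
    analog_hp_hz: float = 1.0
    analog_lp_hz: float = 7000.0
    osr: int | None = None         # oversampling ratio (None: no CIC stage)
    cic_order: int = 4
    cic_diff_delay: int = 1
    noise_rms: float = 2.2e-6      # input-referred noise, volts RMS in band
    electrode_angles: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.enob > 16:
            raise ValueError("enob must fit in 16-bit transport")
        if self.full_scale_pp <= 0:
            raise ValueError("full_scale_pp must be positive")
        if self.electrode_angles and len(self.electrode_angles) != self.n_channels:
            raise ValueError("electrode_angles length must equal n_channels")

    @property
    def oversampled_rate(self) -> int | None:
        return None if self.osr is None else self.out_rate * self.osr

    @property
    def step(self) -> float:
        """Quantization step in volts."""
        return self.full_scale_pp / 2**self.enob

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DeviceProfile":
        d = json.loads(text)
        d["electrode_angles"] = tuple(d.get("electrode_angles", ()))
        return cls(**d)


def builtin_profile(name: str, **overrides) -> DeviceProfile:
    """Load a built-in profile ('3dc' or 'myo'); fields can be overridden."""
    try:
        text = resources.files("armband_bench.profiles").joinpath(f"{name}.json").read_text()
    except FileNotFoundError:
        raise ValueError(f"unknown built-in profile {name!r}") from None
    prof = DeviceProfile.from_json(text)
    if overrides:
        d = asdict(prof)
        d.update(overrides)
        d["electrode_angles"] = tuple(d["electrode_angles"])
        prof = DeviceProfile(**d)
    return prof


# --------------------------------------------------------------------------
# CIC decimation
# --------------------------------------------------------------------------

def _cic_kernel(r: int, m: int, n: int) -> np.ndarray:
    """Impulse response of ((1 - z^-RM)/(1 - z^-1))^N, normalized to DC gain 1."""
    h = np.ones(r * m)
    k = h.copy()
    for _ in range(n - 1):
        k = np.convolve(k, h)
    return k / float(r * m) ** n


def cic_decimate(x: np.ndarray, r: int, m: int = 1, n: int = 4,
                 axis: int = -1) -> np.ndarray:
    """Cascaded integrator-comb decimation by ``r``.

    Implements H(z) = ((1 − z^(−RM)) / (1 − z^(−1)))^N followed by
    decimation, realized as the equivalent N-fold boxcar FIR (numerically
    stable and mathematically identical to integrators at the input rate
    plus combs at the output rate).  DC gain is normalized to 1.
    """
    if int(r) != r or r <= 0:
        raise ValueError("decimation ratio R must be a positive integer")
    r, m, n = int(r), int(m), int(n)
    x = np.asarray(x, dtype=float)
    if x.shape[axis] < r:
        raise ValueError("signal shorter than one decimation period")
    h = _cic_kernel(r, m, n)
    shape = [1] * x.ndim
    shape[axis] = h.size
    y = signal.oaconvolve(x, h.reshape(shape), axes=axis)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(0, x.shape[axis], r)  # causal: keep first L samples, take every Rth
    return y[tuple(sl)]


def cic_frequency_response(f_hz, fs_in: float, r: int, m: int = 1, n: int = 4):
    """Normalized CIC magnitude |sin(πfRM/fs) / (RM sin(πf/fs))|^N (1 at DC)."""
    f = np.asarray(f_hz, dtype=float)
    if np.any(f < 0) or np.any(f >= fs_in / 2):
        raise ValueError("frequency must satisfy 0 <= f < fs_in/2")
    rm = r * m
    num = np.sin(np.pi * f * rm / fs_in)
    den = rm * np.sin(np.pi * f / fs_in)
    h = np.ones_like(np.atleast_1d(den))
    nz = np.atleast_1d(den) != 0.0
    h[nz] = np.abs(np.atleast_1d(num)[nz] / np.atleast_1d(den)[nz])
    out = (h ** n).reshape(np.shape(f))
    return float(out) if np.isscalar(f_hz) else out


def cic_compensator(out_rate: int, osr: int, m: int = 1, n: int = 4,
                    numtaps: int = 63, flat_fraction: float = 0.86) -> np.ndarray:
    """Inverse-sinc FIR at the decimated rate flattening the CIC passband.

    Gain 1/|H_cic(f)| up to ``flat_fraction`` of Nyquist, tapering to 0 at
    Nyquist.  Linear phase.
    """
    fs_in = out_rate * osr
    nyq = out_rate / 2.0
    freqs = np.linspace(0.0, nyq, 256)
    hcic = cic_frequency_response(freqs, fs_in, osr, m, n)
    gains = np.where(freqs <= flat_fraction * nyq, 1.0 / np.maximum(hcic, 1e-6), 0.0)
    edge = int(np.searchsorted(freqs, flat_fraction * nyq))
    # smooth taper from the flat edge down to zero at Nyquist
    taper = np.cos(0.5 * np.pi * np.linspace(0, 1, freqs.size - edge))
    gains[edge:] = gains[max(edge - 1, 0)] * taper
    return signal.firwin2(numtaps, freqs / nyq, gains)


# --------------------------------------------------------------------------
# quantization
# --------------------------------------------------------------------------

def quantize(volts: np.ndarray, profile: DeviceProfile) -> np.ndarray:
    """Uniform quantizer to unsigned codes.

    step = full_scale_pp / 2^enob; code = round(v/step) + 2^(enob−1),
    clipped at the rails (clipping is defined behavior and logged).
    0 V maps to the mid-scale code and ``dequantize`` inverts to within
    step/2 everywhere inside the rails.
    """
    v = np.asarray(volts, dtype=float)
    half = 2 ** (profile.enob - 1)
    codes = np.round(v / profile.step).astype(np.int64) + half
    n_clip = int(np.sum((codes < 0) | (codes > 2**profile.enob - 1)))
    if n_clip:
        log.debug("%s: %d samples clipped at the rails", profile.name, n_clip)
    return np.clip(codes, 0, 2**profile.enob - 1).astype(np.uint16)


def dequantize(codes: np.ndarray, profile: DeviceProfile) -> np.ndarray:
    """volts = (codes − mid) × step."""
    half = 2 ** (profile.enob - 1)
    return (np.asarray(codes, dtype=float) - half) * profile.step


# --------------------------------------------------------------------------
# acquisition
# --------------------------------------------------------------------------

@dataclass
class AcquiredRecording:
    """Device-sampled, labeled data as one armband delivers it."""

    codes: np.ndarray            # (channels, time) unsigned integer codes
    rate: int
    labels: np.ndarray           # per-sample gesture id at the device rate
    profile: DeviceProfile
    boundaries: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def volts(self) -> np.ndarray:
        return dequantize(self.codes, self.profile)

    @property
    def duration_s(self) -> float:
        return self.codes.shape[1] / self.rate

    @property
    def n_channels(self) -> int:
        return self.codes.shape[0]


def _one_pole(x: np.ndarray, f_hz: float, fs: float, btype: str) -> np.ndarray:
    if f_hz is None or f_hz <= 0:
        return x
    if f_hz >= fs / 2:
        return x  # corner beyond Nyquist: filter is transparent at this rate
    sos = signal.butter(1, f_hz, btype=btype, fs=fs, output="sos")
    return signal.sosfilt(sos, x, axis=-1)


def _select_channels(master: MasterSignal, profile: DeviceProfile) -> np.ndarray:
    """Map the profile's electrode angles onto master channels (exact match)."""
    if not profile.electrode_angles:
        if master.samples.shape[0] != profile.n_channels:
            raise ValueError("profile without electrode angles needs matching channel count")
        return np.arange(profile.n_channels)
    master_angles = np.asarray(master.channel_angles_deg, dtype=float)
    idx = []
    for a in profile.electrode_angles:
        j = np.argmin(np.abs(((master_angles - a) + 180) % 360 - 180))
        if abs(((master_angles[j] - a) + 180) % 360 - 180) > 1e-6:
            raise ValueError(f"master signal has no channel at electrode angle {a} deg")
        idx.append(int(j))
    return np.asarray(idx)


def _resample_labels(labels: np.ndarray, n_out: int, rate_in: float, rate_out: float) -> np.ndarray:
    idx = np.clip(np.round(np.arange(n_out) * rate_in / rate_out).astype(int), 0, labels.size - 1)
    return labels[idx]


def _fast_chain_fir(profile: DeviceProfile, master_rate: int, numtaps: int = 255) -> np.ndarray:
    """FIR at the master rate emulating the compensated CIC magnitude."""
    osr = profile.osr
    fs_in = profile.out_rate * osr
    comp = cic_compensator(profile.out_rate, osr, profile.cic_diff_delay, profile.cic_order)
    nyq_m = master_rate / 2.0
    freqs = np.linspace(0.0, nyq_m, 512)
    resp = np.zeros_like(freqs)
    inband = freqs < profile.out_rate / 2.0
    hcic = cic_frequency_response(freqs[inband], fs_in, osr, profile.cic_diff_delay, profile.cic_order)
    _, hcomp = signal.freqz(comp, worN=2 * np.pi * freqs[inband] / profile.out_rate)
    resp[inband] = hcic * np.abs(hcomp)
    return signal.firwin2(numtaps, freqs / nyq_m, resp)


def acquire(
    master: MasterSignal,
    profile: DeviceProfile,
    fidelity: str = "fast",
    rng: np.random.Generator | None = None,
) -> AcquiredRecording:
    """Render a master signal through one armband's acquisition chain.

    ``full`` fidelity (validation, segments ≤ 60 s) runs the chain in the
    oversampled domain including the real CIC; ``fast`` fidelity runs the
    baseband-equivalent chain at the master rate.  Input-referred noise is
    injected as white noise with the profile's in-band RMS at the output
    rate (see module docstring), then the signal is quantized.  Labels are
    decimated by nearest sample.
    """
    if fidelity not in ("full", "fast"):
        raise ValueError("fidelity must be 'full' or 'fast'")
    if master.rate < profile.out_rate:
        raise ValueError("master rate below the device output rate")
    rng = np.random.default_rng() if rng is None else rng

    x = master.samples[_select_channels(master, profile)]
    n_out = int(x.shape[1] * profile.out_rate // master.rate)

    if fidelity == "full" and profile.osr is not None:
        if master.duration_s > _FULL_FIDELITY_MAX_S:
            raise ValueError(
                f"full fidelity is for validation segments <= {_FULL_FIDELITY_MAX_S:.0f} s"
            )
        fs_ov = profile.oversampled_rate
        frac = Fraction(fs_ov, master.rate)
        y = signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
        y = _one_pole(y, profile.analog_hp_hz, fs_ov, "highpass")
        y = _one_pole(y, profile.analog_lp_hz, fs_ov, "lowpass")
        y = cic_decimate(y, profile.osr, profile.cic_diff_delay, profile.cic_order)
        comp = cic_compensator(profile.out_rate, profile.osr,
                               profile.cic_diff_delay, profile.cic_order)
        y = signal.lfilter(comp, [1.0], y, axis=-1)
    else:
        y = _one_pole(x, profile.analog_hp_hz, master.rate, "highpass")
        y = _one_pole(y, profile.analog_lp_hz, master.rate, "lowpass")
        if profile.osr is not None:
            fir = _fast_chain_fir(profile, master.rate)
            y = signal.lfilter(fir, [1.0], y, axis=-1)
        frac = Fraction(profile.out_rate, master.rate)
        y = signal.resample_poly(y, frac.numerator, frac.denominator, axis=-1)

    y = y[:, :n_out]
    if profile.noise_rms > 0:
        y = y + rng.normal(0.0, profile.noise_rms, size=y.shape)
    codes = quantize(y, profile)
    labels = _resample_labels(master.labels, y.shape[1], master.rate, profile.out_rate)
    return AcquiredRecording(codes=codes, rate=profile.out_rate, labels=labels,
                             profile=profile, boundaries=list(master.boundaries))
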