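"""Filtering chains and spectral utilities.

The default chain mirrors the device's static-experiment settings: 0.5 Hz
high-pass, 50 Hz and 100 Hz notches, 100 Hz low-pass; the modified-electrode
arm lowers the high-pass cutoff to 0.25 Hz to preserve more of the ECG band.
Filters are maximally-flat (Butterworth) IIR, applied forward-backward so
R-peak timing is not skewed by phase distortion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import ECGSignal

__all__ = [
    "FilterChainSpec",
    "FilterChain",
    "design_filter_chain",
    "apply_filter_chain",
    "band_energy_fraction",
    "STATIC_ARM",
    "MODIFIED_ARM",
]


@dataclass(frozen=True)
class FilterChainSpec:
    highpass_cutoff_hz: float = 0.5
    lowpass_cutoff_hz: float = 100.0
    notch_freqs_hz: tuple[float, ...] = (50.0, 100.0)
    highpass_order: int = 4
    lowpass_order: int = 4
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 < self.highpass_cutoff_hz < self.lowpass_cutoff_hz <= nyq):
            raise ValueError(
                f"need 0 < highpass ({self.highpass_cutoff_hz}) < lowpass "
                f"({self.lowpass_cutoff_hz}) <= Nyquist ({nyq})")
        for f in self.notch_freqs_hz:
            if not (0 < f < nyq):
                raise ValueError(f"notch frequency {f} Hz not below Nyquist {nyq}")


#: 0.5 Hz-arm used with the plain single-position electrode.
STATIC_ARM = FilterChainSpec(highpass_cutoff_hz=0.5)
#: 0.25 Hz-arm used with the modified (two-contact) electrode.
MODIFIED_ARM = FilterChainSpec(highpass_cutoff_hz=0.25)


@dataclass(frozen=True)
class FilterChain:
    """Designed cascade: high-pass -> notches -> low-pass (SOS sections)."""

    spec: FilterChainSpec
    fs: float
    sos_stages: tuple[np.ndarray, ...]

    def frequency_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Complex single-pass response of the cascade at ``freqs_hz``."""
        freqs_hz = np.asarray(freqs_hz, dtype=float)
        h = np.ones_like(freqs_hz, dtype=complex)
        for sos in self.sos_stages:
            _, stage = sps.sosfreqz(sos, worN=freqs_hz, fs=self.fs)
            h *= stage
        return h

    def magnitude(self, freqs_hz: np.ndarray) -> np.ndarray:
        return np.abs(self.frequency_response(freqs_hz))

    @property
    def transient_samples(self) -> int:
        """Rough impulse-response length of the slowest stage (the high-pass),
        used as the minimum-length guard for zero-phase filtering."""
        return int(np.ceil(3.0 * self.fs / self.spec.highpass_cutoff_hz / (2 * np.pi)))


def design_filter_chain(spec: FilterChainSpec, fs: float) -> FilterChain:
    spec.validate(fs)
    stages = [sps.butter(spec.highpass_order, spec.highpass_cutoff_hz,
                         btype="highpass", fs=fs, output="sos")]
    for f0 in spec.notch_freqs_hz:
        b, a = sps.iirnotch(f0, spec.notch_q, fs=fs)
        stages.append(sps.tf2sos(b, a))
    stages.append(sps.butter(spec.lowpass_order, spec.lowpass_cutoff_hz,
                             btype="lowpass", fs=fs, output="sos"))
    return FilterChain(spec=spec, fs=fs, sos_stages=tuple(stages))


def apply_filter_chain(chain: FilterChain, signal: ECGSignal) -> ECGSignal:
    """Zero-phase (forward-backward) application; length preserved."""
    if abs(signal.fs - chain.fs) > 1e-6 * chain.fs:
        raise ValueError(
            f"signal rate {signal.fs} Hz does not match chain design rate {chain.fs} Hz")
    if signal.n <= 3 * chain.transient_samples:
        raise ValueError(
            f"signal too short for zero-phase filtering: {signal.n} samples, "
            f"need more than {3 * chain.transient_samples}")
    y = signal.samples
    for sos in chain.sos_stages:
        y = sps.sosfiltfilt(sos, y)
    return signal.with_samples(y)


def band_energy_fraction(signal: ECGSignal, f_lo: float, f_hi: float,
                         nperseg: int = 4096) -> float:
    """Fraction of Welch spectral energy in [f_lo, f_hi), relative to the
    total above DC.  Half-open bands over a disjoint partition sum to one."""
    if signal.n == 0:
        raise ValueError("empty signal")
    if not (f_lo < f_hi <= signal.fs / 2 + 1e-9):
        raise ValueError("need f_lo < f_hi <= Nyquist")
    freqs, psd = sps.welch(signal.samples, fs=signal.fs,
                           nperseg=min(nperseg, signal.n))
    above_dc = freqs > 0
    total = psd[above_dc].sum()
    if total == 0:
        return 0.0
    # half-open [f_lo, f_hi); a band ending at Nyquist keeps the Nyquist bin
    upper = (freqs <= f_hi) if f_hi >= signal.fs / 2 else (freqs < f_hi)
    band = above_dc & (freqs >= f_lo) & upper
    return float(psd[band].sum() / total)
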