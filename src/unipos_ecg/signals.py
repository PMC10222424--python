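"""Uniformly sampled physiological signal container shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ECGSignal"]


@dataclass(frozen=True)
class ECGSignal:
    """A uniformly sampled 1-D trace.

    Parameters
    ----------
    samples : ndarray
        Signal values, arbitrary units (the forward model and the synthetic
        generator are not amplitude-calibrated).
    T : float
        Sampling interval in seconds.
    channel : str
        Channel label, e.g. ``"control"`` or ``"experimental"``.
    provenance : str
        One of ``{"clean", "noisy", "simulated"}``.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    T: float
    channel: str = ""
    provenance: str = "clean"
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("ECGSignal requires a 1-D series of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("ECGSignal samples must be finite")
        if not (self.T > 0):
            raise ValueError("sampling interval T must be positive")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.T

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds (n * T)."""
        return self.n * self.T

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * self.T

    def with_samples(self, samples: np.ndarray, provenance: str | None = None) -> "ECGSignal":
        """Return a copy with new sample values (same sampling metadata)."""
        return replace(self, samples=np.asarray(samples, dtype=float),
                       provenance=provenance if provenance is not None else self.provenance)
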