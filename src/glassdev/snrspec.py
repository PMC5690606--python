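"""Spectral signal-to-noise at the stimulus alternation frequency.

The signal amplitude is the modulus of the discrete Fourier coefficient at
the bin nearest the fundamental alternation frequency FF; the noise
estimate is the mean amplitude at the two flanking frequencies 0.5 FF and
1.5 FF, which are not harmonics of FF and hence stimulus-independent.
Signal is declared present when the ratio exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimgen import pinwheel_fundamental_frequency

__all__ = ["SnrSpec", "spectral_snr", "spectral_phase"]


@dataclass(frozen=True)
class SnrSpec:
    """Frequencies (cycles/min) and sampling interval for the SNR metric."""

    ff_per_min: float = pinwheel_fundamental_frequency()
    tr: float = 6.0
    flank_factors: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        if self.ff_per_min <= 0:
            raise ValueError("fundamental frequency must be > 0")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        for f in self.flank_factors:
            # flanks must not coincide with harmonics of FF
            if abs(f - round(f)) < 1e-9:
                raise ValueError(f"flank factor {f} is a harmonic of FF")

    @property
    def ff_hz(self) -> float:
        return self.ff_per_min / 60.0


def _amplitude_at(series: np.ndarray, tr: float, freq_hz: float) -> tuple[float, float]:
    """(amplitude, phase) of the DFT coefficient at the bin nearest freq_hz."""
    n = series.size
    coeffs = np.fft.rfft(series - series.mean())
    freqs = np.fft.rfftfreq(n, d=tr)
    k = int(np.argmin(np.abs(freqs - freq_hz)))
    # one-sided amplitude of a real sinusoid component
    scale = 2.0 / n if 0 < k < (n // 2 if n % 2 == 0 else (n + 1) // 2) else 1.0 / n
    return float(np.abs(coeffs[k]) * scale), float(np.angle(coeffs[k]))


def spectral_snr(series: np.ndarray, spec: SnrSpec = SnrSpec()) -> float:
    """amp(FF) / mean(amp(0.5 FF), amp(1.5 FF)) for one time series."""
    series = np.asarray(series, dtype=float)
    record_s = series.size * spec.tr
    cycles = record_s * spec.ff_hz
    if cycles < 2.0 - 1e-9:
        raise ValueError(
            f"series spans {cycles:.2f} cycles of FF; need at least 2"
        )
    sig, _ = _amplitude_at(series, spec.tr, spec.ff_hz)
    flanks = [
        _amplitude_at(series, spec.tr, f * spec.ff_hz)[0] for f in spec.flank_factors
    ]
    noise = float(np.mean(flanks))
    return sig / noise if noise > 0 else float("inf")


def spectral_phase(series: np.ndarray, spec: SnrSpec = SnrSpec()) -> float:
    """Phase (radians) of the FF coefficient; optional timing QC report."""
    series = np.asarray(series, dtype=float)
    return _amplitude_at(series, spec.tr, spec.ff_hz)[1]
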