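"""Periodogram computation and hidden-period detection.

The periodogram at Fourier frequency f_k = k/n is

    I_n(f_k) = (1/n) | sum_{t=1}^{n} X_t e^{-i 2 pi f_k t} |^2,

evaluated for k = 1..floor(n/2); the zero frequency is excluded so that the
series mean (always large for positive counts) does not dominate the
maximum.  The period is read off as the integer part of 1 / argmax_f I_n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Periodogram", "periodogram", "detect_period"]


@dataclass(frozen=True)
class Periodogram:
    freqs: np.ndarray  # k/n, k = 1..floor(n/2)
    power: np.ndarray  # I_n(f_k) >= 0
    n: int

    @property
    def argmax_freq(self) -> float:
        """Maximizing frequency; ties broken by the lowest frequency."""
        return float(self.freqs[int(np.argmax(self.power))])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"freq": self.freqs, "power": self.power})


def periodogram(values) -> Periodogram:
    """Periodogram of a series at the positive Fourier frequencies.

    Computed through the FFT; the squared modulus at k is identical to
    a_k^2 + b_k^2 with the usual cosine/sine magnitudes.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    # note: the model's time index is 1-based; the phase shift from using
    # 0-based FFT indexing leaves |.|^2 unchanged
    spec = np.fft.rfft(x)
    k = np.arange(1, n // 2 + 1)
    power = np.abs(spec[k]) ** 2 / n
    return Periodogram(freqs=k / n, power=power, n=n)


def detect_period(values) -> int:
    """Dominant period: floor(1 / argmax_f I_n(f_k)).

    Raises for a constant series, which has no dominant frequency.
    """
    pg = periodogram(values)
    if np.max(pg.power) <= 1e-12 * max(1.0, float(np.sum(np.asarray(values) ** 2))):
        raise ValueError("no dominant frequency: series is constant")
    return int(np.floor(1.0 / pg.argmax_freq))
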