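"""The measured-field container: complex S21 indexed [tx, rx, freq]."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionGeometry

__all__ = ["SignalSet"]


@dataclass
class SignalSet:
    """Complex transmission samples on an acquisition geometry.

    s21[t, m, f] is the transmission coefficient from transmitter ``t`` to
    receiver ``m`` at frequency index ``f``; shape must equal
    ``geometry.shape`` and values must be finite.  ``noise_sigma`` records
    the per-sample complex-noise standard deviation used in synthesis (0 for
    measured or noiseless data).
    """

    s21: np.ndarray
    geometry: AcquisitionGeometry
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.s21 = np.asarray(self.s21, dtype=complex)
        if self.s21.shape != self.geometry.shape:
            raise ValueError(
                f"s21 shape {self.s21.shape} does not match geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.s21)):
            raise ValueError("s21 contains non-finite values")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.s21.shape

    def copy_with(self, s21: np.ndarray) -> "SignalSet":
        return SignalSet(s21, self.geometry, self.noise_sigma)
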