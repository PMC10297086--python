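"""Multi-bistatic acquisition geometry.

The scanner rotates a transmitting and a receiving antenna azimuthally on a
common ring around a cup holding the pendant breast.  For every transmitter
position the receiver steps around the full circle (default 4.5°, i.e. 80
positions); the transmitters are grouped into doublet sections whose centres
sit at 0°, 72°, 144°, 216° and 288° (10 transmitter positions in total).
Signals are swept over the 1–9 GHz band.

Angles are measured counter-clockwise from the +x axis, in degrees, reduced
to the half-open interval [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeometryError", "AcquisitionGeometry", "make_geometry", "angle_to_index"]

_ANGLE_TOL = 1e-9


class GeometryError(ValueError):
    """Raised for inconsistent acquisition-geometry parameters."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Antenna ring, transmitter doublets, receiver steps and frequency grid.

    Parameters
    ----------
    antenna_radius
        Radius in metres of the ring on which both antennas rotate.  Must
        exceed the largest cup radius (67.5 mm).
    rx_step
        Receiver angular step in degrees; must divide 360.
    section_centres
        Centres, in degrees, of the transmitter doublet sections.
    doublet_offset
        Angular separation in degrees between the two transmitters of one
        doublet; members sit at centre ± doublet_offset / 2.
    frequencies
        Strictly increasing frequency grid in Hz, within [1, 9] GHz.
    """

    antenna_radius: float
    rx_step: float
    section_centres: tuple[float, ...]
    doublet_offset: float
    frequencies: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, dtype=float))
        if self.antenna_radius <= 0:
            raise GeometryError("antenna_radius must be positive")
        n = 360.0 / self.rx_step
        if self.rx_step <= 0 or abs(n - round(n)) > _ANGLE_TOL:
            raise GeometryError(f"rx_step={self.rx_step} does not divide 360")
        if not self.section_centres:
            raise GeometryError("section_centres must be non-empty")
        f = self.frequencies
        if f.size < 2 or np.any(np.diff(f) <= 0):
            raise GeometryError("frequencies must be strictly increasing, length >= 2")
        if f[0] < 1e9 - _ANGLE_TOL or f[-1] > 9e9 + _ANGLE_TOL:
            raise GeometryError("frequencies must lie within [1, 9] GHz")
        tx = self.tx_angles
        if len(np.unique(np.round(tx, 9))) != tx.size:
            raise GeometryError("duplicate transmitter angles after reduction mod 360")

    # -- derived quantities -------------------------------------------------

    @property
    def n_rx(self) -> int:
        return int(round(360.0 / self.rx_step))

    @property
    def n_tx(self) -> int:
        return 2 * len(self.section_centres)

    @property
    def n_freq(self) -> int:
        return int(self.frequencies.size)

    @property
    def rx_angles(self) -> np.ndarray:
        """Receiver angles in degrees, index order."""
        return np.arange(self.n_rx) * self.rx_step

    @property
    def tx_angles(self) -> np.ndarray:
        """Transmitter angles in degrees: centre ± doublet_offset/2, mod 360."""
        half = self.doublet_offset / 2.0
        angles = [a for c in self.section_centres for a in (c - half, c + half)]
        return np.mod(np.asarray(angles, dtype=float), 360.0)

    def _ring_xy(self, angles_deg: np.ndarray) -> np.ndarray:
        rad = np.deg2rad(angles_deg)
        return self.antenna_radius * np.column_stack([np.cos(rad), np.sin(rad)])

    @property
    def rx_positions(self) -> np.ndarray:
        """(n_rx, 2) receiver coordinates in metres."""
        return self._ring_xy(self.rx_angles)

    @property
    def tx_positions(self) -> np.ndarray:
        """(n_tx, 2) transmitter coordinates in metres."""
        return self._ring_xy(self.tx_angles)

    @property
    def shape(self) -> tuple[int, int, int]:
        """Shape (n_tx, n_rx, n_freq) of a signal cube on this geometry."""
        return (self.n_tx, self.n_rx, self.n_freq)


def make_geometry(
    rx_step: float = 4.5,
    section_centres: tuple[float, ...] = (0.0, 72.0, 144.0, 216.0, 288.0),
    doublet_offset: float = 9.0,
    antenna_radius: float = 0.10,
    n_freq: int = 81,
    f_min: float = 1e9,
    f_max: float = 9e9,
) -> AcquisitionGeometry:
    """Build an acquisition geometry with a uniform frequency grid.

    Defaults reproduce the clinical configuration: 80 receiver positions
    (4.5° step), 10 transmitters in 5 doublet sections, 1–9 GHz sweep.
    """
    if n_freq < 2:
        raise GeometryError("n_freq must be >= 2")
    freqs = np.linspace(f_min, f_max, n_freq)
    return AcquisitionGeometry(
        antenna_radius=antenna_radius,
        rx_step=rx_step,
        section_centres=tuple(float(c) for c in section_centres),
        doublet_offset=doublet_offset,
        frequencies=freqs,
    )


def angle_to_index(geometry: AcquisitionGeometry, angle: float) -> int:
    """Receiver index m with m * rx_step == angle (mod 360).

    Inverse of ``geometry.rx_angles[m]``; the angle must lie on the receiver
    grid (any multiple of rx_step, wrap-around allowed).
    """
    ratio = np.mod(angle, 360.0) / geometry.rx_step
    m = int(round(ratio))
    if abs(ratio - m) > 1e-6:
        raise GeometryError(f"angle {angle} deg is not on the {geometry.rx_step} deg receiver grid")
    return m % geometry.n_rx
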