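"""Huygens-principle back-propagation imaging.

Measured surface-field samples (S21 over transmitter angle × receiver angle ×
frequency) are treated as secondary sources and back-propagated into the
breast with the 2D outgoing-wave Green's function, after a rotation
subtraction that cancels rotation-invariant signal components (antenna
coupling, skin ring).  The intensity image is a coherent sum over receivers
followed by an incoherent (power) sum over transmitters and frequency
points:

    I(rho) = sum_f sum_tx | sum_rx dS21[tx, rx, f] * K_f(rx, rho) |^2

where the back-propagation kernel K is the phase-compensating (conjugated)
Green's factor, matched to the rotation subtraction applied to the data:
when the data are receiver-shift differences dS21[m] = S21[m] - S21[m+s],
the kernel is the same difference of Green's factors,

    K_f(m, rho) = conj( G(k_f, |r_m - rho|) - G(k_f, |r_{m+s} - rho|) ),

normalised to unit energy over receivers at each pixel.  Conjugation makes
the receiver sum phase-coherent at a scatterer position (back-propagation
in the time-reversal sense); the matched difference keeps the focal peak
centred between the scatterer and its subtraction ghost; the unit-norm
weighting removes the radial bias of the raw kernel energy.

The back-propagation wavenumber is conductivity weighted: the medium is
free space apart from an assumed conductivity (default 0.3 S/m) that damps
the kernel with depth, emphasising dielectric inhomogeneity.  No
patient-specific dielectric knowledge enters the algorithm.

Time convention is e^{+j omega t}; outgoing waves are H0^(2) and lossy
wavenumbers have Im(k) <= 0 so fields decay with distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import epsilon_0, mu_0
from scipy.special import hankel2

from .acquisition import AcquisitionGeometry, GeometryError
from .signals import SignalSet

__all__ = [
    "MediumParameters",
    "ImageGrid",
    "MicrowaveImage",
    "DegenerateImageError",
    "complex_wavenumber",
    "green2d",
    "rotation_subtract",
    "GreenOperator",
    "huygens_reconstruct",
    "normalize_mean1",
    "mip",
]


class DegenerateImageError(ValueError):
    """Raised when an operation requires a non-degenerate (non-zero) image."""


@dataclass(frozen=True)
class MediumParameters:
    """Homogeneous background: relative permittivity and conductivity (S/m)."""

    relative_permittivity: float = 1.0
    conductivity: float = 0.3

    def __post_init__(self) -> None:
        if self.relative_permittivity < 1.0:
            raise ValueError("relative_permittivity must be >= 1")
        if self.conductivity < 0.0:
            raise ValueError("conductivity must be >= 0")


@dataclass(frozen=True)
class ImageGrid:
    """Square pixel grid covering the coronal imaging plane.

    Pixel (iy, ix) has centre (x, y) = (-half_extent + (ix + 1/2) * dx,
    -half_extent + (iy + 1/2) * dx); y grows with the row index (upward in
    physical coordinates), storage is 0-based row-major.  The breast mask is
    the disk of ``mask_radius`` about the origin (cup axis).
    """

    half_extent: float
    n_pixels_per_side: int = 64
    mask_radius: float | None = None

    def __post_init__(self) -> None:
        if self.half_extent <= 0 or self.n_pixels_per_side < 2:
            raise ValueError("half_extent must be > 0 and n_pixels_per_side >= 2")

    @property
    def pixel_spacing(self) -> float:
        return 2.0 * self.half_extent / self.n_pixels_per_side

    @property
    def axis(self) -> np.ndarray:
        n = self.n_pixels_per_side
        return -self.half_extent + (np.arange(n) + 0.5) * self.pixel_spacing

    @property
    def pixel_centres(self) -> np.ndarray:
        """(n, n, 2) array of (x, y) pixel-centre coordinates."""
        ax = self.axis
        xx, yy = np.meshgrid(ax, ax)  # rows index y
        return np.stack([xx, yy], axis=-1)

    @property
    def breast_mask(self) -> np.ndarray:
        r = self.mask_radius if self.mask_radius is not None else self.half_extent
        c = self.pixel_centres
        return c[..., 0] ** 2 + c[..., 1] ** 2 < r**2


@dataclass
class MicrowaveImage:
    """Coronal intensity map in linear arbitrary units on a masked grid."""

    intensity: np.ndarray
    grid: ImageGrid
    normalized: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = self.grid.n_pixels_per_side
        if self.intensity.shape != (n, n):
            raise ValueError("intensity shape does not match grid")
        if np.any(self.intensity < 0) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def masked_values(self) -> np.ndarray:
        return self.intensity[self.grid.breast_mask]


def complex_wavenumber(frequency: float, medium: MediumParameters) -> complex:
    """Conductivity-weighted wavenumber k (rad/m) at one frequency.

    k = omega * sqrt(mu0 eps0 eps_r) * sqrt(1 - j sigma / (omega eps0 eps_r)),
    principal square root, so Im(k) <= 0 under e^{+j omega t} and the wave
    decays with distance.  Satisfies k^2 = omega^2 mu0 eps0 eps_r
    - j omega mu0 sigma exactly.
    """
    frequency = np.asarray(frequency, dtype=float)
    if np.any(frequency <= 0):
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * frequency
    eps = epsilon_0 * medium.relative_permittivity
    k = omega * np.sqrt(mu_0 * eps) * np.sqrt(1.0 - 1j * medium.conductivity / (omega * eps))
    return complex(k) if k.ndim == 0 else k


def green2d(k: complex, distance) -> np.ndarray | complex:
    """Outgoing-wave 2D Helmholtz Green's function -(j/4) H0^(2)(k d).

    The -(j/4) prefactor is the standard free-space normalisation; any
    constant cancels under the unit-mean image normalisation, so only the
    relative structure matters downstream.  Self-points (d <= 0) are
    rejected.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive (self-point excluded)")
    out = -0.25j * hankel2(0, k * d)
    return complex(out) if out.ndim == 0 else out


def rotation_subtract(signals: SignalSet, delta: float = 9.0) -> SignalSet:
    """Rotation-subtraction artifact removal.

    out[t, m, f] = s21[t, m, f] - s21[t, (m + delta/rx_step) mod n_rx, f].
    Cancels exactly any component constant across receiver index (skin ring,
    antenna coupling).  ``delta`` must be a positive multiple of the receiver
    step; the clinical setting is 9° (an index shift of 2 on the 4.5° grid).
    """
    geometry = signals.geometry
    shift_f = delta / geometry.rx_step
    shift = int(round(shift_f))
    if delta <= 0 or abs(shift_f - shift) > 1e-9 or shift == 0:
        raise GeometryError(f"delta={delta} deg is not a positive multiple of rx_step={geometry.rx_step}")
    return signals.copy_with(signals.s21 - np.roll(signals.s21, -shift, axis=1))


class GreenOperator:
    """Per-frequency back-propagation kernels K[f][rx, masked-pixel].

    Computing Hankel functions dominates reconstruction cost; the kernels
    depend only on (geometry, medium, grid, match_delta), so one operator is
    shared across all breasts of a cohort.

    ``match_delta`` (degrees) matches the kernel to rotation-subtracted
    data: each kernel column becomes the same receiver-shift difference that
    produced the data.  ``None`` leaves the plain Green's factors (for raw,
    unsubtracted signals).  Kernels are conjugated and normalised to unit
    receiver-energy per pixel at application time.
    """

    def __init__(
        self,
        geometry: AcquisitionGeometry,
        medium: MediumParameters,
        grid: ImageGrid,
        match_delta: float | None = None,
    ):
        self.geometry = geometry
        self.medium = medium
        self.grid = grid
        self.match_delta = match_delta
        mask = grid.breast_mask
        self._mask = mask
        pix = grid.pixel_centres[mask]  # (n_pix, 2)
        rx = geometry.rx_positions  # (n_rx, 2)
        dist = np.linalg.norm(rx[:, None, :] - pix[None, :, :], axis=-1)
        dist = np.maximum(dist, 1e-9)  # antennas sit outside the mask; guard rounding
        shift = 0
        if match_delta is not None:
            shift_f = match_delta / geometry.rx_step
            shift = int(round(shift_f))
            if match_delta <= 0 or abs(shift_f - shift) > 1e-9 or shift == 0:
                raise GeometryError(
                    f"match_delta={match_delta} deg is not a positive multiple of rx_step"
                )
        self._kernels = []
        self._weights = []
        for f in geometry.frequencies:
            g = green2d(complex_wavenumber(f, medium), dist)
            h = g - np.roll(g, -shift, axis=0) if shift else g
            norm = np.linalg.norm(h, axis=0)
            w = np.where(norm > 1e-12 * norm.max(), 1.0 / np.maximum(norm, 1e-300), 0.0)
            self._kernels.append(np.conj(h))
            self._weights.append(w)

    def kernel(self, f_index: int) -> np.ndarray:
        """Conjugated (n_rx, n_pix) kernel at one frequency index."""
        return self._kernels[f_index]

    def weight(self, f_index: int) -> np.ndarray:
        """Per-pixel unit-energy normalisation at one frequency index."""
        return self._weights[f_index]

    @property
    def mask(self) -> np.ndarray:
        return self._mask


def huygens_reconstruct(
    signals: SignalSet,
    medium: MediumParameters | None = None,
    grid: ImageGrid | None = None,
    operator: GreenOperator | None = None,
    match_delta: float | None = None,
) -> MicrowaveImage:
    """Back-propagate a (rotation-subtracted) signal set into an image.

    Coherent sum over receivers, incoherent sum over transmitters and
    frequencies; pixels outside the breast mask are zero.  The output is not
    yet normalised.  An all-zero input yields an all-zero image flagged
    degenerate.

    ``match_delta`` should equal the rotation-subtraction angle applied to
    the signals (the kernel is matched to the subtracted response); leave
    ``None`` for raw signals.  Pass a precomputed :class:`GreenOperator` to
    amortise the kernel over many reconstructions.
    """
    geometry = signals.geometry
    if operator is None:
        if medium is None or grid is None:
            raise ValueError("provide either an operator or (medium, grid)")
        operator = GreenOperator(geometry, medium, grid, match_delta=match_delta)
    grid = operator.grid
    s21 = signals.s21
    lam_min = 299792458.0 / geometry.frequencies[-1]
    if grid.pixel_spacing > lam_min / 4.0:
        import warnings

        warnings.warn(
            f"pixel spacing {grid.pixel_spacing:.4g} m exceeds lambda_min/4 "
            f"({lam_min / 4.0:.4g} m); image may be under-sampled",
            stacklevel=2,
        )
    n = grid.n_pixels_per_side
    acc = np.zeros(int(operator.mask.sum()))
    for fi in range(geometry.n_freq):
        field_txpix = (s21[:, :, fi] @ operator.kernel(fi)) * operator.weight(fi)
        acc += np.sum(np.abs(field_txpix) ** 2, axis=0)
    intensity = np.zeros((n, n))
    intensity[operator.mask] = acc
    return MicrowaveImage(intensity, grid, normalized=False, degenerate=not np.any(acc))


def normalize_mean1(image: MicrowaveImage) -> MicrowaveImage:
    """Normalise to unitary average intensity over the breast mask."""
    mean = image.masked_values.mean() if image.masked_values.size else 0.0
    if not mean > 0:
        raise DegenerateImageError("cannot normalise an image with zero masked mean")
    return MicrowaveImage(image.intensity / mean, image.grid, normalized=True)


def mip(images: list[MicrowaveImage]) -> MicrowaveImage:
    """Maximum intensity projection: per-pixel maximum over image planes."""
    if not images:
        raise ValueError("mip of an empty image list")
    grid = images[0].grid
    if any(im.grid != grid for im in images):
        raise ValueError("mip requires a common grid")
    out = np.maximum.reduce([im.intensity for im in images])
    return MicrowaveImage(out, grid, normalized=False)
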