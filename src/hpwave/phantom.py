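"""Synthetic breast phantoms, Born-model S21 synthesis and study cohorts.

The forward model is a 2D scalar Born (single-scattering) approximation:
each scatterer contributes the product of two outgoing-wave Green's factors,
transmitter-to-scatterer and scatterer-to-receiver, weighted by a
dimensionless dielectric-contrast amplitude.  This is the standard
desk-scale surrogate in radar-based breast imaging: it is linear in the
contrast and exercises every downstream stage (rotation subtraction,
back-propagation, features, scoring) without a full-wave solver.

Phantoms carry three signal components:

* lesions — few strong scatterers (present only in WF breasts);
* clutter — many weak random scatterers emulating fibroglandular
  heterogeneity, with amplitude increasing over BI-RADS density classes
  A < B < C < D;
* a rotation-invariant artifact — a frequency-only response A(f) emulating
  antenna coupling / skin-ring reflection, identical at every transmitter
  and receiver index, hence exactly cancelled by rotation subtraction.

Cohorts follow the two-phase clinical protocol: per site, the first
subjects (default 15) are lesion-free calibration cases; the remainder are
evaluation cases with ~50% lesion prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import speed_of_light

from .acquisition import AcquisitionGeometry
from .reconstruction import MediumParameters, complex_wavenumber, green2d
from .signals import SignalSet

__all__ = [
    "Scatterer",
    "PhantomParameters",
    "BreastPhantom",
    "CohortRecord",
    "simulate_s21",
    "sample_phantom",
    "simulate_cohort",
    "DENSITY_CLASSES",
]

DENSITY_CLASSES = ("A", "B", "C", "D")
_WF_BIRADS = (2, 3, 4, 5, 6)
_WF_BIRADS_WEIGHTS = (0.35, 0.20, 0.20, 0.15, 0.10)


@dataclass(frozen=True)
class Scatterer:
    """Point/disk scatterer: position (m), complex contrast amplitude, radius (m)."""

    x: float
    y: float
    amplitude: complex
    radius: float = 0.0


@dataclass(frozen=True)
class PhantomParameters:
    """Generator configuration for synthetic phantoms.

    Defaults emulate the protocol conditions at desk scale: breasts fit the
    largest cup (radius <= 67.5 mm); scatterer ``amplitude`` is a lumped
    dimensionless scattering strength (dielectric contrast x cross-section),
    so a centimetre-scale lesion sits well above a millimetre-scale
    fibroglandular speck, while aggregate clutter grows with density class
    A < B < C < D, making detection harder in dense breasts; the
    rotation-invariant artifact dominates the raw signal, as skin/coupling
    does in measured data.
    """

    breast_radius: float = 0.06
    lesion_amplitude_range: tuple[float, float] = (1.0, 3.0)
    lesion_radius_range: tuple[float, float] = (0.003, 0.008)
    lesion_margin: float = 0.8
    clutter_count: dict[str, int] = field(
        default_factory=lambda: {"A": 15, "B": 25, "C": 35, "D": 45}
    )
    clutter_amplitude: dict[str, float] = field(
        default_factory=lambda: {"A": 0.02, "B": 0.04, "C": 0.08, "D": 0.15}
    )
    clutter_radius: float = 0.002
    symmetric_artifact_amplitude: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.breast_radius <= 0.0675:
            raise ValueError("breast_radius must be in (0, 0.0675] m (largest cup)")


@dataclass
class BreastPhantom:
    """A 2D breast section: lesions, clutter, artifact level, density class."""

    breast_radius: float
    lesions: tuple[Scatterer, ...] = ()
    clutter: tuple[Scatterer, ...] = ()
    clutter_amplitude: float = 0.0
    symmetric_artifact_amplitude: float = 0.0
    density_class: str = "B"

    def __post_init__(self) -> None:
        if self.density_class not in DENSITY_CLASSES:
            raise ValueError(f"unknown density class {self.density_class!r}")
        if self.clutter_amplitude < 0 or self.symmetric_artifact_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        for s in (*self.lesions, *self.clutter):
            if np.hypot(s.x, s.y) + s.radius >= self.breast_radius:
                raise ValueError(f"scatterer at ({s.x:.4f}, {s.y:.4f}) lies outside the breast disk")

    @property
    def scatterers(self) -> tuple[Scatterer, ...]:
        return (*self.lesions, *self.clutter)

    @property
    def truth_label(self) -> str:
        """WF iff at least one lesion scatterer is present."""
        return "WF" if self.lesions else "NF"


@dataclass
class CohortRecord:
    """One assessed breast: identity, reference-standard label, signals."""

    subject_id: str
    site_id: str
    side: str
    density_class: str
    birads: int
    truth_label: str
    phase: str  # "calibration" | "evaluation"
    phantom: BreastPhantom | None = None
    signals: SignalSet | None = None
    signal_file: str | None = None

    def __post_init__(self) -> None:
        if self.truth_label != ("NF" if self.birads == 1 else "WF"):
            raise ValueError("truth_label inconsistent with BI-RADS (NF iff birads == 1)")
        if self.phase == "calibration" and self.truth_label != "NF":
            raise ValueError("calibration records must be NF")
        if self.phase not in ("calibration", "evaluation"):
            raise ValueError(f"unknown phase {self.phase!r}")


def _artifact_response(geometry: AcquisitionGeometry) -> np.ndarray:
    # frequency-only coupling term; round-trip delay across the antenna ring
    tau = 2.0 * geometry.antenna_radius / speed_of_light
    return np.exp(-1j * 2.0 * np.pi * geometry.frequencies * tau)


def simulate_s21(
    phantom: BreastPhantom,
    geometry: AcquisitionGeometry,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    background: MediumParameters | None = None,
) -> SignalSet:
    """Synthesise the multi-bistatic S21 cube for a phantom.

    s21[t, m, f] = sum_s a_s G(k_b, |r_t - r_s|) G(k_b, |r_s - r_m|)
                   + artifact_amplitude * A(f) + complex Gaussian noise

    with k_b the background wavenumber (default free space: eps_r = 1,
    sigma = 0, so the back-propagation's conductivity weighting is a
    deliberate model mismatch, as in the clinical algorithm).  Noise is
    circular complex Gaussian, i.i.d. per sample, with total complex
    standard deviation ``noise_sigma``.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if background is None:
        background = MediumParameters(relative_permittivity=1.0, conductivity=0.0)
    n_tx, n_rx, n_freq = geometry.shape
    s21 = np.zeros((n_tx, n_rx, n_freq), dtype=complex)

    scatterers = phantom.scatterers
    if scatterers:
        pos = np.array([[s.x, s.y] for s in scatterers])
        amp = np.array([s.amplitude for s in scatterers], dtype=complex)
        d_tx = np.linalg.norm(geometry.tx_positions[:, None, :] - pos[None, :, :], axis=-1)
        d_rx = np.linalg.norm(geometry.rx_positions[:, None, :] - pos[None, :, :], axis=-1)
        for fi, f in enumerate(geometry.frequencies):
            k = complex_wavenumber(f, background)
            gt = green2d(k, d_tx)  # (n_tx, n_s)
            gr = green2d(k, d_rx)  # (n_rx, n_s)
            s21[:, :, fi] = (gt * amp) @ gr.T

    if phantom.symmetric_artifact_amplitude > 0:
        s21 += phantom.symmetric_artifact_amplitude * _artifact_response(geometry)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(s21.shape) + 1j * rng.standard_normal(s21.shape)
        s21 += noise * (noise_sigma / np.sqrt(2.0))

    return SignalSet(s21, geometry, noise_sigma=noise_sigma)


def _uniform_disk(rng: np.random.Generator, radius: float, n: int) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def sample_phantom(
    truth_label: str,
    density_class: str,
    seed: int | np.random.Generator | None = None,
    params: PhantomParameters | None = None,
) -> BreastPhantom:
    """Draw a random phantom for the given label and density class.

    NF phantoms have no lesion; WF phantoms carry one lesion scatterer at a
    uniform in-breast position with amplitude/radius from the configured
    ranges.  Clutter count and amplitude grow monotonically A < B < C < D.
    """
    if truth_label not in ("NF", "WF"):
        raise ValueError(f"unknown truth label {truth_label!r}")
    if density_class not in DENSITY_CLASSES:
        raise ValueError(f"unknown density class {density_class!r}")
    p = params or PhantomParameters()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lesions: tuple[Scatterer, ...] = ()
    if truth_label == "WF":
        xy = _uniform_disk(rng, p.lesion_margin * p.breast_radius, 1)[0]
        lesions = (
            Scatterer(
                x=xy[0],
                y=xy[1],
                amplitude=rng.uniform(*p.lesion_amplitude_range),
                radius=rng.uniform(*p.lesion_radius_range),
            ),
        )

    n_cl = p.clutter_count[density_class]
    a_cl = p.clutter_amplitude[density_class]
    xy = _uniform_disk(rng, 0.9 * p.breast_radius - p.clutter_radius, n_cl)
    phases = np.exp(1j * rng.uniform(0, 2 * np.pi, size=n_cl))
    mags = a_cl * rng.uniform(0.5, 1.5, size=n_cl)
    clutter = tuple(
        Scatterer(x=xy[i, 0], y=xy[i, 1], amplitude=mags[i] * phases[i], radius=p.clutter_radius)
        for i in range(n_cl)
    )
    return BreastPhantom(
        breast_radius=p.breast_radius,
        lesions=lesions,
        clutter=clutter,
        clutter_amplitude=a_cl,
        symmetric_artifact_amplitude=p.symmetric_artifact_amplitude,
        density_class=density_class,
    )


def simulate_cohort(
    n_subjects: int,
    prevalence: float = 0.5,
    density_weights: dict[str, float] | None = None,
    n_calibration_per_site: int = 15,
    sites: tuple[str, ...] = ("site1", "site2", "site3"),
    seed: int = 0,
    params: PhantomParameters | None = None,
    geometry: AcquisitionGeometry | None = None,
    noise_sigma: float = 0.0,
) -> list[CohortRecord]:
    """Generate a two-phase protocol cohort, one record per assessed breast.

    Per site the first ``n_calibration_per_site`` subjects are NF with
    phase="calibration"; remaining subjects are assigned cyclically across
    sites, WF with probability ``prevalence``, phase="evaluation".  Density
    classes are drawn from ``density_weights``.  When a geometry is given,
    each record also carries a synthesised :class:`SignalSet`.
    """
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    if n_calibration_per_site < 0:
        raise ValueError("n_calibration_per_site must be >= 0")
    if n_subjects < len(sites) * n_calibration_per_site:
        raise ValueError("n_subjects smaller than total calibration requirement")
    weights = density_weights or {"A": 0.1, "B": 0.4, "C": 0.4, "D": 0.1}
    classes = [c for c in DENSITY_CLASSES if weights.get(c, 0) > 0]
    probs = np.array([weights[c] for c in classes], dtype=float)
    probs /= probs.sum()

    rng = np.random.default_rng(seed)
    plan: list[tuple[str, str]] = []  # (site, phase)
    for site in sites:
        plan.extend((site, "calibration") for _ in range(n_calibration_per_site))
    n_eval = n_subjects - len(plan)
    for i in range(n_eval):
        plan.append((sites[i % len(sites)] if sites else "", "evaluation"))

    records: list[CohortRecord] = []
    counters: dict[str, int] = {}
    for site, phase in plan:
        counters[site] = counters.get(site, 0) + 1
        if phase == "calibration":
            label = "NF"
            birads = 1
        else:
            label = "WF" if rng.uniform() < prevalence else "NF"
            birads = int(rng.choice(_WF_BIRADS, p=_WF_BIRADS_WEIGHTS)) if label == "WF" else 1
        density = str(rng.choice(classes, p=probs))
        phantom = sample_phantom(label, density, rng, params)
        signals = None
        if geometry is not None:
            noise_seed = int(rng.integers(2**31))
            signals = simulate_s21(phantom, geometry, noise_sigma=noise_sigma, seed=noise_seed)
        records.append(
            CohortRecord(
                subject_id=f"{site}-{counters[site]:04d}",
                site_id=site,
                side=str(rng.choice(["left", "right"])),
                density_class=density,
                birads=birads,
                truth_label=label,
                phase=phase,
                phantom=phantom,
                signals=signals,
            )
        )
    return records
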