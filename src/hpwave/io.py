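"""File formats: signal CSV/HDF5, image CSV + JSON sidecar, tables, reports.

Tabular interchange is plain CSV, nested results are JSON, so every
artifact is inspectable and diffable.  Signal sets may also be stored in an
HDF5 container that round-trips the acquisition geometry exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import AcquisitionGeometry, angle_to_index
from .classifier import ThresholdTable
from .features import FEATURE_IDS
from .reconstruction import ImageGrid, MicrowaveImage
from .signals import SignalSet
from .study_stats import PerformanceReport

__all__ = [
    "write_signals_csv",
    "read_signals_csv",
    "write_signals_hdf5",
    "read_signals_hdf5",
    "write_image",
    "read_image",
    "write_feature_table",
    "read_feature_table",
    "write_thresholds",
    "read_thresholds",
    "write_report",
]

_SIGNAL_COLUMNS = ("tx_angle_deg", "rx_angle_deg", "freq_hz", "s21_re", "s21_im")


def write_signals_csv(signals: SignalSet, path: str | Path) -> None:
    """One row per (tx, rx, freq) sample: angles, frequency, Re/Im of S21."""
    g = signals.geometry
    tx, rx, fr = np.meshgrid(g.tx_angles, g.rx_angles, g.frequencies, indexing="ij")
    df = pd.DataFrame(
        {
            "tx_angle_deg": tx.ravel(),
            "rx_angle_deg": rx.ravel(),
            "freq_hz": fr.ravel(),
            "s21_re": signals.s21.real.ravel(),
            "s21_im": signals.s21.imag.ravel(),
        }
    )
    df.to_csv(path, index=False)


def _infer_geometry(tx_angles: np.ndarray, rx_angles: np.ndarray, freqs: np.ndarray,
                    antenna_radius: float) -> AcquisitionGeometry:
    rx_sorted = np.sort(rx_angles)
    steps = np.diff(rx_sorted)
    rx_step = float(steps.min())
    tx_sorted = np.sort(tx_angles)
    if tx_sorted.size % 2:
        raise ValueError("transmitter angles do not form doublets")
    gaps = np.diff(np.append(tx_sorted, tx_sorted[0] + 360.0))
    offset = float(gaps.min())
    centres = []
    used = np.zeros(tx_sorted.size, dtype=bool)
    for i in range(tx_sorted.size):
        j = (i + 1) % tx_sorted.size
        if not used[i] and not used[j] and abs(gaps[i] - offset) < 1e-6:
            centres.append(float(np.mod(tx_sorted[i] + offset / 2.0, 360.0)))
            used[i] = used[j] = True
    if len(centres) != tx_sorted.size // 2:
        raise ValueError("could not pair transmitter angles into doublets")
    return AcquisitionGeometry(
        antenna_radius=antenna_radius,
        rx_step=rx_step,
        section_centres=tuple(sorted(centres)),
        doublet_offset=offset,
        frequencies=freqs,
    )


def read_signals_csv(
    path: str | Path,
    geometry: AcquisitionGeometry | None = None,
    antenna_radius: float = 0.10,
) -> SignalSet:
    """Read a signal CSV; the geometry is inferred from the angle/frequency
    grid when not supplied (the ring radius is not stored in the CSV)."""
    df = pd.read_csv(path)
    missing = [c for c in _SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"signal CSV missing columns {missing}")
    tx_angles = np.unique(df["tx_angle_deg"])
    rx_angles = np.unique(df["rx_angle_deg"])
    freqs = np.unique(df["freq_hz"])
    if geometry is None:
        geometry = _infer_geometry(tx_angles, rx_angles, freqs, antenna_radius)
    s21 = np.zeros(geometry.shape, dtype=complex)
    tx_index = {round(a, 6): i for i, a in enumerate(geometry.tx_angles)}
    f_index = {f: i for i, f in enumerate(geometry.frequencies)}
    t = df["tx_angle_deg"].round(6).map(tx_index).to_numpy()
    m = np.array([angle_to_index(geometry, a) for a in df["rx_angle_deg"]])
    fi = df["freq_hz"].map(f_index).to_numpy()
    if np.any(pd.isna(t)) or np.any(pd.isna(fi)):
        raise ValueError("signal CSV contains samples off the geometry grid")
    s21[t.astype(int), m, fi.astype(int)] = df["s21_re"].to_numpy() + 1j * df["s21_im"].to_numpy()
    return SignalSet(s21, geometry)


def write_signals_hdf5(signals: SignalSet, path: str | Path) -> None:
    import h5py

    g = signals.geometry
    with h5py.File(path, "w") as fh:
        fh.create_dataset("s21", data=signals.s21)
        fh.create_dataset("frequencies", data=g.frequencies)
        fh.attrs["rx_step"] = g.rx_step
        fh.attrs["section_centres"] = list(g.section_centres)
        fh.attrs["doublet_offset"] = g.doublet_offset
        fh.attrs["antenna_radius"] = g.antenna_radius
        fh.attrs["noise_sigma"] = signals.noise_sigma


def read_signals_hdf5(path: str | Path) -> SignalSet:
    import h5py

    with h5py.File(path, "r") as fh:
        geometry = AcquisitionGeometry(
            antenna_radius=float(fh.attrs["antenna_radius"]),
            rx_step=float(fh.attrs["rx_step"]),
            section_centres=tuple(float(c) for c in fh.attrs["section_centres"]),
            doublet_offset=float(fh.attrs["doublet_offset"]),
            frequencies=fh["frequencies"][...],
        )
        return SignalSet(fh["s21"][...], geometry, noise_sigma=float(fh.attrs["noise_sigma"]))


def write_image(image: MicrowaveImage, path: str | Path, extra_meta: dict | None = None) -> None:
    """CSV intensity matrix (row-major, out-of-mask pixels 0) + JSON sidecar."""
    path = Path(path)
    np.savetxt(path, image.intensity, delimiter=",")
    meta = {
        "n_pixels_per_side": image.grid.n_pixels_per_side,
        "half_extent_m": image.grid.half_extent,
        "mask_radius_m": image.grid.mask_radius,
        "normalized": image.normalized,
        "pixel_order": "row-major, 0-based, y increases with row index (upward)",
    }
    meta.update(extra_meta or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_image(path: str | Path) -> MicrowaveImage:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    intensity = np.loadtxt(path, delimiter=",")
    grid = ImageGrid(
        half_extent=meta["half_extent_m"],
        n_pixels_per_side=meta["n_pixels_per_side"],
        mask_radius=meta["mask_radius_m"],
    )
    return MicrowaveImage(intensity, grid, normalized=meta["normalized"])


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_IDS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    return df


def write_thresholds(table: ThresholdTable, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "site_id": table.site_id,
                "n_calibration": table.n_calibration,
                "thresholds": table.thresholds,
            },
            indent=1,
        )
    )


def read_thresholds(path: str | Path) -> ThresholdTable:
    d = json.loads(Path(path).read_text())
    return ThresholdTable(
        site_id=d["site_id"], thresholds=d["thresholds"], n_calibration=d["n_calibration"]
    )


def write_report(report: PerformanceReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))
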