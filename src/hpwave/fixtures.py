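"""Miniature deterministic datasets exercising the whole pipeline quickly.

The bundle is deliberately small — 2 sites × (3 calibration NF + 6
evaluation breasts), a 40-position receiver ring (9° step), 11 frequency
points and a 16×16 image grid — so that simulation, reconstruction,
calibration, scoring and evaluation all run in seconds.  Identical seeds
produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .acquisition import make_geometry
from .config import RunConfig, dump_toml
from .io import write_signals_csv
from .phantom import CohortRecord, PhantomParameters, simulate_cohort

__all__ = ["FixtureBundle", "make_fixtures", "fixture_config"]


def fixture_config(seed: int = 0) -> RunConfig:
    """The miniature run configuration used by the fixture bundle."""
    cfg = RunConfig()
    cfg.geometry.rx_step_deg = 9.0
    cfg.geometry.n_freq = 11
    cfg.reconstruction.grid_size = 16
    cfg.simulation.n_subjects = 18
    cfg.simulation.sites = ["siteA", "siteB"]
    cfg.simulation.n_calibration_per_site = 3
    cfg.simulation.lesion_amplitude = [2.0, 4.0]
    cfg.simulation.noise_sigma = 1e-5
    cfg.simulation.seed = seed
    return cfg


@dataclass
class FixtureBundle:
    root: Path
    config_path: Path
    manifest_path: Path
    records: list[CohortRecord]
    config: RunConfig


def make_fixtures(seed: int = 0, out_dir: str | Path = "fixtures") -> FixtureBundle:
    """Write the miniature dataset: config TOML, cohort manifest, signal CSVs."""
    root = Path(out_dir)
    (root / "signals").mkdir(parents=True, exist_ok=True)
    cfg = fixture_config(seed)
    geometry = cfg.make_geometry()
    params = PhantomParameters(
        breast_radius=cfg.simulation.breast_radius_m,
        lesion_amplitude_range=tuple(cfg.simulation.lesion_amplitude),
    )
    records = simulate_cohort(
        n_subjects=cfg.simulation.n_subjects,
        prevalence=cfg.simulation.prevalence,
        density_weights=cfg.simulation.density_weights,
        n_calibration_per_site=cfg.simulation.n_calibration_per_site,
        sites=tuple(cfg.simulation.sites),
        seed=seed,
        params=params,
        geometry=geometry,
        noise_sigma=cfg.simulation.noise_sigma,
    )
    rows = []
    for rec in records:
        rel = f"signals/{rec.subject_id}.csv"
        write_signals_csv(rec.signals, root / rel)
        rec.signal_file = rel
        rows.append(
            {
                "subject_id": rec.subject_id,
                "site_id": rec.site_id,
                "side": rec.side,
                "phase": rec.phase,
                "density_class": rec.density_class,
                "birads": rec.birads,
                "truth_label": rec.truth_label,
                "signal_file": rel,
            }
        )
    manifest = root / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    config_path = root / "config.toml"
    config_path.write_text(dump_toml(cfg))
    return FixtureBundle(
        root=root, config_path=config_path, manifest_path=manifest, records=records, config=cfg
    )


def read_manifest(manifest_path: str | Path, geometry=None) -> list[CohortRecord]:
    """Load a cohort manifest and its signal CSVs back into records."""
    from .io import read_signals_csv

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    records = []
    for _, row in df.iterrows():
        signals = read_signals_csv(manifest_path.parent / row["signal_file"], geometry=geometry)
        if geometry is None:
            geometry = signals.geometry  # share one geometry (and Green operator)
        records.append(
            CohortRecord(
                subject_id=row["subject_id"],
                site_id=row["site_id"],
                side=row["side"],
                density_class=row["density_class"],
                birads=int(row["birads"]),
                truth_label=row["truth_label"],
                phase=row["phase"],
                signals=signals,
                signal_file=row["signal_file"],
            )
        )
    return records
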