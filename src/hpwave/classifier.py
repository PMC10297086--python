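"""Median-calibrated binary scoring and the NF/WF decision rule.

Each site calibrates a per-feature threshold D_offset|feature as the median
of the feature over its lesion-free (NF) calibration breasts — in the
clinical protocol, the first 15 volunteers per site.  A breast then gets a
binary score per selected feature,

    S = 1  if  feature >  D_offset|feature
    S = 0  if  feature <= D_offset|feature

and the final assessment is "WF" (breast with finding) when the number of
S = 1 occurrences reaches ``min_positives`` (default 5, i.e. every one of
the five default selected features must fire).  Scoring never consults the
reference-standard label: the assessment is blinded by construction.

The default selected features are M2AVG_i (the printed M2MEA_i), MAX_i on
the unit-mean normalised image (the printed MAX_n), VAR_p, MAD0_p and
VAR_r; both the set and the rule count are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_IDS, FeatureVector

__all__ = [
    "DEFAULT_SELECTED_FEATURES",
    "SelectedFeatureSet",
    "ThresholdTable",
    "Assessment",
    "calibrate",
    "score",
]

DEFAULT_SELECTED_FEATURES = ("M2AVG_i", "MAX_i", "VAR_p", "MAD0_p", "VAR_r")


@dataclass(frozen=True)
class SelectedFeatureSet:
    """Ordered feature subset entering the rule, and the WF trigger count."""

    features: tuple[str, ...] = DEFAULT_SELECTED_FEATURES
    min_positives: int = 5

    def __post_init__(self) -> None:
        unknown = [f for f in self.features if f not in FEATURE_IDS]
        if unknown:
            raise ValueError(f"unknown feature ids: {unknown}")
        if not 1 <= self.min_positives <= len(self.features):
            raise ValueError("min_positives must be between 1 and the number of selected features")


@dataclass
class ThresholdTable:
    """Per-site calibrated thresholds D_offset|feature."""

    site_id: str
    thresholds: dict[str, float]
    n_calibration: int

    def __post_init__(self) -> None:
        if self.n_calibration < 1:
            raise ValueError("n_calibration must be >= 1")
        bad = [f for f, v in self.thresholds.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite thresholds for {bad}")


@dataclass
class Assessment:
    """Binary scores, their count, and the final blinded NF/WF label."""

    scores: dict[str, int]
    positives: int
    label: str
    blinded: bool = True


def calibrate(
    calibration_features: pd.DataFrame,
    selected: SelectedFeatureSet | None = None,
) -> ThresholdTable:
    """Median thresholds from one site's NF calibration feature table.

    ``calibration_features`` must hold one row per calibration breast with
    columns ``site_id``, ``truth_label`` and the selected feature columns.
    Medians use the mean-of-middle-two convention for even counts;
    undefined (NaN) values are dropped per feature, and a feature undefined
    in every row is an error.
    """
    selected = selected or SelectedFeatureSet()
    if len(calibration_features) < 1:
        raise ValueError("calibration requires at least one row")
    sites = set(calibration_features["site_id"])
    if len(sites) != 1:
        raise ValueError(f"calibration table must cover exactly one site, got {sorted(sites)}")
    if not (calibration_features["truth_label"] == "NF").all():
        raise ValueError("calibration rows must all be NF")
    thresholds: dict[str, float] = {}
    for f in selected.features:
        vals = pd.to_numeric(calibration_features[f], errors="coerce").dropna()
        if vals.empty:
            raise ValueError(f"feature {f} undefined in every calibration row")
        thresholds[f] = float(vals.median())
    return ThresholdTable(
        site_id=sites.pop(),
        thresholds=thresholds,
        n_calibration=len(calibration_features),
    )


def score(
    features: FeatureVector | dict[str, float] | pd.Series,
    thresholds: ThresholdTable,
    selected: SelectedFeatureSet | None = None,
) -> Assessment:
    """Score one breast against calibrated thresholds (blinded).

    S = 1 only on strict exceedance; a value exactly at the threshold, or
    undefined (NaN), scores 0 — conservative toward NF.
    """
    selected = selected or SelectedFeatureSet()
    missing = [f for f in selected.features if f not in thresholds.thresholds]
    if missing:
        raise ValueError(f"thresholds missing for selected features: {missing}")
    getter = features.__getitem__
    scores: dict[str, int] = {}
    for f in selected.features:
        v = float(getter(f))
        scores[f] = int(math.isfinite(v) and v > thresholds.thresholds[f])
    positives = sum(scores.values())
    label = "WF" if positives >= selected.min_positives else "NF"
    return Assessment(scores=scores, positives=positives, label=label, blinded=True)
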