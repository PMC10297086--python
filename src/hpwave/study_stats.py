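"""Diagnostic-study statistics and the two-phase protocol runner.

Implements the protocol's statistical plan: per-feature Welch two-sample
t-tests (unpooled variances, Welch–Satterthwaite degrees of freedom,
two-tailed, alpha = 0.05) comparing NF vs WF breasts; ROC curves and AUC;
sensitivity and specificity with exact 95% Clopper–Pearson confidence
intervals, stratified by BI-RADS density; and the exact one-sided binomial
power/sample-size machinery behind the design point (H0: sensitivity 0.60
vs H1: 0.70, alpha = 0.05, power 0.80, lesion prevalence ~50%).

``run_protocol`` drives the full chain on a cohort: calibrate per-site
thresholds on phase-1 NF breasts, score phase-2 breasts blinded, then
evaluate against the reference standard excluding the calibration subjects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

from .classifier import SelectedFeatureSet, ThresholdTable, calibrate, score
from .features import FEATURE_IDS, feature_vector
from .phantom import CohortRecord
from .reconstruction import (
    GreenOperator,
    ImageGrid,
    MediumParameters,
    huygens_reconstruct,
    normalize_mean1,
    rotation_subtract,
)

__all__ = [
    "FeatureTestResult",
    "PerformanceReport",
    "DesignParameters",
    "ProtocolResult",
    "welch_t_test",
    "roc_auc",
    "performance",
    "binomial_critical_value",
    "power_at_n",
    "total_enrollment",
    "required_n",
    "build_feature_table",
    "run_protocol",
]

_LABELS = ("NF", "WF")


@dataclass
class FeatureTestResult:
    feature_id: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    auc: float


@dataclass
class PerformanceReport:
    """Confusion counts and rates against the reference standard (WF = positive)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ci_sensitivity: tuple[float, float]
    ci_specificity: tuple[float, float]
    strata: dict[str, "PerformanceReport"] = field(default_factory=dict)
    n_excluded_calibration: int = 0

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ci_sensitivity": list(self.ci_sensitivity),
            "ci_specificity": list(self.ci_specificity),
            "n_excluded_calibration": self.n_excluded_calibration,
        }
        if self.strata:
            d["strata"] = {k: v.to_dict() for k, v in self.strata.items()}
        return d


@dataclass(frozen=True)
class DesignParameters:
    """Exact-binomial design: H0/H1 sensitivity, alpha, power, prevalence."""

    p0: float = 0.60
    p1: float = 0.70
    alpha: float = 0.05
    power_target: float = 0.80
    prevalence: float = 0.50
    sided: str = "one"

    def __post_init__(self) -> None:
        if not 0 < self.p0 < self.p1 < 1:
            raise ValueError("need 0 < p0 < p1 < 1")
        if not (0 < self.alpha < 1 and 0 < self.power_target < 1 and 0 < self.prevalence <= 1):
            raise ValueError("alpha, power_target in (0,1); prevalence in (0,1]")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's two-sample two-tailed t-test: returns (t, df, p).

    Unpooled sample variances (divisor n-1) and Welch–Satterthwaite degrees
    of freedom.  Each group needs >= 2 values and at least one group must
    have positive variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC with WF as the positive class.

    Thresholds sweep all distinct score values with the classifier's strict
    ">" convention; ties are handled so the AUC equals the Mann–Whitney
    statistic (#(WF > NF) + tied pairs / 2) / (n_WF * n_NF).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == "WF" else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("both NF and WF labels are required")
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return curve, float(roc_auc_score(y, scores))


def _proportion_ci(k: int, n: int, method: str = "beta") -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method=method)
    return float(lo), float(hi)


def performance(
    predictions,
    truth,
    strata=None,
    ci_method: str = "beta",
    n_excluded_calibration: int = 0,
) -> PerformanceReport:
    """Sensitivity/specificity with 95% CIs, optionally stratified by density.

    ``ci_method``: "beta" = exact Clopper–Pearson (default), "wilson"
    available.  An empty positive (or negative) class yields a NaN rate with
    NaN CI bounds rather than an error.
    """
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    bad = [l for l in (*predictions, *truth) if l not in _LABELS]
    if bad:
        raise ValueError(f"labels must be NF or WF, got {sorted(set(bad))}")
    p = np.array([l == "WF" for l in predictions])
    t = np.array([l == "WF" for l in truth])
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    tn = int(np.sum(~p & ~t))
    fn = int(np.sum(~p & t))
    if tp + fn > 0:
        sens = tp / (tp + fn)
        ci_sens = _proportion_ci(tp, tp + fn, ci_method)
    else:
        sens, ci_sens = math.nan, (math.nan, math.nan)
    if tn + fp > 0:
        spec = tn / (tn + fp)
        ci_spec = _proportion_ci(tn, tn + fp, ci_method)
    else:
        spec, ci_spec = math.nan, (math.nan, math.nan)
    sub: dict[str, PerformanceReport] = {}
    if strata is not None:
        strata = list(strata)
        if len(strata) != len(truth):
            raise ValueError("strata must match record count")
        for s in sorted(set(strata)):
            idx = [i for i, v in enumerate(strata) if v == s]
            sub[s] = performance(
                [predictions[i] for i in idx], [truth[i] for i in idx], ci_method=ci_method
            )
    return PerformanceReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        ci_sensitivity=ci_sens,
        ci_specificity=ci_spec,
        strata=sub,
        n_excluded_calibration=n_excluded_calibration,
    )


def binomial_critical_value(n: int, p0: float, alpha: float) -> int:
    """Smallest k with P(Bin(n, p0) >= k) <= alpha (one-sided, upper tail)."""
    if n < 1 or not (0 < p0 < 1 and 0 < alpha < 1):
        raise ValueError("need n >= 1 and p0, alpha in (0, 1)")
    # binom.sf(k-1) = P(X >= k); start near the Gaussian quantile, then scan
    k = int(sps.binom.isf(alpha, n, p0))
    while k > 0 and sps.binom.sf(k - 1, n, p0) <= alpha:
        k -= 1
    while k <= n and sps.binom.sf(k - 1, n, p0) > alpha:
        k += 1
    return k


def power_at_n(n: int, design: DesignParameters) -> float:
    """Exact power P(Bin(n, p1) >= k*) of the one-sided test at size n."""
    alpha = design.alpha if design.sided == "one" else design.alpha / 2.0
    k = binomial_critical_value(n, design.p0, alpha)
    return float(sps.binom.sf(k - 1, n, design.p1))


def total_enrollment(n_lesion: int, prevalence: float) -> int:
    """Total cohort size implied by a lesion-arm size at a given prevalence."""
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must be in (0, 1]")
    return math.ceil(n_lesion / prevalence)


def required_n(design: DesignParameters, n_max: int = 10_000) -> tuple[int, int]:
    """Smallest lesion-arm size meeting the power target, and the total.

    Scans n = 1..n_max for the first n with exact power >= ``power_target``
    (exact binomial power is not monotone in n, so the scan is direct);
    n_total = ceil(n_lesion / prevalence).
    """
    for n in range(1, n_max + 1):
        if power_at_n(n, design) >= design.power_target:
            return n, total_enrollment(n, design.prevalence)
    raise ValueError(f"power target {design.power_target} unreachable within n <= {n_max}")


# ---------------------------------------------------------------------------
# protocol runner
# ---------------------------------------------------------------------------

_META_COLUMNS = ("subject_id", "site_id", "side", "phase", "density_class", "birads", "truth_label")


def build_feature_table(
    records: list[CohortRecord],
    medium: MediumParameters | None = None,
    grid: ImageGrid | None = None,
    delta: float = 9.0,
) -> pd.DataFrame:
    """Reconstruct, normalise and featurise every record's signal set.

    Returns one row per breast: the cohort metadata columns followed by the
    34 feature columns.  Records whose image is degenerate (all-zero
    signals) get NaN features.  One Green operator is shared per geometry.
    """
    medium = medium or MediumParameters()
    rows = []
    operators: dict[int, GreenOperator] = {}
    for rec in records:
        if rec.signals is None:
            raise ValueError(f"record {rec.subject_id} has no signals")
        geom = rec.signals.geometry
        g = grid or ImageGrid(half_extent=rec.phantom.breast_radius if rec.phantom else 0.0675)
        key = id(geom)
        if key not in operators:
            operators[key] = GreenOperator(geom, medium, g, match_delta=delta)
        ds = rotation_subtract(rec.signals, delta=delta)
        img = huygens_reconstruct(ds, operator=operators[key])
        if img.degenerate:
            feats = {f: math.nan for f in FEATURE_IDS}
        else:
            feats = feature_vector(normalize_mean1(img)).as_dict()
        row = {
            "subject_id": rec.subject_id,
            "site_id": rec.site_id,
            "side": rec.side,
            "phase": rec.phase,
            "density_class": rec.density_class,
            "birads": rec.birads,
            "truth_label": rec.truth_label,
        }
        row.update(feats)
        rows.append(row)
    return pd.DataFrame(rows, columns=[*_META_COLUMNS, *FEATURE_IDS])


@dataclass
class ProtocolResult:
    thresholds: dict[str, ThresholdTable]
    assessments: pd.DataFrame
    report: PerformanceReport | None
    feature_tests: list[FeatureTestResult]
    feature_table: pd.DataFrame


def run_protocol(
    cohort: list[CohortRecord],
    selected: SelectedFeatureSet | None = None,
    medium: MediumParameters | None = None,
    grid: ImageGrid | None = None,
    delta: float = 9.0,
    ci_method: str = "beta",
    alpha: float = 0.05,
    feature_table: pd.DataFrame | None = None,
) -> ProtocolResult:
    """Run the two-phase protocol on a cohort.

    Phase 1: per-site median calibration on the calibration (NF) breasts.
    Phase 2: blinded scoring of the evaluation breasts; performance against
    the reference standard excludes calibration subjects and is stratified
    by density; per-feature Welch tests and AUC compare NF vs WF evaluation
    breasts.  Deterministic given the cohort and configuration.
    """
    selected = selected or SelectedFeatureSet()
    table = (
        feature_table
        if feature_table is not None
        else build_feature_table(cohort, medium=medium, grid=grid, delta=delta)
    )
    calib = table[table["phase"] == "calibration"]
    eval_ = table[table["phase"] == "evaluation"]
    thresholds: dict[str, ThresholdTable] = {}
    for site in sorted(set(table["site_id"])):
        site_calib = calib[calib["site_id"] == site]
        if site_calib.empty:
            raise ValueError(f"site {site} has no calibration records")
        thresholds[site] = calibrate(site_calib, selected)

    assess_rows = []
    for _, row in eval_.iterrows():
        a = score(row, thresholds[row["site_id"]], selected)
        out = {
            "subject_id": row["subject_id"],
            "site_id": row["site_id"],
            "positives": a.positives,
            "label": a.label,
        }
        out.update({f"S_{f}": s for f, s in a.scores.items()})
        assess_rows.append(out)
    assessments = pd.DataFrame(assess_rows)

    report = None
    feature_tests: list[FeatureTestResult] = []
    if not eval_.empty:
        report = performance(
            assessments["label"],
            eval_["truth_label"],
            strata=eval_["density_class"],
            ci_method=ci_method,
            n_excluded_calibration=len(calib),
        )
        is_wf = eval_["truth_label"] == "WF"
        if is_wf.any() and (~is_wf).any():
            for f in FEATURE_IDS:
                vals = pd.to_numeric(eval_[f], errors="coerce")
                a = vals[is_wf].dropna().to_numpy()
                b = vals[~is_wf].dropna().to_numpy()
                try:
                    # near-constant features (e.g. MEA_i == 1 by normalisation)
                    # trigger scipy's precision-loss warning; the test result
                    # is still reported, flagged by its p-value
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        t, df, p = welch_t_test(a, b)
                except ValueError:
                    t = df = p = math.nan
                ok = vals.notna()
                try:
                    _, auc = roc_auc(vals[ok], eval_["truth_label"][ok])
                except ValueError:
                    auc = math.nan
                feature_tests.append(
                    FeatureTestResult(
                        feature_id=f,
                        t_statistic=t,
                        degrees_of_freedom=df,
                        p_value=p,
                        significant=bool(p < alpha) if math.isfinite(p) else False,
                        auc=auc,
                    )
                )
    return ProtocolResult(
        thresholds=thresholds,
        assessments=assessments,
        report=report,
        feature_tests=feature_tests,
        feature_table=table,
    )
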