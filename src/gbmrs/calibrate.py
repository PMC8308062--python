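"""Risk-score calibration: map raw scores to absolute risk percentages.

Training scores are cut into equal-count bins; within each bin the disease
prevalence among training statuses is the estimated absolute risk at that
score level. The discrete map is smoothed with a centered rolling average
over bin prevalences (truncated at the edges) and made continuous by linear
interpolation between bin-center knots; outside the knot range the end
values are held. No monotonicity is enforced by default — the smoothed
prevalences are reported as estimated — but a monotone (isotonic) variant
is available behind a flag.

The module also draws calibration curves (predicted versus actual risk per
bin with bootstrap confidence intervals), 2-D risk heatmaps crossing two
predictors, and fits the combined dense regressions used to merge a
biomarker panel with an external clinical risk estimator's inputs/output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UsageError
from .sparse_model import DensePredictor, ols_fit


@dataclass
class RiskCalibrationMap:
    """Monotone-smoothed mapping from raw risk score to absolute risk (%)."""

    bin_edges: np.ndarray
    bin_counts: np.ndarray
    bin_prevalence: np.ndarray  # raw per-bin prevalence
    smoothed: np.ndarray  # rolling-average prevalence (the knot values)
    knots: np.ndarray  # bin-center score values
    window: int
    monotone: bool = False
    merged_bins: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "bin_edges": list(self.bin_edges),
                "bin_counts": [int(c) for c in self.bin_counts],
                "bin_prevalence": list(self.bin_prevalence),
                "smoothed": list(self.smoothed),
                "knots": list(self.knots),
                "window": self.window,
                "monotone": self.monotone,
                "merged_bins": self.merged_bins,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RiskCalibrationMap":
        d = json.loads(text)
        return cls(
            bin_edges=np.asarray(d["bin_edges"]),
            bin_counts=np.asarray(d["bin_counts"]),
            bin_prevalence=np.asarray(d["bin_prevalence"]),
            smoothed=np.asarray(d["smoothed"]),
            knots=np.asarray(d["knots"]),
            window=d["window"],
            monotone=d["monotone"],
            merged_bins=d["merged_bins"],
        )


def _quantile_bins(scores: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-count bin assignment; massive ties can merge bins."""
    edges = np.quantile(scores, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:  # constant score: one bin holding everything
        return np.zeros(len(scores), dtype=int), np.array([scores.min(), scores.max()])
    idx = np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, len(edges) - 2)
    return idx, edges


def fit_calibration(
    scores: np.ndarray,
    statuses: np.ndarray,
    n_bins: int = 40,
    window: int = 5,
    monotone: bool = False,
) -> RiskCalibrationMap:
    """Fit the binned-prevalence calibration map on training data."""
    scores = np.asarray(scores, float)
    statuses = np.asarray(statuses, float)
    if n_bins < 3:
        raise UsageError("n_bins must be >= 3")
    if statuses.min() == statuses.max():
        raise UsageError("both classes must be present to estimate prevalence")
    idx, edges = _quantile_bins(scores, n_bins)
    k = len(edges) - 1
    counts = np.bincount(idx, minlength=k)
    cases = np.bincount(idx, weights=statuses, minlength=k)
    merged = n_bins - k
    prevalence = cases / np.maximum(counts, 1)
    # centered rolling average, truncated windows at the edges
    half = window // 2
    smoothed = np.array(
        [
            np.average(
                prevalence[max(0, i - half) : i + half + 1],
                weights=counts[max(0, i - half) : i + half + 1],
            )
            if counts[max(0, i - half) : i + half + 1].sum() > 0
            else prevalence[i]
            for i in range(k)
        ]
    )
    if monotone:
        smoothed = np.maximum.accumulate(smoothed)
    # knots at within-bin mean scores
    knots = np.array(
        [scores[idx == i].mean() if counts[i] else 0.5 * (edges[i] + edges[i + 1]) for i in range(k)]
    )
    return RiskCalibrationMap(
        bin_edges=edges,
        bin_counts=counts,
        bin_prevalence=prevalence,
        smoothed=smoothed,
        knots=knots,
        window=window,
        monotone=monotone,
        merged_bins=merged,
    )


def apply_calibration(cal: RiskCalibrationMap, scores: np.ndarray) -> np.ndarray:
    """Absolute risk in percent (0-100); clamps beyond the knot range."""
    scores = np.asarray(scores, float)
    return 100.0 * np.interp(scores, cal.knots, cal.smoothed)


# ---------------------------------------------------------------------------
# calibration curves and heatmaps


def calibration_curve(
    risks: np.ndarray,
    statuses: np.ndarray,
    n_bins: int = 20,
    n_boot: int = 100,
    seed: int = 0,
    small_bin: int = 50,
) -> pd.DataFrame:
    """Predicted-versus-actual risk per bin with bootstrap 95% CIs.

    Risks are percentages in [0, 100]. Bins are equal-count over the
    predicted risk; within each bin the actual prevalence and its
    ``n_boot``-fold bootstrap 2.5/97.5 percentiles (resampling individuals
    within the bin) are reported. Bins with fewer than ``small_bin`` samples
    carry a flag (plotted hollow).
    """
    risks = np.asarray(risks, float)
    statuses = np.asarray(statuses, float)
    if risks.min() < 0 or risks.max() > 100:
        raise UsageError("risks must be percentages in [0, 100]")
    idx, edges = _quantile_bins(risks, n_bins)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(edges) - 1):
        in_bin = idx == i
        n = int(in_bin.sum())
        if n == 0:
            continue
        s = statuses[in_bin]
        actual = float(s.mean())
        boots = rng.choice(s, size=(n_boot, n), replace=True).mean(axis=1)
        rows.append(
            {
                "mean_predicted_risk": float(risks[in_bin].mean()),
                "actual_prevalence_pct": 100.0 * actual,
                "ci_low_pct": 100.0 * float(np.percentile(boots, 2.5)),
                "ci_high_pct": 100.0 * float(np.percentile(boots, 97.5)),
                "count": n,
                "small_bin": n < small_bin,
            }
        )
    return pd.DataFrame(rows)


def risk_heatmap(
    risk_a: np.ndarray,
    risk_b: np.ndarray,
    statuses: np.ndarray,
    grid: int = 10,
) -> dict:
    """2-D binned prevalence crossing two risk predictors.

    Returns per-cell prevalence and counts over a grid x grid quantile
    binning of both axes, plus the marginal cross-section prevalences along
    each axis.
    """
    a = np.asarray(risk_a, float)
    b = np.asarray(risk_b, float)
    s = np.asarray(statuses, float)
    if not (len(a) == len(b) == len(s)):
        raise UsageError("risk vectors and statuses must cover the same samples")
    ia, _ = _quantile_bins(a, grid)
    ib, _ = _quantile_bins(b, grid)
    ka, kb = ia.max() + 1, ib.max() + 1
    counts = np.zeros((ka, kb), dtype=int)
    cases = np.zeros((ka, kb))
    np.add.at(counts, (ia, ib), 1)
    np.add.at(cases, (ia, ib), s)
    with np.errstate(invalid="ignore"):
        prevalence = np.where(counts > 0, cases / np.maximum(counts, 1), np.nan)
    marg_a = np.array([s[ia == i].mean() if (ia == i).any() else np.nan for i in range(ka)])
    marg_b = np.array([s[ib == j].mean() if (ib == j).any() else np.nan for j in range(kb)])
    return {
        "prevalence": prevalence,
        "counts": counts,
        "marginal_a": marg_a,
        "marginal_b": marg_b,
    }


# ---------------------------------------------------------------------------
# combined dense regressions


@dataclass
class CombinedFit:
    predictor: DensePredictor
    coefficients: pd.DataFrame  # feature, weight, sorted by |weight|
    dropped: list[str] = field(default_factory=list)


def fit_combined(
    biomarker_features: pd.DataFrame,
    external_inputs: pd.DataFrame,
    statuses: pd.Series,
    include_external_output: bool = False,
    external_risk: pd.Series | None = None,
) -> CombinedFit:
    """OLS on biomarkers plus an external estimator's inputs (and output).

    Discrete external input columns are z-scored so everything sits on the
    same scale; zero-variance columns are dropped. With
    ``include_external_output`` the external risk column joins the design
    (collinearity with its own inputs resolves to the minimum-norm
    solution). Coefficients are reported sorted by magnitude.
    """
    ids = list(biomarker_features.index)
    ext = external_inputs.reindex(ids)
    blocks = [biomarker_features]
    dropped = []
    zcols = {}
    for c in ext.columns:
        v = ext[c].to_numpy(float)
        sd = v.std()
        if sd == 0:
            dropped.append(c)
            continue
        zcols[c] = (v - v.mean()) / sd
    if zcols:
        blocks.append(pd.DataFrame(zcols, index=ids))
    if include_external_output:
        if external_risk is None:
            raise UsageError("include_external_output requires an external risk column")
        v = external_risk.reindex(ids).to_numpy(float)
        sd = v.std()
        if sd == 0:
            dropped.append("external_risk")
        else:
            blocks.append(pd.DataFrame({"external_risk": (v - v.mean()) / sd}, index=ids))
    design = pd.concat(blocks, axis=1)
    y = statuses.reindex(ids).to_numpy(float)
    fit = ols_fit(design.to_numpy(float), y, feature_ids=list(design.columns))
    coef = pd.DataFrame({"feature": fit.feature_ids, "weight": fit.weights})
    coef = coef.reindex(coef["weight"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
    return CombinedFit(predictor=fit, coefficients=coef, dropped=dropped)


def toy_external_estimator(
    inputs: pd.DataFrame, weights: dict[str, float], intercept: float = -2.0
) -> pd.Series:
    """Synthetic stand-in for an external clinical risk estimator.

    A logistic function of a weighted input subset, returning a 10-year-risk
    style percentage. Used for end-to-end tests of the combination and
    comparison machinery; it implements no published clinical equation.
    """
    lin = np.full(len(inputs), float(intercept))
    for c, w in weights.items():
        lin += w * inputs[c].to_numpy(float)
    return pd.Series(100.0 / (1.0 + np.exp(-lin)), index=inputs.index, name="external_risk")
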