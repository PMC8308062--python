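"""Evaluation battery: correlation/AUC, percentile odds-ratio curves,
sibling-pair tests, PCA-adjustment comparisons and ensemble statistics.

Conventions: AUC is the Mann-Whitney probability that a random case outranks
a random control (ties count one half). Odds-ratio curves follow the
"percentile and above" convention: the high-risk group at percentile q holds
everyone whose score is at or above the nearest-rank q-th percentile of the
evaluated cohort, the complement is the reference group. Ensemble spread is
the sample standard deviation over the five fold predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import EvaluationError, UsageError


@dataclass
class EvaluationReport:
    metric: str
    values: list[float]
    mean: float
    sd: float
    cohort: str = ""
    n_cases: int | None = None
    n_controls: int | None = None
    extra: dict = field(default_factory=dict)


def ensemble_stats(values, metric: str = "", cohort: str = "") -> EvaluationReport:
    """Arithmetic mean and sample SD (n-1) over ensemble members."""
    values = [float(v) for v in values]
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return EvaluationReport(metric=metric, values=values, mean=mean, sd=sd, cohort=cohort)


def auc(scores: np.ndarray, statuses: np.ndarray) -> float:
    """Mann-Whitney AUC: P(case score > control score) + P(tie)/2."""
    scores = np.asarray(scores, dtype=float)
    statuses = np.asarray(statuses)
    cases = statuses == 1
    n1, n0 = int(cases.sum()), int((~cases).sum())
    if n1 == 0 or n0 == 0:
        raise EvaluationError("AUC needs both cases and controls")
    ranks = rankdata(scores)
    u = ranks[cases].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def correlation(scores: np.ndarray, phenotype: np.ndarray) -> float:
    scores = np.asarray(scores, float)
    phenotype = np.asarray(phenotype, float)
    if scores.std() == 0 or phenotype.std() == 0:
        return 0.0
    return float(np.corrcoef(scores, phenotype)[0, 1])


# ---------------------------------------------------------------------------
# percentile odds-ratio curves


def _odds_ratio(cases_hi, controls_hi, cases_lo, controls_lo) -> tuple[float, float, bool]:
    """OR with its log-scale SE; Haldane-Anscombe +0.5 on any empty cell."""
    cells = np.array([cases_hi, controls_hi, cases_lo, controls_lo], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    or_val = (a / b) / (c / d)
    se_log = float(np.sqrt((1.0 / cells).sum()))
    return float(or_val), se_log, corrected


def or_curve(
    scores: np.ndarray | list[np.ndarray],
    statuses: np.ndarray,
    percentiles=(50, 60, 70, 80, 90, 95, 99),
) -> pd.DataFrame:
    """Odds ratio of the percentile-and-above group versus the complement.

    ``scores`` may be a single vector or a list of ensemble score vectors;
    with an ensemble, the reported SEM combines the per-member binomial
    (log-OR, delta-method) error with the spread across members.

    Returns a table (percentile, odds_ratio, sem, n_high, corrected).
    """
    if isinstance(scores, np.ndarray) and scores.ndim == 1:
        scores = [scores]
    statuses = np.asarray(statuses)
    rows = []
    for q in percentiles:
        if not 0 < q < 100:
            raise UsageError("percentiles must lie strictly between 0 and 100")
        ors, ses, flags, n_highs = [], [], [], []
        for s in scores:
            s = np.asarray(s, float)
            # individuals whose percentile rank is at or above q: the top
            # ceil(n*(1-q/100)) by score, with ties at the cut included
            k = int(np.ceil(len(s) * q / 100.0))
            cut = np.sort(s)[min(k, len(s) - 1)]
            hi = s >= cut
            ch, bh = int(statuses[hi].sum()), int((~statuses.astype(bool))[hi].sum())
            cl, bl = int(statuses[~hi].sum()), int((~statuses.astype(bool))[~hi].sum())
            or_val, se_log, corrected = _odds_ratio(ch, bh, cl, bl)
            ors.append(or_val)
            ses.append(or_val * se_log)  # delta method to the OR scale
            flags.append(corrected)
            n_highs.append(int(hi.sum()))
        m = len(ors)
        binom = float(np.sqrt(np.mean(np.square(ses))) / np.sqrt(m))
        spread = float(np.std(ors, ddof=1) / np.sqrt(m)) if m > 1 else 0.0
        rows.append(
            {
                "percentile": q,
                "odds_ratio": float(np.mean(ors)),
                "sem": float(np.hypot(binom, spread)),
                "n_high": int(np.mean(n_highs)),
                "corrected": bool(any(flags)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sibling-pair tests


def _pair_differences(values: dict[str, float], pairs: list[tuple[str, str]]) -> np.ndarray:
    return np.array([values[a] - values[b] for a, b in pairs])


def random_pairs(ids: list[str], n_pairs: int, seed: int = 0) -> list[tuple[str, str]]:
    """Disjoint random pairs among the given samples, seeded."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_pairs = min(n_pairs, len(ids) // 2)
    return [(ids[perm[2 * i]], ids[perm[2 * i + 1]]) for i in range(n_pairs)]


def sibling_delta_corr(
    scores: dict[str, float],
    phenotype: dict[str, float],
    sibling_pairs: list[tuple[str, str]],
    thresholds=(0.5, 1.0, 1.5),
    seed: int = 0,
) -> pd.DataFrame:
    """corr(delta phenotype, delta score) for sibling versus random pairs.

    Differences are taken in the fixed (first, second) member order. Sibling
    rows are additionally filtered to |delta phenotype| above each threshold
    (in phenotype SD units over all evaluated samples). Rows with fewer than
    two pairs after filtering are flagged and carry NaN.
    """
    ids = sorted(phenotype)
    sd = float(np.std([phenotype[s] for s in ids]))
    rnd = random_pairs(ids, len(sibling_pairs), seed=seed)

    rows = []

    def _one(label: str, pairs: list[tuple[str, str]]):
        if len(pairs) < 2:
            rows.append({"group": label, "n_pairs": len(pairs), "correlation": np.nan, "flagged": True})
            return
        dp = _pair_differences(phenotype, pairs)
        ds = _pair_differences(scores, pairs)
        rows.append(
            {
                "group": label,
                "n_pairs": len(pairs),
                "correlation": correlation(dp, ds),
                "flagged": False,
            }
        )

    _one("random", rnd)
    _one("siblings", sibling_pairs)
    dp_sib = _pair_differences(phenotype, sibling_pairs)
    for t in thresholds:
        keep = np.abs(dp_sib) > t * sd
        _one(f"siblings_{t}sd", [p for p, k in zip(sibling_pairs, keep) if k])
    return pd.DataFrame(rows)


def sibling_call_fraction(
    scores: dict[str, float],
    statuses: dict[str, int],
    sibling_pairs: list[tuple[str, str]],
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of discordant pairs whose case scores strictly higher.

    A pair counts when exactly one member is a case; ties between the two
    scores contribute one half. A random-pair baseline (one case, one control
    drawn from the same evaluated samples) is reported alongside.
    """

    def _fraction(pairs) -> tuple[float, int]:
        hits, n = 0.0, 0
        for a, b in pairs:
            sa, sb = statuses[a], statuses[b]
            if sa + sb != 1:
                continue
            case, ctrl = (a, b) if sa == 1 else (b, a)
            n += 1
            if scores[case] > scores[ctrl]:
                hits += 1.0
            elif scores[case] == scores[ctrl]:
                hits += 0.5
        return (hits / n if n else np.nan), n

    frac_sib, n_sib = _fraction(sibling_pairs)
    if n_sib == 0:
        raise EvaluationError("no discordant sibling pairs")
    ids = sorted(statuses)
    cases = [s for s in ids if statuses[s] == 1]
    controls = [s for s in ids if statuses[s] == 0]
    rng = np.random.default_rng(seed)
    m = min(n_sib, len(cases), len(controls))
    rnd = list(
        zip(
            rng.choice(cases, size=m, replace=False),
            rng.choice(controls, size=m, replace=False),
        )
    )
    frac_rnd, n_rnd = _fraction(rnd)
    return pd.DataFrame(
        [
            {"group": "siblings", "n_pairs": n_sib, "fraction_correct": frac_sib},
            {"group": "random", "n_pairs": n_rnd, "fraction_correct": frac_rnd},
        ]
    )


# ---------------------------------------------------------------------------
# PCA-adjustment comparison


def pca_effect(report_a: dict[str, float], report_b: dict[str, float], kind: str = "auc") -> dict:
    """Compare metrics with and without PC adjustment.

    report_a holds the unadjusted metrics m, report_b the PC-adjusted m_PCA,
    keyed identically. Returns the RMS difference sqrt(mean (m - m_PCA)^2),
    the mean percent difference (m - m_PCA) / m_PCA, and the per-key relative
    differences (m - m_PCA) / m_PCA.
    """
    if set(report_a) != set(report_b):
        raise UsageError("mismatched keys between reports")
    keys = sorted(report_a)
    a = np.array([report_a[k] for k in keys], dtype=float)
    b = np.array([report_b[k] for k in keys], dtype=float)
    rel = (a - b) / b
    return {
        "kind": kind,
        "rms_difference": float(np.sqrt(np.mean((a - b) ** 2))),
        "mean_percent_difference": float(np.mean(rel)),
        "relative": {k: float(r) for k, r in zip(keys, rel)},
    }
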