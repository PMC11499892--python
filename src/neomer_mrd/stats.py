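"""Evaluation statistics for MRD prediction.

Confusion-matrix metrics with exact (Clopper-Pearson) binomial CIs,
Cohen's kappa with a bootstrap percentile CI, Kaplan-Meier curves and
univariate Cox hazard ratios with Wald CIs, the neomer-OR-mutation
combination rule, any-positive longitudinal aggregation, and a paired
bootstrap comparison of accuracies.  Metrics whose denominator is zero
are reported as undefined (None), never as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from neomer_mrd.errors import NeomerMRDError


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts against observed progression status (Table-1 layout:
    prediction rows = progress / progress-free, truth columns)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricWithCI:
    estimate: float
    ci_low: float
    ci_high: float
    n_success: int
    n_total: int
    alpha: float = 0.05

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_success": self.n_success,
            "n_total": self.n_total,
        }


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_high: int
    n_low: int
    converged: bool = True

    def as_dict(self) -> dict:
        return {
            "hr": self.hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "converged": self.converged,
        }


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> MetricWithCI:
    """Exact binomial proportion CI via beta quantiles; the lower bound is
    0 at x = 0 and the upper bound 1 at x = n."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, {n}]")
    lo = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return MetricWithCI(x / n, lo, hi, x, n, alpha)


def confusion_from_calls(
    high_risk: Sequence[bool], progressed: Sequence[bool]
) -> ConfusionMatrix:
    calls = np.asarray(high_risk, dtype=bool)
    labels = np.asarray(progressed, dtype=bool)
    if calls.shape != labels.shape:
        raise ValueError("call and label vectors differ in length")
    return ConfusionMatrix(
        tp=int((calls & labels).sum()),
        fp=int((calls & ~labels).sum()),
        fn=int((~calls & labels).sum()),
        tn=int((~calls & ~labels).sum()),
    )


def metrics(cm: ConfusionMatrix, alpha: float = 0.05) -> dict[str, Optional[MetricWithCI]]:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact binomial
    CIs; a metric with a zero denominator is None."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def m(x: int, n: int) -> Optional[MetricWithCI]:
        return clopper_pearson(x, n, alpha) if n > 0 else None

    return {
        "sensitivity": m(cm.tp, cm.tp + cm.fn),
        "specificity": m(cm.tn, cm.tn + cm.fp),
        "ppv": m(cm.tp, cm.tp + cm.fp),
        "npv": m(cm.tn, cm.tn + cm.fn),
        "accuracy": m(cm.tp + cm.tn, cm.total),
    }


def kappa_from_table(a: int, b: int, c: int, d: int) -> float:
    """Cohen's kappa of a 2x2 agreement table (a = both positive,
    b = rater1 only, c = rater2 only, d = both negative).  NaN when
    chance agreement is 1 (kappa undefined)."""
    n = a + b + c + d
    if n < 2:
        raise ValueError("agreement table needs >= 2 observations")
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if pe == 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def cohens_kappa(
    a: int,
    b: int,
    c: int,
    d: int,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Kappa with a bootstrap percentile CI.

    The n paired binary calls implied by the table are resampled with
    replacement ``n_boot`` times; resamples with undefined kappa
    (degenerate marginals) are dropped from the percentile computation.
    """
    kappa = kappa_from_table(a, b, c, d)
    n = a + b + c + d
    pairs = np.array(
        [(1, 1)] * a + [(1, 0)] * b + [(0, 1)] * c + [(0, 0)] * d, dtype=bool
    )
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        resample = pairs[rng.integers(0, n, size=n)]
        r1, r2 = resample[:, 0], resample[:, 1]
        kb = kappa_from_table(
            int((r1 & r2).sum()),
            int((r1 & ~r2).sum()),
            int((~r1 & r2).sum()),
            int((~r1 & ~r2).sum()),
        )
        if not np.isnan(kb):
            boots.append(kb)
    if boots:
        lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        lo = hi = float("nan")
    return {
        "kappa": kappa,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n": n,
        "n_boot": n_boot,
    }


def km_cox_hr(
    time: Sequence[float],
    event: Sequence[bool],
    high_risk: Sequence[bool],
    ties: str = "efron",
) -> tuple[HazardRatioResult, pd.DataFrame]:
    """Univariate Cox PH fit on the binary high-risk indicator plus
    Kaplan-Meier curve coordinates per group.

    HR and Wald CI are exp(beta -/+ 1.96 se).  Ties are handled by
    Efron's approximation (the only method lifelines implements, and
    the survival-package default).  When the partial likelihood is
    monotone (e.g. all events in one group) the result is flagged
    unconverged with infinite-bound CI rather than raising.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is supported")
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.exceptions import ConvergenceError

    df = pd.DataFrame(
        {
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=bool).astype(int),
            "high_risk": np.asarray(high_risk, dtype=bool).astype(int),
        }
    )
    n_high = int(df["high_risk"].sum())
    n_low = len(df) - n_high
    if n_high == 0 or n_low == 0:
        raise NeomerMRDError("both risk groups must be non-empty for a Cox fit")
    if df["event"].sum() == 0:
        raise NeomerMRDError("at least one event is required for a Cox fit")

    km = []
    for label, grp in df.groupby("high_risk"):
        fitter = KaplanMeierFitter()
        fitter.fit(grp["time"], grp["event"])
        sf = fitter.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf.insert(0, "group", "high" if label else "low")
        km.append(sf)
    km_df = pd.concat(km, ignore_index=True)

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        summary = cph.summary.loc["high_risk"]
        beta = float(summary["coef"])
        se = float(summary["se(coef)"])
        converged = np.isfinite(se) and se < 50
        z = 1.959963984540054
        with np.errstate(over="ignore"):
            result = HazardRatioResult(
                hr=float(np.exp(beta)),
                ci_low=float(np.exp(beta - z * se)),
                ci_high=float(np.exp(beta + z * se)),
                p_value=float(summary["p"]),
                n_high=n_high,
                n_low=n_low,
                converged=bool(converged),
            )
        if not converged:
            result.ci_low, result.ci_high = 0.0, float("inf")
    except ConvergenceError:
        events_high = int(df.loc[df["high_risk"] == 1, "event"].sum())
        hr = float("inf") if events_high > 0 else 0.0
        result = HazardRatioResult(
            hr=hr,
            ci_low=0.0,
            ci_high=float("inf"),
            p_value=float("nan"),
            n_high=n_high,
            n_low=n_low,
            converged=False,
        )
    return result, km_df


def combine_status(
    neomer_high_risk: Sequence[bool], ctdna_mutation_positive: Sequence[bool]
) -> np.ndarray:
    """OR combination: high risk when the model calls high risk or the
    ctDNA mutation assay is positive; low risk requires both negative."""
    a = np.asarray(neomer_high_risk, dtype=bool)
    b = np.asarray(ctdna_mutation_positive, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("call vectors differ in length")
    return a | b


def aggregate_longitudinal(
    calls: pd.DataFrame,
    complete_cases_only: bool = False,
    n_timepoints: int = 3,
) -> pd.DataFrame:
    """Patient-level any-positive aggregation over time points.

    ``calls`` needs columns patient_id, timepoint, high_risk.  A patient
    is high-risk when any available time point's call is high-risk.
    With ``complete_cases_only`` the analysis is restricted to patients
    sampled at all ``n_timepoints`` time points.
    """
    required = {"patient_id", "timepoint", "high_risk"}
    if not required <= set(calls.columns):
        raise ValueError(f"calls frame needs columns {sorted(required)}")
    grouped = calls.groupby("patient_id").agg(
        high_risk=("high_risk", "any"),
        n_timepoints=("timepoint", "nunique"),
    )
    if complete_cases_only:
        grouped = grouped[grouped["n_timepoints"] >= n_timepoints]
    return grouped.reset_index()


def bootstrap_accuracy_compare(
    calls_a: Sequence[bool],
    calls_b: Sequence[bool],
    labels: Sequence[bool],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Paired bootstrap comparison of two call sets' accuracies.

    Units (patients) are resampled with replacement ``n_boot`` times;
    accuracy is computed per resample for each call set and the paired
    accuracy vectors are compared with a two-sided Wilcoxon signed-rank
    test.  Identical call sets give p = 1 (all differences zero).
    """
    a = np.asarray(calls_a, dtype=bool)
    b = np.asarray(calls_b, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("call/label vectors differ in length")
    n = len(y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    acc_a = (a[idx] == y[idx]).mean(axis=1)
    acc_b = (b[idx] == y[idx]).mean(axis=1)
    diffs = acc_a - acc_b
    if np.all(diffs == 0):
        p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(sps.wilcoxon(acc_a, acc_b, zero_method="wilcox").pvalue)
    return {
        "mean_accuracy_a": float(acc_a.mean()),
        "mean_accuracy_b": float(acc_b.mean()),
        "mean_difference": float(diffs.mean()),
        "wilcoxon_p": p,
        "n_boot": n_boot,
        "n": n,
    }
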