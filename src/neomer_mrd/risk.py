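"""Survival-SVM risk scoring with leave-one-out cross-validation.

The model is a linear ranking SVM over comparable survival pairs: pair
(i, j) is comparable when sample i progressed (event observed) strictly
before sample j's observed time, so their risk order is known despite
censoring.  Fitting minimizes

    0.5 * ||w||^2  +  gamma * mean over comparable (i, j) of
                       max(0, 1 - w . (x_i - x_j))

and the risk score of a sample is w . x (higher = higher progression
risk).  The pair loss is averaged, not summed, so gamma's meaning does
not depend on cohort size (the number of comparable pairs grows
quadratically); averaging also makes the fit exactly invariant to
duplicating every sample.  Under LOOCV every sample is scored by a model fitted without
it, with feature standardization recomputed inside each fold.  Binary
high/low-risk calls anchor the cutoff at a target specificity (default
0.90) among non-progressors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from neomer_mrd.config import ModelConfig
from neomer_mrd.errors import UnfittableError


@dataclass
class FittedSSVM:
    """Linear scorer w . standardize(x); no intercept (ranking is
    translation-invariant and the cutoff is chosen downstream)."""

    weights: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    converged: bool
    objective: float

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.feature_mean) / self.feature_scale @ self.weights


def comparable_pairs(time: np.ndarray, event: np.ndarray) -> list[tuple[int, int]]:
    """(i, j) with event_i and t_i < t_j (ties excluded)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    return [
        (i, j)
        for i in np.flatnonzero(event)
        for j in range(len(time))
        if time[i] < time[j]
    ]


def fit_ssvm(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    config: Optional[ModelConfig] = None,
) -> FittedSSVM:
    """Fit the comparable-pair hinge objective with L-BFGS-B.

    Raises :class:`UnfittableError` when no comparable pair exists.
    """
    if config is None:
        config = ModelConfig()
    X = np.asarray(X, dtype=float)
    pairs = comparable_pairs(time, event)
    if not pairs:
        raise UnfittableError(
            "no comparable survival pairs (need an observed event strictly "
            "earlier than another sample's time)"
        )
    if config.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale
    ii = np.fromiter((i for i, _ in pairs), dtype=int)
    jj = np.fromiter((j for _, j in pairs), dtype=int)
    gamma = config.gamma / len(pairs)  # mean-normalized pair loss
    n, p = Xs.shape

    if len(pairs) <= _MAX_DUAL_PAIRS:
        weights, objective, success = _fit_dual_qp(Xs, ii, jj, gamma)
    else:  # pair Gram matrix would not fit comfortably; subgradient fallback
        weights, objective, success = _fit_subgradient(Xs, ii, jj, gamma)
    return FittedSSVM(
        weights=weights,
        feature_mean=mean,
        feature_scale=scale,
        converged=success,
        objective=objective,
    )


_MAX_DUAL_PAIRS = 4000


def _primal_objective(
    w: np.ndarray, D: np.ndarray, gamma: float
) -> float:
    return float(0.5 * w @ w + gamma * np.maximum(0.0, 1.0 - D @ w).sum())


try:  # numba makes the sequential dual sweeps fast; pure fallback below
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _cd_sweeps(K: np.ndarray, gamma: float, max_sweeps: int, tol: float):
    """Cyclic coordinate descent on the dual box QP
    min 0.5 l.K.l - 1.l over 0 <= l <= gamma (liblinear-style)."""
    n_pairs = K.shape[0]
    lam = np.zeros(n_pairs)
    Kl = np.zeros(n_pairs)
    for _ in range(max_sweeps):
        max_delta = 0.0
        for k in range(n_pairs):
            kkk = K[k, k]
            if kkk <= 1e-12:  # zero pair difference: multiplier irrelevant
                continue
            new = lam[k] + (1.0 - Kl[k]) / kkk
            if new < 0.0:
                new = 0.0
            elif new > gamma:
                new = gamma
            delta = new - lam[k]
            if delta != 0.0:
                lam[k] = new
                Kl += delta * K[k]
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            break
    return lam, Kl


if _HAVE_NUMBA:
    _cd_sweeps = _njit(cache=False)(_cd_sweeps)


def _fit_dual_qp(
    Xs: np.ndarray, ii: np.ndarray, jj: np.ndarray, gamma: float
) -> tuple[np.ndarray, float, bool]:
    """Exact solution via the box-constrained quadratic dual.

    The hinge problem's Lagrange dual is max_l 1.l - 0.5 l.K.l over
    0 <= l <= gamma with K the Gram matrix of pair differences, solved
    by cyclic coordinate descent (each coordinate update is an exact
    1-d minimization clipped to the box); the primal optimum is
    w = sum_k l_k (x_ik - x_jk).  Convergence is certified by the
    primal-dual gap.
    """
    G = Xs @ Xs.T
    AG = G[ii] - G[jj]  # (pairs, n)
    K = np.ascontiguousarray(AG[:, ii] - AG[:, jj])  # pair-diff Gram

    lam, Kl = _cd_sweeps(K, gamma, 2000, 1e-10)
    quad = 0.5 * lam @ Kl
    primal = quad + gamma * np.maximum(0.0, 1.0 - Kl).sum()
    gap = primal - (lam.sum() - quad)

    coef = np.zeros(Xs.shape[0])
    np.add.at(coef, ii, lam)
    np.add.at(coef, jj, -lam)
    w = Xs.T @ coef
    D = Xs[ii] - Xs[jj]
    converged = gap <= 1e-5 * max(1.0, abs(primal))
    return w, _primal_objective(w, D, gamma), bool(converged)


def _fit_subgradient(
    Xs: np.ndarray, ii: np.ndarray, jj: np.ndarray, gamma: float
) -> tuple[np.ndarray, float, bool]:
    """L-BFGS-B on the (nonsmooth) primal hinge objective, in the span of
    the training rows when that is the smaller parametrization."""
    n, p = Xs.shape
    D = Xs[ii] - Xs[jj]
    opts = {"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10}
    if p > n:
        G = Xs @ Xs.T
        M = D @ Xs.T

        def objective(alpha: np.ndarray) -> tuple[float, np.ndarray]:
            margins = 1.0 - M @ alpha
            active = margins > 0
            Ga = G @ alpha
            f = 0.5 * alpha @ Ga + gamma * margins[active].sum()
            g = Ga - gamma * M[active].sum(axis=0)
            return f, g

        res = minimize(objective, np.zeros(n), jac=True, method="L-BFGS-B",
                       options=opts)
        w = Xs.T @ res.x
    else:

        def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
            margins = 1.0 - D @ w
            active = margins > 0
            f = 0.5 * w @ w + gamma * margins[active].sum()
            g = w - gamma * D[active].sum(axis=0)
            return f, g

        res = minimize(objective, np.zeros(p), jac=True, method="L-BFGS-B",
                       options=opts)
        w = res.x
    return w, _primal_objective(w, D, gamma), bool(res.success)


def loocv_scores(
    features: pd.DataFrame,
    records: pd.DataFrame,
    config: Optional[ModelConfig] = None,
) -> pd.Series:
    """Out-of-fold risk score per sample.

    ``features`` is indexed by sample_id; ``records`` carries sample_id,
    pfs_time and event.  Folds are identified by sample id (sorted), so
    scores are invariant to input row order.  Standardization is
    recomputed per fold from the N-1 training samples only.
    """
    if config is None:
        config = ModelConfig()
    ids, oof, _, _ = _oof_scores(features, records, config)
    return pd.Series(oof, index=pd.Index(ids, name="sample_id"), name="oof_score")


def _oof_scores(
    features: pd.DataFrame, records: pd.DataFrame, config: ModelConfig
) -> tuple[list[str], np.ndarray, dict, dict]:
    """Shared LOOCV machinery: one held-out score per sample, folds
    identified by sorted sample id.  Also returns per-fold convergence
    and, in per_fold cutoff mode, the per-fold cutoffs/calls."""
    records = records.reset_index(drop=True)
    ids = records["sample_id"].tolist()
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids")
    if len(ids) < 3:
        raise UnfittableError(f"LOOCV needs >= 3 samples, got {len(ids)}")
    X = features.loc[ids].to_numpy(dtype=float)
    time = records["pfs_time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=bool)

    order = sorted(range(len(ids)), key=lambda i: ids[i])
    oof = np.full(len(ids), np.nan)
    fold_cut = np.full(len(ids), np.nan)
    fold_call = np.zeros(len(ids), dtype=bool)
    converged: dict[str, bool] = {}
    failed: list[str] = []
    for i in order:
        train = [j for j in order if j != i]
        try:
            model = fit_ssvm(X[train], time[train], event[train], config)
        except UnfittableError:
            failed.append(ids[i])
            continue
        converged[ids[i]] = model.converged
        oof[i] = model.score(X[i : i + 1])[0]
        if config.cutoff_mode == "per_fold":
            train_scores = model.score(X[train])
            cut, _, _ = choose_cutoff(
                train_scores, event[train], config.target_specificity
            )
            fold_cut[i] = cut
            fold_call[i] = oof[i] >= cut
    if failed:
        raise UnfittableError(
            "unfittable LOOCV fold(s) (no comparable pairs when holding out): "
            + ", ".join(failed)
        )
    per_fold = {"cutoffs": fold_cut, "calls": fold_call}
    return ids, oof, converged, per_fold


def loocv_predict(
    features: pd.DataFrame,
    records: pd.DataFrame,
    config: Optional[ModelConfig] = None,
) -> tuple[pd.DataFrame, dict]:
    """LOOCV scores plus high/low-risk calls at the specificity anchor.

    Returns a predictions frame (sample_id, oof_score, cutoff_used,
    high_risk) aligned to ``records`` order, and an info dict with
    per-fold convergence and the achieved specificity.

    In ``pooled`` cutoff mode (default) one cutoff is chosen on the
    pooled out-of-fold scores; in ``per_fold`` mode each fold's cutoff
    is chosen on that fold's in-sample training scores.
    """
    if config is None:
        config = ModelConfig()
    records = records.reset_index(drop=True)
    ids, oof, converged, per_fold = _oof_scores(features, records, config)
    event = records["event"].to_numpy(dtype=bool)

    if config.cutoff_mode == "pooled":
        cutoff, calls, achieved = choose_cutoff(
            oof, event, config.target_specificity
        )
        cutoffs = np.full(len(ids), cutoff)
    else:
        calls = per_fold["calls"]
        cutoffs = per_fold["cutoffs"]
        neg = ~event
        achieved = float((~calls[neg]).mean()) if neg.any() else float("nan")

    preds = pd.DataFrame(
        {
            "sample_id": ids,
            "oof_score": oof,
            "cutoff_used": cutoffs,
            "high_risk": calls,
        }
    )
    info = {
        "n_folds": len(ids),
        "cutoff_mode": config.cutoff_mode,
        "target_specificity": config.target_specificity,
        "achieved_specificity": achieved,
        "fold_converged": converged,
    }
    return preds, info


def choose_cutoff(
    scores: Sequence[float],
    progression_labels: Sequence[bool],
    target_specificity: float = 0.90,
) -> tuple[float, np.ndarray, float]:
    """Smallest cutoff achieving the target specificity among
    non-progressors (censored samples count as non-progressors).

    The cutoff is drawn from the observed scores (plus +inf); a call is
    high-risk when score >= cutoff.  Returns (cutoff, calls, achieved
    specificity); the achieved specificity is >= the target by
    construction.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(progression_labels, dtype=bool)
    negatives = scores[~labels]
    if negatives.size == 0:
        raise ValueError("cannot anchor specificity: no non-progressors present")
    cutoff = np.inf
    for c in np.unique(scores):
        if (negatives < c).mean() >= target_specificity:
            cutoff = float(c)
            break
    calls = scores >= cutoff
    achieved = float((negatives < cutoff).mean()) if np.isfinite(cutoff) else 1.0
    return cutoff, calls, achieved
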