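"""Post-fit predictions: cure proportion, relative survival, excess hazard,
survival and median survival of the "uncured", with delta-method confidence
intervals.

Confidence intervals are built on range-respecting scales: log(-log) for the
cure proportion, the log cumulative excess hazard for relative survival, and
log time for the median survival of the uncured.  Gradients with respect to
the parameter vector are exact where the quantity is linear in the
parameters and central finite differences otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .models import FlexibleParametricModel, WeibullCureModel

__all__ = [
    "predict_cure",
    "predict_relative_survival",
    "predict_survival_uncured",
    "median_survival_uncured",
    "predict_excess_hazard",
    "MedianNotReached",
    "prediction_table",
]


class MedianNotReached(ValueError):
    """S_u stays above 0.5 up to the cure point; no median exists."""


def _z(level):
    return stats.norm.ppf(0.5 + level / 2.0)


def _is_cure_family(model) -> bool:
    if isinstance(model, FlexibleParametricModel):
        return bool(model.cure)
    return isinstance(model, WeibullCureModel)


def _require_cure(model, what):
    if not _is_cure_family(model):
        raise ValueError(
            f"{what} is only defined for cure families; this is a "
            f"{model.family} model")


def _fd_param_grad(fun, theta, rel_step=1e-6):
    """Central-difference gradient of a (possibly vector-valued) function of
    the parameter vector; returns shape (n_out, n_params)."""
    base = np.atleast_1d(fun(theta))
    G = np.empty((base.size, theta.size))
    for i in range(theta.size):
        h = rel_step * (1.0 + abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        G[:, i] = (np.atleast_1d(fun(tp)) - np.atleast_1d(fun(tm))) / (2 * h)
    return G


def predict_cure(model, pattern=None, level=0.95):
    """Cure proportion pi = exp(-exp(gamma00 + z'beta)) with CI.

    The CI is the delta method on the log(-log) scale — exact here, since the
    linear predictor of cure is linear in the parameters — so the interval
    respects (0, 1).  Returns a dict with ``estimate``, ``lo``, ``hi``.
    """
    _require_cure(model, "the cure proportion")
    lp = model.cure_linear_predictor(pattern)
    row = model.cure_design_row(pattern)
    se = float(np.sqrt(row @ model.covariance_ @ row))
    z = _z(level)
    est = np.exp(-np.exp(lp))
    lo = np.exp(-np.exp(lp + z * se))
    hi = np.exp(-np.exp(lp - z * se))
    return {"estimate": float(est), "lo": float(lo), "hi": float(hi), "se_link": se}


def predict_relative_survival(model, pattern=None, times=None, level=0.95):
    """R(t) = exp(-Lambda(t)) with a delta-method CI on the ln Lambda scale.

    Returns a DataFrame with columns ``t``, ``estimate``, ``lo``, ``hi``.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if isinstance(model, FlexibleParametricModel):
        Xeta = model.linear_predictor_design(t, pattern)
        lp = Xeta @ model.params_
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xeta, model.covariance_, Xeta))
    else:
        def f(theta):
            return np.log(np.clip(model.excess_cumhaz(t, pattern, theta),
                                  1e-300, None))
        lp = f(model.params_)
        G = _fd_param_grad(f, model.params_)
        se = np.sqrt(np.einsum("ij,jk,ik->i", G, model.covariance_, G))
    z = _z(level)
    est = np.exp(-np.exp(lp))
    lo = np.exp(-np.exp(lp + z * se))
    hi = np.exp(-np.exp(lp - z * se))
    return pd.DataFrame({"t": t, "estimate": est, "lo": lo, "hi": hi})


def _survival_uncured_at(model, t, pattern, theta=None):
    theta = model.params_ if theta is None else theta
    pi = np.exp(-np.exp(model.cure_linear_predictor(pattern, theta)))
    R = model.relative_survival(t, pattern, theta)
    return (R - pi) / (1.0 - pi)


def predict_survival_uncured(model, pattern=None, times=None, level=0.95):
    """Survival of the "uncured", S_u(t) = (R(t) - pi) / (1 - pi), with CI.

    This is the mixture rewriting of the cure model (identical for the
    non-mixture form R = pi^F: S_u = (pi^F - pi)/(1 - pi)).  The delta-method
    CI is computed on the plain S_u scale and clipped to [0, 1].
    """
    _require_cure(model, "survival of the uncured")
    t = np.atleast_1d(np.asarray(times, dtype=float))
    pi = np.exp(-np.exp(model.cure_linear_predictor(pattern)))
    if pi >= 1.0 - 1e-10:
        raise ValueError("degenerate pattern: cure proportion is 1, the "
                         "survival of the uncured is undefined")

    def f(theta):
        return _survival_uncured_at(model, t, pattern, theta)

    est = f(model.params_)
    G = _fd_param_grad(f, model.params_)
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", G, model.covariance_, G), 0, None))
    z = _z(level)
    return pd.DataFrame({
        "t": t, "estimate": est,
        "lo": np.clip(est - z * se, 0.0, 1.0),
        "hi": np.clip(est + z * se, 0.0, 1.0),
    })


def _cure_point(model) -> float:
    if isinstance(model, FlexibleParametricModel):
        return float(np.exp(model.knots_[-1]))
    return np.inf


def median_survival_uncured(model, pattern=None, level=0.95):
    """Median survival time of the "uncured": t_m with S_u(t_m) = 1/2.

    Solved by Newton–Raphson on log time with a bisection fallback bracketed
    at (0, cure point).  The CI is the delta method on the log-time scale.
    Raises :class:`MedianNotReached` when S_u stays above 0.5 up to the cure
    point.
    """
    _require_cure(model, "the median survival of the uncured")
    t_hi = _cure_point(model)
    if not np.isfinite(t_hi):
        t_hi = 200.0  # Weibull families: S_u -> 0, any large bracket works

    def su(t, theta=None):
        return float(_survival_uncured_at(model, np.array([t]), pattern, theta)[0])

    if su(t_hi * (1 - 1e-9)) > 0.5:
        raise MedianNotReached(
            "S_u(t) > 0.5 up to the cure point; median not reached before cure")

    # Newton-Raphson on ln t
    lx = np.log(t_hi) - 1.0
    converged = False
    for _ in range(100):
        t = np.exp(lx)
        g = su(t) - 0.5
        if abs(g) < 1e-8:
            converged = True
            break
        lam_u = _uncured_density(model, t, pattern)  # -dS_u/dt
        slope = -lam_u * t  # dS_u/d ln t
        if slope == 0 or not np.isfinite(slope):
            break
        step = -g / slope
        lx = lx + np.clip(step, -1.0, 1.0)
        if np.exp(lx) >= t_hi:
            lx = np.log(t_hi) - 1e-6
    if not converged:
        from scipy.optimize import brentq

        lx = np.log(brentq(lambda tt: su(tt) - 0.5, 1e-10, t_hi * (1 - 1e-9),
                           xtol=1e-12))
    t_m = float(np.exp(lx))

    # delta method on ln t_m: d ln t_m / d theta = -(dS_u/dtheta)/(dS_u/dln t)
    dSu_dtheta = _fd_param_grad(
        lambda th: np.array([su(t_m, th)]), model.params_)[0]
    slope = -_uncured_density(model, t_m, pattern) * t_m
    grad_lnt = -dSu_dtheta / slope
    se = float(np.sqrt(max(grad_lnt @ model.covariance_ @ grad_lnt, 0.0)))
    z = _z(level)
    return {"estimate": t_m, "lo": t_m * np.exp(-z * se), "hi": t_m * np.exp(z * se),
            "se_log": se}


def _uncured_density(model, t, pattern):
    """-dS_u/dt = lambda(t) R(t) / (1 - pi): density of the uncured times."""
    pi = np.exp(-np.exp(model.cure_linear_predictor(pattern)))
    lam = float(model.excess_hazard(np.array([t]), pattern)[0])
    R = float(model.relative_survival(np.array([t]), pattern)[0])
    return lam * R / (1.0 - pi)


def predict_excess_hazard(model, pattern=None, times=None, level=0.95):
    """Excess hazard lambda(t), with a log-scale delta-method CI where
    positive.  For cure fits lambda(t) is exactly 0 at and beyond the last
    knot."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    est = model.excess_hazard(t, pattern)

    def f(theta):
        return model.excess_hazard(t, pattern, theta)

    G = _fd_param_grad(f, model.params_)
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", G, model.covariance_, G), 0, None))
    z = _z(level)
    pos = est > 0
    lo = np.where(pos, est * np.exp(-z * se / np.where(pos, est, 1.0)), est - z * se)
    hi = np.where(pos, est * np.exp(z * se / np.where(pos, est, 1.0)), est + z * se)
    return pd.DataFrame({"t": t, "estimate": est, "lo": lo, "hi": hi})


def prediction_table(model, quantity, patterns=None, times=None, level=0.95):
    """Tidy long-format predictions over covariate patterns.

    ``patterns`` is a DataFrame (one row per pattern) or a list of dicts;
    returns columns (pattern id, pattern values, t, quantity, estimate, lo,
    hi).
    """
    if patterns is None:
        patterns = [{}]
    if isinstance(patterns, pd.DataFrame):
        patterns = patterns.to_dict("records")
    frames = []
    for i, pat in enumerate(patterns):
        if quantity == "cure_proportion":
            d = predict_cure(model, pat, level)
            df = pd.DataFrame([{"t": np.nan, "estimate": d["estimate"],
                                "lo": d["lo"], "hi": d["hi"]}])
        elif quantity == "median_uncured":
            try:
                d = median_survival_uncured(model, pat, level)
                df = pd.DataFrame([{"t": np.nan, "estimate": d["estimate"],
                                    "lo": d["lo"], "hi": d["hi"]}])
            except MedianNotReached:
                warnings.warn(f"median not reached for pattern {pat}", stacklevel=2)
                df = pd.DataFrame([{"t": np.nan, "estimate": np.nan,
                                    "lo": np.nan, "hi": np.nan}])
        elif quantity == "relative_survival":
            df = predict_relative_survival(model, pat, times, level)
        elif quantity == "survival_uncured":
            df = predict_survival_uncured(model, pat, times, level)
        elif quantity == "excess_hazard":
            df = predict_excess_hazard(model, pat, times, level)
        else:
            raise ValueError(f"unknown quantity {quantity!r}")
        df.insert(0, "pattern", i)
        for k, v in pat.items():
            df[k] = v
        df["quantity"] = quantity
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
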