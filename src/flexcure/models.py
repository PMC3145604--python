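"""Maximum-likelihood relative-survival models with and without cure.

Two estimator families, both scikit-learn style (``fit(X, y)``, fitted
attributes with trailing underscores, ``get_params``/``set_params``):

:class:`FlexibleParametricModel`
    Royston–Parmar flexible parametric relative-survival model on the log
    cumulative excess hazard scale, ``ln Lambda(t) = eta(ln t)``, with a
    restricted cubic spline baseline, proportional excess hazard covariates
    and optional time-dependent effects.  With ``cure=True`` the spline is
    calculated backwards and the linear term is structurally removed, forcing
    the cumulative excess hazard to be constant at and beyond the last knot;
    the cure proportion is then ``pi = exp(-exp(intercept + z'beta))``.

:class:`WeibullCureModel`
    The classical Weibull mixture, ``R(t) = pi + (1-pi) S_u(t)``, and
    non-mixture, ``R(t) = pi^{F_Z(t)}``, cure models, as comparators.

The likelihood is built from the excess-hazard decomposition
``h(t) = h*(t) + lambda(t)``: each subject contributes
``d * ln(h*(t) + lambda(t)) - Lambda(t)`` where ``h*`` is the expected
(population) hazard from a rate table, ``lambda`` the model's excess hazard
and ``Lambda`` its cumulative; the parameter-free ``ln S*(t)`` term is
dropped.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .lifetable import RateTable, _expected_hazard_frame, records_to_frame
from .splines import RestrictedCubicSpline, resolve_knots

__all__ = [
    "FlexibleParametricModel",
    "WeibullCureModel",
    "ConvergenceError",
    "lrt_cure",
    "information_criteria",
    "loglik_flexible",
    "loglik_weibull_cure",
]


class ConvergenceError(RuntimeError):
    """Optimization failed; carries the iteration trace in ``.trace``."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# covariate design
# ---------------------------------------------------------------------------

class CovariateDesign:
    """Dummy coding for a list of covariate columns (reference = first level).

    Numeric columns enter as-is; categorical/object columns are expanded into
    indicator columns dropping the first (sorted) level.
    """

    def __init__(self, columns):
        self.columns = list(columns or [])

    def fit(self, X: pd.DataFrame):
        self.spec_ = []
        for c in self.columns:
            s = X[c]
            if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype.kind in "OUSb":
                self.spec_.append((c, sorted(map(str, pd.unique(s.astype(str))))))
            else:
                self.spec_.append((c, None))
        self.names_ = []
        for c, levels in self.spec_:
            if levels is None:
                self.names_.append(c)
            else:
                self.names_ += [f"{c}[{lv}]" for lv in levels[1:]]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        cols = []
        for c, levels in self.spec_:
            if levels is None:
                cols.append(X[c].to_numpy(dtype=float))
            else:
                s = X[c].astype(str).to_numpy()
                cols += [(s == lv).astype(float) for lv in levels[1:]]
        return np.column_stack(cols) if cols else np.zeros((len(X), 0))

    def pattern_row(self, pattern=None) -> np.ndarray:
        """Design row for a covariate pattern dict; missing entries take the
        reference level (categorical) or 0 (numeric)."""
        pattern = pattern or {}
        unknown = set(pattern) - {c for c, _ in self.spec_}
        row = []
        for c, levels in self.spec_:
            v = pattern.get(c)
            if levels is None:
                row.append(float(v) if v is not None else 0.0)
            else:
                v = str(v) if v is not None else levels[0]
                if v not in levels:
                    raise KeyError(f"level {v!r} of {c!r} not seen at fit time "
                                   f"(levels: {levels})")
                row += [1.0 if v == lv else 0.0 for lv in levels[1:]]
        if unknown:
            raise KeyError(f"pattern names {sorted(unknown)} are not model covariates")
        return np.asarray(row, dtype=float)


# ---------------------------------------------------------------------------
# generic optimisation helpers
# ---------------------------------------------------------------------------

def _fd_grad(f, theta, rel_step=1e-6):
    g = np.empty_like(theta)
    for i in range(theta.size):
        h = rel_step * (1.0 + abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        g[i] = (f(tp) - f(tm)) / (2 * h)
    return g


def _fd_hess(grad, theta, rel_step=1e-5):
    p = theta.size
    H = np.empty((p, p))
    for i in range(p):
        h = rel_step * (1.0 + abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        H[:, i] = (grad(tp) - grad(tm)) / (2 * h)
    return 0.5 * (H + H.T)


def _maximize_loglik(nll, grad, theta0, max_iter=500, gtol=1e-5, n_restarts=3):
    """Minimise mean negative log-likelihood: BFGS then Newton polish.

    Returns (theta, nll_value, grad_inf_norm, trace).  ``grad`` may be None,
    in which case central finite differences of ``nll`` are used throughout.
    """
    if grad is None:
        grad = lambda th: _fd_grad(nll, th)  # noqa: E731
    rng = np.random.default_rng(0)
    best = None
    trace = []
    theta_init = np.asarray(theta0, dtype=float)
    for attempt in range(n_restarts + 1):
        th0 = theta_init if attempt == 0 else (
            theta_init + rng.normal(scale=0.3 * (1 + np.abs(theta_init)))
        )
        res = optimize.minimize(nll, th0, jac=grad, method="BFGS",
                                options=dict(gtol=1e-7, maxiter=max_iter))
        th, f = res.x, res.fun
        # Newton polish with finite-difference Hessian
        for it in range(15):
            g = grad(th)
            ginf = float(np.max(np.abs(g)))
            trace.append((attempt, it, float(f), ginf))
            if ginf < 0.1 * gtol:
                break
            H = _fd_hess(grad, th)
            try:
                step = np.linalg.solve(H + 1e-10 * np.eye(th.size), -g)
            except np.linalg.LinAlgError:
                break
            # backtracking on the polish step
            ok = False
            for s in (1.0, 0.5, 0.25, 0.1, 0.01):
                f_new = nll(th + s * step)
                if np.isfinite(f_new) and f_new <= f + 1e-12 * (1 + abs(f)):
                    th, f, ok = th + s * step, f_new, True
                    break
            if not ok:
                break
        g = grad(th)
        ginf = float(np.max(np.abs(g)))
        if np.isfinite(f) and (best is None or f < best[1] - 1e-12 or
                               (abs(f - best[1]) < 1e-9 and ginf < best[2])):
            best = (th, f, ginf)
        if best is not None and best[2] < gtol:
            break
    if best is None or not np.isfinite(best[1]):
        raise ConvergenceError("optimizer failed to find a finite optimum", trace)
    return best[0], best[1], best[2], trace


def _check_y(y):
    """Accept (time, event) as a structured array, 2-column array, tuple or
    DataFrame; return (time, event) float/int arrays."""
    if isinstance(y, pd.DataFrame):
        return y["time"].to_numpy(float), y["event"].to_numpy(int)
    if isinstance(y, tuple) and len(y) == 2:
        return np.asarray(y[0], float), np.asarray(y[1], int)
    y = np.asarray(y)
    if y.dtype.names:  # structured (scikit-survival convention, either order)
        names = y.dtype.names
        ev = [n for n in names if y[n].dtype.kind == "b" or set(np.unique(y[n])) <= {0, 1}]
        tname = [n for n in names if n not in ev[:1]][0]
        return y[tname].astype(float), y[ev[0]].astype(int)
    if y.ndim == 2 and y.shape[1] == 2:
        return y[:, 0].astype(float), y[:, 1].astype(int)
    raise ValueError("y must provide follow-up time and event indicator")


class _RelativeSurvivalEstimator(BaseEstimator):
    """Shared fitting/prediction plumbing for the model families."""

    def _prepare(self, X, y):
        X = records_to_frame(X)
        time, event = _check_y(y)
        time = np.asarray(time, dtype=float).copy()
        event = np.asarray(event, dtype=int)
        if np.any(time < 0) or not np.all(np.isfinite(time)):
            raise ValueError("follow-up times must be finite and non-negative")
        nz = time == 0
        self.zero_time_shifted_ = int(nz.sum())
        if self.zero_time_shifted_:
            tmin = time[time > 0].min()
            time[nz] = tmin / 2.0
            warnings.warn(f"{self.zero_time_shifted_} records with time 0 shifted "
                          f"to {tmin / 2.0:g}y", stacklevel=3)
        if event.sum() < 1:
            raise ValueError("need at least one event to fit an excess hazard model")
        if self.ratetable is None:
            hstar = np.zeros(time.size)
        else:
            hstar = np.atleast_1d(_expected_hazard_frame(
                X.rename(columns={self.age_col: "age", self.sex_col: "sex",
                                  self.year_col: "year"}),
                time, self.ratetable))
        return X, time, event, hstar

    def _finalize(self, theta, mean_nll, ginf, trace, n):
        self.params_ = theta
        self.loglik_ = -mean_nll * n
        self.gradient_norm_ = ginf
        self.trace_ = trace
        self.converged_ = ginf < 1e-5
        if ginf > 1e-3:
            raise ConvergenceError(
                f"gradient max-norm {ginf:.2e} after restarts; model not converged",
                trace)
        H = _fd_hess(self._grad_total, theta)
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            warnings.warn("observed information is singular; using pseudo-inverse",
                          stacklevel=3)
        # enforce symmetry; flag non-PSD covariance
        cov = 0.5 * (cov + cov.T)
        if np.any(np.diag(cov) <= 0):
            warnings.warn("non-positive variance encountered in covariance",
                          stacklevel=3)
        self.covariance_ = cov
        self.se_ = np.sqrt(np.clip(np.diag(cov), 0, None))

    def _grad_total(self, theta):
        raise NotImplementedError

    # -- common post-fit surface -------------------------------------------
    def loglikelihood(self, theta=None):
        """Total log-likelihood at ``theta`` (default: the fitted MLE)."""
        theta = self.params_ if theta is None else np.asarray(theta, float)
        return -self._nll_mean(theta) * self.n_

    def summary(self) -> pd.DataFrame:
        z = self.params_ / np.where(self.se_ > 0, self.se_, np.nan)
        return pd.DataFrame({
            "coef": self.params_, "se": self.se_, "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
        }, index=self.param_names_)


# ---------------------------------------------------------------------------
# flexible parametric model
# ---------------------------------------------------------------------------

class FlexibleParametricModel(_RelativeSurvivalEstimator):
    """Flexible parametric relative-survival model, optionally with cure.

    Parameters
    ----------
    knots : str or array-like
        Knot rule (see :func:`flexcure.splines.resolve_knots`) or explicit
        knot positions; explicit positions are in years unless
        ``knots_scale="log"``.
    cure : bool
        Impose the cure restriction: backward spline basis with the linear
        term structurally removed, so the cumulative excess hazard is
        constant at and beyond the last knot.
    direction : {"standard", "backward"} or None
        Basis direction for the unrestricted model; default backward when
        ``cure`` else standard.  ``cure=True`` requires backward.
    covariates : list of str, optional
        Columns of ``X`` entering as constant (proportional excess hazard)
        effects.
    td_effects : list of str, optional
        Subset of ``covariates`` whose effects are time-dependent, each
        interacted with its own spline (``td_knots``; fewer knots than the
        baseline by default).  Under ``cure=True`` the linear-term
        restriction applies to every time-dependent spline as well.
    ratetable : RateTable or None
        Population rates supplying ``h*``; ``None`` means zero background
        (pure net-survival setting).
    orthogonalize : bool
        Gram–Schmidt orthogonalise spline columns.  Bases are always centered
        at the last knot, so the intercept is the log cumulative excess
        hazard there.

    Attributes (after fit)
    ----------------------
    params_, param_names_, covariance_, se_, loglik_, n_, n_events_, knots_,
    converged_, gradient_norm_.
    """

    def __init__(self, knots="centiles 0 25 50 75 95 + fixed 12", cure=False,
                 direction=None, covariates=None, td_effects=None,
                 td_knots="centiles 0 25 50 75 100", ratetable=None,
                 orthogonalize=True, knots_scale="time",
                 age_col="age", sex_col="sex", year_col="year", max_iter=500):
        self.knots = knots
        self.cure = cure
        self.direction = direction
        self.covariates = covariates
        self.td_effects = td_effects
        self.td_knots = td_knots
        self.ratetable = ratetable
        self.orthogonalize = orthogonalize
        self.knots_scale = knots_scale
        self.age_col = age_col
        self.sex_col = sex_col
        self.year_col = year_col
        self.max_iter = max_iter

    @property
    def family(self) -> str:
        return "flexible_cure" if self.cure else "flexible"

    def _resolve_direction(self):
        d = self.direction or ("backward" if self.cure else "standard")
        if self.cure and d != "backward":
            raise ValueError("the cure restriction requires the backward basis")
        return d

    def _resolve_knot_positions(self, rule, death_times):
        if isinstance(rule, str):
            return resolve_knots(rule, death_times)
        k = np.asarray(rule, dtype=float)
        return np.sort(np.log(k)) if self.knots_scale == "time" else np.sort(k)

    def fit(self, X, y):
        X, time, event, hstar = self._prepare(X, y)
        n = time.size
        x = np.log(time)
        death_times = time[event == 1]

        direction = self._resolve_direction()
        self.knots_ = self._resolve_knot_positions(self.knots, death_times)
        if self.cure and self.knots_.size < 3:
            raise ValueError("the cure model needs K >= 3 knots")
        if self.knots_[-1] < np.log(death_times.max()):
            warnings.warn(
                "last knot is before the last observed death time; the cure "
                "proportion may be unreliable — place the last knot at or "
                "beyond the last death time", stacklevel=2)

        self.baseline_spline_ = RestrictedCubicSpline(
            knots=self.knots_, direction=direction,
            include_linear=not self.cure, orthogonalize=self.orthogonalize,
            center_last_knot=True).fit(x)

        self.design_ = CovariateDesign(self.covariates).fit(X)
        Z = self.design_.transform(X)

        self.td_design_ = CovariateDesign(self.td_effects).fit(X)
        Ztd = self.td_design_.transform(X)
        if self.td_design_.names_:
            td_knots = self._resolve_knot_positions(self.td_knots, death_times)
            self.td_spline_ = RestrictedCubicSpline(
                knots=td_knots, direction=direction,
                include_linear=not self.cure, orthogonalize=self.orthogonalize,
                center_last_knot=True).fit(x)
        else:
            self.td_spline_ = None

        Xeta, Xd = self._design_matrices(x, Z, Ztd)
        self.param_names_ = self._make_names()
        self.n_, self.n_events_ = n, int(event.sum())

        # data bound into closures for the optimizer
        self._bind_data(Xeta, Xd, time, event, hstar)
        theta0 = self._initial_values(Xeta, time, event)
        theta, f, ginf, trace = _maximize_loglik(
            self._nll_mean, self._grad_mean, theta0, max_iter=self.max_iter)
        self._finalize(theta, f, ginf, trace, n)
        self._flag_negative_excess(Xeta, Xd, time, event, hstar)
        return self

    # -- design -------------------------------------------------------------
    def _design_matrices(self, x, Z, Ztd):
        B0 = self.baseline_spline_.transform(x)
        B0d = self.baseline_spline_.derivative(x)
        n = x.size
        cols = [np.ones((n, 1)), B0, Z]
        dcols = [np.zeros((n, 1)), B0d, np.zeros_like(Z)]
        if self.td_spline_ is not None:
            Bt = self.td_spline_.transform(x)
            Btd = self.td_spline_.derivative(x)
            for j in range(Ztd.shape[1]):
                cols.append(Ztd[:, j:j + 1] * Bt)
                dcols.append(Ztd[:, j:j + 1] * Btd)
        return np.hstack(cols), np.hstack(dcols)

    def _make_names(self):
        names = ["Intercept"]
        names += [f"s{j}" for j in range(1, self.baseline_spline_.n_features_out_ + 1)]
        names += self.design_.names_
        if self.td_spline_ is not None:
            for nm in self.td_design_.names_:
                names += [f"{nm}:s{j}"
                          for j in range(1, self.td_spline_.n_features_out_ + 1)]
        return names

    def _initial_values(self, Xeta, time, event):
        # exponential-excess start: ln Lambda ~ ln(rate) + ln t
        rate = max(event.sum() / time.sum(), 1e-10)
        target = np.log(rate) + np.log(time)
        theta0, *_ = np.linalg.lstsq(Xeta, target, rcond=None)
        return theta0

    # -- likelihood ----------------------------------------------------------
    def _bind_data(self, Xeta, Xd, time, event, hstar):
        self._fit_data = (Xeta, Xd, time, event.astype(float), hstar)

    @staticmethod
    def _nll_core(theta, Xeta, Xd, t, d, hstar, want_grad):
        eta = np.clip(Xeta @ theta, -200.0, 200.0)
        ds = Xd @ theta
        Lam = np.exp(eta)
        lam = Lam * ds / t
        u = hstar + lam
        eps = 1e-8
        ok = u > eps
        usafe = np.where(ok, u, eps)
        # soft barrier: linear continuation of ln below eps keeps the
        # gradient informative when the excess hazard goes negative
        logu = np.where(ok, np.log(usafe), np.log(eps) + (u - eps) / eps)
        ll = d * logu - Lam
        n = t.size
        f = -ll.sum() / n
        if not want_grad:
            return f
        w = np.where(ok, 1.0 / usafe, 1.0 / eps)
        coef_eta = d * w * lam - Lam
        coef_ds = d * w * Lam / t
        g = -(Xeta.T @ coef_eta + Xd.T @ coef_ds) / n
        return f, g

    def _nll_mean(self, theta):
        return self._nll_core(theta, *self._fit_data, want_grad=False)

    def _grad_mean(self, theta):
        return self._nll_core(theta, *self._fit_data, want_grad=True)[1]

    def _grad_total(self, theta):
        return self._grad_mean(theta) * self.n_

    def _flag_negative_excess(self, Xeta, Xd, time, event, hstar):
        ds = Xd @ self.params_
        lam = np.exp(np.clip(Xeta @ self.params_, -200, 200)) * ds / time
        self.n_negative_excess_ = int((lam < 0).sum())
        # warn only where it bites the likelihood: events with h* + lambda <= 0
        bad = int(((hstar + lam <= 0) & (event == 1)).sum())
        if bad:
            warnings.warn(f"{bad} event records have non-positive fitted total "
                          "hazard at the MLE (soft barrier active)", stacklevel=3)

    # -- prediction plumbing -------------------------------------------------
    def _design_for(self, t, pattern=None):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t <= 0):
            raise ValueError("prediction times must be positive")
        x = np.log(t)
        pattern = pattern or {}
        known = ({c for c, _ in self.design_.spec_}
                 | {c for c, _ in self.td_design_.spec_})
        if set(pattern) - known:
            raise KeyError(f"pattern names {sorted(set(pattern) - known)} "
                           "are not model covariates")
        zrow = self.design_.pattern_row(
            {k: v for k, v in pattern.items()
             if k in {c for c, _ in self.design_.spec_}})
        Z = np.tile(zrow, (t.size, 1))
        ztd = self.td_design_.pattern_row(
            {k: v for k, v in pattern.items()
             if k in {c for c, _ in self.td_design_.spec_}})
        Ztd = np.tile(ztd, (t.size, 1))
        return self._design_matrices(x, Z, Ztd)

    def linear_predictor(self, t, pattern=None, theta=None):
        """eta(ln t) = ln Lambda(t) at a covariate pattern."""
        theta = self.params_ if theta is None else theta
        Xeta, _ = self._design_for(t, pattern)
        return Xeta @ theta

    def linear_predictor_design(self, t, pattern=None):
        return self._design_for(t, pattern)[0]

    def excess_cumhaz(self, t, pattern=None, theta=None):
        return np.exp(self.linear_predictor(t, pattern, theta))

    def excess_hazard(self, t, pattern=None, theta=None):
        theta = self.params_ if theta is None else theta
        t = np.atleast_1d(np.asarray(t, dtype=float))
        Xeta, Xd = self._design_for(t, pattern)
        return np.exp(Xeta @ theta) * (Xd @ theta) / t

    def relative_survival(self, t, pattern=None, theta=None):
        return np.exp(-self.excess_cumhaz(t, pattern, theta))

    def cure_linear_predictor(self, pattern=None, theta=None):
        """gamma00 + z'beta: the log cumulative excess hazard at/beyond the
        last knot (only a cure transform when ``cure=True``)."""
        lp = self.linear_predictor(np.exp(self.knots_[-1]), pattern, theta)
        return float(lp[0])

    def cure_design_row(self, pattern=None):
        return self.linear_predictor_design(np.exp(self.knots_[-1]), pattern)[0]


# ---------------------------------------------------------------------------
# Weibull mixture / non-mixture cure models
# ---------------------------------------------------------------------------

class WeibullCureModel(_RelativeSurvivalEstimator):
    """Weibull mixture or non-mixture cure model for relative survival.

    Mixture: ``R(t) = pi + (1 - pi) exp(-(lam t)^... )`` with Weibull
    survival of the uncured ``S_u(t) = exp(-scale * t^shape)``.
    Non-mixture: ``R(t) = pi^{F_Z(t)}`` with Weibull distribution function
    ``F_Z(t) = 1 - exp(-scale * t^shape)``.

    ``pi`` is linked via log(-log); scale and shape via log.  Covariates may
    enter the cure proportion (``covariates``), the log scale
    (``scale_covariates``) and the log shape (``shape_covariates``).
    """

    def __init__(self, kind="nonmixture", covariates=None, scale_covariates=None,
                 shape_covariates=None, ratetable=None,
                 age_col="age", sex_col="sex", year_col="year", max_iter=500):
        self.kind = kind
        self.covariates = covariates
        self.scale_covariates = scale_covariates
        self.shape_covariates = shape_covariates
        self.ratetable = ratetable
        self.age_col = age_col
        self.sex_col = sex_col
        self.year_col = year_col
        self.max_iter = max_iter

    @property
    def family(self) -> str:
        return f"weibull_{self.kind}"

    def fit(self, X, y):
        if self.kind not in ("mixture", "nonmixture"):
            raise ValueError("kind must be 'mixture' or 'nonmixture'")
        X, time, event, hstar = self._prepare(X, y)
        n = time.size
        self.design_ = CovariateDesign(self.covariates).fit(X)
        self.scale_design_ = CovariateDesign(self.scale_covariates).fit(X)
        self.shape_design_ = CovariateDesign(self.shape_covariates).fit(X)
        Zc = self.design_.transform(X)
        Za = self.scale_design_.transform(X)
        Zb = self.shape_design_.transform(X)
        self._blocks = (1 + Zc.shape[1], 1 + Za.shape[1], 1 + Zb.shape[1])
        self.param_names_ = (
            ["cure:Intercept"] + [f"cure:{nm}" for nm in self.design_.names_]
            + ["lnscale:Intercept"] + [f"lnscale:{nm}" for nm in self.scale_design_.names_]
            + ["lnshape:Intercept"] + [f"lnshape:{nm}" for nm in self.shape_design_.names_]
        )
        self.n_, self.n_events_ = n, int(event.sum())
        self._fit_data = (Zc, Za, Zb, time, event.astype(float), hstar)

        # crude data-driven start: cure ~ censored fraction, exponential scale
        pi0 = float(np.clip(1.0 - event.mean(), 0.05, 0.9))
        rate0 = max(event.sum() / time.sum(), 1e-10)
        theta0 = np.zeros(sum(self._blocks))
        theta0[0] = np.log(-np.log(pi0))
        theta0[self._blocks[0]] = np.log(rate0)
        theta, f, ginf, trace = _maximize_loglik(
            self._nll_mean, None, theta0, max_iter=self.max_iter)
        self._finalize(theta, f, ginf, trace, n)
        return self

    def _split(self, theta):
        p1, p2, p3 = self._blocks
        return theta[:p1], theta[p1:p1 + p2], theta[p1 + p2:]

    def _curves(self, theta, t, Zc, Za, Zb):
        """Return (Lambda, lambda) for the excess component."""
        thc, tha, thb = self._split(theta)
        c = thc[0] + Zc @ thc[1:]
        lnsc = tha[0] + Za @ tha[1:]
        lnsh = thb[0] + Zb @ thb[1:]
        sc = np.exp(np.clip(lnsc, -50, 50))
        sh = np.exp(np.clip(lnsh, -10, 10))
        w = np.clip(sc * t ** sh, 1e-300, 500.0)  # Weibull cumulative hazard
        Sw = np.exp(-w)  # Weibull survival exp(-scale t^shape)
        fw = sc * sh * t ** (sh - 1.0) * Sw  # Weibull density
        theta_c = np.exp(np.clip(c, -200, 200))  # -ln(pi)
        if self.kind == "nonmixture":
            F = 1.0 - Sw
            Lam = theta_c * F
            lam = theta_c * fw
        else:  # mixture
            pi = np.exp(-theta_c)
            R = pi + (1.0 - pi) * Sw
            Lam = -np.log(np.clip(R, 1e-300, None))
            lam = (1.0 - pi) * fw / np.clip(R, 1e-300, None)
        return Lam, lam

    def _nll_mean(self, theta):
        Zc, Za, Zb, t, d, hstar = self._fit_data
        Lam, lam = self._curves(theta, t, Zc, Za, Zb)
        u = hstar + lam
        eps = 1e-8
        logu = np.where(u > eps, np.log(np.clip(u, eps, None)),
                        np.log(eps) + (u - eps) / eps)
        return -(d * logu - Lam).sum() / t.size

    def _grad_mean(self, theta):
        return _fd_grad(self._nll_mean, theta)

    def _grad_total(self, theta):
        return self._grad_mean(theta) * self.n_

    # -- prediction plumbing -------------------------------------------------
    def _pattern_designs(self, pattern, m):
        zc = np.tile(self.design_.pattern_row(pattern), (m, 1))
        za = np.tile(self.scale_design_.pattern_row(pattern), (m, 1))
        zb = np.tile(self.shape_design_.pattern_row(pattern), (m, 1))
        return zc, za, zb

    def excess_cumhaz(self, t, pattern=None, theta=None):
        theta = self.params_ if theta is None else theta
        t = np.atleast_1d(np.asarray(t, dtype=float))
        Zc, Za, Zb = self._pattern_designs(pattern, t.size)
        return self._curves(theta, t, Zc, Za, Zb)[0]

    def excess_hazard(self, t, pattern=None, theta=None):
        theta = self.params_ if theta is None else theta
        t = np.atleast_1d(np.asarray(t, dtype=float))
        Zc, Za, Zb = self._pattern_designs(pattern, t.size)
        return self._curves(theta, t, Zc, Za, Zb)[1]

    def relative_survival(self, t, pattern=None, theta=None):
        return np.exp(-self.excess_cumhaz(t, pattern, theta))

    def cure_linear_predictor(self, pattern=None, theta=None):
        theta = self.params_ if theta is None else theta
        thc, _, _ = self._split(theta)
        return float(thc[0] + self.design_.pattern_row(pattern) @ thc[1:])

    def cure_design_row(self, pattern=None):
        row = np.zeros(self.params_.size)
        row[0] = 1.0
        row[1:self._blocks[0]] = self.design_.pattern_row(pattern)
        return row

    def as_mixture(self, pattern=None):
        """Mixture-form components (pi, S_u) of a fitted non-mixture model.

        The non-mixture model ``R = pi^F`` is algebraically a mixture with
        ``S_u(t) = (pi^F(t) - pi) / (1 - pi)``; returns ``(pi, S_u)`` with
        ``S_u`` a callable on time.
        """
        pi = float(np.exp(-np.exp(self.cure_linear_predictor(pattern))))

        def S_u(t):
            R = self.relative_survival(t, pattern)
            return (R - pi) / (1.0 - pi)

        return pi, S_u


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

LRT_CAVEAT = ("The likelihood-ratio test compares fit over the whole time "
              "scale, not just the end where cure is estimated; the cure "
              "assumption and model fit should be assessed graphically.")


def lrt_cure(restricted, unrestricted):
    """Likelihood-ratio test of the cure (zero linear spline term) restriction.

    Returns ``(statistic, df, p)``.  The statistic is ``2 * (l_unres -
    l_res)``; ``df`` is the number of restricted coefficients.  A significant
    result rejects that the linear term is zero (i.e. that cure is reached)
    — interpret with caution and prefer graphical assessment.
    """
    for m in (restricted, unrestricted):
        if not hasattr(m, "loglik_"):
            raise ValueError("both models must be fitted")
    if not (isinstance(restricted, FlexibleParametricModel)
            and isinstance(unrestricted, FlexibleParametricModel)):
        raise ValueError("the cure LRT applies to flexible parametric models")
    if not restricted.cure or unrestricted.cure:
        raise ValueError("pass (restricted cure model, unrestricted model)")
    if restricted.n_ != unrestricted.n_ or restricted.n_events_ != unrestricted.n_events_:
        raise ValueError("models were not fitted on the same data")
    if not np.allclose(restricted.knots_, unrestricted.knots_):
        raise ValueError("models must share the same knots to be nested")
    df = len(unrestricted.params_) - len(restricted.params_)
    if df <= 0:
        raise ValueError("the unrestricted model has no extra parameters")
    stat = max(2.0 * (unrestricted.loglik_ - restricted.loglik_), 0.0)
    return stat, df, float(stats.chi2.sf(stat, df))


def information_criteria(model, n_convention="subjects"):
    """(AIC, BIC) with p = number of estimated parameters.

    ``n_convention`` selects the BIC sample size: "subjects" (default) or
    "events".
    """
    p = len(model.params_)
    n = model.n_ if n_convention == "subjects" else model.n_events_
    aic = -2.0 * model.loglik_ + 2.0 * p
    bic = -2.0 * model.loglik_ + p * np.log(n)
    return aic, bic


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimator surface
# ---------------------------------------------------------------------------

def loglik_flexible(params, data, ratetable, model: FlexibleParametricModel):
    """Total flexible-model log-likelihood at ``params`` (fitted design)."""
    del data, ratetable  # bound into the fitted estimator
    return model.loglikelihood(params)


def loglik_weibull_cure(params, data, ratetable, model: WeibullCureModel):
    """Total Weibull cure-model log-likelihood at ``params``."""
    del data, ratetable
    return model.loglikelihood(params)


def fit(spec: dict, data, ratetable=None):
    """Fit a model described by a spec dict (``family`` plus estimator
    keyword arguments); returns the fitted estimator."""
    spec = dict(spec)
    family = spec.pop("family")
    df = records_to_frame(data)
    y = (df["time"].to_numpy(float), df["event"].to_numpy(int))
    if family in ("flexible", "flexible_cure"):
        est = FlexibleParametricModel(cure=(family == "flexible_cure"),
                                      ratetable=ratetable, **spec)
    elif family in ("weibull_mixture", "weibull_nonmixture"):
        est = WeibullCureModel(kind=family.removeprefix("weibull_"),
                               ratetable=ratetable, **spec)
    else:
        raise ValueError(f"unknown model family {family!r}")
    return est.fit(df, y)
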