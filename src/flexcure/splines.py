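"""Restricted cubic spline bases on log time.

Both the standard (Royston–Parmar) basis and the "backward" basis, in which
the knots are treated in reversed order so that every non-linear basis column
vanishes at and beyond the last knot.  Constraining the coefficient of the
linear column to zero then forces the represented function — the log
cumulative excess hazard — to be constant from the last knot onward, which is
the statistical-cure restriction.

All spline work is carried out on ``x = ln(t)`` with ``t`` in years.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "KnotSet",
    "RestrictedCubicSpline",
    "basis_standard",
    "basis_backward",
    "basis_derivative",
    "orthogonalize",
    "resolve_knots",
    "SENSITIVITY_KNOT_RULES",
]


class InvalidKnotsError(ValueError):
    """Raised when a knot vector is unusable (unsorted, duplicated, K < 2)."""


class KnotSet:
    """Strictly increasing knot positions on the log-time axis.

    Parameters
    ----------
    knots : array-like
        Positions ``k_1 < k_2 < ... < k_K`` on the log-time scale, K >= 2.
    """

    def __init__(self, knots):
        k = np.asarray(knots, dtype=float).ravel()
        if k.size < 2:
            raise InvalidKnotsError(f"need at least 2 knots, got {k.size}")
        if not np.all(np.isfinite(k)):
            raise InvalidKnotsError("knots must be finite")
        if np.any(np.diff(k) <= 0):
            raise InvalidKnotsError(f"knots must be strictly increasing: {k}")
        self.knots = k

    @property
    def K(self) -> int:
        return self.knots.size

    @property
    def first(self) -> float:
        return float(self.knots[0])

    @property
    def last(self) -> float:
        return float(self.knots[-1])

    def __repr__(self) -> str:  # pragma: no cover
        return f"KnotSet({np.array2string(self.knots, precision=4)})"


def _cube_pos(u: np.ndarray) -> np.ndarray:
    """(u)_+^3 : cubed positive part."""
    return np.where(u > 0.0, u, 0.0) ** 3


def _cube_pos_deriv(u: np.ndarray) -> np.ndarray:
    """d/du of (u)_+^3 = 3 (u)_+^2."""
    return 3.0 * np.where(u > 0.0, u, 0.0) ** 2


def basis_standard(x, knotset: KnotSet) -> np.ndarray:
    """Standard restricted cubic spline basis, K-1 columns per point.

    Column 1 is the identity v1(x) = x; columns j = 2..K-1 are
    ``(x-kj)_+^3 - lam_j (x-k1)_+^3 - (1-lam_j)(x-kK)_+^3`` with
    ``lam_j = (kK-kj)/(kK-k1)``, which makes the function linear outside
    [k1, kK].  All non-linear columns are exactly 0 for x <= k1.
    """
    if not isinstance(knotset, KnotSet):
        knotset = KnotSet(knotset)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    k = knotset.knots
    K = knotset.K
    out = np.empty((x.size, K - 1))
    out[:, 0] = x
    k1, kK = k[0], k[-1]
    for j in range(2, K):
        kj = k[j - 1]
        lam = (kK - kj) / (kK - k1)
        out[:, j - 1] = (
            _cube_pos(x - kj) - lam * _cube_pos(x - k1) - (1.0 - lam) * _cube_pos(x - kK)
        )
    return out


def basis_backward(x, knotset: KnotSet) -> np.ndarray:
    """Backward-calculated restricted cubic spline basis.

    The knots are treated in reversed order: column 1 is still v1(x) = x, but
    for j = 2..K-1 the truncation runs from the right,

        vj(x) = (k_{K-j+1} - x)_+^3 - mu_j (kK - x)_+^3 - (1-mu_j)(k1 - x)_+^3,
        mu_j  = (k_{K-j+1} - k1) / (kK - k1),

    so every non-linear column is exactly 0 for x >= kK and linearity below
    k1 is preserved.  A coefficient vector with zero weight on column 1 then
    represents a function that is constant on [kK, inf).
    """
    if not isinstance(knotset, KnotSet):
        knotset = KnotSet(knotset)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    k = knotset.knots
    K = knotset.K
    out = np.empty((x.size, K - 1))
    out[:, 0] = x
    k1, kK = k[0], k[-1]
    for j in range(2, K):
        kj = k[K - j]  # k_{K-j+1} in 1-based indexing
        mu = (kj - k1) / (kK - k1)
        out[:, j - 1] = (
            _cube_pos(kj - x) - mu * _cube_pos(kK - x) - (1.0 - mu) * _cube_pos(k1 - x)
        )
    return out


def basis_derivative(x, knotset: KnotSet, direction: str = "standard") -> np.ndarray:
    """Analytic derivative d v_j / d x of each basis column."""
    if not isinstance(knotset, KnotSet):
        knotset = KnotSet(knotset)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    k = knotset.knots
    K = knotset.K
    out = np.empty((x.size, K - 1))
    out[:, 0] = 1.0
    k1, kK = k[0], k[-1]
    if direction == "standard":
        for j in range(2, K):
            kj = k[j - 1]
            lam = (kK - kj) / (kK - k1)
            out[:, j - 1] = (
                _cube_pos_deriv(x - kj)
                - lam * _cube_pos_deriv(x - k1)
                - (1.0 - lam) * _cube_pos_deriv(x - kK)
            )
    elif direction == "backward":
        for j in range(2, K):
            kj = k[K - j]
            mu = (kj - k1) / (kK - k1)
            out[:, j - 1] = -(
                _cube_pos_deriv(kj - x)
                - mu * _cube_pos_deriv(kK - x)
                - (1.0 - mu) * _cube_pos_deriv(k1 - x)
            )
    else:
        raise ValueError(f"direction must be 'standard' or 'backward', got {direction!r}")
    return out


def orthogonalize(basis: np.ndarray):
    """Gram–Schmidt orthogonalisation of spline columns against a constant.

    Returns ``(transformed, R)`` where ``R`` is the (p+1)x(p+1) upper
    triangular matrix from the reduced QR factorisation of ``[1 | basis]``
    scaled by sqrt(n); replaying the transform on new points is
    ``[1 | basis_new] @ inv(R)`` dropping the leading (constant) column.
    The transform is invertible, so fitted models are reparameterisations of
    the raw-basis model.
    """
    basis = np.asarray(basis, dtype=float)
    n = basis.shape[0]
    aug = np.column_stack([np.ones(n), basis])
    q, r = np.linalg.qr(aug)
    # normalise so the transform is scale-free in n and diag(R) > 0
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    r = (signs[:, None] * r) / np.sqrt(n)
    diag = np.abs(np.diag(r))
    if np.any(diag < 1e-12 * max(diag.max(), 1.0)):
        bad = int(np.argmin(diag)) - 1
        raise np.linalg.LinAlgError(
            f"basis is rank deficient: column {bad} is collinear with earlier columns"
        )
    transformed = _apply_transform(basis, r)
    return transformed, r


def _apply_transform(basis: np.ndarray, r: np.ndarray) -> np.ndarray:
    n = basis.shape[0]
    aug = np.column_stack([np.ones(n), basis])
    from scipy.linalg import solve_triangular

    out = solve_triangular(r, aug.T, lower=False, trans="T").T
    return out[:, 1:]


class RestrictedCubicSpline(TransformerMixin, BaseEstimator):
    """Restricted cubic spline transformer on log time.

    A scikit-learn style transformer: ``fit`` resolves the orthogonalisation
    transform (and the centering values at the last knot) on the training
    points; ``transform`` evaluates the basis — identically parameterised —
    at new points.

    Parameters
    ----------
    knots : array-like
        Knot positions on the log-time scale (strictly increasing, K >= 2).
    direction : {"standard", "backward"}
        Standard Royston–Parmar truncation (non-linear terms vanish below the
        first knot) or backward truncation (they vanish above the last knot).
    include_linear : bool
        Whether the linear column v1(x) = x is part of the basis.  The cure
        restriction is imposed structurally by dropping it
        (``include_linear=False`` with ``direction="backward"``).
    orthogonalize : bool
        Gram–Schmidt orthogonalise the columns (against a constant) using the
        training sample.
    center_last_knot : bool
        Subtract from every column its value at the last knot, so that all
        columns evaluate to exactly 0 at and beyond ``kK`` (restoring the
        direct cure interpretation of the intercept after orthogonalisation).

    Attributes
    ----------
    knotset_ : KnotSet
    transform_r_ : ndarray or None
        Recorded upper-triangular orthogonalisation transform.
    center_ : ndarray
        Values subtracted from each column (zeros when centering is off).
    """

    def __init__(self, knots=None, direction="standard", include_linear=True,
                 orthogonalize=False, center_last_knot=False):
        self.knots = knots
        self.direction = direction
        self.include_linear = include_linear
        self.orthogonalize = orthogonalize
        self.center_last_knot = center_last_knot

    # -- raw (pre-orthogonalisation) basis ---------------------------------
    def _raw(self, x):
        if self.direction == "standard":
            b = basis_standard(x, self.knotset_)
        elif self.direction == "backward":
            b = basis_backward(x, self.knotset_)
        else:
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.include_linear:
            b = b[:, 1:]
        return b

    def _raw_deriv(self, x):
        d = basis_derivative(x, self.knotset_, self.direction)
        if not self.include_linear:
            d = d[:, 1:]
        return d

    def fit(self, X, y=None):
        self.knotset_ = KnotSet(self.knots)
        x = np.asarray(X, dtype=float).ravel()
        raw = self._raw(x)
        self.n_features_out_ = raw.shape[1]
        if self.n_features_out_ == 0:
            self.transform_r_ = None
            self.center_ = np.zeros(0)
            return self
        if self.orthogonalize:
            _, r = orthogonalize(raw)
            self.transform_r_ = r
        else:
            self.transform_r_ = None
        self.center_ = np.zeros(self.n_features_out_)
        if self.center_last_knot:
            at_last = self._eval(np.array([self.knotset_.last]))
            self.center_ = at_last[0].copy()
        return self

    def _eval(self, x):
        raw = self._raw(x)
        if self.transform_r_ is not None:
            raw = _apply_transform(raw, self.transform_r_)
        return raw

    def transform(self, X):
        x = np.asarray(X, dtype=float).ravel()
        if self.n_features_out_ == 0:
            return np.zeros((x.size, 0))
        return self._eval(x) - self.center_

    def derivative(self, X):
        """d(basis)/dx at the given log-time points (centering drops out)."""
        x = np.asarray(X, dtype=float).ravel()
        if self.n_features_out_ == 0:
            return np.zeros((x.size, 0))
        d = self._raw_deriv(x)
        if self.transform_r_ is not None:
            # derivative of [1|raw] @ inv(R) dropping the constant column:
            # the constant column has derivative 0
            from scipy.linalg import solve_triangular

            aug = np.column_stack([np.zeros(x.size), d])
            d = solve_triangular(self.transform_r_, aug.T, lower=False, trans="T").T[:, 1:]
        return d


# ---------------------------------------------------------------------------
# knot placement rules
# ---------------------------------------------------------------------------

#: The six knot-placement rules of the sensitivity protocol, as rule strings.
#: Centiles refer to centiles of log observed death times; "fixed <y>" pins a
#: knot at ln(<y> years); "years ..." pins knots at ln of follow-up years with
#: "first"/"last" meaning the first/last observed death time.
SENSITIVITY_KNOT_RULES = (
    "centiles 0 20 40 60 80 100",
    "centiles 0 25 50 75 95 100",
    "centiles 0 35 65 80 95 100",
    "centiles 0 35 65 75 85 95",
    "years first 3 5 7 8 last",
    "centiles 0 25 50 75 95 + fixed 12",
)


def resolve_knots(rule, death_times=None) -> np.ndarray:
    """Resolve a knot rule into log-time knot positions.

    ``rule`` may be an array of log-time positions (used as-is), or a string:

    - ``"centiles 0 25 50 75 95 100"`` — centiles of log observed death times;
    - ``"centiles 0 25 50 75 95 + fixed 12"`` — centiles plus a knot pinned at
      ln(12 years);
    - ``"years first 3 5 7 8 last"`` — knots at ln(years), with ``first`` and
      ``last`` the first and last observed death times.

    ``death_times`` (years, events only) is required for centile/first/last
    rules.
    """
    if not isinstance(rule, str):
        return KnotSet(rule).knots

    toks = rule.split()
    if toks[0] == "centiles":
        fixed = []
        if "+" in toks:
            plus = toks.index("+")
            if toks[plus + 1] != "fixed":
                raise ValueError(f"cannot parse knot rule {rule!r}")
            fixed = [np.log(float(v)) for v in toks[plus + 2:]]
            toks = toks[:plus]
        pct = [float(v) for v in toks[1:]]
        if death_times is None:
            raise ValueError("centile knot rules need observed death times")
        logd = np.log(np.asarray(death_times, dtype=float))
        knots = np.percentile(logd, pct).tolist() + fixed
    elif toks[0] == "years":
        knots = []
        for v in toks[1:]:
            if v in ("first", "last"):
                if death_times is None:
                    raise ValueError("'first'/'last' knot rules need death times")
                t = np.min(death_times) if v == "first" else np.max(death_times)
                knots.append(np.log(float(t)))
            else:
                knots.append(np.log(float(v)))
    else:
        raise ValueError(f"cannot parse knot rule {rule!r}")
    knots = np.unique(np.asarray(knots, dtype=float))
    return KnotSet(knots).knots
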