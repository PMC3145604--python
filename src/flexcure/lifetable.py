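"""Population rate tables and Ederer II life-table relative survival.

A :class:`RateTable` holds expected (background) mortality rates of the
general population indexed by attained age, calendar year and sex.  It
supplies the expected hazard ``h*(t)``, the expected cumulative hazard
``H*(t)`` and the expected survival ``S*(t)`` for an individual diagnosed at
a given age and calendar year, under the usual piecewise-constant convention:
rates are constant within one-year age x calendar-year cells, attained age
and year are indexed by completed years (floor), and lookups beyond the
table's declared ranges use the boundary cell.

:func:`ederer2` computes actuarial life-table relative survival where the
expected component follows only the patients still at risk at the start of
each interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RateTable",
    "SurvivalRecord",
    "LifeTableEstimate",
    "expected_hazard_at",
    "expected_cum_hazard",
    "ederer2",
    "default_intervals",
]


@dataclass
class SurvivalRecord:
    """One subject: follow-up, event flag and lifetable-matching attributes.

    ``time`` is years from diagnosis (> 0), ``event`` 1 for death and 0 for
    censoring; ``covariates`` holds any additional modelling variables.
    """

    time: float
    event: int
    age_dx: float
    sex: str
    year_dx: float
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError(f"time must be finite and positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


def records_to_frame(records) -> pd.DataFrame:
    """Convert SurvivalRecord objects (or pass through a DataFrame)."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        row = dict(time=r.time, event=r.event, age=r.age_dx, sex=r.sex, year=r.year_dx)
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


class RateTable:
    """Expected mortality rates by age x calendar year x sex.

    Parameters
    ----------
    frame : DataFrame
        Columns ``age`` (integer years), ``year`` (integer calendar year),
        ``sex`` and ``rate`` (deaths per person-year), or ``prob`` (annual
        death probability, converted via ``rate = -ln(1 - prob)``).

    Rates must be finite and non-negative with unique (age, year, sex) keys
    and contiguous coverage over the declared age and year ranges.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if "rate" not in frame.columns:
            if "prob" in frame.columns:
                q = frame["prob"].to_numpy(dtype=float)
                if np.any(q >= 1) or np.any(q < 0):
                    raise ValueError("annual death probabilities must be in [0, 1)")
                frame["rate"] = -np.log1p(-q)
            else:
                raise ValueError("rate table needs a 'rate' or 'prob' column")
        for col in ("age", "year", "sex"):
            if col not in frame.columns:
                raise ValueError(f"rate table is missing column {col!r}")
        rates = frame["rate"].to_numpy(dtype=float)
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise ValueError("rates must be finite and >= 0")

        self.age_min = int(frame["age"].min())
        self.age_max = int(frame["age"].max())
        self.year_min = int(frame["year"].min())
        self.year_max = int(frame["year"].max())
        self.sexes = sorted(frame["sex"].astype(str).unique())
        n_age = self.age_max - self.age_min + 1
        n_year = self.year_max - self.year_min + 1

        self._grid = np.full((n_age, n_year, len(self.sexes)), np.nan)
        ai = frame["age"].to_numpy(dtype=int) - self.age_min
        yi = frame["year"].to_numpy(dtype=int) - self.year_min
        si = np.array([self.sexes.index(s) for s in frame["sex"].astype(str)])
        if len({(a, y, s) for a, y, s in zip(ai, yi, si)}) != len(frame):
            raise ValueError("duplicate (age, year, sex) keys in rate table")
        self._grid[ai, yi, si] = rates
        if np.any(np.isnan(self._grid)):
            raise ValueError("rate table coverage is not contiguous over its ranges")
        self._frame = frame[["age", "year", "sex", "rate"]].reset_index(drop=True)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read_csv(cls, path, sep=",", dialect="rate"):
        """Read a delimited rate table; ``dialect`` 'rate' or 'prob'."""
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        if dialect == "prob" and "rate" in df.columns:
            df = df.rename(columns={"rate": "prob"})
        return cls(df)

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def write_csv(self, path, sep=","):
        self._frame.to_csv(path, sep=sep, index=False)

    # -- lookups -----------------------------------------------------------
    def _sex_index(self, sex) -> np.ndarray:
        sex = np.atleast_1d(np.asarray(sex)).astype(str)
        lut = {s: i for i, s in enumerate(self.sexes)}
        try:
            return np.array([lut[s] for s in sex])
        except KeyError as e:
            raise KeyError(
                f"sex level {e.args[0]!r} not in rate table (has {self.sexes})"
            ) from None

    def rate_at(self, age, year, sex) -> np.ndarray:
        """Rate for attained age/year (floored, capped at table boundaries)."""
        ai = np.clip(np.floor(np.atleast_1d(age)).astype(int) - self.age_min,
                     0, self.age_max - self.age_min)
        yi = np.clip(np.floor(np.atleast_1d(year)).astype(int) - self.year_min,
                     0, self.year_max - self.year_min)
        si = self._sex_index(sex)
        return self._grid[ai, yi, si]


class _PiecewiseExpectedHazard:
    """Per-subject expected-hazard trajectories, vectorised.

    For subjects diagnosed at (age, year, sex), the expected hazard as a
    function of time since diagnosis is piecewise constant with breaks at
    every crossing of an integer attained age or calendar year.  This class
    precomputes, over a horizon, per-subject break times, segment rates and
    cumulative hazards, enabling fast evaluation of h*(t), H*(t) and
    inverse-cumulative-hazard sampling of background death times.
    """

    def __init__(self, table: RateTable, age, year, sex, horizon: float):
        age = np.atleast_1d(np.asarray(age, dtype=float))
        year = np.atleast_1d(np.asarray(year, dtype=float))
        n = age.size
        m = int(np.ceil(horizon)) + 1
        # candidate breaks: crossings of integer attained age and year
        frac_a = 1.0 - (age - np.floor(age))
        frac_y = 1.0 - (year - np.floor(year))
        ks = np.arange(m, dtype=float)
        breaks = np.concatenate(
            [np.zeros((n, 1)),
             frac_a[:, None] + ks[None, :],
             frac_y[:, None] + ks[None, :],
             np.full((n, 1), float(horizon))],
            axis=1,
        )
        breaks = np.clip(breaks, 0.0, float(horizon))
        breaks.sort(axis=1)
        mid = 0.5 * (breaks[:, :-1] + breaks[:, 1:])
        si = table._sex_index(sex)
        ai = np.clip(np.floor(age[:, None] + mid).astype(int) - table.age_min,
                     0, table.age_max - table.age_min)
        yi = np.clip(np.floor(year[:, None] + mid).astype(int) - table.year_min,
                     0, table.year_max - table.year_min)
        self.rates = table._grid[ai, yi, si[:, None]]
        self.breaks = breaks
        seg = np.diff(breaks, axis=1) * self.rates
        self.cumhaz = np.concatenate(
            [np.zeros((n, 1)), np.cumsum(seg, axis=1)], axis=1
        )
        self.horizon = float(horizon)
        self.n = n

    def _segment_of(self, t: np.ndarray) -> np.ndarray:
        t = np.clip(t, 0.0, self.horizon)
        idx = (self.breaks[:, :-1] <= t[:, None]).sum(axis=1) - 1
        return np.clip(idx, 0, self.breaks.shape[1] - 2)

    def hazard_at(self, t) -> np.ndarray:
        t = np.broadcast_to(np.asarray(t, dtype=float), (self.n,)).copy()
        idx = self._segment_of(t)
        return self.rates[np.arange(self.n), idx]

    def cumhaz_at(self, t) -> np.ndarray:
        t = np.broadcast_to(np.asarray(t, dtype=float), (self.n,)).copy()
        t = np.clip(t, 0.0, self.horizon)
        idx = self._segment_of(t)
        rows = np.arange(self.n)
        return self.cumhaz[rows, idx] + (t - self.breaks[rows, idx]) * self.rates[rows, idx]

    def sample_death_times(self, u: np.ndarray) -> np.ndarray:
        """Invert H*(t) = -ln(u); inf where death falls beyond the horizon."""
        target = -np.log(u)
        rows = np.arange(self.n)
        out = np.full(self.n, np.inf)
        reached = target < self.cumhaz[:, -1]
        idx = (self.cumhaz[:, :-1] <= target[:, None]).sum(axis=1) - 1
        idx = np.clip(idx, 0, self.breaks.shape[1] - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.breaks[rows, idx] + (target - self.cumhaz[rows, idx]) / self.rates[rows, idx]
        out[reached] = t[reached]
        return out


def expected_hazard_at(record, t, table: RateTable):
    """Expected (population) hazard for a subject at time t since diagnosis."""
    df = records_to_frame([record] if isinstance(record, SurvivalRecord) else record)
    return _expected_hazard_frame(df, np.asarray(t, dtype=float), table)


def _expected_hazard_frame(df: pd.DataFrame, t, table: RateTable) -> np.ndarray:
    age = df["age"].to_numpy(dtype=float)
    year = df["year"].to_numpy(dtype=float)
    t = np.broadcast_to(np.asarray(t, dtype=float), age.shape)
    out = table.rate_at(age + t, year + t, df["sex"].to_numpy())
    return out if out.size > 1 else float(out[0])


def expected_cum_hazard(record, t, table: RateTable):
    """Cumulative expected hazard H*(t), exact piecewise-constant integral."""
    df = records_to_frame([record] if isinstance(record, SurvivalRecord) else record)
    t = np.broadcast_to(np.asarray(t, dtype=float), (len(df),)).astype(float)
    pw = _PiecewiseExpectedHazard(
        table, df["age"].to_numpy(float), df["year"].to_numpy(float),
        df["sex"].to_numpy(), horizon=float(t.max()) + 1e-12,
    )
    out = pw.cumhaz_at(t)
    return out if out.size > 1 else float(out[0])


def default_intervals(horizon: float = 10.0) -> np.ndarray:
    """Monthly breaks over year 1, annual thereafter, up to the horizon."""
    months = np.arange(0, 13) / 12.0
    years = np.arange(2.0, np.floor(horizon) + 1.0)
    return np.unique(np.concatenate([months, years, [horizon]]))


@dataclass
class LifeTableEstimate:
    """Ederer II life-table relative survival with Greenwood variances."""

    table: pd.DataFrame  # one row per interval

    @property
    def relative_survival(self) -> np.ndarray:
        return self.table["cum_relative_survival"].to_numpy()

    @property
    def intervals(self) -> np.ndarray:
        return self.table["end"].to_numpy()

    def confidence_band(self, level: float = 0.95):
        """Log-scale confidence band for cumulative relative survival."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        r = self.table["cum_relative_survival"].to_numpy()
        se = self.table["se_log"].to_numpy()
        return r * np.exp(-z * se), r * np.exp(z * se)


def ederer2(records, table: RateTable, interval_breaks=None) -> LifeTableEstimate:
    """Ederer II actuarial relative survival.

    Per interval i: observed conditional survival
    ``p_i = 1 - d_i / (n_i - c_i/2)`` with the actuarial half-interval
    adjustment for censoring; expected conditional survival ``p*_i`` is the
    mean, over patients at risk at the interval start, of their individual
    expected survival across the interval (Ederer II: the expectation follows
    only those still at risk).  Cumulative relative survival is
    ``R = prod(p_i / p*_i)`` with Greenwood variance on the observed
    component.
    """
    df = records_to_frame(records)
    if len(df) == 0:
        raise ValueError("need at least one record")
    if interval_breaks is None:
        interval_breaks = default_intervals(float(df["time"].max()))
    breaks = np.asarray(interval_breaks, dtype=float)
    if breaks[0] != 0 or np.any(np.diff(breaks) <= 0):
        raise ValueError("interval breaks must start at 0 and increase")

    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    pw = _PiecewiseExpectedHazard(
        table, df["age"].to_numpy(float), df["year"].to_numpy(float),
        df["sex"].to_numpy(), horizon=float(breaks[-1]),
    )
    H_at = {b: pw.cumhaz_at(np.full(len(df), b)) for b in breaks}

    rows = []
    cum_obs = 1.0
    cum_rel = 1.0
    green = 0.0
    for b0, b1 in zip(breaks[:-1], breaks[1:]):
        at_risk = time >= b0
        n_i = int(at_risk.sum())
        if n_i == 0:
            import warnings

            warnings.warn(
                f"no patients at risk at {b0:g}y; life table truncated", stacklevel=2
            )
            break
        in_int = at_risk & (time < b1)
        d_i = int((in_int & (event == 1)).sum())
        c_i = int((in_int & (event == 0)).sum())
        n_eff = n_i - c_i / 2.0
        p_i = 1.0 - d_i / n_eff if n_eff > 0 else np.nan
        p_star = float(np.mean(np.exp(-(H_at[b1][at_risk] - H_at[b0][at_risk]))))
        cum_obs *= p_i
        cum_rel *= p_i / p_star
        if n_eff > d_i > 0:
            green += d_i / (n_eff * (n_eff - d_i))
        rows.append(dict(start=b0, end=b1, n_risk=n_i, deaths=d_i, censored=c_i,
                         p_obs=p_i, p_exp=p_star, cum_observed=cum_obs,
                         cum_relative_survival=cum_rel, se_log=np.sqrt(green)))
    return LifeTableEstimate(pd.DataFrame(rows))
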