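"""Model-ready dataset construction: response transforms, covariate encoding, calendar utilities.

Daily life satisfaction (LS, a 0-100 two-item mean) and physical activity
(PA, steps per valid wear-hour) are mapped to the real line before entering
the Gaussian VAR model:

* ``L = logit((ls_mean + 1) / 102)`` -- the +1/102 shift keeps both slider
  endpoints strictly inside (0, 1);
* ``P = log(pa_rate + 1)`` -- the +1 avoids log(0) on sedentary days.

Covariates enter the mean model as an ANCOVA-style linear predictor:
weekday (reference Monday), month (reference January), SES (reference
"below average"), education (reference non-university), gender (reference
female), region (reference low-pollution), plus continuous age and
day-in-study. Continuous covariates and the exercise-identity moderator are
standardized; the :class:`CovariateCodebook` records the statistics needed
to put fitted coefficients back on the original scale bit-exactly.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "transform_ls",
    "inverse_transform_ls",
    "transform_pa",
    "inverse_transform_pa",
    "inclusive_day_count",
    "weekday_occurrences",
    "CovariateCodebook",
    "encode_covariates",
    "ModelDataset",
    "build_model_dataset",
    "WEEKDAY_NAMES",
    "MONTH_NAMES",
]

WEEKDAY_NAMES = [
    "monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday",
]
MONTH_NAMES = [
    "january", "february", "march", "april", "may", "june",
    "july", "august", "september", "october", "november", "december",
]

#: categorical covariates: name -> (ordered levels, reference level)
CATEGORICAL_LEVELS = {
    "gender": (["female", "male"], "female"),
    "region": (["low_pollution", "high_pollution"], "low_pollution"),
    "education": (["non_university", "university"], "non_university"),
    "ses": (["below_average", "average", "above_average"], "below_average"),
}

CONTINUOUS_COVARIATES = ["age", "day_in_study"]


# ---------------------------------------------------------------------------
# response transforms
# ---------------------------------------------------------------------------

def transform_ls(ls_mean):
    """Logit transform of the LS slider mean: ``logit((ls_mean + 1) / 102)``.

    Defined for ``0 <= ls_mean <= 100``; strictly increasing, with
    ``transform_ls(50) == 0`` exactly.
    """
    x = np.asarray(ls_mean, dtype=float)
    if np.any((x < 0) | (x > 100)):
        raise ValueError("ls_mean must lie in [0, 100]")
    out = logit((x + 1.0) / 102.0)
    return float(out) if np.isscalar(ls_mean) else out


def inverse_transform_ls(L):
    """Inverse of :func:`transform_ls`: ``102 * expit(L) - 1`` (range (-1, 101))."""
    x = np.asarray(L, dtype=float)
    out = 102.0 * expit(x) - 1.0
    return float(out) if np.isscalar(L) else out


def transform_pa(pa_rate):
    """Log transform of the daily step rate: ``log(pa_rate + 1)``, requires rate >= 0."""
    x = np.asarray(pa_rate, dtype=float)
    if np.any(x < 0):
        raise ValueError("pa_rate must be non-negative")
    out = np.log1p(x)
    return float(out) if np.isscalar(pa_rate) else out


def inverse_transform_pa(P):
    """Inverse of :func:`transform_pa`: ``exp(P) - 1``."""
    x = np.asarray(P, dtype=float)
    out = np.expm1(x)
    return float(out) if np.isscalar(P) else out


# ---------------------------------------------------------------------------
# calendar utilities
# ---------------------------------------------------------------------------

def _as_date(d) -> _dt.date:
    if isinstance(d, _dt.datetime):
        return d.date()
    if isinstance(d, _dt.date):
        return d
    return pd.Timestamp(d).date()


def inclusive_day_count(start, end) -> int:
    """Number of calendar dates from ``start`` through ``end``, both inclusive."""
    start, end = _as_date(start), _as_date(end)
    if start > end:
        raise ValueError("start date must not be after end date")
    return (end - start).days + 1


def weekday_occurrences(start, end) -> dict:
    """Count each weekday (monday..sunday) in the inclusive date span."""
    start, end = _as_date(start), _as_date(end)
    n = inclusive_day_count(start, end)
    full, rem = divmod(n, 7)
    counts = {name: full for name in WEEKDAY_NAMES}
    w0 = start.weekday()
    for k in range(rem):
        counts[WEEKDAY_NAMES[(w0 + k) % 7]] += 1
    return counts


# ---------------------------------------------------------------------------
# covariate encoding
# ---------------------------------------------------------------------------

@dataclass
class CovariateCodebook:
    """Layout and standardization metadata of the encoded design matrix.

    ``columns`` lists the design columns in order (intercept first).
    ``continuous`` maps each standardized column to its sample (mean, sd).
    ``exid`` holds the (mean, sd) used to standardize the exercise-identity
    moderator. ``dropped`` lists indicator columns removed because the
    corresponding level never occurs in the dataset (they would be
    unidentifiable under the flat coefficient prior). When a *reference*
    level is absent, the group's indicators would sum to the intercept, so
    the first observed level is promoted to reference instead and recorded
    in ``re_referenced``.
    """

    columns: list
    continuous: dict
    exid: tuple
    reference_levels: dict = field(default_factory=lambda: {
        "weekday": "monday",
        "month": "january",
        "ses": "below_average",
        "education": "non_university",
        "gender": "female",
        "region": "low_pollution",
    })
    dropped: list = field(default_factory=list)
    re_referenced: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "columns": list(self.columns),
            "continuous": {k: list(map(float, v)) for k, v in self.continuous.items()},
            "exid": list(map(float, self.exid)),
            "reference_levels": self.reference_levels,
            "dropped": list(self.dropped),
            "re_referenced": dict(self.re_referenced),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CovariateCodebook":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            columns=payload["columns"],
            continuous={k: tuple(v) for k, v in payload["continuous"].items()},
            exid=tuple(payload["exid"]),
            reference_levels=payload["reference_levels"],
            dropped=payload["dropped"],
            re_referenced=payload.get("re_referenced", {}),
        )


def raw_covariate_row(date, participant: dict, entry_date) -> dict:
    """Raw (unstandardized) covariate values for one person-day.

    Indicator entries are 0/1; ``age`` is in years and ``day_in_study``
    counts days since the person's own first study day (entry day = 0).
    Used both by the synthetic generator (with original-scale coefficients)
    and by :func:`encode_covariates` (which then standardizes).
    """
    date = _as_date(date)
    row = {"intercept": 1.0}
    wd = WEEKDAY_NAMES[date.weekday()]
    for name in WEEKDAY_NAMES[1:]:
        row[f"weekday_{name}"] = 1.0 if wd == name else 0.0
    mo = MONTH_NAMES[date.month - 1]
    for name in MONTH_NAMES[1:]:
        row[f"month_{name}"] = 1.0 if mo == name else 0.0
    for cov, (levels, ref) in CATEGORICAL_LEVELS.items():
        value = participant[cov]
        if value not in levels:
            raise ValueError(f"unseen level {value!r} for covariate {cov!r}")
        for level in levels:
            if level != ref:
                row[f"{cov}_{level}"] = 1.0 if value == level else 0.0
    row["age"] = float(participant["age"])
    row["day_in_study"] = float((date - _as_date(entry_date)).days)
    return row


def raw_design_columns() -> list:
    """Ordered names of the full raw design (before any column drops)."""
    cols = ["intercept"]
    cols += [f"weekday_{n}" for n in WEEKDAY_NAMES[1:]]
    cols += [f"month_{n}" for n in MONTH_NAMES[1:]]
    for cov, (levels, ref) in CATEGORICAL_LEVELS.items():
        cols += [f"{cov}_{lev}" for lev in levels if lev != ref]
    cols += CONTINUOUS_COVARIATES
    return cols


def raw_design_frame(participants: pd.DataFrame, daily: pd.DataFrame,
                     entry_dates: pd.Series | None = None) -> pd.DataFrame:
    """Full raw design (0/1 indicators, age in years, day-in-study in days).

    One row per ``daily`` row, columns ordered as :func:`raw_design_columns`.
    Used directly by the synthetic generator (whose true coefficients live on
    the original covariate scale) and standardized by
    :func:`encode_covariates` for fitting.
    """
    part = participants.set_index("person_id")
    for cov, (levels, _) in CATEGORICAL_LEVELS.items():
        bad = set(part[cov]) - set(levels)
        if bad:
            raise ValueError(f"unseen level(s) {sorted(bad)!r} for covariate {cov!r}")
    dates = pd.to_datetime(daily["date"])
    if entry_dates is None:
        entry_dates = dates.groupby(daily["person_id"].values).min()
    entry = daily["person_id"].map(entry_dates)

    X = pd.DataFrame(index=daily.index)
    X["intercept"] = 1.0
    wd = dates.dt.weekday
    for j, name in enumerate(WEEKDAY_NAMES[1:], start=1):
        X[f"weekday_{name}"] = (wd == j).astype(float)
    mo = dates.dt.month
    for j, name in enumerate(MONTH_NAMES[1:], start=2):
        X[f"month_{name}"] = (mo == j).astype(float)
    for cov, (levels, ref) in CATEGORICAL_LEVELS.items():
        values = daily["person_id"].map(part[cov])
        for level in levels:
            if level != ref:
                X[f"{cov}_{level}"] = (values == level).astype(float)
    X["age"] = daily["person_id"].map(part["age"]).astype(float)
    X["day_in_study"] = (dates - pd.to_datetime(entry)).dt.days.astype(float)
    return X


def encode_covariates(participants: pd.DataFrame, daily: pd.DataFrame,
                      entry_dates: pd.Series | None = None,
                      drop_absent_levels: bool = True):
    """Encode person-day covariates into a standardized design matrix.

    Parameters
    ----------
    participants : DataFrame with columns person_id, age, gender, region,
        education, ses, exid.
    daily : DataFrame with columns person_id, date (one row per analysis day).
    entry_dates : optional Series person_id -> entry date; defaults to each
        person's first date in ``daily``.
    drop_absent_levels : drop indicator columns with no occurrences (keeps
        the design full rank under flat priors).

    Returns
    -------
    (X, codebook) : X is a DataFrame of encoded covariates aligned with
    ``daily`` rows; continuous columns are standardized to sample mean 0 /
    sd 1 and the statistics are stored in the codebook along with the
    exercise-identity standardization.
    """
    part = participants.set_index("person_id")
    dates = pd.to_datetime(daily["date"])
    X = raw_design_frame(participants, daily, entry_dates=entry_dates)

    dropped = []
    re_referenced = {}
    if drop_absent_levels:
        for col in X.columns:
            if col not in ("intercept", *CONTINUOUS_COVARIATES) and X[col].sum() == 0:
                dropped.append(col)
        X = X.drop(columns=dropped)
        # if a group's reference level never occurs, its indicators sum to the
        # intercept; promote the first observed level to reference instead
        wd = dates.dt.weekday
        mo = dates.dt.month
        groups = {
            "weekday": ([f"weekday_{n}" for n in WEEKDAY_NAMES[1:]], (wd == 0).any()),
            "month": ([f"month_{n}" for n in MONTH_NAMES[1:]], (mo == 1).any()),
        }
        for cov, (levels, ref) in CATEGORICAL_LEVELS.items():
            values = daily["person_id"].map(part[cov])
            groups[cov] = ([f"{cov}_{lev}" for lev in levels if lev != ref],
                           (values == ref).any())
        for group, (cols, ref_present) in groups.items():
            present = [c for c in cols if c in X.columns]
            if present and not ref_present:
                new_ref = present[0]
                X = X.drop(columns=[new_ref])
                dropped.append(new_ref)
                re_referenced[group] = new_ref

    continuous = {}
    for col in CONTINUOUS_COVARIATES:
        mean = float(X[col].mean())
        sd = float(X[col].std(ddof=0))
        if sd == 0.0:
            sd = 1.0
        continuous[col] = (mean, sd)
        X[col] = (X[col] - mean) / sd

    ex = part["exid"].astype(float)
    ex_mean = float(ex.mean())
    ex_sd = float(ex.std(ddof=0))
    if ex_sd == 0.0:
        ex_sd = 1.0
    codebook = CovariateCodebook(
        columns=list(X.columns), continuous=continuous,
        exid=(ex_mean, ex_sd), dropped=dropped, re_referenced=re_referenced,
    )
    return X, codebook


# ---------------------------------------------------------------------------
# model dataset
# ---------------------------------------------------------------------------

@dataclass
class ModelDataset:
    """Encoded person x burst x day dataset ready for likelihood evaluation.

    Rows are sorted by person and date; within each (person, segment) the
    dates are consecutive, so ``lag_available`` is exactly
    ``day_within_burst > 1``. Missing responses are NaN in ``y`` and flagged
    in ``miss_mask``; they stay in the table for full-information estimation.
    """

    df: pd.DataFrame                 # person_id, date, burst_index, day_within_burst, L, P
    y: np.ndarray                    # (N, 2) float, NaN where missing
    X: np.ndarray                    # (N, p) encoded covariates (standardized)
    columns: list                    # design column names
    person_index: np.ndarray         # (N,) int, index into person_ids
    person_ids: list
    exid_std: np.ndarray             # (n_persons,) standardized moderator
    first_day: np.ndarray            # (N,) bool: no usable lag (burst-first day)
    prev_row: np.ndarray             # (N,) int row index of previous day (-1 on first days)
    codebook: CovariateCodebook

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def n_rows(self) -> int:
        return self.y.shape[0]

    @property
    def miss_mask(self) -> np.ndarray:
        return np.isnan(self.y)


def build_model_dataset(daily: pd.DataFrame, participants: pd.DataFrame,
                        entry_dates: pd.Series | None = None) -> ModelDataset:
    """Assemble a :class:`ModelDataset` from daily observations and covariates.

    ``daily`` needs columns person_id, date, ls_mean, pa_rate (NaN where
    missing). Consecutive-date runs define bursts/segments; the day-level
    Markov chain is broken across any calendar gap, so bursts are linked
    only through the person random effects.
    """
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    daily = daily.sort_values(["person_id", "date"]).reset_index(drop=True)
    if daily.duplicated(subset=["person_id", "date"]).any():
        raise ValueError("duplicate person-date rows in daily table")

    gap = daily.groupby("person_id")["date"].diff().dt.days
    new_segment = gap.isna() | (gap > 1)
    daily["burst_index"] = new_segment.groupby(daily["person_id"]).cumsum().astype(int)
    daily["day_within_burst"] = (
        daily.groupby(["person_id", "burst_index"]).cumcount() + 1
    )

    with np.errstate(invalid="ignore"):
        L = np.where(daily["ls_mean"].notna(),
                     logit((daily["ls_mean"].fillna(50.0).to_numpy() + 1.0) / 102.0),
                     np.nan)
        P = np.where(daily["pa_rate"].notna(),
                     np.log1p(daily["pa_rate"].fillna(0.0).to_numpy()),
                     np.nan)
    ls_obs = daily["ls_mean"].dropna()
    if len(ls_obs) and ((ls_obs < 0).any() or (ls_obs > 100).any()):
        raise ValueError("ls_mean out of [0, 100]")
    pa_obs = daily["pa_rate"].dropna()
    if len(pa_obs) and (pa_obs < 0).any():
        raise ValueError("pa_rate must be non-negative")
    daily["L"] = L
    daily["P"] = P

    X, codebook = encode_covariates(participants, daily, entry_dates=entry_dates)

    person_ids = list(pd.unique(daily["person_id"]))
    pid_to_idx = {p: i for i, p in enumerate(person_ids)}
    person_index = daily["person_id"].map(pid_to_idx).to_numpy()

    part = participants.set_index("person_id")
    ex_mean, ex_sd = codebook.exid
    exid_std = ((part["exid"].reindex(person_ids).astype(float) - ex_mean) / ex_sd).to_numpy()

    first_day = (daily["day_within_burst"] == 1).to_numpy()
    prev_row = np.arange(len(daily)) - 1
    prev_row[first_day] = -1

    daily["lag_available"] = ~first_day
    return ModelDataset(
        df=daily,
        y=np.column_stack([L, P]).astype(float),
        X=X.to_numpy(dtype=float),
        columns=list(X.columns),
        person_index=person_index.astype(int),
        person_ids=person_ids,
        exid_std=exid_std,
        first_day=first_day,
        prev_row=prev_row,
        codebook=codebook,
    )
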