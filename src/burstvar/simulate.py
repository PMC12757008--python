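"""Synthetic burst-design generator: population, calendars, latent VAR series, wearables.

Emulates a four-burst intensive longitudinal study of daily life
satisfaction and Fitbit-derived physical activity: n participants with
baseline covariates drawn to match the study composition, four 2-week
bursts at months 0/4/8/12 after a person-specific entry date, a bivariate
Gaussian VAR(1) on the transformed (L, P) scales with person random
intercepts and an exercise-identity-moderated disturbance correlation,
missing-at-random masking driven by observed quantities only, and a
minute-level wearable stream plus a two-item evening survey that invert the
analysis transforms.

Every stage takes an explicit seed and is byte-reproducible. The defaults
(category shares, age distribution, true coefficients) reproduce the
published study regime so the generator doubles as the ground-truth oracle
for parameter-recovery simulations.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    MONTH_NAMES,
    WEEKDAY_NAMES,
    inverse_transform_ls,
    inverse_transform_pa,
    raw_design_frame,
)
from .model import (
    ParameterSet,
    _person_covariances,
    _stationary_covariances,
    moderated_correlation,
    spectral_radius,
)

__all__ = [
    "PopulationConfig",
    "BurstDesign",
    "RenderConfig",
    "MarConfig",
    "SimulatedDataset",
    "default_true_parameters",
    "simulate_population",
    "make_burst_calendar",
    "simulate_latent_series",
    "render_observables",
    "apply_missingness",
    "simulate_dataset",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Between-person covariate distributions (defaults match the study sample).

    Ages are truncated-normal within ``age_bounds``; exercise identity (9-item
    scale, totals on [9, 63]) is drawn from activity-status-specific normals,
    runners scoring higher, truncated to the scale range.
    """

    p_female: float = 0.463
    p_high_pollution: float = 0.571     # Moravian-Silesian region share
    p_university: float = 0.430
    ses_probs: tuple = (0.0254, 0.7976, 0.1770)  # below_average / average / above_average
    p_runner: float = 0.568
    age_mean: float = 38.09
    age_sd: float = 12.55
    age_bounds: tuple = (18.0, 65.0)
    exid_runner: tuple = (48.0, 8.0)
    exid_inactive: tuple = (30.0, 9.0)
    exid_bounds: tuple = (9.0, 63.0)

    def validate(self) -> None:
        for name in ("p_female", "p_high_pollution", "p_university", "p_runner"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        probs = np.asarray(self.ses_probs, dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("ses_probs must be non-negative and sum to 1")


@dataclass
class BurstDesign:
    """Burst calendar layout: four 2-week bursts at months 0/4/8/12 by default.

    Entry dates are dispersed uniformly over ``entry_window`` (the study
    enrolled continuously over more than two years), which also guarantees
    that all months and weekdays occur in the pooled design.
    """

    n_bursts: int = 4
    burst_length: int = 14
    burst_offsets_months: tuple = (0, 4, 8, 12)
    entry_window: tuple = ("2019-04-19", "2021-08-31")

    def validate(self) -> None:
        if self.n_bursts < 1 or self.burst_length < 1:
            raise ValueError("n_bursts and burst_length must be positive")
        if len(self.burst_offsets_months) < self.n_bursts:
            raise ValueError("need a month offset for every burst")
        offsets = self.offsets_days()
        if any(b - a < self.burst_length for a, b in zip(offsets, offsets[1:])):
            raise ValueError("bursts overlap: offsets closer than burst_length")

    def offsets_days(self) -> list:
        return [int(round(30.437 * m)) for m in
                self.burst_offsets_months[: self.n_bursts]]


@dataclass
class RenderConfig:
    """Minute-stream and survey rendering knobs.

    A fixed sleep block (23:00-07:00 by default) is flagged asleep with heart
    rate present, exercising the rule that sleep minutes never count as wear
    time. Wake minutes are worn with fraction ``wear_frac``; of the worn
    minutes, ``zero_step_frac`` carry a heart-rate reading but no steps
    (sedentary wear) and a small fraction of stepping minutes lack a
    heart-rate reading (steps alone already make them valid).
    """

    sleep_start_hour: int = 23
    sleep_end_hour: int = 7
    wear_frac_mean: float = 0.875
    wear_frac_sd: float = 0.05
    zero_step_frac: float = 0.55
    p_hr_missing_on_step: float = 0.05
    hr_during_sleep: bool = True
    item_offset: float = 2.0            # half-distance between the two LS slider items


_MAR_ALLOWED_KEYS = {
    "ls_rate", "pa_rate", "ls_weekday_multipliers", "pa_weekday_multipliers",
}


@dataclass
class MarConfig:
    """Missing-at-random masking driven by observed quantities only.

    Per-day masking probabilities are ``rate * weekday_multiplier``; the
    schema only admits predictors that are always observed (the calendar),
    so the mechanism is MAR by construction. Any attempt to key the
    mechanism on the outcome values themselves is rejected.
    """

    ls_rate: float = 0.0
    pa_rate: float = 0.0
    ls_weekday_multipliers: dict = field(default_factory=dict)
    pa_weekday_multipliers: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("ls_rate", "pa_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        for name in ("ls_weekday_multipliers", "pa_weekday_multipliers"):
            mult = getattr(self, name)
            bad = set(mult) - set(WEEKDAY_NAMES)
            if bad:
                raise ValueError(
                    f"{name} keys must be weekday names (got {sorted(bad)!r}); "
                    "masking probabilities may depend on observed quantities only"
                )
            if any(v < 0 for v in mult.values()):
                raise ValueError("weekday multipliers must be non-negative")

    @classmethod
    def from_dict(cls, config: dict) -> "MarConfig":
        unknown = set(config) - _MAR_ALLOWED_KEYS
        if unknown:
            raise ValueError(
                f"unsupported missingness predictors {sorted(unknown)!r}: a mechanism "
                "referencing the to-be-masked values would be MNAR; only observed-data "
                f"predictors {sorted(_MAR_ALLOWED_KEYS)} are allowed"
            )
        return cls(**config)

    def probabilities(self, dates: pd.Series):
        wd = pd.to_datetime(dates).dt.weekday.map(lambda j: WEEKDAY_NAMES[j])
        p_ls = self.ls_rate * wd.map(lambda w: self.ls_weekday_multipliers.get(w, 1.0))
        p_pa = self.pa_rate * wd.map(lambda w: self.pa_weekday_multipliers.get(w, 1.0))
        return np.clip(p_ls.to_numpy(float), 0, 1), np.clip(p_pa.to_numpy(float), 0, 1)


def default_mar_config() -> MarConfig:
    """Occasional missingness typical of evening-survey compliance and non-wear days."""
    return MarConfig(ls_rate=0.12, pa_rate=0.05,
                     ls_weekday_multipliers={"saturday": 1.3, "sunday": 1.3})


def default_true_parameters() -> ParameterSet:
    """Ground-truth parameters mimicking the published posterior means.

    Coefficients are on the original covariate scale (years of age, raw study
    day, 0/1 indicators); alpha0/alpha1 act on the standardized
    exercise-identity score, so tanh(alpha0) is the contemporaneous
    correlation at average exercise identity.
    """
    delta_L = {
        "intercept": -0.4327, "day_in_study": 0.0017, "gender_male": 0.0910,
        "age": 0.0151, "region_high_pollution": -0.0917,
        "weekday_tuesday": 0.2556, "weekday_wednesday": 0.2017,
        "weekday_thursday": 0.2202, "weekday_friday": 0.3623,
        "weekday_saturday": 0.7257, "weekday_sunday": 0.4406,
        "month_february": -0.0556, "month_march": -0.2274, "month_april": -0.0112,
        "month_may": -0.0034, "month_june": 0.0825, "month_july": 0.2484,
        "month_august": 0.1270, "month_september": 0.0225, "month_october": -0.0270,
        "month_november": -0.0903, "month_december": 0.0422,
        "education_university": -0.0273, "ses_average": 0.4257,
        "ses_above_average": 0.5129,
    }
    delta_P = {
        "intercept": 6.1004, "day_in_study": -0.0019, "gender_male": 0.0840,
        "age": 0.0069, "region_high_pollution": -0.0183,
        "weekday_tuesday": 0.0914, "weekday_wednesday": 0.0490,
        "weekday_thursday": 0.0713, "weekday_friday": 0.0752,
        "weekday_saturday": 0.1676, "weekday_sunday": 0.0388,
        "month_february": 0.0474, "month_march": 0.1074, "month_april": 0.1086,
        "month_may": 0.1346, "month_june": 0.2298, "month_july": 0.2086,
        "month_august": 0.1952, "month_september": 0.1985, "month_october": 0.0846,
        "month_november": 0.0797, "month_december": 0.0520,
        "education_university": 0.0051, "ses_average": -0.0091,
        "ses_above_average": 0.0155,
    }
    return ParameterSet(
        delta_L=delta_L, delta_P=delta_P,
        beta=np.array([[0.3941, 0.0011], [-0.0013, 0.3158]]),
        sigma_L=1.2342, sigma_P=0.5855,
        tau_L=1.1847, tau_P=0.3870,
        alpha0=0.0872, alpha1=0.0105,
    )


# ---------------------------------------------------------------------------
# population and calendar
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():                           # resample the tails
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_population(n: int, config: PopulationConfig | None = None,
                        seed=0) -> pd.DataFrame:
    """Draw n participants with covariates and exercise identity."""
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or PopulationConfig()
    config.validate()
    rng = _rng(seed)
    runner = rng.random(n) < config.p_runner
    age = _truncated_normal(rng, config.age_mean, config.age_sd,
                            *config.age_bounds, size=n)
    gender = np.where(rng.random(n) < config.p_female, "female", "male")
    region = np.where(rng.random(n) < config.p_high_pollution,
                      "high_pollution", "low_pollution")
    education = np.where(rng.random(n) < config.p_university,
                         "university", "non_university")
    ses = rng.choice(["below_average", "average", "above_average"],
                     size=n, p=np.asarray(config.ses_probs, float))
    exid = np.where(
        runner,
        _truncated_normal(rng, *config.exid_runner, *config.exid_bounds, size=n),
        _truncated_normal(rng, *config.exid_inactive, *config.exid_bounds, size=n),
    )
    return pd.DataFrame({
        "person_id": [f"p{i:05d}" for i in range(n)],
        "age": age, "gender": gender, "region": region,
        "education": education, "ses": ses,
        "runner": runner, "exid": exid,
    })


def make_burst_calendar(participants: pd.DataFrame,
                        design: BurstDesign | None = None,
                        seed=0) -> pd.DataFrame:
    """Person-specific burst calendar: one row per person-burst-day."""
    design = design or BurstDesign()
    design.validate()
    rng = _rng(seed)
    start, end = (pd.Timestamp(d) for d in design.entry_window)
    span = (end - start).days
    offsets = design.offsets_days()
    rows = []
    for pid in participants["person_id"]:
        entry = start + pd.Timedelta(days=int(rng.integers(0, span + 1)))
        for b, off in enumerate(offsets, start=1):
            burst_start = entry + pd.Timedelta(days=off)
            for d in range(design.burst_length):
                rows.append((pid, b, burst_start + pd.Timedelta(days=d)))
    return pd.DataFrame(rows, columns=["person_id", "burst_index", "date"])


# ---------------------------------------------------------------------------
# latent VAR series
# ---------------------------------------------------------------------------

def standardized_exid(participants: pd.DataFrame) -> pd.Series:
    """Exercise identity standardized within the sample (sd 1 guard for n=1)."""
    ex = participants["exid"].astype(float)
    sd = float(ex.std(ddof=0))
    return (ex - float(ex.mean())) / (sd if sd > 0 else 1.0)


def simulate_latent_series(participants: pd.DataFrame, calendar: pd.DataFrame,
                           params: ParameterSet, seed=0):
    """Simulate the transformed daily series (L, P) on the burst calendar.

    Within each burst the first day is drawn from the stationary VAR
    distribution centred at mu + m and later days follow the VAR(1)
    recursion; dynamics never propagate across the months-long gaps between
    bursts (bursts are linked only through the person random effects).

    Returns ``(table, params)`` where the table has one row per
    person-burst-day with columns L and P, and ``params`` carries the
    realized random effects (drawn here when absent from the input).
    """
    params.validate()
    if spectral_radius(params.beta) >= 1.0:
        raise ValueError("beta is not stationary (spectral radius >= 1): "
                         "no stationary burst initialization exists")
    rng = _rng(seed)

    cal = calendar.sort_values(["person_id", "burst_index", "date"]).reset_index(drop=True)
    cal["date"] = pd.to_datetime(cal["date"])
    person_ids = list(pd.unique(participants["person_id"]))
    missing = set(cal["person_id"]) - set(person_ids)
    if missing:
        raise ValueError(f"calendar references unknown persons: {sorted(missing)[:5]}")
    pid_to_idx = {p: i for i, p in enumerate(person_ids)}
    n = len(person_ids)

    entry = cal.groupby("person_id")["date"].min()
    Xraw = raw_design_frame(participants, cal, entry_dates=entry)
    dL = params.delta_vector(list(Xraw.columns), "L")
    dP = params.delta_vector(list(Xraw.columns), "P")
    mu = Xraw.to_numpy(float) @ np.column_stack([dL, dP])

    if params.m is None:
        m = np.column_stack([
            rng.normal(0.0, params.tau_L, size=n),
            rng.normal(0.0, params.tau_P, size=n),
        ])
        params = params.with_random_effects(m)
    else:
        if params.m.shape[0] != n:
            raise ValueError("params.m does not match the number of participants")
        m = params.m

    ex_std = standardized_exid(participants).to_numpy()
    sig = _person_covariances(params, ex_std)
    chol = np.linalg.cholesky(sig)
    chol_stat = np.linalg.cholesky(_stationary_covariances(params.beta, sig))

    # group rows into equal-length (person, burst) blocks
    pb = cal.groupby(["person_id", "burst_index"], sort=False).size()
    if pb.nunique() != 1:
        raise ValueError("all bursts must have the same length")
    T = int(pb.iloc[0])
    n_blocks = len(pb)
    block_pidx = np.array([pid_to_idx[p] for p, _ in pb.index])

    mu3 = mu.reshape(n_blocks, T, 2)
    center = mu3 + m[block_pidx][:, None, :]
    y = np.empty_like(mu3)
    z = rng.standard_normal((n_blocks, T, 2))
    Ls = chol_stat[block_pidx]
    Le = chol[block_pidx]
    B = params.beta
    y[:, 0] = center[:, 0] + np.einsum("nij,nj->ni", Ls, z[:, 0])
    for t in range(1, T):
        dev = y[:, t - 1] - center[:, t - 1]
        y[:, t] = center[:, t] + dev @ B.T + np.einsum("nij,nj->ni", Le, z[:, t])

    out = cal.copy()
    flat = y.reshape(-1, 2)
    out["day_within_burst"] = np.tile(np.arange(1, T + 1), n_blocks)
    out["L"] = flat[:, 0]
    out["P"] = flat[:, 1]
    return out, params


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def apply_missingness(table: pd.DataFrame, mar_config: MarConfig | dict, seed=0) -> pd.DataFrame:
    """Mask daily responses at random with observed-covariate-driven probabilities.

    Works on either a latent table (columns L, P) or a daily observation
    table (columns ls_mean, pa_rate). Masked entries become NaN and are
    flagged in ``ls_missing`` / ``pa_missing``; no row is dropped.
    """
    if isinstance(mar_config, dict):
        mar_config = MarConfig.from_dict(mar_config)
    ls_col = "L" if "L" in table.columns else "ls_mean"
    pa_col = "P" if "P" in table.columns else "pa_rate"
    for col in (ls_col, pa_col):
        if col not in table.columns:
            raise ValueError(f"table lacks a response column {col!r}")
    rng = _rng(seed)
    p_ls, p_pa = mar_config.probabilities(table["date"])
    out = table.copy()
    ls_miss = rng.random(len(table)) < p_ls
    pa_miss = rng.random(len(table)) < p_pa
    out.loc[ls_miss, ls_col] = np.nan
    out.loc[pa_miss, pa_col] = np.nan
    out["ls_missing"] = ls_miss
    out["pa_missing"] = pa_miss
    return out


# ---------------------------------------------------------------------------
# observable rendering (minute stream + evening survey)
# ---------------------------------------------------------------------------

def _split_ls_items(ls: float, offset: float, rng) -> tuple:
    """Two integer slider items whose mean reproduces ``ls`` within rounding."""
    d = min(offset, ls, 100.0 - ls)
    lo = int(round(ls - d))
    hi = int(round(2.0 * ls)) - lo
    lo, hi = int(np.clip(lo, 0, 100)), int(np.clip(hi, 0, 100))
    if rng.random() < 0.5:                     # randomize which item is higher
        lo, hi = hi, lo
    return lo, hi


def render_observables(latent: pd.DataFrame, config: RenderConfig | None = None,
                       seed=0):
    """Invert the analysis transforms into raw observables.

    P becomes a daily steps-per-wear-hour target realized as a 1440-minute
    record stream (sleep block, worn/not-worn wake minutes, integer step
    counts distributed over stepping minutes); L becomes a 0-100 LS mean
    split into two integer slider items. Days with masked P are rendered as
    all-day non-wear; days with masked L produce no survey row.

    Returns ``(minutes, surveys)`` data frames.
    """
    config = config or RenderConfig()
    rng = _rng(seed)
    sleep_min = [m for m in range(1440)
                 if (m < config.sleep_end_hour * 60) or (m >= config.sleep_start_hour * 60)]
    wake_min = np.array([m for m in range(1440) if m not in set(sleep_min)])
    sleep_min = np.array(sleep_min)
    n_wake = len(wake_min)

    minute_frames = []
    survey_rows = []
    for row in latent.itertuples(index=False):
        date = pd.Timestamp(row.date)
        base = date.normalize()
        steps = np.zeros(1440, dtype=np.int64)
        hr = np.zeros(1440, dtype=bool)
        asleep = np.zeros(1440, dtype=bool)
        asleep[sleep_min] = True
        if config.hr_during_sleep:
            hr[sleep_min] = True

        if not np.isnan(row.P):
            rate = max(float(inverse_transform_pa(row.P)), 0.0)
            frac = np.clip(rng.normal(config.wear_frac_mean, config.wear_frac_sd), 0.3, 1.0)
            n_wear = max(int(round(frac * n_wake)), 60)
            worn = rng.choice(wake_min, size=n_wear, replace=False)
            hr[worn] = True
            n_step_minutes = max(int(round((1.0 - config.zero_step_frac) * n_wear)), 1)
            stepping = rng.choice(worn, size=n_step_minutes, replace=False)
            total_steps = int(round(rate * n_wear / 60.0))
            if total_steps > 0:
                alloc = rng.multinomial(total_steps, np.full(n_step_minutes, 1.0 / n_step_minutes))
                steps[stepping] = alloc
            # some stepping minutes lack a heart-rate reading: steps alone make them valid
            drop_hr = rng.random(n_step_minutes) < config.p_hr_missing_on_step
            hr[stepping[drop_hr & (steps[stepping] > 0)]] = False

        minute_frames.append(pd.DataFrame({
            "person_id": row.person_id,
            "timestamp": base + pd.to_timedelta(np.arange(1440), unit="m"),
            "steps": steps,
            "hr_present": hr.astype(np.int8),
            "asleep": asleep.astype(np.int8),
        }))

        if not np.isnan(row.L):
            ls = float(np.clip(inverse_transform_ls(row.L), 0.0, 100.0))
            item1, item2 = _split_ls_items(ls, config.item_offset, rng)
            survey_rows.append((row.person_id, base.date().isoformat(), item1, item2))

    minutes = pd.concat(minute_frames, ignore_index=True) if minute_frames else pd.DataFrame(
        columns=["person_id", "timestamp", "steps", "hr_present", "asleep"])
    surveys = pd.DataFrame(survey_rows,
                           columns=["person_id", "date", "ls_item1", "ls_item2"])
    return minutes, surveys


# ---------------------------------------------------------------------------
# end-to-end bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Everything one replication produces, including the ground truth."""

    participants: pd.DataFrame
    calendar: pd.DataFrame
    latent: pd.DataFrame          # unmasked L/P (the oracle)
    daily: pd.DataFrame           # person_id, date, ls_mean, pa_rate (NaN = missing)
    truth: ParameterSet           # includes realized random effects
    minutes: pd.DataFrame | None = None
    surveys: pd.DataFrame | None = None


def simulate_dataset(n_persons: int, seed: int = 0,
                     params: ParameterSet | None = None,
                     population: PopulationConfig | None = None,
                     design: BurstDesign | None = None,
                     mar: MarConfig | None = None,
                     render: RenderConfig | bool = False) -> SimulatedDataset:
    """Generate one complete study: population -> calendar -> latent -> observables.

    With ``render`` falsy, the daily table is produced by direct transform
    inversion (fast path, no rounding); pass ``render=True`` (or a
    :class:`RenderConfig`) to go through the full minute-level stream and the
    wear-time preprocessing, which adds slider/step rounding noise exactly as
    a real pipeline would.
    """
    from .preprocess import build_daily_table  # local import to avoid a cycle

    params = params or default_true_parameters()
    mar = default_mar_config() if mar is None else mar
    ss = np.random.SeedSequence(seed).spawn(4)

    participants = simulate_population(n_persons, config=population, seed=_rng(ss[0]))
    calendar = make_burst_calendar(participants, design=design, seed=_rng(ss[1]))
    latent, truth = simulate_latent_series(participants, calendar, params, seed=_rng(ss[2]))
    masked = apply_missingness(latent, mar, seed=_rng(ss[3]))

    minutes = surveys = None
    if render:
        config = render if isinstance(render, RenderConfig) else None
        minutes, surveys = render_observables(masked, config=config, seed=_rng(ss[3]))
        daily = build_daily_table(minutes, surveys)
    else:
        with np.errstate(invalid="ignore"):
            daily = pd.DataFrame({
                "person_id": masked["person_id"],
                "date": masked["date"],
                "ls_mean": np.clip(inverse_transform_ls(masked["L"].to_numpy(float)), 0, 100),
                "pa_rate": np.maximum(inverse_transform_pa(masked["P"].to_numpy(float)), 0.0),
            })
    return SimulatedDataset(
        participants=participants, calendar=calendar, latent=latent,
        daily=daily, truth=truth, minutes=minutes, surveys=surveys,
    )


def write_dataset(data: SimulatedDataset, out_dir) -> None:
    """Write participants/minutes/surveys/daily CSVs and the truth JSON."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data.participants.to_csv(out / "participants.csv", index=False)
    data.daily.to_csv(out / "daily.csv", index=False)
    data.latent.to_csv(out / "latent.csv", index=False)
    if data.minutes is not None:
        data.minutes.to_csv(out / "minutes.csv", index=False)
        data.surveys.to_csv(out / "surveys.csv", index=False)
    data.truth.to_json(out / "truth.json")
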