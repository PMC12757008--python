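import numpy as np
import pandas as pd
import pytest

from burstvar import BurstDesign, MarConfig, build_model_dataset, simulate_dataset
from burstvar.design import CovariateCodebook
from burstvar.inference import McmcConfig, PosteriorDraws


@pytest.fixture
def participants3() -> pd.DataFrame:
    """Three hand-written participants covering several covariate levels."""
    return pd.DataFrame({
        "person_id": ["a", "b", "c"],
        "age": [25.0, 40.0, 61.0],
        "gender": ["female", "male", "female"],
        "region": ["low_pollution", "high_pollution", "low_pollution"],
        "education": ["non_university", "university", "university"],
        "ses": ["below_average", "average", "above_average"],
        "exid": [20.0, 45.0, 55.0],
    })


@pytest.fixture
def tiny_dataset(participants3):
    """Complete 3-person, 5-day dataset (single segment per person)."""
    rng = np.random.default_rng(42)
    rows = []
    for pid in participants3["person_id"]:
        for d in pd.date_range("2020-01-06", periods=5):
            rows.append((pid, d, rng.uniform(30, 70), rng.uniform(200, 700)))
    daily = pd.DataFrame(rows, columns=["person_id", "date", "ls_mean", "pa_rate"])
    return build_model_dataset(daily, participants3)


@pytest.fixture(scope="session")
def small_fit_inputs():
    """A small complete simulated study reused by inference-level tests."""
    sim = simulate_dataset(
        16, seed=7, mar=MarConfig(),
        design=BurstDesign(n_bursts=2, burst_length=8, burst_offsets_months=(0, 4)),
    )
    ds = build_model_dataset(sim.daily, sim.participants)
    return sim, ds


@pytest.fixture
def fast_mcmc():
    return McmcConfig(chains=2, warmup=80, draws=120, seed=3)


def synthetic_draws(values: dict, chains: int = 2) -> PosteriorDraws:
    """Assemble a PosteriorDraws object from raw (chains, draws) arrays.

    ``values`` may provide any of delta_L/delta_P (dict col -> array),
    beta_* / sigma_* / tau_* / alpha* scalars; missing entries are zeros.
    Used to unit-test summaries/diagnostics/reporting without running MCMC.
    """
    def shape_of():
        for v in values.values():
            if isinstance(v, dict):
                return next(iter(v.values())).shape
            return v.shape
        raise ValueError("need at least one array")

    c, d = shape_of()
    dl = values.get("delta_L", {})
    dp = values.get("delta_P", {})
    columns = sorted(set(dl) | set(dp)) or ["intercept"]
    p = len(columns)
    delta = np.zeros((c, d, 2 * p))
    for j, col in enumerate(columns):
        if col in dl:
            delta[:, :, j] = dl[col]
        if col in dp:
            delta[:, :, p + j] = dp[col]
    beta = np.zeros((c, d, 4))
    for j, name in enumerate(["beta_LL", "beta_LP", "beta_PL", "beta_PP"]):
        if name in values:
            beta[:, :, j] = values[name]
    sigma = np.ones((c, d, 2))
    tau = np.ones((c, d, 2))
    alpha = np.zeros((c, d, 2))
    for arr, names in ((sigma, ["sigma_L", "sigma_P"]),
                       (tau, ["tau_L", "tau_P"]),
                       (alpha, ["alpha0", "alpha1"])):
        for j, name in enumerate(names):
            if name in values:
                arr[:, :, j] = values[name]
    codebook = CovariateCodebook(
        columns=columns,
        continuous={k: v for k, v in values.get("continuous", {}).items()},
        exid=(0.0, 1.0),
    )
    return PosteriorDraws(
        delta=delta, m=np.zeros((c, d, 1, 2)), beta=beta, sigma=sigma,
        tau=tau, alpha=alpha, y_miss=np.zeros((c, d, 0)),
        columns=columns, person_ids=["p0"], miss_labels=[],
        codebook=codebook, meta={"counters": {}},
    )
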