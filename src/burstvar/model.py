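"""Joint probability model: mean structure, VAR(1) dynamics, moderated disturbances, priors.

The daily bivariate state (L, P) of person i follows

    y_it = mu_it + m_i + B (y_{i,t-1} - mu_{i,t-1} - m_i) + eps_it

with mu the covariate-driven mean, m_i ~ N(0, diag(tau_L^2, tau_P^2)) person
random intercepts, B the 2x2 transition matrix (row-equation convention:
``beta[0, 1]`` is the effect of yesterday's P on today's L), and Gaussian
disturbances whose contemporaneous correlation depends on the person's
standardized exercise identity through the inverse Fisher z link

    rho_i = tanh(alpha0 + alpha1 * exid_std_i).

The first day of each burst has no usable lag; by default it contributes its
stationary marginal N(mu + m, Sigma_stat) where Sigma_stat solves the
discrete Lyapunov equation Sigma = B Sigma B' + Sigma_eps. Bursts are
dynamically independent given m_i.

Priors: uniform on (-1, 1) for each entry of B, improper flat for the
regression coefficients (a wide-normal fallback is available), half-normal
for the standard deviations, flat for alpha0/alpha1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "ParameterSet",
    "PriorConfig",
    "moderated_correlation",
    "disturbance_covariance",
    "stationary_covariance",
    "spectral_radius",
    "log_likelihood",
    "log_prior",
    "log_random_effects",
]


def spectral_radius(beta) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(beta, dtype=float)))))


@dataclass
class ParameterSet:
    """Every symbol of the model; used as simulation truth and as posterior draws.

    ``delta_L`` / ``delta_P`` map design-column names (including
    ``intercept``) to coefficients. Whether those coefficients live on the
    raw or the standardized covariate scale is up to the caller; the
    synthetic generator uses the raw scale (as the study reports them) and
    the sampler works on the standardized scale internally.
    """

    delta_L: dict
    delta_P: dict
    beta: np.ndarray
    sigma_L: float
    sigma_P: float
    tau_L: float
    tau_P: float
    alpha0: float
    alpha1: float
    m: np.ndarray | None = None      # (n_persons, 2) random effects, optional

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).reshape(2, 2)
        if self.m is not None:
            self.m = np.asarray(self.m, dtype=float).reshape(-1, 2)

    def validate(self) -> None:
        if not np.all(np.abs(self.beta) < 1.0):
            raise ValueError("every entry of beta must lie strictly in (-1, 1)")
        for name in ("sigma_L", "sigma_P", "tau_L", "tau_P"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("alpha0", "alpha1"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def delta_vector(self, columns, which: str) -> np.ndarray:
        """Coefficient vector aligned with ``columns`` (missing names -> 0)."""
        d = self.delta_L if which == "L" else self.delta_P
        return np.array([float(d.get(c, 0.0)) for c in columns])

    def with_random_effects(self, m: np.ndarray) -> "ParameterSet":
        return replace(self, m=np.asarray(m, dtype=float))

    def to_json(self, path) -> None:
        payload = {
            "delta_L": {k: float(v) for k, v in self.delta_L.items()},
            "delta_P": {k: float(v) for k, v in self.delta_P.items()},
            "beta": self.beta.tolist(),
            "sigma_L": self.sigma_L, "sigma_P": self.sigma_P,
            "tau_L": self.tau_L, "tau_P": self.tau_P,
            "alpha0": self.alpha0, "alpha1": self.alpha1,
            "m": None if self.m is None else self.m.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            payload = json.load(fh)
        m = payload.pop("m", None)
        return cls(m=None if m is None else np.asarray(m), **payload)


@dataclass
class PriorConfig:
    """Prior hyperparameters.

    ``sigma_scale`` / ``tau_scale`` are half-normal scales for the
    disturbance and random-effect standard deviations (on the transformed
    response scale). ``delta_sd`` / ``alpha_sd`` default to None meaning
    improper flat priors; set them for samplers that need proper priors.
    ``multiplier`` rescales the half-normal scales (0.5 / 1 / 2 in the
    sensitivity analysis).
    """

    sigma_scale: float = 1.0
    tau_scale: float = 1.0
    delta_sd: float | None = None
    alpha_sd: float | None = None
    multiplier: float = 1.0

    def scaled(self, multiplier: float) -> "PriorConfig":
        return replace(self, multiplier=self.multiplier * multiplier)

    @property
    def sigma_scale_eff(self) -> float:
        return self.sigma_scale * self.multiplier

    @property
    def tau_scale_eff(self) -> float:
        return self.tau_scale * self.multiplier


# ---------------------------------------------------------------------------
# covariance building blocks
# ---------------------------------------------------------------------------

def moderated_correlation(alpha0, alpha1, exid_std):
    """Inverse Fisher z link: ``tanh(alpha0 + alpha1 * exid_std)``, in (-1, 1)."""
    out = np.tanh(np.asarray(alpha0, dtype=float)
                  + np.asarray(alpha1, dtype=float) * np.asarray(exid_std, dtype=float))
    return float(out) if out.ndim == 0 else out


def disturbance_covariance(sigma_L: float, sigma_P: float, rho: float) -> np.ndarray:
    """2x2 disturbance covariance with off-diagonal sigma_L * sigma_P * rho."""
    if not (sigma_L > 0 and sigma_P > 0):
        raise ValueError("standard deviations must be positive")
    if not abs(rho) < 1.0:
        raise ValueError("|rho| must be < 1")
    off = sigma_L * sigma_P * rho
    return np.array([[sigma_L ** 2, off], [off, sigma_P ** 2]])


def stationary_covariance(beta, sigma_matrix) -> np.ndarray:
    """Solve the discrete Lyapunov equation Sigma = B Sigma B' + Sigma_eps.

    Solved exactly through the 4x4 vec-equation (I - B kron B) vec(Sigma) =
    vec(Sigma_eps); requires spectral radius of ``beta`` below 1.
    """
    B = np.asarray(beta, dtype=float).reshape(2, 2)
    S = np.asarray(sigma_matrix, dtype=float).reshape(2, 2)
    if spectral_radius(B) >= 1.0:
        raise ValueError("beta is not stationary (spectral radius >= 1)")
    A = np.eye(4) - np.kron(B, B)
    sig = np.linalg.solve(A, S.reshape(4)).reshape(2, 2)
    return (sig + sig.T) / 2.0


def _stationary_covariances(beta: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Vectorized Lyapunov solve for a stack of (n, 2, 2) disturbance covariances."""
    A = np.eye(4) - np.kron(beta, beta)
    out = np.linalg.solve(A, sigmas.reshape(-1, 4).T).T.reshape(-1, 2, 2)
    return (out + np.transpose(out, (0, 2, 1))) / 2.0


# ---------------------------------------------------------------------------
# log densities
# ---------------------------------------------------------------------------

_LOG2PI = float(np.log(2.0 * np.pi))


def _person_covariances(params: ParameterSet, exid_std: np.ndarray):
    rho = moderated_correlation(params.alpha0, params.alpha1, exid_std)
    n = len(np.atleast_1d(rho))
    sig = np.empty((n, 2, 2))
    sig[:, 0, 0] = params.sigma_L ** 2
    sig[:, 1, 1] = params.sigma_P ** 2
    sig[:, 0, 1] = sig[:, 1, 0] = params.sigma_L * params.sigma_P * np.atleast_1d(rho)
    return sig


def _inv_logdet_2x2(mats: np.ndarray):
    det = mats[:, 0, 0] * mats[:, 1, 1] - mats[:, 0, 1] * mats[:, 1, 0]
    inv = np.empty_like(mats)
    inv[:, 0, 0] = mats[:, 1, 1]
    inv[:, 1, 1] = mats[:, 0, 0]
    inv[:, 0, 1] = -mats[:, 0, 1]
    inv[:, 1, 0] = -mats[:, 1, 0]
    inv /= det[:, None, None]
    return inv, np.log(det)


def log_likelihood(dataset, params: ParameterSet, first_day: str = "stationary") -> float:
    """Complete-data log likelihood of a :class:`~burstvar.design.ModelDataset`.

    ``params.delta_*`` must be on the dataset's (standardized) covariate
    scale and aligned with ``dataset.columns``; ``params.m`` defaults to
    zeros. Burst-first days contribute the stationary marginal when
    ``first_day='stationary'`` and are dropped from the likelihood when
    ``first_day='condition'``.

    Missing responses are not accepted here: the sampler treats them as
    latent quantities (full-information estimation); see
    :func:`burstvar.inference.fit`.
    """
    if first_day not in ("stationary", "condition"):
        raise ValueError("first_day must be 'stationary' or 'condition'")
    params.validate()
    if spectral_radius(params.beta) >= 1.0:
        raise ValueError("beta is not stationary (spectral radius >= 1)")
    y = dataset.y
    if np.isnan(y).any():
        raise ValueError(
            "dataset contains missing responses; log_likelihood is defined for "
            "complete data -- fit() samples missing values as latent quantities"
        )
    dL = params.delta_vector(dataset.columns, "L")
    dP = params.delta_vector(dataset.columns, "P")
    mu = dataset.X @ np.column_stack([dL, dP])
    m = params.m if params.m is not None else np.zeros((dataset.n_persons, 2))
    if m.shape[0] != dataset.n_persons:
        raise ValueError("params.m does not match the dataset's person count")

    e = y - mu - m[dataset.person_index]
    sig = _person_covariances(params, dataset.exid_std)
    W, logdet = _inv_logdet_2x2(sig)

    trans = ~dataset.first_day
    resid = e[trans] - e[dataset.prev_row[trans]] @ params.beta.T
    pidx_t = dataset.person_index[trans]
    quad = np.einsum("ti,tij,tj->t", resid, W[pidx_t], resid)
    ll = -0.5 * float(np.sum(quad + logdet[pidx_t])) - trans.sum() * _LOG2PI

    if first_day == "stationary":
        sig_stat = _stationary_covariances(params.beta, sig)
        Ws, logdets = _inv_logdet_2x2(sig_stat)
        first = dataset.first_day
        pidx_f = dataset.person_index[first]
        e0 = e[first]
        quad0 = np.einsum("ti,tij,tj->t", e0, Ws[pidx_f], e0)
        ll += -0.5 * float(np.sum(quad0 + logdets[pidx_f])) - first.sum() * _LOG2PI
    return float(ll)


def log_random_effects(params: ParameterSet) -> float:
    """Log density of the person random effects m_i ~ N(0, diag(tau^2))."""
    if params.m is None:
        return 0.0
    return float(
        stats.norm.logpdf(params.m[:, 0], scale=params.tau_L).sum()
        + stats.norm.logpdf(params.m[:, 1], scale=params.tau_P).sum()
    )


def log_prior(params: ParameterSet, prior: PriorConfig | None = None) -> float:
    """Joint log prior; -inf outside the support.

    Uniform(-1, 1) per transition-matrix entry, half-normal on the standard
    deviations with scales from ``prior`` (times its sensitivity
    multiplier), flat (or optional normal) on regression coefficients and on
    alpha0/alpha1.
    """
    prior = prior or PriorConfig()
    if not np.all(np.abs(params.beta) < 1.0):
        return -np.inf
    sds = np.array([params.sigma_L, params.sigma_P])
    taus = np.array([params.tau_L, params.tau_P])
    if np.any(sds <= 0) or np.any(taus <= 0):
        return -np.inf
    lp = 4.0 * np.log(0.5)  # uniform(-1,1) density per beta entry
    lp += float(stats.halfnorm.logpdf(sds, scale=prior.sigma_scale_eff).sum())
    lp += float(stats.halfnorm.logpdf(taus, scale=prior.tau_scale_eff).sum())
    if prior.delta_sd is not None:
        coefs = np.concatenate([
            np.array(list(params.delta_L.values()), dtype=float),
            np.array(list(params.delta_P.values()), dtype=float),
        ])
        lp += float(stats.norm.logpdf(coefs, scale=prior.delta_sd).sum())
    if prior.alpha_sd is not None:
        lp += float(stats.norm.logpdf([params.alpha0, params.alpha1],
                                      scale=prior.alpha_sd).sum())
    return lp
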