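"""Blocked Gibbs sampler for the burst VAR model (internal).

One sweep updates, in order:

1. latent missing responses -- exact bivariate-normal conditionals combining
   the own-day term and the successor-day term, in two checkerboard batches
   (odd/even day within burst) so no two simultaneously updated days are
   adjacent;
2. regression coefficients delta (both responses jointly) from their exact
   Gaussian conditional with the person random effects analytically
   marginalized (Woodbury identity), which removes the classic
   intercept/random-effect funnel; the Gaussian's precision is assembled
   from per-person covariate Gram matrices precomputed once per chain,
   exploiting that the weight matrix is constant within person;
3. person random effects m_i from their exact bivariate-normal conditionals;
4. the transition matrix B by independence Metropolis-Hastings: the proposal
   is the exact Gaussian conditional implied by the transition terms alone,
   so the acceptance ratio reduces to the burst-first-day (stationary
   marginal) terms plus the uniform(-1,1) support -- acceptance is near 1;
5. log sigma_L, log sigma_P, alpha0, alpha1 by univariate slice sampling on
   per-person residual cross-product statistics (O(n_persons) per density
   evaluation);
6. log tau_L, log tau_P by slice sampling given m.

All conditionals are exact; there is no step-size tuning and no rejection
except the (counted) MH step, so "divergences" in the HMC sense cannot
occur. The `failures` counter records non-finite update events instead.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .model import PriorConfig

_EYE2 = np.eye(2)
_SQRT_2_PI = float(np.sqrt(2.0 / np.pi))


# ---------------------------------------------------------------------------
# small linear-algebra helpers (stacks of 2x2 matrices)
# ---------------------------------------------------------------------------

def _inv_logdet(mats):
    det = mats[..., 0, 0] * mats[..., 1, 1] - mats[..., 0, 1] * mats[..., 1, 0]
    inv = np.empty_like(mats)
    inv[..., 0, 0] = mats[..., 1, 1]
    inv[..., 1, 1] = mats[..., 0, 0]
    inv[..., 0, 1] = -mats[..., 0, 1]
    inv[..., 1, 0] = -mats[..., 1, 0]
    inv /= det[..., None, None]
    return inv, np.log(det)


def _specrad2(B) -> float:
    """Spectral radius of a real 2x2 matrix, closed form."""
    tr = B[0, 0] + B[1, 1]
    det = B[0, 0] * B[1, 1] - B[0, 1] * B[1, 0]
    disc = tr * tr - 4.0 * det
    if disc >= 0.0:
        s = np.sqrt(disc)
        return max(abs(tr + s), abs(tr - s)) / 2.0
    return float(np.sqrt(det))


def _lyapunov_inverse(B) -> np.ndarray:
    """inv(I4 - B kron B); multiply vec(Sigma_eps) stacks to get Sigma_stat."""
    K = np.einsum("ab,cd->acbd", B, B).reshape(4, 4)
    return np.linalg.inv(np.eye(4) - K)


def _stationary_from_inverse(Ainv, sigmas):
    out = (sigmas.reshape(-1, 4) @ Ainv.T).reshape(-1, 2, 2)
    return (out + np.transpose(out, (0, 2, 1))) / 2.0


def _person_sigmas(sigma, alpha, exid_std):
    rho = np.tanh(alpha[0] + alpha[1] * exid_std)
    n = exid_std.shape[0]
    sig = np.empty((n, 2, 2))
    sig[:, 0, 0] = sigma[0] ** 2
    sig[:, 1, 1] = sigma[1] ** 2
    sig[:, 0, 1] = sig[:, 1, 0] = sigma[0] * sigma[1] * rho
    return sig


def _halfnorm_logpdf(x, scale):
    return np.log(_SQRT_2_PI / scale) - 0.5 * (x / scale) ** 2


def _segment_starts(idx: np.ndarray) -> np.ndarray:
    """reduceat start positions for a sorted person-index vector."""
    return np.flatnonzero(np.r_[True, idx[1:] != idx[:-1]])


def _reduce_by_person(arr: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(arr, starts, axis=0)


# ---------------------------------------------------------------------------
# slice sampler (Neal 2003, stepping out + shrinkage)
# ---------------------------------------------------------------------------

def slice_update(x0, logf, rng, w=0.25, max_expand=50):
    f0 = logf(x0)
    if not np.isfinite(f0):
        raise FloatingPointError("slice sampler started outside the support")
    logy = f0 + np.log(rng.random())
    left = x0 - w * rng.random()
    right = left + w
    for _ in range(max_expand):
        if logf(left) <= logy:
            break
        left -= w
    for _ in range(max_expand):
        if logf(right) <= logy:
            break
        right += w
    while True:
        x1 = left + (right - left) * rng.random()
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


# ---------------------------------------------------------------------------
# likelihood pieces on per-person sufficient statistics
# ---------------------------------------------------------------------------

def _transition_loglik(beta, W, logdet, S11, S01, S00, n_trans):
    BS = beta @ S01.transpose(0, 2, 1)          # B S01'
    Q = S11 - BS.transpose(0, 2, 1) - BS + np.einsum(
        "ab,nbc,dc->nad", beta, S00, beta)
    return -0.5 * float(np.sum(W * Q)) - 0.5 * float(n_trans @ logdet)


def _first_day_loglik(sigmas, F, n_first, lyap_inv):
    stat = _stationary_from_inverse(lyap_inv, sigmas)
    Ws, logdets = _inv_logdet(stat)
    return -0.5 * float(np.sum(Ws * F)) - 0.5 * float(n_first @ logdets)


# ---------------------------------------------------------------------------
# chain state and sweep
# ---------------------------------------------------------------------------

class _ChainState:
    def __init__(self, ds, prior: PriorConfig, first_day: str, rng):
        self.ds = ds
        self.prior = prior
        self.stationary_first = first_day == "stationary"
        self.rng = rng
        self.p = len(ds.columns)
        self.n = ds.n_persons
        N = ds.n_rows

        self.pidx = ds.person_index
        self.first = ds.first_day
        self.trans = ~ds.first_day
        self.prev = ds.prev_row
        self.X = ds.X
        self.exid = ds.exid_std
        self.starts_all = _segment_starts(self.pidx)
        if len(self.starts_all) != self.n:
            raise ValueError("dataset rows must be grouped by person")
        pidx_t = self.pidx[self.trans]
        pidx_f = self.pidx[self.first]
        if len(np.unique(pidx_t)) != self.n or len(np.unique(pidx_f)) != self.n:
            raise ValueError("every person needs at least one burst of >= 2 days")
        self.pidx_t = pidx_t
        self.pidx_f = pidx_f
        self.starts_t = _segment_starts(pidx_t)
        self.starts_f = _segment_starts(pidx_f)
        self.n_trans = np.bincount(pidx_t, minlength=self.n).astype(float)
        self.n_first = np.bincount(pidx_f, minlength=self.n).astype(float)

        # successor row within the same segment (-1 when none)
        succ = np.full(N, -1, dtype=int)
        t_idx = np.flatnonzero(self.trans)
        succ[t_idx - 1] = t_idx
        self.succ = succ

        # lagged design (zero rows on burst-first days)
        self.XP = np.zeros_like(self.X)
        self.XP[self.trans] = self.X[self.prev[self.trans]]

        # per-person covariate Gram matrices (constant across sweeps)
        p = self.p
        self.Gxx = np.zeros((self.n, p, p))
        self.Gxp = np.zeros((self.n, p, p))
        self.Gpp = np.zeros((self.n, p, p))
        self.Gff = np.zeros((self.n, p, p))
        self.sx = np.zeros((self.n, p))
        self.sxp = np.zeros((self.n, p))
        self.sxf = np.zeros((self.n, p))
        bounds = np.r_[self.starts_all, N]
        for i in range(self.n):
            rows = slice(bounds[i], bounds[i + 1])
            Xi = self.X[rows]
            XPi = self.XP[rows]
            tr = self.trans[rows]
            Xt, XPt, Xf = Xi[tr], XPi[tr], Xi[~tr]
            self.Gxx[i] = Xt.T @ Xt
            self.Gxp[i] = Xt.T @ XPt
            self.Gpp[i] = XPt.T @ XPt
            self.Gff[i] = Xf.T @ Xf
            self.sx[i] = Xt.sum(axis=0)
            self.sxp[i] = XPt.sum(axis=0)
            self.sxf[i] = Xf.sum(axis=0)

        self.miss = ds.miss_mask.copy()
        miss_rows = np.flatnonzero(self.miss.any(axis=1))
        parity = (ds.df["day_within_burst"].to_numpy() % 2)
        self.miss_batches = [miss_rows[parity[miss_rows] == k] for k in (0, 1)]
        self.n_miss = int(self.miss.sum())

        self.failures = 0
        self.beta_rejects = 0
        self.beta_proposals = 0
        self.stationarity_rejects = 0

        self._initialize()

    # -- initialization ------------------------------------------------------
    def _initialize(self):
        ds, rng = self.ds, self.rng
        y = ds.y.copy()
        for j in range(2):
            col = y[:, j]
            obs = ~np.isnan(col)
            fill = float(np.nanmean(col)) if obs.any() else 0.0
            col[~obs] = fill
        self.y = y

        ridge = 1e-8 * np.eye(self.p)
        XtX = self.X.T @ self.X + ridge
        coef = np.linalg.solve(XtX, self.X.T @ y)       # (p, 2)
        self.delta = np.concatenate([coef[:, 0], coef[:, 1]])
        self.delta += 0.02 * rng.standard_normal(2 * self.p)

        resid = y - self.X @ coef
        pm = _reduce_by_person(resid, self.starts_all) / np.bincount(
            self.pidx, minlength=self.n)[:, None]
        self.m = 0.8 * pm + 0.05 * rng.standard_normal((self.n, 2))

        within = resid - pm[self.pidx]
        sd = np.maximum(within.std(axis=0), 0.05)
        self.sigma = sd * np.exp(0.05 * rng.standard_normal(2))
        self.tau = np.maximum(pm.std(axis=0), 0.05) * np.exp(
            0.05 * rng.standard_normal(2))
        r = np.corrcoef(within[:, 0], within[:, 1])[0, 1]
        r = float(np.clip(np.nan_to_num(r), -0.9, 0.9))
        self.alpha = np.array([np.arctanh(r), 0.0]) + 0.02 * rng.standard_normal(2)
        self.beta = 0.05 * rng.uniform(-1, 1, size=(2, 2))

    # -- cached per-sweep covariance structures ------------------------------
    def _refresh_covs(self):
        self.sig = _person_sigmas(self.sigma, self.alpha, self.exid)
        self.W, self.logdet = _inv_logdet(self.sig)
        self.lyap_inv = _lyapunov_inverse(self.beta)
        stat = _stationary_from_inverse(self.lyap_inv, self.sig)
        self.Wstat, self.logdet_stat = _inv_logdet(stat)
        self.BWB = np.einsum("ba,nbc,cd->nad", self.beta, self.W, self.beta)

    def _mu(self):
        return self.X @ np.column_stack([self.delta[: self.p], self.delta[self.p:]])

    # -- latent missing responses -------------------------------------------
    def _update_missing(self, mu):
        if self.n_miss == 0:
            return
        rng = self.rng
        madd = self.m[self.pidx]
        for rows in self.miss_batches:
            if len(rows) == 0:
                continue
            pr = self.pidx[rows]
            is_first = self.first[rows]
            center = mu[rows] + madd[rows]
            a = center.copy()
            has_prev = ~is_first
            prev_rows = self.prev[rows[has_prev]]
            dev_prev = (self.y[prev_rows] - mu[prev_rows] - madd[rows[has_prev]])
            a[has_prev] += dev_prev @ self.beta.T
            P_own = np.where(is_first[:, None, None], self.Wstat[pr], self.W[pr])

            Lam = P_own.copy()
            eta = np.einsum("nij,nj->ni", P_own, a)
            succ = self.succ[rows]
            has_succ = succ >= 0
            if has_succ.any():
                sr = succ[has_succ]
                pr_s = pr[has_succ]
                d = self.y[sr] - mu[sr] - self.m[pr_s]
                BW = np.einsum("ba,nbc->nac", self.beta, self.W[pr_s])
                eta[has_succ] += np.einsum("nij,nj->ni", BW, d) + np.einsum(
                    "nij,nj->ni", self.BWB[pr_s], center[has_succ])
                Lam[has_succ] += self.BWB[pr_s]

            cov, _ = _inv_logdet(Lam)
            mean = np.einsum("nij,nj->ni", cov, eta)

            mask = self.miss[rows]
            both = mask.all(axis=1)
            if both.any():
                ch = np.linalg.cholesky(cov[both])
                z = rng.standard_normal((int(both.sum()), 2))
                self.y[rows[both]] = mean[both] + np.einsum("nij,nj->ni", ch, z)
            for k in (0, 1):
                o = 1 - k
                only = mask[:, k] & ~mask[:, o]
                if not only.any():
                    continue
                rr = rows[only]
                mu_k = mean[only, k] + cov[only, k, o] / cov[only, o, o] * (
                    self.y[rr, o] - mean[only, o])
                var_k = cov[only, k, k] - cov[only, k, o] ** 2 / cov[only, o, o]
                self.y[rr, k] = mu_k + np.sqrt(np.maximum(var_k, 0.0)) * \
                    rng.standard_normal(int(only.sum()))

    # -- joint delta draw with m marginalized --------------------------------
    def _update_delta_m(self, mu):
        rng = self.rng
        p = self.p
        B = self.beta
        W = self.W
        Wf = self.Wstat if self.stationary_first else np.zeros_like(self.W)
        IB = _EYE2 - B

        WB = W @ B
        BtWB = np.einsum("ba,nbc,cd->nad", B, W, B)
        WC = W @ IB
        BtWC = np.einsum("ba,nbc->nac", B, WC)

        def kron_sum(K, G):
            # sum_i K_i kron-expanded against person Gram G_i -> (2p, 2p)
            return np.einsum("nab,npq->apbq", K, G).reshape(2 * p, 2 * p)

        A0 = kron_sum(W, self.Gxx) + kron_sum(BtWB, self.Gpp) + kron_sum(Wf, self.Gff)
        T1 = kron_sum(WB, self.Gxp)
        A0 -= T1 + T1.T

        # residual target r_t = y_t - B y_{t-1} (first days: r_t = y_t)
        r = self.y.copy()
        tr = self.trans
        r[tr] -= self.y[self.prev[tr]] @ B.T
        Wrows = np.where(self.first[:, None, None], Wf[self.pidx], W[self.pidx])
        v = np.einsum("nij,nj->ni", Wrows, r)
        vB = v @ B
        b0 = np.concatenate([
            self.X.T @ v[:, 0] - self.XP.T @ vB[:, 0],
            self.X.T @ v[:, 1] - self.XP.T @ vB[:, 1],
        ])

        # person-level cross terms for the Woodbury correction
        U = (np.einsum("nac,np->apnc", WC, self.sx)
             - np.einsum("nac,np->apnc", BtWC, self.sxp)
             + np.einsum("nac,np->apnc", Wf, self.sxf))
        U = U.reshape(2 * p, self.n, 2).transpose(1, 0, 2)    # (n, 2p, 2)
        CtWC = np.einsum("ba,nbc,cd->nad", IB, W, IB)
        V = (self.n_trans[:, None, None] * CtWC
             + self.n_first[:, None, None] * Wf)
        vsum = _reduce_by_person(v, self.starts_all)
        vsum_f = np.zeros((self.n, 2))
        np.add.at(vsum_f, self.pidx_f, v[self.first])
        h = (vsum - vsum_f) @ IB + vsum_f

        Tinv = np.diag(1.0 / self.tau ** 2)
        D, _ = _inv_logdet(Tinv[None, :, :] + V)

        A = A0 - np.einsum("npc,ncd,nqd->pq", U, D, U)
        b = b0 - np.einsum("npc,ncd,nd->p", U, D, h)
        if self.prior.delta_sd is not None:
            A = A + np.eye(2 * p) / self.prior.delta_sd ** 2
        A = (A + A.T) / 2.0
        try:
            cf = cho_factor(A, lower=True)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(
                "singular coefficient precision: the design is rank-deficient; "
                "set PriorConfig.delta_sd to use the proper wide-normal prior"
            ) from err
        mean = cho_solve(cf, b)
        z = rng.standard_normal(2 * p)
        self.delta = mean + solve_triangular(cf[0].T, z, lower=False)

        # conditional draw of the random effects given the new delta
        hh = h - np.einsum("npc,p->nc", U, self.delta)
        mmean = np.einsum("ncd,nd->nc", D, hh)
        chD = np.linalg.cholesky(D)
        self.m = mmean + np.einsum("nij,nj->ni", chD,
                                   rng.standard_normal((self.n, 2)))

    # -- residual cross-products --------------------------------------------
    def _stats(self, mu):
        e = self.y - mu - self.m[self.pidx]
        e1 = e[self.trans]
        e0 = e[self.prev[self.trans]]
        S11 = _reduce_by_person(np.einsum("ti,tj->tij", e1, e1), self.starts_t)
        S01 = _reduce_by_person(np.einsum("ti,tj->tij", e1, e0), self.starts_t)
        S00 = _reduce_by_person(np.einsum("ti,tj->tij", e0, e0), self.starts_t)
        ef = e[self.first]
        F = _reduce_by_person(np.einsum("ti,tj->tij", ef, ef), self.starts_f)
        return S11, S01, S00, F

    # -- transition matrix ---------------------------------------------------
    def _update_beta(self, S11, S01, S00, F):
        rng = self.rng
        self.beta_proposals += 1
        A = np.einsum("nab,ncd->acbd", self.W, S00).reshape(4, 4)
        A = (A + A.T) / 2.0 + 1e-10 * np.eye(4)
        bvec = np.einsum("nab,nbc->ac", self.W, S01).reshape(4)
        try:
            cf = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            self.failures += 1
            return
        mean = cho_solve(cf, bvec)
        prop = mean + solve_triangular(cf[0].T, rng.standard_normal(4), lower=False)
        if np.any(np.abs(prop) >= 1.0):
            self.beta_rejects += 1
            return
        Bprop = prop.reshape(2, 2)
        if self.stationary_first:
            if _specrad2(Bprop) >= 1.0:
                self.stationarity_rejects += 1
                self.beta_rejects += 1
                return
            cur = _first_day_loglik(self.sig, F, self.n_first, self.lyap_inv)
            new = _first_day_loglik(self.sig, F, self.n_first,
                                    _lyapunov_inverse(Bprop))
            log_acc = new - cur
        else:
            log_acc = 0.0
        if np.log(rng.random()) < log_acc:
            self.beta = Bprop
            self.lyap_inv = _lyapunov_inverse(Bprop)

    # -- sigma / alpha / tau -------------------------------------------------
    def _cov_target(self, sigma, alpha, S11, S01, S00, F):
        sig = _person_sigmas(sigma, alpha, self.exid)
        W, logdet = _inv_logdet(sig)
        ll = _transition_loglik(self.beta, W, logdet, S11, S01, S00, self.n_trans)
        if self.stationary_first:
            ll += _first_day_loglik(sig, F, self.n_first, self.lyap_inv)
        return ll

    def _update_scales(self, S11, S01, S00, F):
        rng = self.rng
        scale = self.prior.sigma_scale_eff

        for j in (0, 1):
            def logf(ls, j=j):
                s = self.sigma.copy()
                s[j] = np.exp(ls)
                return (self._cov_target(s, self.alpha, S11, S01, S00, F)
                        + _halfnorm_logpdf(s[j], scale) + ls)
            self.sigma[j] = np.exp(slice_update(np.log(self.sigma[j]), logf,
                                                rng, w=0.1))
        for j in (0, 1):
            def logf(a, j=j):
                al = self.alpha.copy()
                al[j] = a
                lp = self._cov_target(self.sigma, al, S11, S01, S00, F)
                if self.prior.alpha_sd is not None:
                    lp += -0.5 * (a / self.prior.alpha_sd) ** 2
                return lp
            self.alpha[j] = slice_update(self.alpha[j], logf, rng, w=0.1)

    def _update_tau(self):
        rng = self.rng
        scale = self.prior.tau_scale_eff
        for j in (0, 1):
            ssq = float(np.sum(self.m[:, j] ** 2))
            def logf(lt, ssq=ssq):
                t = np.exp(lt)
                return (-self.n * lt - 0.5 * ssq / t ** 2
                        + _halfnorm_logpdf(t, scale) + lt)
            self.tau[j] = np.exp(slice_update(np.log(self.tau[j]), logf,
                                              rng, w=0.3))

    # -- one sweep -----------------------------------------------------------
    def sweep(self):
        self._refresh_covs()
        mu = self._mu()
        self._update_missing(mu)
        self._update_delta_m(mu)
        mu = self._mu()
        stats_ = self._stats(mu)
        self._update_beta(*stats_)
        self._update_scales(*stats_)
        self._update_tau()
        if not (np.all(np.isfinite(self.delta)) and np.all(np.isfinite(self.m))
                and np.all(np.isfinite(self.sigma)) and np.all(np.isfinite(self.tau))
                and np.all(np.isfinite(self.alpha)) and np.all(np.isfinite(self.beta))):
            self.failures += 1

    def snapshot(self):
        return (self.delta.copy(), self.m.copy(), self.beta.reshape(4).copy(),
                self.sigma.copy(), self.tau.copy(), self.alpha.copy(),
                self.y[self.miss].copy())


def run_chain(ds, prior: PriorConfig, warmup: int, draws: int,
              first_day: str, rng) -> dict:
    """Run one chain; returns stacked draw arrays and sampler counters."""
    state = _ChainState(ds, prior, first_day, rng)
    p, n = state.p, state.n
    out = {
        "delta": np.empty((draws, 2 * p)),
        "m": np.empty((draws, n, 2)),
        "beta": np.empty((draws, 4)),
        "sigma": np.empty((draws, 2)),
        "tau": np.empty((draws, 2)),
        "alpha": np.empty((draws, 2)),
        "y_miss": np.empty((draws, state.n_miss)),
    }
    for _ in range(warmup):
        state.sweep()
    for it in range(draws):
        state.sweep()
        d, m, b, s, t, a, ym = state.snapshot()
        out["delta"][it] = d
        out["m"][it] = m
        out["beta"][it] = b
        out["sigma"][it] = s
        out["tau"][it] = t
        out["alpha"][it] = a
        out["y_miss"][it] = ym
    out["counters"] = {
        "failures": state.failures,
        "beta_rejects": state.beta_rejects,
        "beta_proposals": state.beta_proposals,
        "stationarity_rejects": state.stationarity_rejects,
    }
    return out
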