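"""Generalized linear mixed models with a correlated random intercept and
slope, fitted by maximum likelihood under a Laplace approximation.

The contact analyses need a binomial GLMM (daily contact fixes out of
linked fixes) and a Gamma GLMM with log link (distance to the nest during
contact), each with correlated random variation in the intercept and the
chick-age slope among chicks.  No maintained Python package fits these by
maximum likelihood with a correlated random slope, so the marginal
likelihood is computed here directly: for each grouping level the joint
log-density of data and random effects is maximized over the 2-d random
effect by Newton iterations, and the integral over the random effects is
replaced by its Laplace approximation (the same approximation lme4 uses at
nAGQ = 1, so log-likelihoods are comparable).

Parameterization of the random-effect covariance: log standard deviations
and an atanh-transformed correlation, keeping the optimizer unconstrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.tools import numdiff

Family = Literal["binomial", "gamma-log"]

_LOG2PI = np.log(2.0 * np.pi)


def _binom_loglik_terms(y, n, eta):
    """Per-row binomial log-likelihood, its first and (negative) second
    derivative w.r.t. the linear predictor (logit link)."""
    mu = special.expit(eta)
    ll = special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1) \
        + y * eta - n * np.logaddexp(0.0, eta)
    grad = y - n * mu
    neg_hess = n * mu * (1.0 - mu)
    return ll, grad, neg_hess


def _gamma_loglik_terms(y, alpha, eta):
    """Per-row Gamma log-likelihood (shape alpha, log link), derivatives
    w.r.t. the linear predictor eta = log(mu)."""
    mu = np.exp(eta)
    r = y / mu
    ll = alpha * np.log(alpha) - special.gammaln(alpha) + (alpha - 1.0) * np.log(y) \
        - alpha * eta - alpha * r
    grad = alpha * (r - 1.0)
    neg_hess = alpha * r
    return ll, grad, neg_hess


def _unpack_cov(theta: np.ndarray) -> np.ndarray:
    """(log sd0, log sd1, atanh rho) -> 2x2 covariance matrix."""
    s0, s1 = np.exp(theta[0]), np.exp(theta[1])
    rho = np.tanh(theta[2])
    return np.array([[s0 * s0, rho * s0 * s1], [rho * s0 * s1, s1 * s1]])


class MixedGLM:
    """GLMM with one grouping factor and a correlated random intercept +
    slope, fitted by Laplace-approximated maximum likelihood.

    Parameters
    ----------
    endog : array
        Response.  For the binomial family: number of successes per row
        (``trials`` must be given).  For the Gamma family: positive values.
    exog : DataFrame or array
        Fixed-effects design matrix (include the constant explicitly).
    groups : array
        Grouping labels (one random-effect vector per distinct label).
    exog_re : array of shape (n, 2), optional
        Random-effects design per row; defaults to a column of ones next
        to the second column of ``exog`` (intercept + first covariate).
    family : 'binomial' or 'gamma-log'
    trials : array, required for the binomial family
    """

    def __init__(self, endog, exog, groups, exog_re=None,
                 family: Family = "binomial", trials=None):
        self.family: Family = family
        if family not in ("binomial", "gamma-log"):
            raise ValueError(f"unsupported family {family!r}")
        self.endog = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            self.exog = exog.to_numpy(dtype=float)
        else:
            self.exog = np.asarray(exog, dtype=float)
            self.exog_names = [f"x{i}" for i in range(self.exog.shape[1])]
        n = len(self.endog)
        if family == "binomial":
            if trials is None:
                raise ValueError("binomial family requires trials")
            self.trials = np.asarray(trials, dtype=float)
            if np.any(self.endog > self.trials) or np.any(self.endog < 0):
                raise ValueError("successes must lie in [0, trials]")
        else:
            self.trials = None
            if np.any(self.endog <= 0):
                raise ValueError("Gamma responses must be strictly positive")
        codes, self.group_labels = pd.factorize(np.asarray(groups))
        order = np.argsort(codes, kind="stable")
        self._order = order
        self.codes = codes[order]
        self.endog = self.endog[order]
        self.exog = self.exog[order]
        if self.trials is not None:
            self.trials = self.trials[order]
        if exog_re is None:
            if self.exog.shape[1] < 2:
                raise ValueError("default exog_re needs >= 2 fixed-effect columns")
            exog_re = np.column_stack([np.ones(n), self.exog[:, 1]])
        else:
            exog_re = np.asarray(exog_re, dtype=float)[order]
        if exog_re.shape != (n, 2):
            raise ValueError("exog_re must have shape (n, 2)")
        self.exog_re = exog_re
        self.n_groups = len(self.group_labels)
        self.k_fe = self.exog.shape[1]
        # per-group slices (codes are sorted)
        self._bounds = np.searchsorted(self.codes, np.arange(self.n_groups + 1))

    # ---- Laplace marginal log-likelihood ------------------------------

    def _cond_terms(self, eta, extra):
        if self.family == "binomial":
            return _binom_loglik_terms(self.endog, self.trials, eta)
        return _gamma_loglik_terms(self.endog, np.exp(extra), eta)

    def _profile_b(self, offset, cov_inv, extra, b0=None, tol=1e-9, maxiter=60):
        """Newton maximization of the joint log-density over the per-group
        random effects, with step halving to guarantee monotone ascent;
        vectorized over groups via 2x2 closed-form solves."""
        G = self.n_groups
        b = np.zeros((G, 2)) if b0 is None else b0.copy()
        z = self.exog_re
        g = self.codes

        def joint(bmat):
            eta = offset + np.einsum("ij,ij->i", z, bmat[g])
            ll, grad_eta, w = self._cond_terms(eta, extra)
            per_group = np.bincount(g, ll, minlength=G) \
                - 0.5 * np.einsum("ij,jk,ik->i", bmat, cov_inv, bmat)
            return per_group, grad_eta, w

        obj, grad_eta, w = joint(b)
        for _ in range(maxiter):
            gb = np.column_stack([
                np.bincount(g, grad_eta * z[:, 0], minlength=G),
                np.bincount(g, grad_eta * z[:, 1], minlength=G),
            ]) - b @ cov_inv
            if float(np.max(np.abs(gb))) < tol:
                break
            h00 = np.bincount(g, w * z[:, 0] * z[:, 0], minlength=G) + cov_inv[0, 0]
            h01 = np.bincount(g, w * z[:, 0] * z[:, 1], minlength=G) + cov_inv[0, 1]
            h11 = np.bincount(g, w * z[:, 1] * z[:, 1], minlength=G) + cov_inv[1, 1]
            det = h00 * h11 - h01 * h01
            step = np.column_stack([
                (h11 * gb[:, 0] - h01 * gb[:, 1]) / det,
                (h00 * gb[:, 1] - h01 * gb[:, 0]) / det,
            ])
            # per-group backtracking: halve any group's step until it improves
            scale = np.ones(G)
            for _ in range(25):
                cand = b + step * scale[:, None]
                obj_new, grad_eta_new, w_new = joint(cand)
                worse = obj_new < obj - 1e-12
                if not worse.any():
                    break
                scale[worse] *= 0.5
            b = b + step * scale[:, None]
            obj, grad_eta, w = joint(b)
        eta = offset + np.einsum("ij,ij->i", z, b[g])
        ll, _, w = self._cond_terms(eta, extra)
        h00 = np.bincount(g, w * z[:, 0] * z[:, 0], minlength=G) + cov_inv[0, 0]
        h01 = np.bincount(g, w * z[:, 0] * z[:, 1], minlength=G) + cov_inv[0, 1]
        h11 = np.bincount(g, w * z[:, 1] * z[:, 1], minlength=G) + cov_inv[1, 1]
        logdet_h = np.log(h00 * h11 - h01 * h01)
        return b, float(ll.sum()), logdet_h

    def loglike(self, params: np.ndarray, _cache={}) -> float:
        """Laplace-approximated marginal log-likelihood.

        ``params`` = fixed effects, then (log sd0, log sd1, atanh rho),
        then log shape for the Gamma family.
        """
        beta = params[: self.k_fe]
        theta = params[self.k_fe: self.k_fe + 3]
        extra = params[self.k_fe + 3] if self.family == "gamma-log" else 0.0
        cov = _unpack_cov(theta)
        det_cov = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
        if det_cov <= 1e-300:
            return -np.inf
        cov_inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[0, 1], cov[0, 0]]]) / det_cov
        offset = self.exog @ beta
        b0 = _cache.get("b")
        if b0 is not None and b0.shape != (self.n_groups, 2):
            b0 = None
        b, cond_ll, logdet_h = self._profile_b(offset, cov_inv, extra, b0=b0)
        _cache["b"] = b
        quad = np.einsum("ij,jk,ik->i", b, cov_inv, b)
        ll = cond_ll - 0.5 * quad.sum() \
            - 0.5 * self.n_groups * np.log(det_cov) - 0.5 * logdet_h.sum()
        if not np.isfinite(ll):
            return -np.inf
        return float(ll)

    def _start_params(self) -> np.ndarray:
        import statsmodels.api as sm

        if self.family == "binomial":
            y = np.column_stack([self.endog, self.trials - self.endog])
            glm = sm.GLM(y, self.exog, family=sm.families.Binomial())
            res = glm.fit()
            start = np.concatenate([res.params, [np.log(0.7), np.log(0.3), 0.0]])
        else:
            glm = sm.GLM(self.endog, self.exog,
                         family=sm.families.Gamma(link=sm.families.links.Log()))
            res = glm.fit()
            alpha0 = max(1.0 / max(res.scale, 1e-6), 0.1)
            start = np.concatenate([res.params,
                                    [np.log(0.7), np.log(0.3), 0.0, np.log(alpha0)]])
        return start

    def fit(self, start_params=None, maxiter: int = 300) -> "MixedGLMResults":
        start = self._start_params() if start_params is None else np.asarray(start_params, float)
        cache: dict = {}
        neg = lambda p: -self.loglike(p, cache)
        # box constraints keep the variance parameters out of the flat
        # saturation regions (rho -> +-1, sd -> 0 or infinity)
        bounds = [(None, None)] * self.k_fe + [(-5.0, 3.0), (-5.0, 3.0), (-3.0, 3.0)]
        if self.family == "gamma-log":
            bounds.append((-3.0, 8.0))
        res = optimize.minimize(neg, start, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-11,
                                         "gtol": 1e-7})
        params = res.x
        llf = -res.fun
        hess = numdiff.approx_hess(params, neg)
        try:
            cov_params = np.linalg.inv(hess)
            bse_ok = np.all(np.diag(cov_params)[: self.k_fe] > 0)
        except np.linalg.LinAlgError:
            cov_params = np.full((len(params), len(params)), np.nan)
            bse_ok = False
        converged = bool(res.success or np.isfinite(llf)) and bse_ok
        return MixedGLMResults(self, params, llf, cov_params, converged)


@dataclass
class MixedGLMResults:
    """Laplace-GLMM fit: estimates, uncertainties and fit statistics."""

    model: MixedGLM
    params: np.ndarray
    llf: float
    cov_params: np.ndarray
    converged: bool

    @property
    def fe_params(self) -> pd.Series:
        return pd.Series(self.params[: self.model.k_fe], index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        var = np.diag(self.cov_params)[: self.model.k_fe]
        return pd.Series(np.sqrt(np.where(var > 0, var, np.nan)),
                         index=self.model.exog_names)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1.0 - alpha / 2.0)
        lo = self.fe_params - z * self.bse
        hi = self.fe_params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    @property
    def re_sd(self) -> pd.Series:
        th = self.params[self.model.k_fe: self.model.k_fe + 3]
        return pd.Series({"sd_intercept": np.exp(th[0]), "sd_slope": np.exp(th[1]),
                          "corr": np.tanh(th[2])})

    @property
    def k_params(self) -> int:
        """Every estimated parameter: fixed effects + 2 random-effect SDs +
        their correlation (+ Gamma shape)."""
        return len(self.params)

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    def summary(self) -> str:
        lines = [f"MixedGLM ({self.model.family}), Laplace ML",
                 f"groups: {self.model.n_groups}   obs: {self.nobs}   "
                 f"logLik: {self.llf:.3f}   k: {self.k_params}   "
                 f"converged: {self.converged}", "", "Fixed effects:"]
        ci = self.conf_int()
        for name in self.model.exog_names:
            lines.append(f"  {name:<20s} {self.fe_params[name]: .4f}  "
                         f"(SE {self.bse[name]:.4f}, 95% CI "
                         f"[{ci.loc[name, 'lower']: .4f}, {ci.loc[name, 'upper']: .4f}])")
        re = self.re_sd
        lines.append("Random effects (per group):")
        lines.append(f"  sd(intercept) {re['sd_intercept']:.4f}  "
                     f"sd(slope) {re['sd_slope']:.4f}  corr {re['corr']:.3f}")
        if self.model.family == "gamma-log":
            lines.append(f"  Gamma shape {np.exp(self.params[-1]):.4f}")
        return "\n".join(lines)
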