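"""Direct utility-mapping estimators: OLS, upper-censored Tobit, beta-mixture.

All three regress the observed SF-6D utility on FACT-L design matrices
(see :func:`sf6dmap.instruments.build_design_matrix`; the matrices carry
their own intercept column).  Estimators follow the scikit-learn protocol
— ``fit(X, y)``, ``predict(X)``, ``get_params``/``set_params``, fitted
attributes with a trailing underscore — and each exposes the maximised
log-likelihood together with its parameter count so information criteria
are comparable across families.  The parameter count includes *every*
estimated quantity: regression coefficients, the error SD, precisions,
mixture-weight and boundary-mass parameters.

The beta-mixture family targets the two awkward features of utility
data: the ceiling spike at full health (a separately modelled boundary
probability on a logit link) and multimodality below it (a mixture of
beta densities on the rescaled open interval).  The truncated variant
additionally excises the gap between full health and the next feasible
tariff value from the continuous support.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, RegressorMixin

from ._scaling import coef_to_raw, orthonormalize

__all__ = [
    "LinearUtilityRegression",
    "TobitRegression",
    "BetaMixtureRegression",
    "fit_ols",
    "fit_tobit",
    "fit_betamix",
    "predict_direct",
]

_LOG2PI = np.log(2.0 * np.pi)


def _polish(fun_grad, res, args):
    """Drive the gradient further down with a full-BFGS pass; keep the better."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res2 = optimize.minimize(
                fun_grad,
                res.x,
                args=args,
                jac=True,
                method="BFGS",
                options={"maxiter": 1000, "gtol": 1e-10},
            )
        except Exception:
            return res
    if np.isfinite(res2.fun) and res2.fun <= res.fun + 1e-12:
        res2.success = bool(res.success or res2.success)
        return res2
    return res


def _check_Xy(X, y=None):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if y is None:
        return X
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != X.shape[0]:
        raise ValueError("X and y lengths differ")
    return X, y


def _check_columns(fit, X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != fit.n_features_:
        raise ValueError(
            f"X has {X.shape[1]} columns but the fit used {fit.n_features_}"
        )
    return X


class LinearUtilityRegression(RegressorMixin, BaseEstimator):
    """Ordinary least squares with a Gaussian log-likelihood at the ML variance.

    Predictions are the unclamped linear index and may exceed the utility
    bounds — that is the point of comparison with the bounded families.
    """

    def __init__(self, feature_names: list[str] | None = None):
        self.feature_names = feature_names

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        n, p = X.shape
        if n <= p:
            raise ValueError(f"need more observations ({n}) than columns ({p})")
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            # name the columns a pivoted QR pushes to the back
            import scipy.linalg as sla

            _, _, piv = sla.qr(X, mode="economic", pivoting=True)
            bad = sorted(piv[rank:].tolist())
            names = self.feature_names or [f"x{j}" for j in range(p)]
            raise ValueError(
                f"design matrix is rank deficient; collinear columns: "
                f"{[names[j] for j in bad]}"
            )
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / n  # ML (n-divisor) variance
        self.coef_ = beta
        self.sigma_ = float(np.sqrt(sigma2))
        # a perfect fit has unbounded Gaussian likelihood; floor the variance
        self.loglik_ = float(-0.5 * n * (_LOG2PI + np.log(max(sigma2, 1e-300)) + 1.0))
        self.n_obs_ = n
        self.n_features_ = p
        self.n_params_ = p + 1  # + sigma
        self.feature_names_ = list(self.feature_names or [f"x{j}" for j in range(p)])
        return self

    def predict(self, X):
        return _check_columns(self, X) @ self.coef_

    def to_dict(self) -> dict:
        return {
            "type": "ols",
            "feature_names": self.feature_names_,
            "coefficients": self.coef_.tolist(),
            "sigma": self.sigma_,
            "loglik": self.loglik_,
            "n_obs": self.n_obs_,
            "n_params": self.n_params_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearUtilityRegression":
        est = cls(feature_names=d.get("feature_names"))
        est.coef_ = np.asarray(d["coefficients"], dtype=float)
        est.sigma_ = float(d["sigma"])
        est.loglik_ = float(d["loglik"])
        est.n_obs_ = int(d["n_obs"])
        est.n_features_ = len(est.coef_)
        est.n_params_ = int(d["n_params"])
        est.feature_names_ = list(d.get("feature_names") or [])
        return est


class TobitRegression(RegressorMixin, BaseEstimator):
    """Gaussian regression with upper censoring at the utility ceiling.

    Observations at or above ``upper_limit`` contribute the upper-tail
    probability to the likelihood; the rest contribute the normal density.
    ``predict`` returns E[min(Y*, limit)], the expected value of the
    censored outcome under the fitted latent normal.
    """

    def __init__(
        self,
        upper_limit: float = 1.0,
        feature_names: list[str] | None = None,
        tol: float = 1e-10,
    ):
        self.upper_limit = upper_limit
        self.feature_names = feature_names
        self.tol = tol

    def _nll_grad(self, theta, X, y, cens):
        beta, logs = theta[:-1], theta[-1]
        sigma = np.exp(logs)
        eta = X @ beta
        ll = 0.0
        g_eta = np.zeros(len(y))
        g_logs = 0.0
        unc = ~cens
        if unc.any():
            r = (y[unc] - eta[unc]) / sigma
            ll += np.sum(-logs - 0.5 * (_LOG2PI + r * r))
            g_eta[unc] = r / sigma
            g_logs += np.sum(r * r - 1.0)
        if cens.any():
            s = (eta[cens] - self.upper_limit) / sigma
            log_cdf = special.log_ndtr(s)
            ll += np.sum(log_cdf)
            ratio = np.exp(stats.norm.logpdf(s) - log_cdf)  # Mills ratio inverse
            g_eta[cens] = ratio / sigma
            g_logs += np.sum(-ratio * s)
        grad = np.concatenate([X.T @ g_eta, [g_logs]])
        return -ll, -grad

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        cens = y >= self.upper_limit
        self.n_censored_ = int(cens.sum())
        if cens.all():
            raise ValueError("no interior observations: every y is at the limit")
        # optimise in the orthonormal column basis; raw-score columns span
        # three orders of magnitude and stall quasi-Newton steps otherwise
        Z, R = orthonormalize(X)
        ols = LinearUtilityRegression().fit(Z, y)
        x0 = np.concatenate([ols.coef_, [np.log(max(ols.sigma_, 1e-6))]])
        res = optimize.minimize(
            self._nll_grad,
            x0,
            args=(Z, y, cens),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 5000, "gtol": self.tol, "ftol": 1e-15},
        )
        res = _polish(self._nll_grad, res, (Z, y, cens))
        beta = coef_to_raw(res.x[:-1], R)
        # gradient norm in the orthonormal basis; raw-scale components are
        # the same quantity amplified by the column scales
        grad_norm = float(np.max(np.abs(res.jac)))
        self.converged_ = bool(res.success and grad_norm < 1e-5)
        if not self.converged_:
            warnings.warn(
                f"Tobit fit did not converge cleanly (grad norm {grad_norm:.2e}): "
                f"{res.message}",
                stacklevel=2,
            )
        self.coef_ = beta
        self.sigma_ = float(np.exp(res.x[-1]))
        self.loglik_ = float(-res.fun)
        self.grad_norm_ = grad_norm
        self.n_obs_ = len(y)
        self.n_features_ = X.shape[1]
        self.n_params_ = X.shape[1] + 1
        self.feature_names_ = list(
            self.feature_names or [f"x{j}" for j in range(X.shape[1])]
        )
        return self

    def predict(self, X, kind: str = "censored_mean"):
        X = _check_columns(self, X)
        eta = X @ self.coef_
        if kind == "latent":
            return eta
        if kind != "censored_mean":
            raise ValueError("kind must be 'censored_mean' or 'latent'")
        L = self.upper_limit
        z = (L - eta) / self.sigma_
        cdf = special.ndtr(z)
        pdf = np.exp(stats.norm.logpdf(z))
        return eta * cdf - self.sigma_ * pdf + L * (1.0 - cdf)

    def to_dict(self) -> dict:
        return {
            "type": "tobit",
            "feature_names": self.feature_names_,
            "coefficients": self.coef_.tolist(),
            "sigma": self.sigma_,
            "upper_limit": self.upper_limit,
            "n_censored": self.n_censored_,
            "loglik": self.loglik_,
            "n_obs": self.n_obs_,
            "n_params": self.n_params_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TobitRegression":
        est = cls(upper_limit=float(d["upper_limit"]), feature_names=d.get("feature_names"))
        est.coef_ = np.asarray(d["coefficients"], dtype=float)
        est.sigma_ = float(d["sigma"])
        est.loglik_ = float(d["loglik"])
        est.n_censored_ = int(d["n_censored"])
        est.n_obs_ = int(d["n_obs"])
        est.n_features_ = len(est.coef_)
        est.n_params_ = int(d["n_params"])
        est.feature_names_ = list(d.get("feature_names") or [])
        est.converged_ = True
        return est


class BetaMixtureRegression(RegressorMixin, BaseEstimator):
    """Beta-mixture regression with an upper-boundary probability mass.

    The outcome is rescaled to ``y* = (y - lb)/(ub - lb)``.  Observations
    exactly at ``ub`` are modelled by a logit boundary probability p(x) on
    the full design; interior observations follow a C-component beta
    mixture whose component means carry a logit link on the design and
    whose precisions are intercept-only log parameters.  Mixture weights
    are intercept-only multinomial logits.  The truncated variant
    renormalises each beta density to y* <= 1 - gap/(ub - lb), excising
    the infeasible interval just below full health.

    Maximisation is direct quasi-Newton over the joint parameter vector,
    best of ``n_starts`` random starts; components are relabelled by
    ascending mean at the covariate mean for identification.  A fit with
    fewer observations than parameters is flagged as non-converged.
    """

    def __init__(
        self,
        components: int = 1,
        truncated: bool = False,
        bounds: tuple[float, float] = (0.315, 1.0),
        gap: float = 0.0,
        boundary_mass: bool | None = None,
        n_starts: int = 10,
        random_state: int = 0,
        feature_names: list[str] | None = None,
        max_iter: int = 1500,
    ):
        self.components = components
        self.truncated = truncated
        self.bounds = bounds
        self.gap = gap
        self.boundary_mass = boundary_mass
        self.n_starts = n_starts
        self.random_state = random_state
        self.feature_names = feature_names
        self.max_iter = max_iter

    # -- parameter packing -------------------------------------------------

    def _unpack(self, theta, p):
        C = self.components
        pos = 0
        betas = theta[pos : pos + C * p].reshape(C, p)
        pos += C * p
        lnphi = theta[pos : pos + C]
        pos += C
        wlog = theta[pos : pos + C - 1]
        pos += C - 1
        gamma = theta[pos : pos + p] if self._use_boundary else None
        return betas, lnphi, wlog, gamma

    def _n_params(self, p):
        C = self.components
        return C * p + C + (C - 1) + (p if self._use_boundary else 0)

    def _log_weights(self, wlog):
        full = np.concatenate([[0.0], wlog])
        return full - special.logsumexp(full)

    def _nll(self, theta, X, ystar, at_ub, upper):
        n, p = X.shape
        betas, lnphi, wlog, gamma = self._unpack(theta, p)
        phi = np.exp(np.clip(lnphi, -10, 10))
        logw = self._log_weights(wlog)
        interior = ~at_ub
        yi = ystar[interior]
        Xi = X[interior]
        comp_ll = np.empty((interior.sum(), self.components))
        for c in range(self.components):
            mu = special.expit(np.clip(Xi @ betas[c], -30, 30))
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
            a = mu * phi[c]
            b = (1.0 - mu) * phi[c]
            logpdf = stats.beta.logpdf(yi, a, b)
            if self.truncated:
                norm = special.betainc(a, b, upper)
                logpdf -= np.log(np.clip(norm, 1e-300, None))
            comp_ll[:, c] = logw[c] + logpdf
        ll = float(special.logsumexp(comp_ll, axis=1).sum())
        if self._use_boundary:
            eta = np.clip(X @ gamma, -30, 30)
            # B*log p + (1-B)*log(1-p), numerically via log_expit
            ll += float(special.log_expit(eta[at_ub]).sum())
            ll += float(special.log_expit(-eta[interior]).sum())
        if not np.isfinite(ll):
            return 1e10
        return -ll

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        n, p = X.shape
        if not 1 <= self.components <= 3:
            raise ValueError("components must lie in 1..3")
        lb, ub = self.bounds
        if y.min() < lb or y.max() > ub:
            raise ValueError(f"y must lie within the rescaling bounds ({lb}, {ub}]")
        ystar = (y - lb) / (ub - lb)
        at_ub = ystar >= 1.0 - 1e-12
        self._use_boundary = bool(at_ub.any()) if self.boundary_mass is None else bool(
            self.boundary_mass
        )
        if self._use_boundary and not at_ub.any():
            raise ValueError("boundary mass requested but no observations at ub")
        if at_ub.any() and not self._use_boundary:
            raise ValueError(
                "observations at ub present; enable boundary_mass or trim them"
            )
        at_lb = ~at_ub & (ystar <= 0.0)
        if at_lb.any():
            warnings.warn(
                f"{int(at_lb.sum())} observation(s) exactly at the lower bound "
                "nudged inward by 1e-6 of the range (beta support is open)",
                stacklevel=2,
            )
            ystar = np.where(at_lb, 1e-6, ystar)
        g = self.gap / (ub - lb)
        upper = 1.0 - g if self.truncated else 1.0
        if self.truncated:
            bad = ~at_ub & (ystar > upper + 1e-12)
            if bad.any():
                raise ValueError(
                    f"{int(bad.sum())} interior observation(s) fall inside the "
                    "truncation gap below ub"
                )

        # deterministic base start: logit-linear fit for the means, spread
        # intercepts across the interior quantiles for extra components
        Z, R = orthonormalize(X)
        interior = ~at_ub
        yl = special.logit(np.clip(ystar[interior], 1e-6, 1 - 1e-6))
        base_beta, *_ = np.linalg.lstsq(Z[interior], yl, rcond=None)
        rng = np.random.default_rng(self.random_state)
        qs = np.quantile(yl, np.linspace(0.25, 0.75, self.components))
        # coefficient vector of the constant predictor in the Q basis,
        # used to shift component intercepts apart
        ones_coef = Z.T @ np.ones(n)
        # coefficient perturbations sized to move the linear predictor O(1)
        coef_scale = 0.5 * np.sqrt(n / max(p, 1))
        starts = []
        for s in range(self.n_starts):
            betas0 = np.tile(base_beta, (self.components, 1))
            betas0 += np.outer(qs - np.median(yl), ones_coef)
            lnphi0 = np.full(self.components, np.log(8.0))
            wlog0 = np.zeros(self.components - 1)
            if s > 0:
                betas0 = betas0 + rng.normal(scale=coef_scale, size=betas0.shape)
                lnphi0 = lnphi0 + rng.normal(scale=0.5, size=lnphi0.shape)
                wlog0 = wlog0 + rng.normal(scale=0.5, size=wlog0.shape)
            parts = [betas0.ravel(), lnphi0, wlog0]
            if self._use_boundary:
                gamma0 = special.logit(np.clip(at_ub.mean(), 1e-6, 1 - 1e-6)) * ones_coef
                if s > 0:
                    gamma0 = gamma0 + rng.normal(scale=coef_scale, size=gamma0.shape)
                parts.append(gamma0)
            starts.append(np.concatenate(parts))

        best = None
        any_success = False
        for theta0 in starts:
            try:
                res = optimize.minimize(
                    self._nll,
                    theta0,
                    args=(Z, ystar, at_ub, upper),
                    method="L-BFGS-B",
                    options={"maxiter": self.max_iter, "ftol": 1e-12},
                )
            except Exception:  # pragma: no cover - optimizer blow-up
                continue
            if best is None or res.fun < best.fun:
                best = res
            any_success = any_success or bool(res.success)
        if best is None:
            raise RuntimeError("all beta-mixture starts failed")

        betas, lnphi, wlog, gamma = self._unpack(best.x, p)
        betas = np.vstack([coef_to_raw(b, R) for b in betas])
        if gamma is not None:
            gamma = coef_to_raw(gamma, R)
        # relabel by ascending component mean at the covariate mean
        mu_bar = special.expit(X.mean(axis=0) @ betas.T)
        order = np.argsort(mu_bar)
        betas = betas[order]
        lnphi = lnphi[order]
        logw = self._log_weights(wlog)[order]
        wlog = logw[1:] - logw[0]

        self.coef_mu_ = betas
        self.lnphi_ = lnphi
        self.phi_ = np.exp(lnphi)
        self.weight_logits_ = wlog
        self.weights_ = np.exp(self._log_weights(wlog))
        self.coef_boundary_ = gamma
        self.loglik_ = float(-best.fun)
        self.n_obs_ = n
        self.n_features_ = p
        self.n_params_ = self._n_params(p)
        self.gap_frac_ = g
        self.upper_ = upper
        self.n_starts_ = len(starts)
        # honest convergence: the optimiser succeeded, the data can support
        # the parameter count (a mixture needs a few observations per
        # parameter), and no precision ran into its numerical bound
        enough_data = n >= 3 * self.n_params_
        phi_interior = bool(np.all(np.abs(lnphi) < 9.99))
        self.converged_ = bool(any_success and enough_data and phi_interior)
        self.diagnostics_ = {
            "message": str(best.message),
            "n_iter": int(best.nit),
            "optimizer_success": bool(best.success),
            "enough_data": bool(enough_data),
            "precision_interior": phi_interior,
        }
        if not self.converged_:
            warnings.warn(
                f"beta-mixture fit flagged non-converged: {self.diagnostics_}",
                stacklevel=2,
            )
        self.feature_names_ = list(self.feature_names or [f"x{j}" for j in range(p)])
        return self

    def _component_means(self, X):
        """Per-component expected y* (truncated mean under the truncated variant)."""
        mus = special.expit(np.clip(X @ self.coef_mu_.T, -30, 30))  # (n, C)
        if not self.truncated:
            return mus
        out = np.empty_like(mus)
        for c in range(self.components):
            a = mus[:, c] * self.phi_[c]
            b = (1.0 - mus[:, c]) * self.phi_[c]
            num = special.betainc(a + 1.0, b, self.upper_)
            den = np.clip(special.betainc(a, b, self.upper_), 1e-300, None)
            out[:, c] = mus[:, c] * num / den
        return out

    def boundary_probability(self, X):
        X = _check_columns(self, X)
        if not self._use_boundary:
            return np.zeros(X.shape[0])
        return special.expit(np.clip(X @ self.coef_boundary_, -30, 30))

    def predict(self, X):
        X = _check_columns(self, X)
        lb, ub = self.bounds
        m = self._component_means(X) @ self.weights_
        pb = self.boundary_probability(X)
        return pb * ub + (1.0 - pb) * (lb + (ub - lb) * m)

    def to_dict(self) -> dict:
        return {
            "type": "betamix",
            "components": self.components,
            "truncated": self.truncated,
            "bounds": list(self.bounds),
            "gap": self.gap,
            "feature_names": self.feature_names_,
            "coef_mu": self.coef_mu_.tolist(),
            "lnphi": self.lnphi_.tolist(),
            "weight_logits": self.weight_logits_.tolist(),
            "coef_boundary": None
            if self.coef_boundary_ is None
            else self.coef_boundary_.tolist(),
            "loglik": self.loglik_,
            "n_obs": self.n_obs_,
            "n_params": self.n_params_,
            "converged": self.converged_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BetaMixtureRegression":
        est = cls(
            components=int(d["components"]),
            truncated=bool(d["truncated"]),
            bounds=tuple(d["bounds"]),
            gap=float(d["gap"]),
            feature_names=d.get("feature_names"),
        )
        est.coef_mu_ = np.asarray(d["coef_mu"], dtype=float)
        est.lnphi_ = np.asarray(d["lnphi"], dtype=float)
        est.phi_ = np.exp(est.lnphi_)
        est.weight_logits_ = np.asarray(d["weight_logits"], dtype=float)
        est.weights_ = np.exp(est._log_weights(est.weight_logits_))
        gb = d.get("coef_boundary")
        est.coef_boundary_ = None if gb is None else np.asarray(gb, dtype=float)
        est._use_boundary = est.coef_boundary_ is not None
        est.loglik_ = float(d["loglik"])
        est.n_obs_ = int(d["n_obs"])
        est.n_features_ = est.coef_mu_.shape[1]
        est.n_params_ = int(d["n_params"])
        est.converged_ = bool(d.get("converged", True))
        lb, ub = est.bounds
        est.gap_frac_ = est.gap / (ub - lb)
        est.upper_ = 1.0 - est.gap_frac_ if est.truncated else 1.0
        est.feature_names_ = list(d.get("feature_names") or [])
        return est


# -- thin functional wrappers ---------------------------------------------


def fit_ols(X, y, feature_names=None) -> LinearUtilityRegression:
    return LinearUtilityRegression(feature_names=feature_names).fit(X, y)


def fit_tobit(X, y, upper_limit: float = 1.0, feature_names=None) -> TobitRegression:
    return TobitRegression(upper_limit=upper_limit, feature_names=feature_names).fit(X, y)


def fit_betamix(
    X,
    y,
    components: int = 1,
    truncated: bool = False,
    bounds: tuple[float, float] = (0.315, 1.0),
    gap: float = 0.0,
    n_starts: int = 10,
    seed: int = 0,
    **kwargs,
) -> BetaMixtureRegression:
    return BetaMixtureRegression(
        components=components,
        truncated=truncated,
        bounds=bounds,
        gap=gap,
        n_starts=n_starts,
        random_state=seed,
        **kwargs,
    ).fit(X, y)


def predict_direct(fit, X) -> np.ndarray:
    """Predicted utilities from any fitted direct-mapping estimator."""
    return fit.predict(X)
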