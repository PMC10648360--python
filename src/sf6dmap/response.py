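"""Indirect (response) mapping: ordered probits combined through a tariff.

One ordered probit is fitted per SF-6D dimension, predicting the ordinal
response level from the FACT-L design matrix.  The latent index carries
no intercept — the cutpoints absorb location — and cutpoints are
parameterised as a first cutpoint plus exponentiated increments, so
monotonicity holds by construction.  Expected utilities follow by
pushing the per-dimension level probabilities through the tariff,
assuming independence across dimensions conditional on the covariates
(the six equations are estimated separately, so nothing else is
identified anyway).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from ._scaling import coef_to_raw, orthonormalize
from .direct import _polish
from .instruments import build_design_matrix
from .tariff import Tariff

__all__ = [
    "OrderedProbit",
    "ResponseMappingModel",
    "fit_ordered_probit",
    "level_probabilities",
    "fit_response_mapping",
    "expected_utility",
]


class OrderedProbit(BaseEstimator):
    """Ordered probit by maximum likelihood, intercept-free with monotone cutpoints.

    ``P(level = l | x) = ndtr(kappa_l - x beta) - ndtr(kappa_{l-1} - x beta)``
    with ``kappa_0 = -inf`` and ``kappa_L = +inf``.  Levels absent from the
    training data are collapsed onto the nearest observed level (recorded
    in ``level_map_``) and receive zero predicted probability.
    """

    def __init__(self, n_levels: int, name: str = "", tol: float = 1e-10):
        self.n_levels = n_levels
        self.name = name
        self.tol = tol

    def _theta_to_cuts(self, theta, p, K):
        kappa = np.empty(K)
        kappa[0] = theta[p]
        if K > 1:
            kappa[1:] = theta[p] + np.cumsum(np.exp(theta[p + 1 : p + K]))
        return kappa

    def _nll_grad(self, theta, X, cat, K):
        n, p = X.shape
        beta = theta[:p]
        kappa = self._theta_to_cuts(theta, p, K)
        eta = X @ beta
        ext = np.concatenate([[-np.inf], kappa, [np.inf]])
        zu = ext[cat + 1] - eta
        zl = ext[cat] - eta
        P = special.ndtr(zu) - special.ndtr(zl)
        P = np.clip(P, 1e-300, None)
        ll = float(np.log(P).sum())

        pu = np.where(np.isfinite(zu), np.exp(stats.norm.logpdf(zu)), 0.0)
        pl = np.where(np.isfinite(zl), np.exp(stats.norm.logpdf(zl)), 0.0)
        d_eta = -(pu - pl) / P
        g_beta = X.T @ d_eta
        # gradient w.r.t. each cutpoint
        g_kappa = np.zeros(K)
        np.add.at(g_kappa, np.clip(cat, 0, K - 1), np.where(cat <= K - 1, pu / P, 0.0))
        np.add.at(
            g_kappa,
            np.clip(cat - 1, 0, K - 1),
            np.where(cat >= 1, -pl / P, 0.0),
        )
        # chain rule into (kappa_1, log-increments)
        g_theta = np.empty(K)
        g_theta[0] = g_kappa.sum()
        for j in range(1, K):
            g_theta[j] = g_kappa[j:].sum() * np.exp(theta[p + j])
        return -ll, -np.concatenate([g_beta, g_theta])

    def fit(self, X, levels):
        X = np.asarray(X, dtype=float)
        levels = np.asarray(levels, dtype=int)
        if X.ndim != 2 or len(levels) != X.shape[0]:
            raise ValueError("X and levels shapes disagree")
        L = self.n_levels
        if levels.min() < 1 or levels.max() > L:
            raise ValueError(f"levels must lie in 1..{L}")
        observed = np.unique(levels)
        if len(observed) < 2:
            raise ValueError(
                f"dimension {self.name or '?'}: a single observed level cannot "
                "identify an ordered probit"
            )
        # collapse unobserved levels onto the nearest observed one
        level_map = {}
        for l in range(1, L + 1):
            nearest = observed[np.argmin(np.abs(observed - l))]
            level_map[l] = int(nearest)
        if len(observed) < L:
            warnings.warn(
                f"dimension {self.name or '?'}: levels "
                f"{sorted(set(range(1, L + 1)) - set(observed.tolist()))} unobserved; "
                "collapsed onto nearest observed levels",
                stacklevel=2,
            )
        compressed = np.searchsorted(observed, levels)  # 0-based category index
        K = len(observed) - 1
        n, p = X.shape

        freqs = np.bincount(compressed, minlength=K + 1) / n
        kappa0 = stats.norm.ppf(np.cumsum(freqs)[:-1])
        theta0 = np.zeros(p + K)
        theta0[p] = kappa0[0]
        if K > 1:
            theta0[p + 1 :] = np.log(np.clip(np.diff(kappa0), 1e-6, None))
        # optimise in the orthonormal column basis; the linear predictor is
        # identical there, so the cutpoints transfer unchanged
        Z, R = orthonormalize(X)
        res = optimize.minimize(
            self._nll_grad,
            theta0,
            args=(Z, compressed, K),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 5000, "gtol": self.tol, "ftol": 1e-15},
        )
        res = _polish(self._nll_grad, res, (Z, compressed, K))
        beta = coef_to_raw(res.x[:p], R)
        cuts = self._theta_to_cuts(res.x, p, K)
        # gradient norm in the orthonormal basis (raw-scale components are
        # the same quantity amplified by the column scales)
        grad_norm = float(np.max(np.abs(res.jac)))
        self.converged_ = bool(res.success and grad_norm < 1e-5)
        if not self.converged_:
            warnings.warn(
                f"ordered probit {self.name or '?'} convergence doubtful "
                f"(grad norm {grad_norm:.2e}): {res.message}",
                stacklevel=2,
            )
        self.coef_ = beta
        self.cutpoints_ = cuts
        self.observed_levels_ = observed.tolist()
        self.level_map_ = level_map
        self.loglik_ = float(-res.fun)
        self.grad_norm_ = grad_norm
        self.n_obs_ = n
        self.n_features_ = p
        self.n_params_ = p + K
        return self

    def level_probabilities(self, X):
        """(n, n_levels) matrix of level probabilities; rows sum to 1."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"X has {X.shape[1]} columns but the fit used {self.n_features_}"
            )
        eta = X @ self.coef_
        ext = np.concatenate([[-np.inf], self.cutpoints_, [np.inf]])
        cdf = special.ndtr(ext[None, :] - eta[:, None])
        probs_obs = np.diff(cdf, axis=1)
        out = np.zeros((X.shape[0], self.n_levels))
        for j, l in enumerate(self.observed_levels_):
            out[:, l - 1] = probs_obs[:, j]
        return out

    def to_dict(self) -> dict:
        return {
            "n_levels": self.n_levels,
            "name": self.name,
            "coefficients": self.coef_.tolist(),
            "cutpoints": self.cutpoints_.tolist(),
            "observed_levels": self.observed_levels_,
            "loglik": self.loglik_,
            "n_obs": self.n_obs_,
            "n_params": self.n_params_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OrderedProbit":
        est = cls(n_levels=int(d["n_levels"]), name=d.get("name", ""))
        est.coef_ = np.asarray(d["coefficients"], dtype=float)
        est.cutpoints_ = np.asarray(d["cutpoints"], dtype=float)
        if np.any(np.diff(est.cutpoints_) <= 0):
            raise ValueError(f"cutpoints for {est.name!r} are not strictly increasing")
        est.observed_levels_ = [int(x) for x in d.get(
            "observed_levels", range(1, est.n_levels + 1)
        )]
        est.level_map_ = {
            l: est.observed_levels_[
                int(np.argmin(np.abs(np.asarray(est.observed_levels_) - l)))
            ]
            for l in range(1, est.n_levels + 1)
        }
        est.loglik_ = float(d.get("loglik", np.nan))
        est.n_obs_ = int(d.get("n_obs", 0))
        est.n_features_ = len(est.coef_)
        est.n_params_ = int(d.get("n_params", est.n_features_ + len(est.cutpoints_)))
        est.converged_ = True
        return est


class ResponseMappingModel(BaseEstimator):
    """Six ordered probits (one per SF-6D dimension) plus a tariff.

    ``fit(X, Y)`` takes the shared (intercept-free) design matrix and the
    (n, 6) matrix of observed SF-6D levels.  ``predict(X)`` returns
    expected utilities: for a purely additive tariff the expectation is
    ``constant - sum_d sum_l P(level l in d) * decrement_dl``; tariffs with
    indicator terms are handled by exact enumeration of the joint state
    distribution under cross-dimension independence (Monte Carlo with a
    fixed seed beyond ``max_enumerate`` states).
    """

    def __init__(
        self,
        tariff: Tariff,
        spec: str = "M5",
        max_enumerate: int = 20_000,
        mc_draws: int = 200_000,
        mc_seed: int = 0,
    ):
        self.tariff = tariff
        self.spec = spec
        self.max_enumerate = max_enumerate
        self.mc_draws = mc_draws
        self.mc_seed = mc_seed

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=int)
        counts = self.tariff.level_counts
        if Y.ndim != 2 or Y.shape[1] != len(counts):
            raise ValueError(f"Y must have {len(counts)} level columns")
        self.fits_ = {}
        for j, name in enumerate(self.tariff.dimensions):
            try:
                self.fits_[name] = OrderedProbit(n_levels=counts[j], name=name).fit(
                    X, Y[:, j]
                )
            except Exception as exc:
                raise RuntimeError(f"ordered probit failed for dimension {name!r}: {exc}")
        self.loglik_ = float(sum(f.loglik_ for f in self.fits_.values()))
        self.n_params_ = int(sum(f.n_params_ for f in self.fits_.values()))
        self.n_obs_ = X.shape[0]
        self.n_features_ = X.shape[1]
        return self

    def level_probabilities(self, X) -> dict[str, np.ndarray]:
        return {name: f.level_probabilities(X) for name, f in self.fits_.items()}

    def predict(self, X, method: str = "expected"):
        probs = self.level_probabilities(X)
        mats = [probs[name] for name in self.tariff.dimensions]
        for m in mats:
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("level probability rows are not normalised")
        if method == "modal":
            states = np.column_stack([m.argmax(axis=1) + 1 for m in mats])
            return self.tariff.utilities(states)
        if method != "expected":
            raise ValueError("method must be 'expected' or 'modal'")
        if not self.tariff.extra_terms:
            u = np.full(mats[0].shape[0], self.tariff.constant)
            for m, dec in zip(mats, self.tariff.decrements):
                u -= m @ np.asarray(dec)
            return u
        if self.tariff.n_states() <= self.max_enumerate:
            return self._expect_enumerate(mats)
        return self._expect_mc(mats)

    def _expect_enumerate(self, mats):
        states = np.array(list(self.tariff.state_space()), dtype=int)
        utils = self.tariff.utilities(states)
        n = mats[0].shape[0]
        out = np.empty(n)
        # chunk subjects to bound the (chunk x n_states) joint-probability array
        chunk = max(1, int(2e6 // len(states)))
        for s in range(0, n, chunk):
            J = mats[0][s : s + chunk]
            for m in mats[1:]:
                J = (J[:, :, None] * m[s : s + chunk][:, None, :]).reshape(
                    J.shape[0], -1
                )
            out[s : s + chunk] = J @ utils
        return out

    def _expect_mc(self, mats):
        rng = np.random.default_rng(self.mc_seed)
        n = mats[0].shape[0]
        out = np.zeros(n)
        for _ in range(self.mc_draws // 1000):
            draw = np.column_stack(
                [
                    1 + (rng.random((n, 1)) > np.cumsum(m, axis=1)[:, :-1]).sum(axis=1)
                    for m in mats
                ]
            )
            out += self.tariff.utilities(draw)
        return out / (self.mc_draws // 1000)

    def to_dict(self) -> dict:
        return {
            "type": "response_mapping",
            "spec": self.spec,
            "dimensions": [self.fits_[n].to_dict() for n in self.tariff.dimensions],
            "loglik": self.loglik_,
            "n_obs": self.n_obs_,
            "n_params": self.n_params_,
        }


# -- thin functional wrappers ---------------------------------------------


def fit_ordered_probit(X, levels, L: int, name: str = "") -> OrderedProbit:
    return OrderedProbit(n_levels=L, name=name).fit(X, levels)


def level_probabilities(fit: OrderedProbit, X) -> np.ndarray:
    return fit.level_probabilities(X)


def fit_response_mapping(subjects, spec: str, tariff: Tariff) -> ResponseMappingModel:
    """Fit the six-equation system on a cohort DataFrame.

    ``subjects`` needs the FACT-L score columns for ``spec`` plus the six
    SF-6D level columns (``sf6d_pf`` .. ``sf6d_vit``).
    """
    from .synthetic import SF6D_COLUMNS

    Xfull, _ = build_design_matrix(subjects, spec)
    X = Xfull[:, 1:]  # cutpoints absorb the intercept
    Y = subjects[list(SF6D_COLUMNS)].to_numpy(dtype=int)
    return ResponseMappingModel(tariff=tariff, spec=spec).fit(X, Y)


def expected_utility(model: ResponseMappingModel, X) -> np.ndarray:
    return model.predict(X)
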