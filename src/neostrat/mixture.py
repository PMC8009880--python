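"""Dirichlet-process Gaussian mixture via variational inference.

A truncated stick-breaking Dirichlet-process prior over mixture weights is
combined with Normal--Wishart priors over per-component means and full
covariances.  The approximate posterior is optimised by coordinate ascent on
the evidence lower bound (ELBO): responsibilities in the E-step, Beta
stick-breaking posteriors and Normal--Wishart posteriors in the M-step.

Priors follow the data-driven empirical-Bayes convention: the mean prior is
centred on the dataset mean and the scale matrix of the Wishart prior on the
dataset covariance.  A very small weight-concentration (default 1e-5)
expresses a prior preference for few, unevenly sized clusters; the truncation
level only needs to exceed the number of clusters the data support.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``predict_proba`` / ``score_samples`` / ``sample``) and records the full ELBO
trace, which is non-decreasing over iterations.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import betaln, digamma, gammaln, logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, DataError
from .errors import ConvergenceWarning as NeoConvergenceWarning


def _log_gaussian_expectation(X, means, scale_chols, dof, mean_precision):
    """E_q[log N(x | mu_k, Lambda_k^{-1})] for every row and component.

    ``scale_chols[k]`` is the Cholesky factor of the inverse-scale matrix
    Psi_k of the Wishart posterior (dof nu_k, scale Psi_k^{-1}).
    """
    n, d = X.shape
    k = means.shape[0]
    log_prob = np.empty((n, k))
    for j in range(k):
        diff = X - means[j]
        # (x-m)' Psi^{-1} (x-m) via triangular solve
        y = solve_triangular(scale_chols[j], diff.T, lower=True)
        quad = dof[j] * np.einsum("ij,ij->j", y, y)
        logdet_psi = 2.0 * np.sum(np.log(np.diag(scale_chols[j])))
        e_logdet_lambda = (np.sum(digamma(0.5 * (dof[j] - np.arange(d))))
                           + d * np.log(2.0) - logdet_psi)
        log_prob[:, j] = 0.5 * (e_logdet_lambda - d / mean_precision[j]
                                - quad - d * np.log(2.0 * np.pi))
    return log_prob


def _mixture_log_density(X, weights, means, covariances):
    k, d = means.shape
    log_prob = np.empty((X.shape[0], k))
    for j in range(k):
        chol = cholesky(covariances[j], lower=True)
        y = solve_triangular(chol, (X - means[j]).T, lower=True)
        quad = np.einsum("ij,ij->j", y, y)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        log_prob[:, j] = -0.5 * (quad + logdet + d * np.log(2.0 * np.pi))
    return logsumexp(log_prob + np.log(weights), axis=1)


def _sample_mixture(n_samples, weights, means, covariances, rng):
    d = means.shape[1]
    if n_samples == 0:
        return np.empty((0, d))
    comps = rng.choice(len(weights), size=n_samples, p=weights)
    out = np.empty((n_samples, d))
    for j in np.unique(comps):
        mask = comps == j
        out[mask] = rng.multivariate_normal(means[j], covariances[j],
                                            size=int(mask.sum()))
    return out


class FrozenMixture:
    """A fixed-parameter Gaussian mixture density (weights, means, covariances).

    Used both as the plug-in view of a fitted model and as a single draw from
    its parameter posterior.
    """

    def __init__(self, weights, means, covariances):
        self.weights = np.asarray(weights, float)
        self.means = np.asarray(means, float)
        self.covariances = np.asarray(covariances, float)

    def score_samples(self, X):
        return _mixture_log_density(np.asarray(X, float), self.weights,
                                    self.means, self.covariances)

    def score(self, X, y=None):
        return float(np.sum(self.score_samples(X)))

    def sample(self, n_samples, random_state=None):
        rng = check_random_state(random_state)
        return _sample_mixture(n_samples, self.weights, self.means,
                               self.covariances, rng)


class DirichletProcessGMM(ClusterMixin, BaseEstimator):
    """Variational DP Gaussian mixture with full covariances.

    Parameters
    ----------
    truncation : int
        Maximum number of mixture components (stick-breaking truncation).
    weight_concentration : float
        Dirichlet-process concentration; small values prefer few clusters.
    tol : float
        Stop when the ELBO improvement falls below this threshold.
    max_iter : int
        Iteration cap per restart.
    n_init : int
        Random restarts; the restart with the best final ELBO is kept.
    reg_covar : float
        Ridge added to component scale matrices for numerical stability.
    random_state : int, RandomState or None
        Seeds the random-responsibility initialisation and sampling.

    Attributes
    ----------
    weights_ : (K,) normalised effective component weights.
    stick_weights_ : (K,) raw truncated stick-breaking weights (sum <= 1).
    weight_remainder_ : float, stick mass beyond the truncation level.
    means_, covariances_ : plug-in component parameters (posterior means).
    elbo_trace_ : ELBO value after every iteration of the best restart.
    """

    def __init__(self, truncation=60, weight_concentration=1e-5, tol=1e-3,
                 max_iter=500, n_init=1, reg_covar=1e-6, random_state=None):
        self.truncation = truncation
        self.weight_concentration = weight_concentration
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.reg_covar = reg_covar
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def _validate(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise DataError("X must be a non-empty 2-D array")
        if not np.all(np.isfinite(X)):
            raise DataError("X contains non-finite values")
        if self.truncation < 1:
            raise ConfigurationError("truncation must be >= 1")
        if self.tol <= 0 or self.weight_concentration <= 0:
            raise ConfigurationError("tol and weight_concentration must be > 0")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        n, d = X.shape
        rng = check_random_state(self.random_state)

        self._prior_mean = X.mean(axis=0)
        data_cov = np.cov(X.T, bias=True) if n > 1 else np.eye(d)
        data_cov = np.atleast_2d(data_cov) + self.reg_covar * np.eye(d)
        self._prior_scale = data_cov          # Wishart prior centred on data cov
        self._prior_dof = float(d)
        self._prior_mean_precision = 1.0

        best = None
        for init in range(self.n_init):
            resp = self._init_resp(X, rng)
            state = self._fit_single(X, resp)
            if best is None or state["elbo_trace"][-1] > best["elbo_trace"][-1]:
                best = state
        if not best["converged"]:
            warnings.warn("no restart reached the ELBO tolerance; best model kept",
                          NeoConvergenceWarning)

        self._set_state(best)
        self.n_features_in_ = d
        labels = self.predict(X)
        self.labels_ = labels
        return self

    def _init_resp(self, X, rng):
        """Random-parameter initialisation: place component means at randomly
        chosen data points and take one E-step under the broad data
        covariance.  Plain uniform-random responsibilities leave every
        component at the grand mean, where the sparse stick-breaking prior
        can kill all components but one before they differentiate.
        """
        n = X.shape[0]
        k = self.truncation
        anchors = X[rng.choice(n, size=k, replace=n < k)]
        chol = cholesky(self._prior_scale, lower=True)
        logp = np.empty((n, k))
        for j in range(k):
            y = solve_triangular(chol, (X - anchors[j]).T, lower=True)
            logp[:, j] = -0.5 * np.einsum("ij,ij->j", y, y)
        return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))

    def _m_step(self, X, resp):
        n, d = X.shape
        nk = resp.sum(axis=0) + 10 * np.finfo(float).eps
        xk = (resp.T @ X) / nk[:, None]
        sk = np.empty((self.truncation, d, d))
        for j in range(self.truncation):
            diff = X - xk[j]
            sk[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j]

        # stick-breaking Beta posteriors
        tail = np.concatenate([np.cumsum(nk[::-1])[-2::-1], [0.0]])
        beta_a = 1.0 + nk
        beta_b = self.weight_concentration + tail

        mean_precision = self._prior_mean_precision + nk
        means = (self._prior_mean_precision * self._prior_mean + nk[:, None] * xk) \
            / mean_precision[:, None]
        dof = self._prior_dof + nk
        scale_chols = np.empty((self.truncation, d, d))
        for j in range(self.truncation):
            dm = xk[j] - self._prior_mean
            psi = (self._prior_scale + nk[j] * sk[j]
                   + (self._prior_mean_precision * nk[j] / mean_precision[j])
                   * np.outer(dm, dm))
            psi += self.reg_covar * np.eye(d)
            scale_chols[j] = cholesky(psi, lower=True)
        return {"beta_a": beta_a, "beta_b": beta_b, "mean_precision": mean_precision,
                "means": means, "dof": dof, "scale_chols": scale_chols}

    @staticmethod
    def _e_log_weights(beta_a, beta_b):
        e_log_v = digamma(beta_a) - digamma(beta_a + beta_b)
        e_log_1mv = digamma(beta_b) - digamma(beta_a + beta_b)
        return e_log_v + np.concatenate([[0.0], np.cumsum(e_log_1mv)[:-1]])

    def _e_step(self, X, params):
        log_w = self._e_log_weights(params["beta_a"], params["beta_b"])
        log_prob = _log_gaussian_expectation(
            X, params["means"], params["scale_chols"], params["dof"],
            params["mean_precision"])
        weighted = log_prob + log_w
        log_norm = logsumexp(weighted, axis=1)
        log_resp = weighted - log_norm[:, None]
        return log_resp

    def _elbo(self, log_resp, params):
        """Collapsed ELBO (up to an additive constant): responsibility entropy
        plus the log-normalisers of the Beta and Normal--Wishart posteriors."""
        d = params["means"].shape[1]
        resp = np.exp(log_resp)
        entropy = -float(np.sum(resp * np.where(resp > 0, log_resp, 0.0)))
        log_beta_norm = float(np.sum(betaln(params["beta_a"], params["beta_b"])))
        dof = params["dof"]
        logdet_psi = 2.0 * np.sum(np.log(np.diagonal(params["scale_chols"],
                                                     axis1=1, axis2=2)), axis=1)
        arange = np.arange(d)
        log_wishart_norm = float(np.sum(
            -0.5 * dof * logdet_psi
            + 0.5 * dof * d * np.log(2.0)
            + gammaln(0.5 * (dof[:, None] - arange)).sum(axis=1)))
        log_nw_norm = log_wishart_norm - 0.5 * d * float(
            np.sum(np.log(params["mean_precision"])))
        return entropy + log_beta_norm + log_nw_norm

    def _fit_single(self, X, resp):
        params = self._m_step(X, resp)
        trace = []
        converged = False
        for _ in range(self.max_iter):
            log_resp = self._e_step(X, params)
            params = self._m_step(X, np.exp(log_resp))
            elbo = self._elbo(log_resp, params)
            if trace and abs(elbo - trace[-1]) < self.tol:
                trace.append(elbo)
                converged = True
                break
            trace.append(elbo)
        return {"params": params, "elbo_trace": np.asarray(trace),
                "converged": converged}

    def _set_state(self, state):
        params = state["params"]
        a, b = params["beta_a"], params["beta_b"]
        e_v = a / (a + b)
        stick = e_v * np.concatenate([[1.0], np.cumprod(1.0 - e_v)[:-1]])
        self.stick_weights_ = stick
        self.weight_remainder_ = float(max(1.0 - stick.sum(), 0.0))
        self.weights_ = stick / stick.sum()
        self.means_ = params["means"]
        # plug-in covariance: inverse of the posterior-mean precision nu * Psi^{-1}
        d = self.means_.shape[1]
        cov = np.empty((self.truncation, d, d))
        for j in range(self.truncation):
            psi = params["scale_chols"][j] @ params["scale_chols"][j].T
            cov[j] = psi / params["dof"][j]
        self.covariances_ = cov
        self._params = params
        self.elbo_trace_ = state["elbo_trace"]
        self.lower_bound_ = float(state["elbo_trace"][-1])
        self.converged_ = state["converged"]
        self.n_iter_ = len(state["elbo_trace"])

    # ------------------------------------------------------- inference API
    def _check_X(self, X):
        check_is_fitted(self, "means_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.means_.shape[1]:
            raise DataError(
                f"X must have {self.means_.shape[1]} columns, got shape {X.shape}")
        return X

    def predict_proba(self, X):
        """Posterior membership probabilities (responsibilities), rows sum to 1."""
        X = self._check_X(X)
        return np.exp(self._e_step(X, self._params))

    def predict(self, X):
        """Hard assignment: the component with the highest responsibility
        (ties break to the lowest component index)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def score_samples(self, X):
        """Per-row mixture log-density under plug-in posterior-mean parameters."""
        X = self._check_X(X)
        k, d = self.means_.shape
        log_prob = np.empty((X.shape[0], k))
        for j in range(k):
            chol = cholesky(self.covariances_[j], lower=True)
            y = solve_triangular(chol, (X - self.means_[j]).T, lower=True)
            quad = np.einsum("ij,ij->j", y, y)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            log_prob[:, j] = -0.5 * (quad + logdet + d * np.log(2.0 * np.pi))
        return logsumexp(log_prob + np.log(self.weights_), axis=1)

    def score(self, X, y=None):
        """Total log-likelihood of X (sum of per-row values)."""
        return float(np.sum(self.score_samples(X)))

    def sample(self, n_samples, random_state=None):
        """Draw synthetic rows from the fitted generative model."""
        check_is_fitted(self, "means_")
        if n_samples < 0:
            raise DataError("n_samples must be >= 0")
        d = self.means_.shape[1]
        if n_samples == 0:
            return np.empty((0, d))
        rng = check_random_state(random_state)
        comps = rng.choice(len(self.weights_), size=n_samples, p=self.weights_)
        out = np.empty((n_samples, d))
        for j in np.unique(comps):
            mask = comps == j
            out[mask] = rng.multivariate_normal(
                self.means_[j], self.covariances_[j], size=int(mask.sum()))
        return out

    def posterior_draw(self, random_state=None) -> FrozenMixture:
        """Draw one parameter set from the variational posterior.

        Mixture weights come from the Beta stick posteriors, component
        precisions from their Wishart posteriors (means conditionally
        Gaussian), giving a :class:`FrozenMixture` usable as the parameter
        draw of a posterior predictive check.
        """
        check_is_fitted(self, "means_")
        from scipy.stats import wishart

        rng = check_random_state(random_state)
        params = self._params
        v = rng.beta(params["beta_a"], params["beta_b"])
        w = v * np.concatenate([[1.0], np.cumprod(1.0 - v)[:-1]])
        w = np.maximum(w, 1e-300)
        w = w / w.sum()
        k, d = self.means_.shape
        means = np.empty((k, d))
        covs = np.empty((k, d, d))
        for j in range(k):
            psi = params["scale_chols"][j] @ params["scale_chols"][j].T
            lam = wishart.rvs(df=params["dof"][j], scale=np.linalg.inv(psi),
                              random_state=rng)
            covs[j] = np.linalg.inv(lam)
            means[j] = rng.multivariate_normal(
                params["means"][j], covs[j] / params["mean_precision"][j])
        return FrozenMixture(w, means, covs)

    def cluster_sizes(self, X=None, labels=None):
        """Fraction of rows assigned to each component."""
        if labels is None:
            labels = self.predict(X)
        counts = np.bincount(labels, minlength=len(self.weights_))
        return counts / counts.sum()

    def n_effective_clusters(self, X=None, labels=None, min_fraction=0.01):
        """Number of components holding at least ``min_fraction`` of the rows."""
        return int(np.sum(self.cluster_sizes(X, labels) >= min_fraction))
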