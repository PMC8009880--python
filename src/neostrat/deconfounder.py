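"""Deconfounded association between cluster membership and outcomes.

The association of belonging to one nutritional cluster (C1) versus another
(C0) with an outcome is estimated by regression with two layers of
adjustment: observed admission covariates (mean-centred, with the London-like
reference region), and the posterior-mean latent variables of a probabilistic
PCA factor model fitted to the covariates.  The factor model plays the role
of a substitute confounder: if it adequately describes the joint covariate
distribution (checked by a posterior predictive check on a held-out split),
its latents absorb unobserved confounders that act on several covariates at
once.

Probabilistic PCA is the linear-Gaussian factor model x = W z + mu + eps with
isotropic noise; its maximum-likelihood solution is closed-form in the
eigenstructure of the sample covariance (loadings from the top-k eigenpairs,
noise variance equal to the mean of the discarded eigenvalues).

Caveat: PPCA posterior-mean latents are exact affine functions of the
covariates they were fitted on, so adding them to a regression that already
contains every covariate leaves the treatment estimate unchanged (the design
becomes rank-deficient and is resolved by pseudo-inverse).  They carry
independent adjustment value when the outcome model does not span all the
factor-model inputs; see the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted

from .errors import AnalysisError, DataError
from .constants import REGIONS

#: Covariates entering the association design, besides region dummies.
#: Late Apgar scores and resuscitation are excluded as collinear with these.
DESIGN_COVARIATES = ["bw_zscore", "antenatal_steroids", "apgar1",
                     "imd_decile", "smoking", "sex", "ga_weeks"]
REFERENCE_REGION = "London"
REGION_DUMMIES = [r for r in REGIONS if r != REFERENCE_REGION]

BINARY_OUTCOMES = {"bpd", "severe_nec", "mm_at_discharge", "mortality"}


@dataclass
class DeconfounderDesign:
    """Centred covariate design with a binary cluster-membership treatment."""

    covariates: pd.DataFrame          # mean-centred, incl. region dummies
    treatment: pd.Series              # 1 = cluster C1, 0 = cluster C0
    outcome: pd.Series
    outcome_name: str
    family: str                       # "linear" or "logistic"
    c1: object
    c0: object
    dropped_covariates: list = field(default_factory=list)

    @property
    def n1(self) -> int:
        return int(self.treatment.sum())

    @property
    def n0(self) -> int:
        return int((1 - self.treatment).sum())


def build_design(cohort: pd.DataFrame, labels, c1, c0, outcome: str,
                 covariates=None, require_at_36w: bool = True) -> DeconfounderDesign:
    """Assemble the eligible two-arm design for one outcome.

    Eligibility: infants in cluster ``c1`` or ``c0``, still in care at 36
    weeks postmenstrual age, alive at discharge, and with no missing values
    among the analysed variables.  Covariates are mean-centred; region enters
    as dummies against the London-like reference; constant covariates are
    dropped with a warning.
    """
    if c1 == c0:
        raise AnalysisError("c1 and c0 must differ")
    covariates = list(covariates or DESIGN_COVARIATES)
    labels = pd.Series(np.asarray(labels), index=cohort.index)
    sub = cohort[labels.isin([c1, c0])].copy()
    sub_labels = labels[labels.isin([c1, c0])]
    if "mortality" in sub.columns:
        sub = sub[pd.to_numeric(sub["mortality"], errors="coerce") == 0]
    if require_at_36w and "in_care_at_36w" in sub.columns:
        sub = sub[sub["in_care_at_36w"] == 1]

    X = sub[covariates].apply(pd.to_numeric, errors="coerce")
    if "region" in sub.columns:
        dummies = (pd.get_dummies(sub["region"])
                   .reindex(columns=REGION_DUMMIES, fill_value=0).astype(float))
        X = pd.concat([X, dummies], axis=1)
    y = pd.to_numeric(sub[outcome], errors="coerce")
    complete = X.notna().all(axis=1) & y.notna()
    X, y = X[complete], y[complete]
    treatment = (sub_labels.reindex(X.index) == c1).astype(float).rename("treatment")
    if treatment.sum() == 0 or (1 - treatment).sum() == 0:
        raise AnalysisError("one treatment arm is empty after eligibility filters")

    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant covariates: {dropped}")
        X = X.drop(columns=dropped)
    X = X - X.mean(axis=0)

    family = "logistic" if outcome in BINARY_OUTCOMES else "linear"
    return DeconfounderDesign(covariates=X, treatment=treatment, outcome=y,
                              outcome_name=outcome, family=family,
                              c1=c1, c0=c0, dropped_covariates=dropped)


class ProbabilisticPCA(BaseEstimator, TransformerMixin):
    """Maximum-likelihood probabilistic PCA (closed form).

    Model: x = W z + mu + eps, z ~ N(0, I_k), eps ~ N(0, sigma2 I_d).
    ML solution: mu is the sample mean; with eigenpairs (lambda_i, u_i) of
    the sample covariance, sigma2 = mean of the d-k smallest eigenvalues and
    W = U_k (L_k - sigma2 I)^{1/2}.  ``transform`` returns posterior means
    E[z|x] = (W'W + sigma2 I)^{-1} W'(x - mu).
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        k = self.n_components
        if n < k + 2:
            raise DataError(f"PPCA with k={k} needs at least {k + 2} rows")
        if k >= d:
            raise DataError("n_components must be below the data dimension")
        self.mean_ = X.mean(axis=0)
        cov = np.cov(X.T, bias=True)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        rank = int(np.sum(evals > max(evals[0], 1.0) * 1e-12))
        # k == rank is the analytic zero-noise limit; only k beyond the rank
        # is unidentifiable
        if k > rank:
            raise DataError(f"n_components={k} exceeds matrix rank {rank}")
        sigma2 = float(np.mean(evals[k:])) if k < d else 0.0
        sigma2 = max(sigma2, 0.0)
        self.noise_variance_ = sigma2
        self.components_ = (evecs[:, :k]
                            * np.sqrt(np.maximum(evals[:k] - sigma2, 0.0))).T
        self.eigenvalues_ = evals
        self.n_features_in_ = d
        return self

    def _posterior_matrix(self):
        W = self.components_.T
        k = W.shape[1]
        M = W.T @ W + self.noise_variance_ * np.eye(k)
        return W, M

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        W, M = self._posterior_matrix()
        return np.linalg.solve(M, W.T @ (X - self.mean_).T).T

    def get_covariance(self) -> np.ndarray:
        W = self.components_.T
        return W @ W.T + self.noise_variance_ * np.eye(self.n_features_in_)

    def score_samples(self, X):
        """Per-row log-density under the fitted Gaussian N(mu, WW' + sigma2 I)."""
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        C = self.get_covariance()
        d = C.shape[0]
        chol = np.linalg.cholesky(C)
        y = np.linalg.solve(chol, (X - self.mean_).T)
        quad = np.einsum("ij,ij->j", y, y)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        return -0.5 * (quad + logdet + d * np.log(2.0 * np.pi))

    def score(self, X, y=None):
        return float(np.sum(self.score_samples(X)))

    def sample(self, n_samples, random_state=None):
        check_is_fitted(self, "components_")
        rng = check_random_state(random_state)
        W = self.components_.T
        d, k = W.shape
        z = rng.standard_normal((n_samples, k))
        eps = rng.standard_normal((n_samples, d)) * np.sqrt(self.noise_variance_)
        return self.mean_ + z @ W.T + eps


@dataclass
class FactorModelFit:
    """Fitted substitute-confounder factor model with its adequacy check."""

    model: ProbabilisticPCA
    latents: pd.DataFrame             # posterior means Z1..Zk for every row
    train_index: pd.Index
    holdout_index: pd.Index
    ppc_pvalue: float


def fit_ppca(covariates: pd.DataFrame, k: int = 3, train_frac: float = 0.8,
             seed: int = 0, n_reps: int = 100) -> FactorModelFit:
    """Train the PPCA factor model on a random train split and check it.

    The model is fitted on ``train_frac`` of the rows; adequacy is assessed
    by a posterior predictive check of the total log-likelihood statistic on
    the held-out rows against model simulations of the same size.  Posterior
    latent means are returned for every row (train and held-out alike).
    """
    from .reproducibility import posterior_predictive_check

    X = covariates.to_numpy(dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = max(int(round(train_frac * n)), k + 2)
    train_idx, hold_idx = perm[:n_train], perm[n_train:]
    model = ProbabilisticPCA(n_components=k).fit(X[train_idx])
    if len(hold_idx):
        ppc = posterior_predictive_check(model, X[hold_idx],
                                         statistic="likelihood", n_reps=n_reps,
                                         seed=int(rng.integers(0, 2 ** 31)))
    else:
        ppc = float("nan")
    latents = pd.DataFrame(model.transform(X), index=covariates.index,
                           columns=[f"Z{i + 1}" for i in range(k)])
    return FactorModelFit(model=model, latents=latents,
                          train_index=covariates.index[train_idx],
                          holdout_index=covariates.index[hold_idx],
                          ppc_pvalue=ppc)


@dataclass
class AssociationResult:
    """Regression table with per-covariate coefficients, CIs and p-values."""

    table: pd.DataFrame               # coef, ci_low, ci_high, p
    family: str
    fit_quality: float                # adjusted r2 (linear) / McFadden pseudo-r2
    n1: int
    n0: int
    separation_flag: bool = False

    def to_markdown(self) -> str:
        lines = ["| Covariate | Coefficient | 95% CI | p value |",
                 "|---|---|---|---|"]
        for name, row in self.table.iterrows():
            star = "**" if row["p"] < 0.05 else ""
            lines.append(
                f"| {name} | {star}{row['coef']:.2f}{star} "
                f"| [{row['ci_low']:.2f}, {row['ci_high']:.2f}] "
                f"| {row['p']:.3g} |")
        metric = "adjusted r2" if self.family == "linear" else "pseudo r2"
        lines.append(f"\n{metric} = {self.fit_quality:.2f}; "
                     f"n1 = {self.n1}, n0 = {self.n0}")
        return "\n".join(lines)


def _ridge_logit(y: np.ndarray, X: np.ndarray, alpha: float = 1e-2):
    """L2-penalised logistic fit by Newton iterations with Wald covariance.

    Used as the fallback when the unpenalised MLE is unstable (perfect or
    quasi-separation); the penalty keeps coefficients finite.
    """
    n, p = X.shape
    beta = np.zeros(p)
    H = np.eye(p)
    for _ in range(200):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X + alpha * np.eye(p)
        grad = X.T @ (y - mu) - alpha * beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    cov = np.linalg.inv(H)
    eta = np.clip(X @ beta, -30, 30)
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, cov, ll


def association_regression(design: DeconfounderDesign,
                           latents: pd.DataFrame | None = None,
                           include_covariates: bool = True) -> AssociationResult:
    """Latent-augmented outcome regression for the treatment contrast.

    Linear (OLS) for continuous outcomes, logistic for binary ones;
    coefficients on the logistic scale are log-odds changes.  Perfect
    separation in the logistic fit is flagged and resolved by an L2-penalised
    refit with Wald intervals.
    """
    from scipy.stats import norm

    parts = [design.treatment.rename("treatment")]
    if include_covariates:
        parts.insert(0, design.covariates)
    if latents is not None:
        parts.append(latents.reindex(design.treatment.index))
    X = pd.concat(parts, axis=1).astype(float)
    X = sm.add_constant(X, prepend=True, has_constant="add")
    y = design.outcome.astype(float)

    separation = False
    res = None
    if design.family == "linear":
        res = sm.OLS(y, X).fit()
        quality = float(res.rsquared_adj)
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                res = sm.Logit(y, X).fit(disp=0)
            if not (np.all(np.isfinite(res.bse)) and np.all(res.bse < 1e3)):
                raise np.linalg.LinAlgError("unstable logistic fit")
            quality = float(res.prsquared)
        except Exception:
            separation = True
            res = None
            warnings.warn("logistic fit unstable (possible separation); "
                          "L2-penalised refit used")
            beta, cov, ll = _ridge_logit(y.to_numpy(), X.to_numpy())
            se = np.sqrt(np.diag(cov))
            pbar = float(y.mean())
            ll_null = float(len(y) * (pbar * np.log(pbar + 1e-300)
                                      + (1 - pbar) * np.log(1 - pbar + 1e-300)))
            quality = 1.0 - ll / ll_null if ll_null != 0 else float("nan")
            zcrit = norm.ppf(0.975)
            zstat = beta / se
            table = pd.DataFrame({
                "coef": beta, "ci_low": beta - zcrit * se,
                "ci_high": beta + zcrit * se,
                "p": 2 * norm.sf(np.abs(zstat)),
            }, index=X.columns)

    if res is not None:
        ci = res.conf_int(alpha=0.05)
        table = pd.DataFrame({
            "coef": res.params, "ci_low": ci[0], "ci_high": ci[1],
            "p": res.pvalues,
        })
    table = table.rename(index={"const": "Intercept", "treatment": "Nutritional Treatment"})
    return AssociationResult(table=table, family=design.family,
                             fit_quality=quality, n1=design.n1, n0=design.n0,
                             separation_flag=separation)


def deconfound(cohort: pd.DataFrame, labels, c1, c0, outcome: str,
               k: int = 3, train_frac: float = 0.8, seed: int = 0,
               covariates=None):
    """End-to-end deconfounder analysis for one cluster contrast.

    Builds the eligible design, fits and checks the PPCA substitute
    confounder, and runs the latent-augmented regression.  Returns
    ``(design, factor_fit, result)``.
    """
    design = build_design(cohort, labels, c1, c0, outcome, covariates=covariates)
    factor = fit_ppca(design.covariates, k=k, train_frac=train_frac, seed=seed)
    result = association_regression(design, latents=factor.latents)
    return design, factor, result
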