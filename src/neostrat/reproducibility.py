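"""Agreement and adequacy checks for unsupervised stratifications.

Because there is no ground truth for discovered clusters, reproducibility is
quantified with surrogate protocols: the clustering F-measure between
repeated runs, split-cohort refits by birth-year parity, posterior predictive
checks of the generative model, and paired cluster-by-cluster statistical
comparisons across sub-cohorts.

The F-measure variant is the class-weighted best-match form: with contingency
counts ``n_ij`` between true classes i and predicted clusters j,

    precision(i,j) = n_ij / n_.j      (cluster purity)
    recall(i,j)    = n_ij / n_i.      (cluster completeness)
    F(i,j)         = harmonic mean of the two
    F_total        = sum_i (n_i. / n) * max_j F(i,j)

which is 1 exactly when the two labelings are identical up to relabelling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu
from sklearn.metrics.cluster import contingency_matrix

from .errors import DataError

logger = logging.getLogger(__name__)


def f_measure(labels_true, labels_pred) -> float:
    """Class-weighted best-match clustering F-measure in [0, 1]."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.size == 0 or labels_pred.size == 0:
        raise DataError("label vectors must be non-empty")
    if labels_true.shape != labels_pred.shape:
        raise DataError("label vectors must have equal length")
    cont = contingency_matrix(labels_true, labels_pred).astype(float)
    n = cont.sum()
    n_i = cont.sum(axis=1, keepdims=True)
    n_j = cont.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 2.0 * cont / (n_i + n_j)      # harmonic mean of n_ij/n_.j and n_ij/n_i.
    return float(np.sum((n_i[:, 0] / n) * f.max(axis=1)))


def pairwise_run_agreement(runs, seed: int = 0):
    """Mean and sd of the F-measure over disjoint random pairs of runs.

    Runs are shuffled (seeded) and paired disjointly; within each pair one
    labelling arbitrarily plays the ground-truth role.  An odd run is dropped
    with a warning; a single pair reports sd 0 by convention.
    """
    runs = list(runs)
    if len(runs) < 2:
        raise DataError("at least two runs are required")
    if len(runs) % 2:
        warnings.warn("odd number of runs: the last shuffled run is dropped")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(runs))
    scores = [f_measure(runs[order[2 * i]], runs[order[2 * i + 1]])
              for i in range(len(runs) // 2)]
    scores = np.asarray(scores)
    sd = float(scores.std(ddof=1)) if len(scores) > 1 else 0.0
    return float(scores.mean()), sd, scores


def split_by_birth_year(cohort: pd.DataFrame, exclude_years=(2018,),
                        year_col: str = "birth_year"):
    """Partition a cohort into odd and even birth years, excluding listed years."""
    years = pd.to_numeric(cohort[year_col], errors="coerce")
    keep = ~years.isin(exclude_years)
    odd = cohort[keep & (years % 2 == 1)]
    even = cohort[keep & (years % 2 == 0)]
    return odd, even


_STATISTICS = {
    "mean": lambda model, data: float(np.mean(data)),
    "variance": lambda model, data: float(np.var(data)),
    "likelihood": lambda model, data: model.score(data),
}


def posterior_predictive_check(model, heldout, statistic: str = "likelihood",
                               n_reps: int = 100, seed: int | None = None) -> float:
    """PPC p-value: P(statistic of model replicates >= observed statistic).

    Replicate datasets of the held-out size are drawn from the fitted
    generative model (plug-in posterior-mean parameters); ties count towards
    the upper tail.  Values near 0.5 indicate the model reproduces the
    held-out data adequately; for genuinely held-out data and an adequate
    model the p-value is approximately uniform over repeated experiments.
    """
    heldout = np.asarray(heldout, dtype=float)
    if heldout.size == 0:
        raise DataError("held-out set must be non-empty")
    if statistic not in _STATISTICS:
        raise DataError(f"statistic must be one of {sorted(_STATISTICS)}")
    if n_reps < 1:
        raise DataError("n_reps must be >= 1")
    stat = _STATISTICS[statistic]
    observed = stat(model, heldout)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_reps):
        rep = model.sample(heldout.shape[0],
                           random_state=int(rng.integers(0, 2 ** 31)))
        if stat(model, rep) >= observed:
            exceed += 1
    return exceed / n_reps


def match_clusters(labels_x, labels_y, greedy_by_size: bool = True):
    """Greedily pair clusters of two labelings of a common cohort.

    Pair score is the per-pair F value 2 n_ij / (n_i + n_j).  Matching order
    is descending size of the x-clusters (deterministic); each y-cluster is
    used at most once.  Returns a DataFrame (cluster_x, cluster_y, f, n_x, n_y).
    """
    labels_x = np.asarray(labels_x)
    labels_y = np.asarray(labels_y)
    if labels_x.shape != labels_y.shape:
        raise DataError("matching requires labelings of a common cohort")
    cont = contingency_matrix(labels_x, labels_y).astype(float)
    xs = np.unique(labels_x)
    ys = np.unique(labels_y)
    n_i = cont.sum(axis=1)
    n_j = cont.sum(axis=0)
    f = 2.0 * cont / (n_i[:, None] + n_j[None, :])
    order = np.argsort(-n_i, kind="stable") if greedy_by_size else np.arange(len(xs))
    used = set()
    rows = []
    for i in order:
        candidates = [(f[i, j], j) for j in range(len(ys)) if j not in used]
        if not candidates:
            break
        best_f, best_j = max(candidates, key=lambda t: (t[0], -t[1]))
        used.add(best_j)
        rows.append((xs[i], ys[best_j], float(best_f), int(n_i[i]), int(n_j[best_j])))
    return pd.DataFrame(rows, columns=["cluster_x", "cluster_y", "f", "n_x", "n_y"])


@dataclass
class ClusterPairComparison:
    """Matched cluster pairs with per-variable test results."""

    pairs: pd.DataFrame
    tests: pd.DataFrame
    n_tests: int
    alpha: float
    fraction_nonsignificant: float


def compare_cluster_pairs(data_x, labels_x, data_y, labels_y,
                          continuous=(), binary=(),
                          match_on=None, alpha: float = 0.05,
                          min_size: int = 2) -> ClusterPairComparison:
    """Compare matched cluster pairs variable by variable across two cohorts.

    Clusters are matched greedily by maximal per-pair F; matching uses
    ``match_on=(mlab_x, mlab_y)`` — two labelings of a common reference
    cohort (e.g. both models' assignments of the pooled cohort) — or, by
    default, ``labels_x``/``labels_y`` themselves when the two data sets share
    their rows.  Continuous/ordinal variables use the Mann-Whitney U test,
    binary variables Fisher's exact test, with Bonferroni correction over the
    total number of tests performed.  Pairs with fewer than ``min_size``
    members on either side are excluded (logged).
    """
    labels_x = np.asarray(labels_x)
    labels_y = np.asarray(labels_y)
    if match_on is None:
        match_on = (labels_x, labels_y)
    pairs = match_clusters(*match_on)

    rows = []
    for _, pair in pairs.iterrows():
        a = data_x[labels_x == pair["cluster_x"]]
        b = data_y[labels_y == pair["cluster_y"]]
        if len(a) < min_size or len(b) < min_size:
            logger.info("pair (%s, %s) excluded from testing: fewer than %d members",
                        pair["cluster_x"], pair["cluster_y"], min_size)
            continue
        for var in continuous:
            va = pd.to_numeric(a[var], errors="coerce").dropna()
            vb = pd.to_numeric(b[var], errors="coerce").dropna()
            if len(va) < 1 or len(vb) < 1 or (va.nunique() == 1 and vb.nunique() == 1
                                              and va.iat[0] == vb.iat[0]):
                p = 1.0
            else:
                p = float(mannwhitneyu(va, vb, alternative="two-sided").pvalue)
            rows.append((pair["cluster_x"], pair["cluster_y"], var, "mannwhitney", p))
        for var in binary:
            va = pd.to_numeric(a[var], errors="coerce").dropna()
            vb = pd.to_numeric(b[var], errors="coerce").dropna()
            if len(va) < 1 or len(vb) < 1:
                p = 1.0
            else:
                table = [[int(va.sum()), int(len(va) - va.sum())],
                         [int(vb.sum()), int(len(vb) - vb.sum())]]
                p = float(fisher_exact(table).pvalue)
            rows.append((pair["cluster_x"], pair["cluster_y"], var, "fisher", p))

    tests = pd.DataFrame(rows, columns=["cluster_x", "cluster_y", "variable",
                                        "test", "p"])
    n_tests = len(tests)
    if n_tests:
        tests["p_bonferroni"] = np.minimum(tests["p"] * n_tests, 1.0)
        tests["significant"] = tests["p_bonferroni"] < alpha
        frac_ns = float((~tests["significant"]).mean())
    else:
        frac_ns = float("nan")
    return ClusterPairComparison(pairs=pairs, tests=tests, n_tests=n_tests,
                                 alpha=alpha, fraction_nonsignificant=frac_ns)


def split_cohort_protocol(X_a, X_b, model_factory, seeds=(0, 1, 2, 3)):
    """Split-cohort stability protocol on two sub-cohorts.

    Fits one model per sub-cohort and seed.  Reports ``refit_f`` — agreement
    between two differently seeded fits on the same sub-cohort — and
    ``heldout_f`` — agreement between a sub-cohort's own stratification and
    the one induced by the model trained on the *other* sub-cohort.
    ``model_factory(seed)`` must return an unfitted estimator.
    """
    m_a0 = model_factory(seeds[0]).fit(X_a)
    m_a1 = model_factory(seeds[1]).fit(X_a)
    m_b0 = model_factory(seeds[2]).fit(X_b)
    m_b1 = model_factory(seeds[3]).fit(X_b)
    refit = np.mean([f_measure(m_a0.predict(X_a), m_a1.predict(X_a)),
                     f_measure(m_b0.predict(X_b), m_b1.predict(X_b))])
    heldout = np.mean([f_measure(m_b0.predict(X_b), m_a0.predict(X_b)),
                       f_measure(m_a0.predict(X_a), m_b0.predict(X_a))])
    return {"refit_f": float(refit), "heldout_f": float(heldout)}
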