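"""Admission-profile grouping of nutritional clusters.

Each nutritional cluster is summarised by the mean admission variables of its
infants; the per-variable means are standardised as z-scores *across
clusters* (so a z-score says whether a cluster sits above or below the
across-cluster average).  Ward hierarchical clustering and a 2-D PCA
projection of the z-score matrix then aggregate nutritional clusters into
admission groups labelled A, B, C, ... in dendrogram order.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, dendrogram, linkage
from sklearn.decomposition import PCA

from .constants import REGIONS
from .errors import DataError

logger = logging.getLogger(__name__)

DEFAULT_PROFILE_ADMISSION = [
    "ga_weeks", "bw_zscore", "resuscitation", "antenatal_steroids", "sex",
    "apgar1", "apgar5", "apgar10", "imd_decile", "smoking",
]
DEFAULT_PROFILE_OUTCOME = [
    "mortality", "severe_nec", "bpd", "mm_at_discharge", "los",
    "w36_zscore", "w36dz",
]


def zscore_across_rows(means: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardise each column of a cluster-mean table across clusters.

    Uses the sample (n-1) standard deviation.  Zero-variance columns are
    dropped with a warning rather than producing infinities.
    """
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=ddof)
    zero = sd <= 0
    if zero.any():
        logger.warning("dropping zero-variance variables from z-scores: %s",
                       list(means.columns[zero]))
    return (means.loc[:, ~zero] - mu[~zero]) / sd[~zero]


def profile_clusters(cohort: pd.DataFrame, labels, nutrition: pd.DataFrame | None = None,
                     admission_vars=None, outcome_vars=None,
                     min_clusters: int = 2):
    """Per-cluster aggregate profiles and across-cluster z-scores.

    Returns ``(profiles, z)``: ``profiles`` holds cluster size plus mean
    admission, outcome and nutrition variables and region proportions;
    ``z`` holds the across-cluster z-scores of the admission and outcome
    means (the matrix used for grouping).
    """
    labels = pd.Series(np.asarray(labels), index=cohort.index, name="cluster")
    if labels.nunique() < min_clusters:
        raise DataError("cluster profiling requires at least two clusters")
    admission_vars = admission_vars or [
        v for v in DEFAULT_PROFILE_ADMISSION if v in cohort.columns]
    outcome_vars = outcome_vars or [
        v for v in DEFAULT_PROFILE_OUTCOME if v in cohort.columns]

    num = cohort[admission_vars + outcome_vars].apply(pd.to_numeric, errors="coerce")
    profiles = num.groupby(labels).mean()
    profiles.insert(0, "size", labels.value_counts().sort_index())
    if "region" in cohort.columns:
        region_props = (pd.get_dummies(cohort["region"])
                        .reindex(columns=REGIONS, fill_value=0)
                        .groupby(labels).mean())
        profiles = profiles.join(region_props)
    if nutrition is not None:
        profiles = profiles.join(nutrition.groupby(labels.values).mean(),
                                 rsuffix="_prop")

    z = zscore_across_rows(profiles[admission_vars + outcome_vars])
    return profiles, z


@dataclass
class WardTree:
    """Agglomerative merge tree (Ward linkage on Euclidean distance)."""

    linkage_matrix: np.ndarray
    leaf_ids: list

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list:
        order = dendrogram(self.linkage_matrix, no_plot=True)["leaves"]
        return [self.leaf_ids[i] for i in order]

    def to_newick(self) -> str:
        """Nested-parenthesis text rendering of the merge tree."""
        n = len(self.leaf_ids)
        nodes = {i: str(self.leaf_ids[i]) for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.linkage_matrix):
            nodes[n + step] = f"({nodes[int(a)]},{nodes[int(b)]}):{h:.6g}"
        return nodes[n + len(self.linkage_matrix) - 1] + ";"


def ward_tree(z_matrix: pd.DataFrame | np.ndarray) -> WardTree:
    """Ward-linkage merge tree of cluster z-score profiles."""
    values = np.asarray(z_matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise DataError("ward_tree requires at least two rows")
    if not np.all(np.isfinite(values)):
        raise DataError("ward_tree requires finite input")
    ids = (list(z_matrix.index) if isinstance(z_matrix, pd.DataFrame)
           else list(range(values.shape[0])))
    lm = linkage(values, method="ward", metric="euclidean")
    return WardTree(linkage_matrix=lm, leaf_ids=ids)


def pca_project(z_matrix: pd.DataFrame | np.ndarray, n_components: int = 2):
    """Centred PCA of the cluster z-scores.

    Returns ``(coordinates, loadings, variance_fractions)``; if the matrix
    rank is below ``n_components`` fewer components are returned (warned).
    """
    values = np.asarray(z_matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise DataError("pca_project requires at least two rows")
    rank = np.linalg.matrix_rank(values - values.mean(axis=0))
    k = min(n_components, rank, values.shape[1], values.shape[0] - 1)
    if k < n_components:
        logger.warning("input rank %d < %d requested components; returning %d",
                       rank, n_components, k)
    pca = PCA(n_components=k).fit(values)
    coords = pca.transform(values)
    index = (z_matrix.index if isinstance(z_matrix, pd.DataFrame)
             else pd.RangeIndex(values.shape[0]))
    cols = [f"PC{i + 1}" for i in range(k)]
    coordinates = pd.DataFrame(coords, index=index, columns=cols)
    columns = (z_matrix.columns if isinstance(z_matrix, pd.DataFrame)
               else pd.RangeIndex(values.shape[1]))
    loadings = pd.DataFrame(pca.components_.T, index=columns, columns=cols)
    return coordinates, loadings, pca.explained_variance_ratio_


def cut_admission_groups(tree: WardTree, k: int | None = None,
                         height: float | None = None) -> pd.Series:
    """Cut the merge tree into flat admission groups lettered A, B, C, ...

    Letters are assigned in dendrogram (leaf-display) order, replacing visual
    inspection with an explicit, reproducible cut.  Exactly one of ``k``
    (group count) or ``height`` (merge-height threshold) must be given.
    """
    n_leaves = len(tree.leaf_ids)
    if (k is None) == (height is None):
        raise DataError("give exactly one of k or height")
    if k is not None:
        if not 1 <= k <= n_leaves:
            raise DataError(f"k must lie in [1, {n_leaves}]")
        flat = cut_tree(tree.linkage_matrix, n_clusters=k)[:, 0]
    else:
        flat = cut_tree(tree.linkage_matrix, height=height)[:, 0]
    flat = pd.Series(flat, index=tree.leaf_ids)
    letters = list(string.ascii_uppercase) + [
        a + b for a in string.ascii_uppercase for b in string.ascii_uppercase]
    mapping = {}
    for leaf in tree.leaf_order():
        g = flat[leaf]
        if g not in mapping:
            mapping[g] = letters[len(mapping)]
    return flat.map(mapping).rename("admission_group")
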