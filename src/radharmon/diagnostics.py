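"""Residual batch-effect diagnostics: silhouette, kBET, PCA, and a
before/after comparison test.

All distance-based diagnostics default to Euclidean distance on z-scored
features; radiomic features span many orders of magnitude, so unscaled
distances would be dominated by the largest-magnitude feature.

* ``silhouette`` — per-subject mixing score with batch labels as
  clusters: ``s_i = (b_i - a_i) / max(a_i, b_i)`` where ``a_i`` is the
  mean distance to the other same-batch subjects and ``b_i`` the minimum
  over other batches of the mean distance to that batch.  Values near 0
  mean well-mixed batches.
* ``kbet`` — k-nearest-neighbour batch-effect test: repeatedly sample a
  subject, compare its k-neighbourhood's batch composition with the
  global batch proportions by Pearson's chi-squared test, and report the
  fraction of rejections.  Near 0 means well mixed.
* ``pca`` — principal-component scores for visual inspection of batch
  separation.
* ``compare_diagnostics`` — Welch two-sample t-test between a
  diagnostic's replication units before and after correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import FeatureMatrix

__all__ = ["SilhouetteResult", "KbetResult", "PcaScores", "scale_features",
           "silhouette", "kbet", "pca", "compare_diagnostics"]


@dataclass
class SilhouetteResult:
    a: np.ndarray                      # mean within-batch distance, self excluded
    b: np.ndarray                      # min over other batches of mean distance
    s: np.ndarray                      # (b - a) / max(a, b)
    mean_s: float
    mean_abs_s: float


@dataclass
class KbetResult:
    k: int
    n_repeats: int
    alpha: float
    statistics: np.ndarray             # per-repeat Pearson chi-squared
    pvalues: np.ndarray
    rejected: np.ndarray               # per-repeat 0/1 indicators
    rejection_rate: float
    seed: int | None


@dataclass
class PcaScores:
    scores: np.ndarray                 # (n_subjects, n_components)
    explained_variance_ratio: np.ndarray
    components: np.ndarray             # (n_components, n_features) loadings


def scale_features(data: FeatureMatrix) -> FeatureMatrix:
    """Z-score each feature column (mean 0, sample SD 1, ddof=1).

    Constant columns cannot be scaled; they are mapped to all-zeros with a
    warning.
    """
    X = data.values.to_numpy()
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        bad = [data.feature_names[i] for i in np.where(const)[0]]
        warnings.warn(f"constant features scaled to zeros: {bad}")
    sd_safe = np.where(const, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, const] = 0.0
    return data.with_values(Z)


def _distance_matrix(data: FeatureMatrix, metric: str, scale: bool) -> np.ndarray:
    mat = scale_features(data) if scale else data
    return squareform(pdist(mat.values.to_numpy(), metric=metric))


def silhouette(data: FeatureMatrix, metric: str = "euclidean",
               scale: bool = True) -> SilhouetteResult:
    """Per-subject silhouette scores with batch labels as clusters.

    Singleton batches leave ``a_i`` undefined; those subjects get
    ``s_i = 0`` with a warning.  Coincident points (``a_i = b_i = 0``)
    also score 0.
    """
    labels = np.asarray(data.batch)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires >= 2 batches")
    D = _distance_matrix(data, metric, scale)
    n = D.shape[0]
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    singletons = [lab for lab in uniq if (labels == lab).sum() == 1]
    if singletons:
        warnings.warn(f"singleton batches {singletons}: their subjects get s_i = 0")
    for i in range(n):
        same = labels == labels[i]
        own = same.copy()
        own[i] = False
        b[i] = min(D[i, labels == lab].mean() for lab in uniq if lab != labels[i])
        if own.sum() == 0:             # singleton batch
            a[i] = np.nan
            s[i] = 0.0
            continue
        a[i] = D[i, own].mean()
        denom = max(a[i], b[i])
        s[i] = 0.0 if denom == 0 else (b[i] - a[i]) / denom
    return SilhouetteResult(a=a, b=b, s=s, mean_s=float(s.mean()),
                            mean_abs_s=float(np.abs(s).mean()))


def kbet(data: FeatureMatrix, k: int = 10, n_repeats: int = 1000,
         alpha: float = 0.05, seed: int | None = None,
         scale: bool = True) -> KbetResult:
    """k-nearest-neighbour batch-effect test rejection rate.

    Each repeat samples one subject uniformly at random (with replacement
    across repeats), takes its k nearest neighbours by Euclidean distance
    on scaled features (self excluded), and tests the neighbourhood batch
    counts against ``k * global_proportions`` with Pearson's chi-squared
    statistic on ``#batches - 1`` degrees of freedom.  The rejection rate
    is the fraction of repeats with ``p < alpha``.
    """
    n = data.n_subjects
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_subjects={n}")
    labels = np.asarray(data.batch)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("kbet requires >= 2 batches")
    props = np.array([(labels == lab).mean() for lab in uniq])
    if (props == 0).any():
        raise ValueError("every batch must have positive proportion")

    mat = (scale_features(data) if scale else data).values.to_numpy()
    nn = NearestNeighbors(n_neighbors=k + 1).fit(mat)
    _, idx = nn.kneighbors(mat)        # first neighbour is the point itself
    neigh = idx[:, 1:k + 1]

    expected = k * props
    neigh_labels = labels[neigh]       # (n, k)
    counts = np.stack([(neigh_labels == lab).sum(axis=1) for lab in uniq], axis=1)
    chi2_all = (((counts - expected) ** 2) / expected).sum(axis=1)
    p_all = stats.chi2.sf(chi2_all, df=uniq.size - 1)

    rng = np.random.default_rng(seed)
    picks = rng.integers(0, n, size=n_repeats)
    statistics = chi2_all[picks]
    pvalues = p_all[picks]
    rejected = (pvalues < alpha).astype(int)
    return KbetResult(k=k, n_repeats=n_repeats, alpha=alpha,
                      statistics=statistics, pvalues=pvalues, rejected=rejected,
                      rejection_rate=float(rejected.mean()), seed=seed)


def pca(data: FeatureMatrix, n_components: int = 2,
        scale: bool = True) -> PcaScores:
    """Principal-component scores of the centered (and scaled) matrix.

    Sign convention: each component is flipped so that its
    largest-magnitude loading is positive, making score signs
    reproducible across linear-algebra backends.
    """
    if n_components > min(data.n_subjects, data.n_features):
        raise ValueError("n_components exceeds min(n_subjects, n_features)")
    X = (scale_features(data) if scale else data).values.to_numpy()
    model = PCA(n_components=n_components)
    scores = model.fit_transform(X)
    comps = model.components_
    for j in range(comps.shape[0]):
        lead = np.argmax(np.abs(comps[j]))
        if comps[j, lead] < 0:
            comps[j] *= -1
            scores[:, j] *= -1
    return PcaScores(scores=scores,
                     explained_variance_ratio=model.explained_variance_ratio_,
                     components=comps)


def compare_diagnostics(before: np.ndarray, after: np.ndarray
                        ) -> tuple[float, float]:
    """Welch two-sample t-test (two-sided) between diagnostic samples.

    For silhouette comparisons the samples are per-subject ``s_i``; for
    kBET they are per-repeat 0/1 rejection indicators.  Degenerate inputs
    (both samples zero-variance) return p = 1 when the means agree and
    p = 0 otherwise, with a warning.
    """
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            warnings.warn("zero-variance samples with equal means: p = 1")
            return 0.0, 1.0
        warnings.warn("zero-variance samples with different means: p = 0")
        return float(np.inf if x.mean() > y.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)
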