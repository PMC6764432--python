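"""PCA of feature matrices and Welch t-tests between groups.

PCA is column-mean-centered (no variance scaling by default — EFD
coefficients share a scale after outline normalization) with a
deterministic sign convention: the largest-magnitude loading of each
component is positive.  Group comparisons use Welch's unequal-variance
t-test, one- or two-tailed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA as _SkPCA

from ._errors import ValidationError


@dataclass
class PCAResult:
    scores: np.ndarray  # (samples, components)
    loadings: np.ndarray  # (features, components), orthonormal columns
    explained_fraction: np.ndarray  # per-component variance fraction
    mean: np.ndarray  # column means removed before decomposition
    group_labels: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(
    X: np.ndarray,
    n_components: int | None = None,
    scale: bool = False,
    group_labels: Sequence[str] | None = None,
) -> PCAResult:
    """Principal component analysis of a samples-by-features matrix.

    Columns are mean-centered; with ``scale=True`` they are additionally
    divided by their standard deviation (correlation PCA).  Components
    are orthonormal; explained fractions over all components sum to 1.
    A zero-variance matrix yields all-zero scores with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be a 2-D samples-by-features matrix")
    if X.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if np.isnan(X).any():
        raise ValidationError("X contains missing values")
    if group_labels is not None and len(group_labels) != X.shape[0]:
        raise ValidationError("group_labels length must match the sample count")
    mean = X.mean(axis=0)
    Xc = X - mean
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    max_rank = min(X.shape)
    if n_components is None:
        n_components = max_rank
    elif n_components > max_rank:
        warnings.warn(
            f"requested {n_components} components but rank is at most "
            f"{max_rank}; truncating",
            stacklevel=2,
        )
        n_components = max_rank
    total_var = float((Xc**2).sum())
    if total_var == 0:
        warnings.warn("zero total variance; scores are all zero", stacklevel=2)
        return PCAResult(
            scores=np.zeros((X.shape[0], n_components)),
            loadings=np.zeros((X.shape[1], n_components)),
            explained_fraction=np.zeros(n_components),
            mean=mean,
            group_labels=list(group_labels) if group_labels is not None else None,
        )
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(Xc)
    loadings = model.components_.T  # (features, components)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_fraction=model.explained_variance_ratio_.copy(),
        mean=mean,
        group_labels=list(group_labels) if group_labels is not None else None,
    )


def t_test(
    x: Sequence[float], y: Sequence[float], tails: str = "two"
) -> tuple[float, float]:
    """Welch's unequal-variance t-test between two samples.

    Returns ``(t, p)``.  The one-tailed p-value is half the two-tailed
    one, taken in the observed direction of the difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    if tails not in ("one", "two"):
        raise ValidationError("tails must be 'one' or 'two'")
    res = sps.ttest_ind(x, y, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # identical constant samples: no difference at all
        t, p = 0.0, 1.0
    if tails == "one":
        p = p / 2.0
    return t, p
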