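"""Latent-space interpretability: PCA, biomarker scores, permutation tests.

The regressor encodes each image into a pooled feature vector (512-d for the
default backbone).  To relate that space to fluorescence biomarkers, the
latent vectors are decomposed with PCA; principal components nearly
orthogonal to viability (|Pearson r| below a threshold) form the candidate
subspace, and the association between a biomarker and that subspace is
scored as the maximum absolute correlation over the subspace's components.
Because the maximum over several components inflates naive p-values, the
significance is assessed with a permutation test on that max-correlation
statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .segmentation import SpheroidMask

__all__ = [
    "PCADecomposition",
    "biomarker_score",
    "pca_top_k",
    "select_orthogonal_pcs",
    "max_corr_permutation_test",
    "PermutationTestResult",
]


def biomarker_score(fluorescence_image, mask) -> float:
    """Summed fluorescence intensity inside the mask per unit mask area."""
    img = np.asarray(fluorescence_image, dtype=float)
    m = mask.mask if isinstance(mask, SpheroidMask) else np.asarray(mask, bool)
    if img.shape != m.shape:
        raise ValueError("fluorescence frame and mask shapes differ")
    area = int(m.sum())
    if area == 0:
        raise ValueError("empty mask: biomarker score undefined")
    return float(img[m].sum() / area)


@dataclass
class PCADecomposition:
    """Top-k PCA of latent vectors with a deterministic sign convention."""

    components: np.ndarray                   # (k, d) orthonormal rows
    explained_variance_fraction: np.ndarray  # (k,), non-increasing
    scores: np.ndarray                       # (n, k) projections
    mean: np.ndarray                         # (d,) centering vector

    def __post_init__(self):
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(len(self.components)), atol=1e-8):
            raise ValueError("components are not orthonormal")
        evf = self.explained_variance_fraction
        if np.any(np.diff(evf) > 1e-12) or evf.sum() > 1.0 + 1e-9:
            raise ValueError("explained variance fractions must be "
                             "non-increasing and sum to <= 1")

    @property
    def k(self) -> int:
        return len(self.components)

    def project(self, latents) -> np.ndarray:
        return (np.asarray(latents, dtype=float) - self.mean) @ self.components.T


def pca_top_k(latents, k=10) -> PCADecomposition:
    """Top-k principal components of latent vectors (centered internally).

    Sign convention: each component's largest-magnitude loading is positive,
    so the decomposition is reproducible across runs and solvers.
    """
    x = np.asarray(latents, dtype=float)
    if x.ndim != 2:
        raise ValueError("latent vectors must form a 2-D matrix")
    n, d = x.shape
    if k > d:
        raise ValueError(f"k={k} exceeds the latent dimension {d}")
    if n <= k:
        raise ValueError(f"need more than k={k} samples, got {n}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    comps = pca.components_.copy()
    for i in range(k):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]
    return PCADecomposition(
        components=comps,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        scores=scores,
        mean=pca.mean_.copy(),
    )


def _pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def select_orthogonal_pcs(decomposition, viability, threshold=0.1):
    """Indices of PCs with |Pearson correlation to viability| below threshold.

    Zero-variance projections are excluded with a warning (their correlation
    is undefined).  Returns indices into the decomposition's component order.
    """
    scores = decomposition.scores if isinstance(decomposition, PCADecomposition) \
        else np.asarray(decomposition, dtype=float)
    v = np.asarray(viability, dtype=float)
    if len(v) != len(scores):
        raise ValueError("viability and PC scores length mismatch")
    if v.std() == 0:
        raise ValueError("viability has zero variance")
    selected = []
    for i in range(scores.shape[1]):
        r = _pearson(scores[:, i], v)
        if np.isnan(r):
            warnings.warn(f"PC{i + 1} has zero-variance scores; excluded",
                          stacklevel=2)
            continue
        if abs(r) < threshold:
            selected.append(i)
    return selected


@dataclass(frozen=True)
class PermutationTestResult:
    per_pc_correlation: tuple   # observed Pearson r per subspace PC
    max_abs_correlation: float  # the test statistic
    best_pc: int                # index (into the subset) attaining the max
    p_value: float
    n_permutations: int
    seed: int


def max_corr_permutation_test(biomarker, pc_scores, n_perm=1000,
                              seed=0) -> PermutationTestResult:
    """Permutation test for the max |correlation| over a PC subspace.

    The statistic is ``max_j |Pearson r(biomarker, PC_j)|`` over the supplied
    score columns; the null distribution permutes the biomarker values
    ``n_perm`` times.  The add-one estimator
    ``p = (1 + #{null >= observed}) / (n_perm + 1)`` never returns exactly 0.
    """
    b = np.asarray(biomarker, dtype=float)
    s = np.atleast_2d(np.asarray(pc_scores, dtype=float))
    if s.shape[0] != len(b):
        s = s.T
    if s.shape[0] != len(b):
        raise ValueError("biomarker and PC scores length mismatch")
    if len(b) < 10:
        raise ValueError("need at least 10 paired observations")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if b.std() == 0:
        raise ValueError("biomarker has zero variance")

    col_sd = s.std(axis=0)
    if np.any(col_sd == 0):
        warnings.warn("dropping zero-variance PC score column(s)",
                      stacklevel=2)
        s = s[:, col_sd > 0]
        if s.shape[1] == 0:
            raise ValueError("all PC score columns have zero variance")
    # standardize once; correlations become scaled dot products
    sz = (s - s.mean(axis=0)) / s.std(axis=0)
    bz = (b - b.mean()) / b.std()
    n = len(b)
    obs_all = bz @ sz / n
    observed = float(np.max(np.abs(obs_all)))

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.max(np.abs(rng.permutation(bz) @ sz)) / n
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return PermutationTestResult(
        per_pc_correlation=tuple(float(r) for r in obs_all),
        max_abs_correlation=observed,
        best_pc=int(np.argmax(np.abs(obs_all))),
        p_value=float(p),
        n_permutations=int(n_perm),
        seed=int(seed),
    )
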