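"""Classifier interpretation: coefficient back-projection and cluster
permutation validation.

A linear SVM fitted on PCA component weights is itself a linear map on the
(standardized) time-frequency features, so its coefficients can be
projected back through the PCA basis into an "eigenspectrogram" — a signed
coefficient map in (frequency, time) space whose inner product with an
epoch's standardized feature grid reproduces the SVM decision value
exactly.

To separate reliable coefficient structure from noise, per-epoch signed
contribution maps (coefficient map x standardized features, signed by
class) are submitted to a one-sample cluster permutation test: points
exceeding the (1 - alpha) quantile of a t-distribution are grouped into
4-connected clusters, cluster mass is the summed t-statistic, and the null
distribution of the maximum |mass| is built by randomly sign-flipping the
per-epoch maps.  The appended voltage row is clustered separately from the
power rows (the two are incommensurate, so clusters never bridge them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .features import EpochFeatureSet
from .preprocess import ITI, STIMULUS

_CONN4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class CoefMap:
    """SVM coefficient map in (frequency+voltage, time) feature space."""

    grid: np.ndarray
    effective_intercept: float
    fold_id: int = 0

    def decision_values(self, standardized_vectors: np.ndarray) -> np.ndarray:
        """Decision values from standardized feature vectors; equals the
        component-space SVM decision function exactly."""
        return standardized_vectors @ self.grid.reshape(-1) + self.effective_intercept


@dataclass
class Cluster:
    mask: np.ndarray  # boolean grid
    mass: float
    sign: int  # +1 or -1
    p_value: float

    @property
    def significant(self) -> bool:  # set against the test's alpha
        return self._significant

    _significant: bool = field(default=False, repr=False)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    t_map: np.ndarray
    threshold: float
    alpha: float
    n_perm: int
    perm_max_mass: np.ndarray

    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    def significant_mask(self, sign: int | None = None) -> np.ndarray:
        """Union of significant cluster masks (optionally of one sign)."""
        mask = np.zeros_like(self.t_map, dtype=bool)
        for c in self.significant_clusters():
            if sign is None or c.sign == sign:
                mask |= c.mask
        return mask


def eigenspectrogram(fold, shape: tuple[int, int], fold_id: int = 0) -> CoefMap:
    """Back-project one fold's SVM weights through its PCA basis.

    ``grid`` = sum_k w_k * component_k reshaped to the feature grid; the
    effective intercept absorbs the PCA centering so that
    ``grid . z + intercept`` equals the component-space decision value for
    every standardized feature vector z (exact linear-map composition).
    """
    components = np.asarray(fold.components)
    coef = np.asarray(fold.coef)
    if components.shape[0] != coef.shape[0]:
        raise ValueError("weight length does not match the number of components")
    vec = components.T @ coef
    if vec.size != shape[0] * shape[1]:
        raise ValueError(f"basis does not match grid shape {shape}")
    eff_int = float(fold.intercept - coef @ (components @ np.asarray(fold.pca_mean)))
    return CoefMap(grid=vec.reshape(shape), effective_intercept=eff_int, fold_id=fold_id)


def contribution_maps(
    folds, features: EpochFeatureSet, labels
) -> np.ndarray:
    """Per-epoch signed coefficient-contribution maps.

    For each epoch, the element-wise product of the coefficient map of the
    fold in which the epoch was held out with the epoch's standardized
    feature grid, signed +1 for stimulus epochs and -1 for baseline epochs
    (cross-validation covers every epoch exactly once).  Summing a map and
    adding sign x effective_intercept recovers the signed decision value.
    """
    labels = np.asarray(labels, dtype=object)
    n_ep = features.n_epochs
    if n_ep < 2:
        raise ValueError("need at least 2 observations")
    shape = features.grid_shape
    seen = np.zeros(n_ep, dtype=int)
    maps = np.zeros((n_ep,) + shape)
    for fold_id, fold in enumerate(folds):
        cmap = eigenspectrogram(fold, shape, fold_id)
        z = (features.vectors[fold.test_idx] - fold.feat_mean) / fold.feat_sd
        signs = np.where(labels[fold.test_idx] == STIMULUS, 1.0, -1.0)
        maps[fold.test_idx] = (
            signs[:, None, None] * z.reshape(len(fold.test_idx), *shape) * cmap.grid
        )
        seen[fold.test_idx] += 1
    if np.any(seen != 1):
        raise ValueError("cross-validation must hold out every epoch exactly once")
    return maps


def _t_map(maps: np.ndarray) -> np.ndarray:
    """Pointwise one-sample t-statistic against zero; zero-variance points
    carry no sign-flip evidence and are set to 0."""
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / se, 0.0)
    return t


def _clusters_from_t(
    t: np.ndarray, threshold: float, split_last_row: bool
) -> list[tuple[np.ndarray, float, int]]:
    """4-connected suprathreshold clusters, positive and negative formed
    separately; the final (voltage) row is its own connectivity domain."""
    out = []
    blocks: list[tuple[slice, np.ndarray]] = []
    if split_last_row and t.shape[0] > 1:
        blocks = [(slice(0, t.shape[0] - 1), t[:-1]), (slice(t.shape[0] - 1, t.shape[0]), t[-1:])]
    else:
        blocks = [(slice(0, t.shape[0]), t)]
    for rows, tb in blocks:
        for sign in (1, -1):
            mask = tb > threshold if sign == 1 else tb < -threshold
            if not mask.any():
                continue
            labeled, n_lab = ndimage.label(mask, structure=_CONN4)
            for lab in range(1, n_lab + 1):
                m = labeled == lab
                full = np.zeros_like(t, dtype=bool)
                full[rows] = m
                out.append((full, float(tb[m].sum()), sign))
    return out


def _perm_t_maps(
    flat_maps: np.ndarray, signs: np.ndarray
) -> np.ndarray:
    """t-maps for all sign-flip permutations at once.

    Sign flips leave per-point sums of squares unchanged, so only the
    permuted means need a matrix product.
    """
    n = flat_maps.shape[0]
    mean_p = signs @ flat_maps / n  # (n_perm, n_points)
    ss = np.einsum("ij,ij->j", flat_maps, flat_maps)
    var_p = np.maximum(ss / n - mean_p**2, 0.0) * (n / (n - 1))
    se_p = np.sqrt(var_p / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_p = np.where(se_p > 0, mean_p / se_p, 0.0)
    return t_p


def one_sample_cluster_perm(
    maps: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    split_last_row: bool = True,
) -> ClusterSet:
    """One-sample cluster permutation test of observation maps against zero.

    The cluster-forming threshold is the (1 - alpha) quantile of a central
    t-distribution with n_obs - 1 degrees of freedom, applied separately to
    positive and negative t-values; cluster mass is the summed t within a
    4-connected component; the permutation null is the maximum |mass| over
    random per-observation sign flips.  A cluster is significant when its
    permutation p-value (with the +1 correction) is below alpha,
    i.e. its |mass| exceeds essentially all permuted maxima.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 10:
        raise ValueError("need at least 10 observations")
    if n_perm < int(np.ceil(1.0 / alpha)):
        import warnings

        warnings.warn(
            f"n_perm={n_perm} gives poor resolution for alpha={alpha}", RuntimeWarning
        )
    threshold = float(stats.t.ppf(1 - alpha, n - 1))
    t_obs = _t_map(maps)
    observed = _clusters_from_t(t_obs, threshold, split_last_row)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    flat = maps.reshape(n, -1)
    t_perm = _perm_t_maps(flat, signs)
    perm_max = np.zeros(n_perm)
    for i in range(n_perm):
        clusters = _clusters_from_t(
            t_perm[i].reshape(maps.shape[1:]), threshold, split_last_row
        )
        if clusters:
            perm_max[i] = max(abs(mass) for _, mass, _ in clusters)

    out = []
    for mask, mass, sign in observed:
        p = (1 + int(np.sum(perm_max >= abs(mass)))) / (n_perm + 1)
        c = Cluster(mask=mask, mass=mass, sign=sign, p_value=p)
        c._significant = p < alpha
        out.append(c)
    return ClusterSet(
        clusters=out,
        t_map=t_obs,
        threshold=threshold,
        alpha=alpha,
        n_perm=n_perm,
        perm_max_mass=perm_max,
    )
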