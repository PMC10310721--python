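"""Ecological trait space: PCA, density contours, SVM hypervolumes and
rarefied null models.

Species positions are principal-component scores of the five standardized
traits, averaged across imputed datasets. A group's occupied trait volume is
estimated by fitting a one-class support vector machine (Gaussian kernel) to
its scores and Monte-Carlo integrating the inside-boundary region over a
padded bounding box; volumes are in units of principal-component standard
deviations to the power of the dimension (SD^d). Observed groups are
compared with rarefied null hypervolumes — random same-size species samples
from the global pool — via a one-sided permutation p-value,
(#{random > observed} + 1) / (n_random + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.svm import OneClassSVM


# ----------------------------------------------------------------------- PCA

@dataclass
class TraitSpace:
    scores: pd.DataFrame           # per-species mean PC scores across sets
    loadings: np.ndarray           # 5x5, from the first set's PCA
    variance_explained: np.ndarray # mean fractions across sets


def pca_space(imputed_sets: Sequence[pd.DataFrame]) -> TraitSpace:
    """PCA per imputed set, signs aligned to the first set, scores averaged.

    All sets must share species order and columns. Component signs are
    aligned by the correlation of loadings with the first set's loadings
    (imputation noise can flip a component's arbitrary sign).
    """
    if len(imputed_sets) < 1:
        raise ValueError("need at least one imputed set")
    index = imputed_sets[0].index
    cols = list(imputed_sets[0].columns)
    d = len(cols)
    ref_loadings = None
    score_sum = np.zeros((len(index), d))
    var_sum = np.zeros(d)
    for s, df in enumerate(imputed_sets):
        if not df.index.equals(index) or list(df.columns) != cols:
            raise ValueError("imputed sets must share species ordering and columns")
        X = df.to_numpy(dtype=float)
        if np.linalg.matrix_rank(np.cov(X.T)) < d:
            raise ValueError("rank-deficient trait matrix")
        pca = PCA(n_components=d, svd_solver="full")
        scores = pca.fit_transform(X)
        load = pca.components_.T  # columns = components
        if ref_loadings is None:
            ref_loadings = load.copy()
        else:
            for j in range(d):
                if float(ref_loadings[:, j] @ load[:, j]) < 0:
                    load[:, j] = -load[:, j]
                    scores[:, j] = -scores[:, j]
        score_sum += scores
        var_sum += pca.explained_variance_ratio_
    n = len(imputed_sets)
    return TraitSpace(
        scores=pd.DataFrame(
            score_sum / n, index=index, columns=[f"PC{j + 1}" for j in range(d)]
        ),
        loadings=ref_loadings,
        variance_explained=var_sum / n,
    )


# --------------------------------------------------------------- KDE contour

@dataclass
class DensityContour:
    threshold: float
    inside: np.ndarray  # bool per point
    kde: object = field(repr=False, default=None)


def density_contour(points: np.ndarray, prob: float = 0.5) -> DensityContour:
    """Highest-density region containing ``prob`` of the sample.

    Gaussian KDE (Scott/plug-in style reference bandwidth); the threshold is
    the (1 - prob) quantile of the density evaluated at the sample points, so
    the inside mask holds a ``prob`` fraction of points. Degenerate
    (collinear) inputs raise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 20:
        raise ValueError("need an (n >= 20) x d array of points")
    if not 0.0 < prob <= 1.0:
        raise ValueError("prob must be in (0, 1]")
    try:
        kde = stats.gaussian_kde(pts.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate point configuration: {exc}") from exc
    dens = kde(pts.T)
    threshold = float(np.quantile(dens, 1.0 - prob))
    return DensityContour(threshold=threshold, inside=dens >= threshold, kde=kde)


# -------------------------------------------------------------- hypervolumes

@dataclass
class Hypervolume:
    support_points: np.ndarray
    nu: float
    gamma: float
    bounding_box: np.ndarray  # d x 2 (lo, hi), input coordinates
    volume: float             # in the input coordinate units^d
    mc_samples: int
    seed: int
    svm: OneClassSVM = field(repr=False, default=None)
    center: np.ndarray = field(repr=False, default=None)
    scale: np.ndarray = field(repr=False, default=None)

    @property
    def dim(self) -> int:
        return self.support_points.shape[1]

    def contains(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.center) / self.scale
        return self.svm.predict(Z) == 1


@dataclass
class HypervolumeConfig:
    nu: float = 0.01
    gamma: float = 0.5
    padding_sd: float = 1.0
    mc_samples: int = 100_000


def _bounding_box(points: np.ndarray, padding_sd: float) -> np.ndarray:
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    pad = padding_sd * points.std(axis=0, ddof=0)
    return np.stack([lo - pad, hi + pad], axis=1)


def svm_hypervolume(
    points: np.ndarray,
    cfg: HypervolumeConfig | None = None,
    seed: int = 0,
) -> Hypervolume:
    """One-class SVM boundary around ``points`` with Monte-Carlo volume.

    The boundary is a Gaussian-kernel one-class SVM (``nu`` bounds the
    fraction of excluded training points, ``gamma`` sets boundary smoothness)
    fit on per-dimension standardized coordinates, so ``gamma`` is expressed
    in squared-SD units and the estimator is exactly translation- and
    scale-equivariant (volumes obey the 2^d scaling law up to Monte-Carlo
    noise). Volume = bounding-box volume x fraction of uniform samples the
    SVM classifies inside; the box is the per-dimension data range padded by
    ``padding_sd`` standard deviations.
    """
    cfg = cfg or HypervolumeConfig()
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be an n x d array")
    n, d = X.shape
    if not 1 <= d <= 5:
        raise ValueError("dimensionality must be between 1 and 5")
    if n < d + 1:
        raise ValueError(f"need at least d+1={d + 1} points, got {n}")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    if np.any(scale <= 0):
        raise ValueError("degenerate hypervolume: zero spread in some dimension")
    Z = (X - center) / scale
    svm = OneClassSVM(kernel="rbf", nu=cfg.nu, gamma=cfg.gamma)
    svm.fit(Z)
    box = _bounding_box(X, cfg.padding_sd)
    rng = np.random.default_rng(seed)
    samples = rng.uniform(box[:, 0], box[:, 1], size=(cfg.mc_samples, d))
    inside = svm.predict((samples - center) / scale) == 1
    box_vol = float(np.prod(box[:, 1] - box[:, 0]))
    return Hypervolume(
        support_points=X,
        nu=cfg.nu,
        gamma=cfg.gamma,
        bounding_box=box,
        volume=box_vol * inside.mean(),
        mc_samples=cfg.mc_samples,
        seed=seed,
        svm=svm,
        center=center,
        scale=scale,
    )


def unique_volume_percent(
    a: Hypervolume, b: Hypervolume, mc_samples: int | None = None, seed: int = 0
) -> float:
    """Percent of ``a``'s volume not shared with ``b``.

    A single uniform sample over the union bounding box feeds both membership
    tests (shared-sample variance reduction); the result is
    100 x vol(a \\ b) / vol(a) estimated on that sample.
    """
    if a.dim != b.dim:
        raise ValueError("hypervolume dimensionality mismatch")
    n_mc = mc_samples or max(a.mc_samples, b.mc_samples)
    lo = np.minimum(a.bounding_box[:, 0], b.bounding_box[:, 0])
    hi = np.maximum(a.bounding_box[:, 1], b.bounding_box[:, 1])
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n_mc, a.dim))
    in_a = a.contains(samples)
    n_a = int(in_a.sum())
    if n_a == 0:
        return 0.0
    in_b = b.contains(samples[in_a])
    return 100.0 * float((~in_b).sum()) / n_a


# ------------------------------------------------------------------- nulls

def permutation_p(observed: float, randoms: Sequence[float]) -> float:
    """One-sided permutation p: (#{random > observed} + 1) / (n + 1).

    Exact-rational on the counts; ties count as non-exceedances. Always in
    (0, 1].
    """
    randoms = list(randoms)
    if not randoms:
        raise ValueError("randoms must be non-empty")
    exceed = sum(1 for r in randoms if r > observed)
    return float(Fraction(exceed + 1, len(randoms) + 1))


@dataclass
class NullComparison:
    observed_volume: float
    observed_unique_percent: float
    random_volumes: np.ndarray
    random_unique_percents: np.ndarray
    observed_unique_percents: np.ndarray  # unique% of observed vs each random
    p_volume: float
    p_unique: float


def null_distribution(
    group_points: np.ndarray,
    pool_points: np.ndarray,
    n_rand: int = 333,
    cfg: HypervolumeConfig | None = None,
    seed: int = 0,
    compute_unique: bool = True,
) -> NullComparison:
    """Observed vs rarefied-null hypervolume comparison.

    Draws ``n_rand`` without-replacement samples of the group's size from the
    global pool, builds a hypervolume for each, and records volumes plus
    unique-volume percents in both directions against the observed
    hypervolume. Because the observed unique percent depends on which random
    hypervolume it is intersected with, its point estimate is the median over
    replicates. p-values use the permutation formula with strict exceedance.
    """
    cfg = cfg or HypervolumeConfig()
    group = np.asarray(group_points, dtype=float)
    pool = np.asarray(pool_points, dtype=float)
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if len(group) > len(pool):
        raise ValueError("group larger than pool")
    rng = np.random.default_rng(seed)
    observed = svm_hypervolume(group, cfg, seed=int(rng.integers(2**31 - 1)))
    rand_vols = np.empty(n_rand)
    rand_unique = np.empty(n_rand)
    obs_unique = np.empty(n_rand)
    for i in range(n_rand):
        idx = rng.choice(len(pool), size=len(group), replace=False)
        hv = svm_hypervolume(pool[idx], cfg, seed=int(rng.integers(2**31 - 1)))
        rand_vols[i] = hv.volume
        if compute_unique:
            share_seed = int(rng.integers(2**31 - 1))
            obs_unique[i] = unique_volume_percent(observed, hv, seed=share_seed)
            rand_unique[i] = unique_volume_percent(hv, observed, seed=share_seed)
        else:
            obs_unique[i] = rand_unique[i] = np.nan
    obs_unique_pt = float(np.median(obs_unique)) if compute_unique else float("nan")
    return NullComparison(
        observed_volume=observed.volume,
        observed_unique_percent=obs_unique_pt,
        random_volumes=rand_vols,
        random_unique_percents=rand_unique,
        observed_unique_percents=obs_unique,
        p_volume=permutation_p(observed.volume, rand_vols),
        p_unique=permutation_p(obs_unique_pt, rand_unique)
        if compute_unique
        else float("nan"),
    )


# ------------------------------------------------------------- effect sizes

def hedges_g(x: Sequence[float], y: Sequence[float]) -> float:
    """Bias-corrected standardized mean difference (Hedges' g).

    g = J * (mean(x) - mean(y)) / s_pooled with the small-sample correction
    J = 1 - 3 / (4 * (n_x + n_y) - 9).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("both samples need >= 2 observations")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled standard deviation")
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * (nx + ny) - 9.0)
    return float(J * d)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction.

    Exact null distribution for small untied samples (both n <= 8), normal
    approximation with continuity correction otherwise. Returns (U of the
    first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def predator_volume_ratio(
    human_prey_points: np.ndarray,
    predator_prey_points: np.ndarray,
    cfg: HypervolumeConfig | None = None,
    seed: int = 0,
) -> float:
    """vol(human prey hypervolume) / vol(predator prey hypervolume).

    Both hypervolumes use the same configuration and seed policy. Callers
    restrict comparisons to predators whose prey are primarily (>80%)
    terrestrial birds and mammals, matching the trait data's coverage.
    """
    cfg = cfg or HypervolumeConfig()
    hv_h = svm_hypervolume(human_prey_points, cfg, seed=seed)
    hv_p = svm_hypervolume(predator_prey_points, cfg, seed=seed)
    if hv_h.volume <= 0 or hv_p.volume <= 0:
        raise ValueError("degenerate hypervolume (zero estimated volume)")
    return hv_h.volume / hv_p.volume


def per_trait_comparisons(
    imputed_sets: Sequence[pd.DataFrame],
    used_index: Sequence,
    not_used_index: Sequence,
) -> pd.DataFrame:
    """Hedges' g and Mann-Whitney p per trait, run per imputed set and
    summarized by the mean across sets."""
    rows = []
    for df in imputed_sets:
        for trait in df.columns:
            x = df.loc[list(used_index), trait]
            y = df.loc[list(not_used_index), trait]
            _, p = mann_whitney_u(x, y)
            rows.append({"trait": trait, "hedges_g": hedges_g(x, y), "p": p})
    return (
        pd.DataFrame(rows)
        .groupby("trait", sort=False)
        .mean()
        .reset_index()
    )
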