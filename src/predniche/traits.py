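"""Five-trait table construction and random-forest imputation.

The ecological trait set is body mass (g), litter/clutch size, habitat
breadth (number of suitable habitats), generation length (years), and a
continuous diet axis. The diet axis is the first principal coordinate of
Gower distances among 7-category diet proportions. Traits are transformed
(log10 for mass and generation length, square root for litter/clutch and
habitat breadth) and z-scored; missing entries are imputed by iterative
random-forest regression ("missForest" scheme) using the other traits plus
the first 10 phylogenetic eigenvectors as predictors, repeated to give
multiple imputed sets whose spread captures imputation uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestRegressor

from .synthetic import DIET_CATEGORIES

logger = logging.getLogger(__name__)

STANDARD_TRAITS = (
    "body_mass",
    "litter_clutch",
    "habitat_breadth",
    "generation_length",
    "diet",
)

_LOG10 = ("body_mass", "generation_length")
_SQRT = ("litter_clutch", "habitat_breadth")


# ------------------------------------------------------------------ diet axis

def gower_distance(props: np.ndarray) -> np.ndarray:
    """Gower distance on numeric columns: mean |x_i - x_j| / range per column.

    Columns with zero range contribute zero distance.
    """
    X = np.asarray(props, dtype=float)
    ranges = X.max(axis=0) - X.min(axis=0)
    ranges = np.where(ranges > 0, ranges, 1.0)
    return squareform(pdist(X / ranges, metric="cityblock") / X.shape[1])


def classical_scaling(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a distance matrix.

    Double-centers -D^2/2 and eigendecomposes; returns (coordinates for axes
    with positive eigenvalues, the positive eigenvalues, descending).
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    return coords, vals[pos]


def cailliez_correction(D: np.ndarray) -> np.ndarray:
    """Additive constant making a dissimilarity matrix Euclidean.

    Adds the smallest constant c to every off-diagonal entry such that the
    corrected matrix embeds without negative eigenvalues (c is the largest
    real eigenvalue of the standard 2n x 2n companion problem).
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    d1 = -0.5 * J @ (D**2) @ J
    d2 = -0.5 * J @ D @ J
    top = np.hstack([np.zeros((n, n)), 2.0 * d1])
    bottom = np.hstack([-np.eye(n), -4.0 * d2])
    eigs = np.linalg.eigvals(np.vstack([top, bottom]))
    c = float(np.max(eigs.real))
    if c <= 0:
        return D
    out = D + c
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class DietAxis:
    scores: pd.Series
    loadings: pd.Series            # Sigma-scaled regression of categories on axis
    variance_explained: float      # lambda_1 / sum(positive lambdas)


def diet_axis(diet: pd.DataFrame, correction: str = "none") -> DietAxis:
    """First principal coordinate of Gower distances among diet proportions.

    Axis sign is fixed so the invertebrate category loads positively.
    Loadings are regression slopes of each category on the (unit-variance)
    axis, scaled by the axis' singular value — an explicit scale choice, not
    correlations. Negative eigenvalues (Gower is not always Euclidean) are
    dropped from the variance normalization; ``correction="cailliez"``
    instead makes the distances Euclidean first. Raises on all-identical
    rows (zero-variance diet).
    """
    cols = [f"diet_{c}" for c in DIET_CATEGORIES]
    X = diet[cols].to_numpy(dtype=float)
    if len(X) < 3:
        raise ValueError("need >= 3 species for a diet axis")
    if np.allclose(X, X[0]):
        raise ValueError("all diet rows identical: zero-variance diet axis")
    D = gower_distance(X)
    if correction == "cailliez":
        D = cailliez_correction(D)
    elif correction != "none":
        raise ValueError("correction must be 'none' or 'cailliez'")
    coords, vals = classical_scaling(D)
    axis = coords[:, 0]
    if np.corrcoef(axis, X[:, DIET_CATEGORIES.index("invertebrates")])[0, 1] < 0:
        axis = -axis
    sd = axis.std(ddof=0)
    unit = (axis - axis.mean()) / sd
    sigma = np.sqrt(vals[0])
    loadings = pd.Series(
        {c: sigma * float(np.cov(unit, X[:, j], ddof=0)[0, 1])
         for j, c in enumerate(DIET_CATEGORIES)}
    )
    return DietAxis(
        scores=pd.Series(axis, index=diet.index, name="diet"),
        loadings=loadings,
        variance_explained=float(vals[0] / vals.sum()),
    )


# ----------------------------------------------------------------- transforms

@dataclass
class TraitTransform:
    """Per-trait transform + z-score parameters, invertible."""

    means: pd.Series
    sds: pd.Series

    def inverse(self, standardized: pd.DataFrame) -> pd.DataFrame:
        out = standardized * self.sds + self.means
        for col in _LOG10:
            out[col] = 10.0 ** out[col]
        for col in _SQRT:
            out[col] = out[col] ** 2
        return out


def transform_traits(raw: pd.DataFrame) -> tuple[pd.DataFrame, TraitTransform]:
    """log10 / sqrt transforms then z-scoring (zero mean, unit variance).

    ``raw`` must carry the five columns of :data:`STANDARD_TRAITS` (the diet
    axis already extracted); NaN entries stay NaN. Raises on non-positive
    mass/generation length and on zero-variance columns.
    """
    df = raw[list(STANDARD_TRAITS)].astype(float).copy()
    for col in _LOG10:
        bad = df.index[df[col] <= 0].tolist()
        if bad:
            raise ValueError(f"non-positive {col} for species {bad[:5]}")
        df[col] = np.log10(df[col])
    for col in _SQRT:
        bad = df.index[df[col] < 0].tolist()
        if bad:
            raise ValueError(f"negative {col} for species {bad[:5]}")
        df[col] = np.sqrt(df[col])
    means = df.mean()
    sds = df.std(ddof=0)
    zero = sds.index[sds < 1e-12].tolist()
    if zero:
        raise ValueError(f"zero-variance trait column(s): {zero}")
    return (df - means) / sds, TraitTransform(means=means, sds=sds)


# ------------------------------------------------------- phylogenetic vectors

def phylo_eigenvectors(tree, k: int = 10) -> pd.DataFrame:
    """First ``k`` eigenvectors of the double-centered patristic distances.

    These compactly encode shared evolutionary history: eigendecomposition of
    -J D^2 J / 2 with D the patristic distance matrix, eigenvectors ordered
    by descending eigenvalue and sign-fixed so each vector's
    largest-magnitude entry is positive. A non-ultrametric tree is accepted
    with a warning; duplicate tip labels are an error.
    """
    from .synthetic import tree_vcv

    C, tips = tree_vcv(tree)
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip labels in tree")
    if k >= len(tips):
        raise ValueError(f"k={k} must be < number of tips ({len(tips)})")
    depths = np.diag(C)
    if depths.std() > 1e-8 * max(depths.mean(), 1e-12):
        logger.warning("tree is not ultrametric; eigenvectors computed anyway")
    D = depths[:, None] + depths[None, :] - 2.0 * C
    np.fill_diagonal(D, 0.0)
    coords, vals = classical_scaling(D)
    k_eff = min(k, coords.shape[1])
    if k_eff < k:
        logger.warning("only %d positive eigenvalues available (k=%d)", k_eff, k)
    V = coords[:, :k_eff]
    # sign convention: largest-|entry| positive
    for j in range(k_eff):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    return pd.DataFrame(
        V, index=pd.Index(tips, name="binomial"),
        columns=[f"phylo_ev{j + 1}" for j in range(k_eff)],
    )


# ------------------------------------------------------------------ missForest

@dataclass
class ImputationConfig:
    """Defaults follow the study protocol: 15 sets, 500 trees, mtry 4
    (square root of the 15 predictors: 5 traits + 10 eigenvectors)."""

    n_sets: int = 15
    n_trees: int = 500
    mtry: int = 4
    n_eigenvectors: int = 10
    max_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.mtry > len(STANDARD_TRAITS) - 1 + self.n_eigenvectors:
            raise ValueError("mtry exceeds available predictors")


@dataclass
class ImputedTraitSets:
    sets: list[pd.DataFrame]
    oob_nrmse_mean: pd.Series
    oob_nrmse_sd: pd.Series
    per_set_nrmse: pd.DataFrame = field(repr=False, default=None)


def _missforest_once(
    traits: pd.DataFrame,
    predictors: pd.DataFrame,
    cfg: ImputationConfig,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """One missForest run: iterate RF fits per trait in ascending
    missingness until the imputed values stop improving."""
    X = traits.copy()
    mask = X.isna()
    miss_frac = mask.mean().sort_values(kind="stable")
    order = [c for c in miss_frac.index if mask[c].any()]
    for col in X.columns:
        X[col] = X[col].fillna(X[col].mean())

    rng = np.random.default_rng(seed)
    prev_diff = np.inf
    best = X.copy()
    oob: dict[str, float] = {c: np.nan for c in traits.columns}
    for _ in range(cfg.max_iterations):
        X_old = X.copy()
        for col in order:
            others = [c for c in X.columns if c != col]
            design = pd.concat([X[others], predictors], axis=1)
            obs = ~mask[col]
            rf = RandomForestRegressor(
                n_estimators=cfg.n_trees,
                max_features=cfg.mtry,
                oob_score=True,
                bootstrap=True,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(design[obs], X.loc[obs, col])
            X.loc[mask[col], col] = rf.predict(design[mask[col]])
            # NRMSE of out-of-bag predictions on observed entries
            oob_pred = rf.oob_prediction_
            truth = X.loc[obs, col].to_numpy()
            denom = truth.std(ddof=0)
            oob[col] = float(
                np.sqrt(np.mean((oob_pred - truth) ** 2)) / max(denom, 1e-12)
            )
        if not order:
            break
        num = sum(
            ((X[c] - X_old[c])[mask[c]] ** 2).sum() for c in order
        )
        den = sum((X[c][mask[c]] ** 2).sum() for c in order) or 1.0
        diff = num / den
        if diff >= prev_diff:
            break  # stop when the change grows; keep the previous iterate
        best = X.copy()
        prev_diff = diff
    # OOB error for complete columns (and any column when nothing is missing)
    for col in X.columns:
        if col in order:
            continue
        others = [c for c in X.columns if c != col]
        design = pd.concat([X[others], predictors], axis=1)
        rf = RandomForestRegressor(
            n_estimators=cfg.n_trees,
            max_features=cfg.mtry,
            oob_score=True,
            bootstrap=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(design, X[col])
        truth = X[col].to_numpy()
        oob[col] = float(
            np.sqrt(np.mean((rf.oob_prediction_ - truth) ** 2))
            / max(truth.std(ddof=0), 1e-12)
        )
    return best, oob


def rf_impute(
    traits: pd.DataFrame,
    eigenvectors: pd.DataFrame,
    cfg: ImputationConfig | None = None,
) -> ImputedTraitSets:
    """Multiple random-forest imputation of standardized traits.

    ``traits``: the five standardized trait columns with NaN gaps.
    ``eigenvectors``: phylogenetic eigenvectors indexed like ``traits``.
    Observed entries are never altered; the ``cfg.n_sets`` completed tables
    differ only through forest randomness. Out-of-bag NRMSE — RMSE of
    out-of-bag predictions over the standard deviation of observed values —
    is summarized by its mean and sd across sets per trait.
    """
    cfg = cfg or ImputationConfig()
    fully_missing = [c for c in traits.columns if traits[c].isna().all()]
    if fully_missing:
        raise ValueError(f"trait(s) fully missing: {fully_missing}")
    eig = eigenvectors.loc[traits.index].iloc[:, : cfg.n_eigenvectors]
    mask = traits.isna()

    sets: list[pd.DataFrame] = []
    nrmse_rows = []
    for s in range(cfg.n_sets):
        filled, oob = _missforest_once(traits, eig, cfg, seed=cfg.seed + 1000 * s)
        filled[~mask] = traits[~mask]  # bit-identical observed entries
        sets.append(filled)
        nrmse_rows.append(oob)
    per_set = pd.DataFrame(nrmse_rows)
    return ImputedTraitSets(
        sets=sets,
        oob_nrmse_mean=per_set.mean(),
        oob_nrmse_sd=per_set.std(ddof=1) if cfg.n_sets > 1 else per_set.iloc[0] * 0.0,
        per_set_nrmse=per_set,
    )
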