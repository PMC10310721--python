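"""Per-grid-cell use richness and availability standardization.

Species ranges are sets of abstract grid-cell ids. Per cell we tabulate the
number of species present, used (any category), used for food, and used as
pets; cells with zero species are retained with zeros but excluded from
model fitting (log of zero availability is undefined).

Standardization fits a negative-binomial GLM (log link) of the used-species
count on log(species present), cell as case — the same model as
MASS::glm.nb with formula ``used ~ log(present)`` — and maps Pearson
residuals r_i = (y_i - mu_i) / sqrt(mu_i + mu_i^2 / theta). Positive
residuals mark cells where more species are used than availability predicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .iucn import IntegrityError, SpeciesRecord


def tabulate_grid(
    ranges: Mapping[str, set[int]],
    species: Sequence[SpeciesRecord],
    n_cells: int,
) -> pd.DataFrame:
    """Counts per cell: present, any use, food use, pet use.

    Every species in ``ranges`` must appear in ``species``; the cell index
    runs over ``range(n_cells)`` so empty cells keep explicit zero rows.
    """
    by_name = {rec.binomial: rec for rec in species}
    unknown = set(ranges) - set(by_name)
    if unknown:
        raise IntegrityError(
            f"{len(unknown)} species in ranges missing from species table, "
            f"e.g. {sorted(unknown)[:3]}"
        )
    present = np.zeros(n_cells, dtype=int)
    used = np.zeros(n_cells, dtype=int)
    food = np.zeros(n_cells, dtype=int)
    pets = np.zeros(n_cells, dtype=int)
    for name, cells in ranges.items():
        rec = by_name[name]
        idx = np.fromiter(cells, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= n_cells):
            raise IntegrityError(f"{name}: cell id outside grid of {n_cells} cells")
        present[idx] += 1
        if rec.used:
            used[idx] += 1
            if "food" in rec.use_categories:
                food[idx] += 1
            if "pets" in rec.use_categories:
                pets[idx] += 1
    return pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "n_present": present,
            "n_used": used,
            "n_food": food,
            "n_pets": pets,
        }
    )


class FitError(RuntimeError):
    """Degenerate or non-converged GLM fit."""


@dataclass
class NBGlmFit:
    intercept: float
    slope: float
    theta: float
    cell_ids: np.ndarray
    fitted_mu: np.ndarray
    pearson_residuals: np.ndarray
    loglike: float
    converged: bool


def fit_use_availability_glm(grid: pd.DataFrame) -> NBGlmFit:
    """NB GLM of used count on log(present count), fit by maximum likelihood.

    Both the regression coefficients and the NB dispersion are estimated
    jointly (statsmodels NB2 likelihood; theta = 1/alpha). Deterministic
    given the data. Requires >= 10 cells with n_present > 0; cells with zero
    species present are dropped (no-data, not zeros).
    """
    sub = grid[grid["n_present"] > 0]
    if len(sub) < 10:
        raise FitError(f"only {len(sub)} non-empty cells; need >= 10")
    y = sub["n_used"].to_numpy(dtype=float)
    if np.all(y == 0):
        raise FitError("all-zero used counts: degenerate fit")
    logp = np.log(sub["n_present"].to_numpy(dtype=float))
    if np.ptp(logp) < 1e-12:
        # constant availability: slope unidentifiable, fix it at zero and fit
        # the intercept-only model (MLE of mu is the mean)
        mu_hat = float(y.mean())
        resid_var = float(y.var(ddof=0))
        excess = resid_var - mu_hat
        theta = mu_hat**2 / excess if excess > 1e-12 else np.inf
        mu = np.full_like(y, mu_hat)
        resid = (y - mu) / np.sqrt(mu + mu**2 / theta)
        return NBGlmFit(
            intercept=float(np.log(mu_hat)),
            slope=0.0,
            theta=float(theta),
            cell_ids=sub["cell_id"].to_numpy(),
            fitted_mu=mu,
            pearson_residuals=resid,
            loglike=float("nan"),
            converged=True,
        )
    X = sm.add_constant(logp)
    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    try:
        res = model.fit(disp=0, maxiter=200, method="bfgs")
    except Exception as exc:  # pragma: no cover - rare numerical failure
        raise FitError(f"NB GLM failed: {exc}") from exc
    converged = res.mle_retvals.get("converged", False)
    grad = np.max(np.abs(res.mle_retvals.get("gopt", [np.inf])))
    if not converged and grad > 1e-3:
        # underdispersed data push alpha to its zero boundary where BFGS
        # reports precision loss; a Nelder-Mead restart usually settles it
        res = model.fit(disp=0, maxiter=2000, method="nm",
                        start_params=res.params)
        converged = res.mle_retvals.get("converged", False)
        if not converged:
            raise FitError(f"NB GLM did not converge: {res.mle_retvals}")
    beta0, beta1, alpha = res.params
    if alpha <= 0:
        alpha = 1e-8
    theta = 1.0 / alpha
    mu = np.exp(X @ np.array([beta0, beta1]))
    resid = (y - mu) / np.sqrt(mu + mu**2 / theta)
    return NBGlmFit(
        intercept=float(beta0),
        slope=float(beta1),
        theta=float(theta),
        cell_ids=sub["cell_id"].to_numpy(),
        fitted_mu=mu,
        pearson_residuals=resid,
        loglike=float(res.llf),
        converged=True,
    )


def pearson_residuals(
    fit: NBGlmFit, outlier_quantile: float = 0.99
) -> pd.DataFrame:
    """Residual table with outlier flags.

    A cell is flagged when |r| exceeds the ``outlier_quantile`` quantile of
    |r| — in the real data such outliers concentrate in polar regions where
    richness is very low or exploitation saturates.
    """
    absr = np.abs(fit.pearson_residuals)
    cutoff = np.quantile(absr, outlier_quantile)
    return pd.DataFrame(
        {
            "cell_id": fit.cell_ids,
            "fitted_mu": fit.fitted_mu,
            "pearson_residual": fit.pearson_residuals,
            "outlier": absr > cutoff,
        }
    )


def simulate_nb_grid(
    n_cells: int,
    intercept: float,
    slope: float,
    theta: float,
    seed: int,
) -> pd.DataFrame:
    """Synthetic grid table drawn from the NB model itself (for recovery
    checks): n_present ~ 1 + lognormal richness, n_used ~ NB(mu, theta) with
    log mu = intercept + slope * log(n_present), truncated at n_present."""
    rng = np.random.default_rng(seed)
    present = np.maximum(1, np.round(rng.lognormal(3.0, 1.0, size=n_cells))).astype(int)
    mu = np.exp(intercept + slope * np.log(present))
    # NB2 as gamma-Poisson mixture
    lam = rng.gamma(shape=theta, scale=mu / theta)
    used = np.minimum(rng.poisson(lam), present)
    zeros = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "n_present": present,
            "n_used": used,
            "n_food": 0,
            "n_pets": 0,
        }
    )
    return zeros
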