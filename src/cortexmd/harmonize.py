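"""Multi-site harmonization of vertex-wise maps (parametric ComBat).

Removes additive (location) and multiplicative (scale) site effects per
vertex via an empirical Bayes model, while preserving modeled biological
covariates (group, age, sex, handedness by default).  The model is
y_ijv = alpha_v + x_j' beta_v + gamma_iv + delta_iv * eps_ijv: least-squares
estimation with site effects constrained to a weighted zero sum, normal /
inverse-gamma hyperpriors fitted by method of moments across vertices, and
the standard EB shrinkage recursion per site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HarmonizationModel",
    "combat_fit",
    "combat_apply",
    "combat_fit_apply",
    "make_covariate_design",
    "DEFAULT_COMBAT_COVARIATES",
]

DEFAULT_COMBAT_COVARIATES = ("group", "age", "sex", "handedness")


@dataclass
class HarmonizationModel:
    """Fitted ComBat parameters.

    Per vertex: grand intercept ``alpha``, covariate coefficients ``beta``,
    pooled residual scale ``sigma``; per site: shrunken location ``gamma_star``
    and scale ``delta_star`` (both sites x vertices) plus the normal /
    inverse-gamma hyperparameters and subject counts used to fit them.
    """

    sites: list[str]
    alpha: np.ndarray            # (V,)
    beta: np.ndarray             # (p, V)
    sigma: np.ndarray            # (V,) pooled residual SD
    gamma_star: np.ndarray       # (n_sites, V)
    delta_star: np.ndarray       # (n_sites, V), > 0
    gamma_bar: np.ndarray        # (n_sites,)
    tau_bar_sq: np.ndarray       # (n_sites,)
    lambda_bar: np.ndarray       # (n_sites,)
    theta_bar: np.ndarray        # (n_sites,)
    n_per_site: np.ndarray       # (n_sites,)
    covariate_names: list[str] = field(default_factory=list)
    n_iterations: int = 0
    incomplete_vertices: np.ndarray | None = None  # QC: excluded from hyperpriors

    def to_json(self, path: str | Path) -> None:
        obj = {
            "sites": self.sites,
            "covariate_names": self.covariate_names,
            "n_iterations": self.n_iterations,
            "n_per_site": self.n_per_site.tolist(),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "sigma": self.sigma.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "gamma_bar": self.gamma_bar.tolist(),
            "tau_bar_sq": self.tau_bar_sq.tolist(),
            "lambda_bar": self.lambda_bar.tolist(),
            "theta_bar": self.theta_bar.tolist(),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "HarmonizationModel":
        obj = json.loads(Path(path).read_text())
        alpha = np.asarray(obj["alpha"])
        beta = np.asarray(obj["beta"])
        if beta.size == 0:  # empty covariate block loses its (0, V) shape in JSON
            beta = beta.reshape(0, len(alpha))
        return cls(
            sites=list(obj["sites"]),
            alpha=alpha,
            beta=beta,
            sigma=np.asarray(obj["sigma"]),
            gamma_star=np.asarray(obj["gamma_star"]),
            delta_star=np.asarray(obj["delta_star"]),
            gamma_bar=np.asarray(obj["gamma_bar"]),
            tau_bar_sq=np.asarray(obj["tau_bar_sq"]),
            lambda_bar=np.asarray(obj["lambda_bar"]),
            theta_bar=np.asarray(obj["theta_bar"]),
            n_per_site=np.asarray(obj["n_per_site"]),
            covariate_names=list(obj["covariate_names"]),
            n_iterations=int(obj["n_iterations"]),
        )


def make_covariate_design(
    cohort: pd.DataFrame, covariates: tuple[str, ...] = DEFAULT_COMBAT_COVARIATES
) -> tuple[np.ndarray, list[str]]:
    """Numeric design columns (no intercept) from cohort covariates;
    categorical variables become k-1 reference-coded indicators."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov not in cohort.columns:
            raise ValueError(f"covariate {cov!r} not in cohort table")
        series = cohort[cov]
        if series.dtype.kind in "ifu":
            cols.append(series.to_numpy(dtype=np.float64))
            names.append(cov)
        else:
            levels = sorted(series.astype(str).unique())
            for lev in levels[1:]:
                cols.append((series.astype(str) == lev).to_numpy(dtype=np.float64))
                names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols) if cols else np.empty((len(cohort), 0))
    return X, names


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept: list[int] = []
        for j in range(design.shape[1]):
            sub = design[:, kept + [j]]
            if np.linalg.matrix_rank(sub) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(
            "rank-deficient harmonization design; confounded columns: " + ", ".join(bad)
        )


def combat_fit(
    data: np.ndarray,
    site: np.ndarray | pd.Series,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> HarmonizationModel:
    """Fit the parametric ComBat model.

    ``data`` is subjects x vertices; ``site`` one label per subject;
    ``covariates`` an optional subjects x p numeric matrix of biological
    variables to preserve.  Vertices with any missing value are excluded
    from hyperprior estimation and receive site parameters shrunk fully to
    the hyperprior means (flagged in ``incomplete_vertices``).
    """
    Y = np.asarray(data, dtype=np.float64)
    if Y.ndim != 2:
        raise ValueError("data must be subjects x vertices")
    site = np.asarray(site)
    if len(site) != Y.shape[0]:
        raise ValueError("site labels must match the number of subjects")
    sites = sorted(set(site.tolist()))
    if len(sites) < 2:
        raise ValueError("all subjects share one site; nothing to harmonize across")
    n, V = Y.shape
    site_idx = np.array([sites.index(s) for s in site])
    n_i = np.bincount(site_idx, minlength=len(sites))
    if np.any(n_i < 2):
        lone = [sites[i] for i in np.nonzero(n_i < 2)[0]]
        raise ValueError(f"sites with fewer than 2 subjects cannot be modeled: {lone}")

    if covariates is None:
        X_cov = np.empty((n, 0))
    else:
        X_cov = np.asarray(covariates, dtype=np.float64)
        if X_cov.ndim == 1:
            X_cov = X_cov[:, None]
    p = X_cov.shape[1]
    names = covariate_names or [f"x{j}" for j in range(p)]

    # full design: one indicator per site + covariates
    S = np.zeros((n, len(sites)))
    S[np.arange(n), site_idx] = 1.0
    X_full = np.hstack([S, X_cov])
    _check_rank(
        np.hstack([S[:, 1:], X_cov, np.ones((n, 1))]),
        [f"site[{s}]" for s in sites[1:]] + names + ["intercept"],
    )

    complete = ~np.any(np.isnan(Y), axis=0)
    if not complete.any():
        raise ValueError("no complete vertices to fit on")
    Yc = np.where(np.isnan(Y), 0.0, Y)

    B, *_ = np.linalg.lstsq(X_full, Yc, rcond=None)
    # incomplete columns: complete-case refit so alpha/beta/sigma are honest
    for v in np.nonzero(~complete)[0]:
        ok = ~np.isnan(Y[:, v])
        if ok.sum() >= X_full.shape[1] + 1 and len(set(site[ok].tolist())) == len(sites):
            B[:, v], *_ = np.linalg.lstsq(X_full[ok], Y[ok, v], rcond=None)
        else:
            B[:, v] = np.nan
    gamma_hat = B[: len(sites), :]                      # (n_sites, V)
    beta = B[len(sites):, :]                            # (p, V)
    # grand intercept: subject-weighted mean of per-site intercepts
    w = n_i / n
    alpha = w @ gamma_hat
    gamma_hat = gamma_hat - alpha[None, :]

    fitted = X_full @ B
    resid = Y - fitted  # NaN-propagating
    with np.errstate(invalid="ignore"):
        sigma = np.sqrt(np.nanmean(resid**2, axis=0))
    sigma = np.where(np.isfinite(sigma), np.maximum(sigma, 1e-300), 1.0)

    # standardize (NaNs propagate; they are excluded below)
    Z = (Y - alpha[None, :] - X_cov @ beta) / sigma[None, :]

    # per-site naive estimates on standardized data
    gam = np.where(np.isfinite(gamma_hat), gamma_hat, 0.0) / sigma[None, :]  # (n_sites, V)
    d2 = np.empty((len(sites), V))
    with np.errstate(invalid="ignore"):
        for i in range(len(sites)):
            zi = Z[site_idx == i]
            d2[i] = np.nansum((zi - gam[i][None, :]) ** 2, axis=0) / (n_i[i] - 1)
    d2 = np.maximum(d2, 1e-300)

    # method-of-moments hyperpriors across complete vertices
    gamma_bar = gam[:, complete].mean(axis=1)
    tau_bar_sq = gam[:, complete].var(axis=1, ddof=1)
    m = d2[:, complete].mean(axis=1)
    s2 = d2[:, complete].var(axis=1, ddof=1)
    s2 = np.maximum(s2, 1e-300)
    lambda_bar = (m**2 + 2.0 * s2) / s2               # inverse-gamma shape
    theta_bar = (m**3 + m * s2) / s2                  # inverse-gamma scale

    # EB iteration
    gamma_star = gam.copy()
    delta_sq = d2.copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        g_old, d_old = gamma_star.copy(), delta_sq.copy()
        num_g = n_i[:, None] * tau_bar_sq[:, None] * gam + delta_sq * gamma_bar[:, None]
        den_g = n_i[:, None] * tau_bar_sq[:, None] + delta_sq
        gamma_star = num_g / den_g
        sse = np.empty_like(delta_sq)
        for i in range(len(sites)):
            zi = Z[site_idx == i]
            sse[i] = np.nansum((zi - gamma_star[i][None, :]) ** 2, axis=0)
        delta_sq = (theta_bar[:, None] + 0.5 * sse) / (
            n_i[:, None] / 2.0 + lambda_bar[:, None] - 1.0
        )
        change = max(
            np.nanmax(np.abs(gamma_star - g_old)), np.nanmax(np.abs(delta_sq - d_old))
        )
        if change < tol:
            break

    # incomplete vertices: fall back to the fully-shrunken hyperprior means
    incomplete = ~complete
    if incomplete.any():
        gamma_star[:, incomplete] = gamma_bar[:, None]
        delta_sq[:, incomplete] = (
            theta_bar[:, None] / np.maximum(lambda_bar[:, None] - 1.0, 1e-6)
        )

    return HarmonizationModel(
        sites=sites,
        alpha=alpha,
        beta=beta,
        sigma=sigma,
        gamma_star=gamma_star,
        delta_star=np.sqrt(delta_sq),
        gamma_bar=gamma_bar,
        tau_bar_sq=tau_bar_sq,
        lambda_bar=lambda_bar,
        theta_bar=theta_bar,
        n_per_site=n_i,
        covariate_names=names,
        n_iterations=n_iter,
        incomplete_vertices=np.nonzero(incomplete)[0],
    )


def combat_apply(
    data: np.ndarray,
    model: HarmonizationModel,
    site: np.ndarray | pd.Series,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Remove the fitted site effects:
    y* = sigma * (z - gamma*_i) / delta*_i + alpha + x' beta.

    Missing values stay missing.  Raises on sites absent from the model.
    """
    Y = np.asarray(data, dtype=np.float64)
    site = np.asarray(site)
    unseen = set(site.tolist()) - set(model.sites)
    if unseen:
        raise ValueError(f"sites not present in the harmonization model: {sorted(unseen)}")
    if covariates is None:
        X_cov = np.empty((Y.shape[0], 0))
    else:
        X_cov = np.asarray(covariates, dtype=np.float64)
        if X_cov.ndim == 1:
            X_cov = X_cov[:, None]
    if X_cov.shape[1] != model.beta.shape[0]:
        raise ValueError("covariate count differs from the fitted model")
    site_idx = np.array([model.sites.index(s) for s in site])
    biological = model.alpha[None, :] + X_cov @ model.beta
    Z = (Y - biological) / model.sigma[None, :]
    Zadj = (Z - model.gamma_star[site_idx]) / model.delta_star[site_idx]
    return Zadj * model.sigma[None, :] + biological


def combat_fit_apply(
    data: np.ndarray,
    site: np.ndarray | pd.Series,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
) -> tuple[np.ndarray, HarmonizationModel]:
    model = combat_fit(data, site, covariates, covariate_names)
    return combat_apply(data, model, site, covariates), model
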