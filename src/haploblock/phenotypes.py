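"""Quantitative-trait preparation: outlier exclusion and Box-Cox normalization.

The preparation order mirrors a standard imaging-genetics pipeline for
positive-valued traits such as sulcal opening: (1) regress each raw trait on
age and sex and flag outliers of the residual distribution with Tukey's IQR
fences; (2) Box-Cox transform the surviving raw values with a per-trait
exponent lambda chosen by profile likelihood for normality; (3) standardize.
Age/sex (and any further covariates, e.g. genetic PCs) re-enter the
association model afterwards — the transform is applied to raw positive
values, not residuals, because residuals violate Box-Cox positivity.

lambda = 1 leaves a normal trait essentially affine-unchanged; lambda = 0 is
the log transform appropriate for log-normal traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger(__name__)

#: Below this |lambda| the log branch of the transform is used.
LOG_BRANCH_EPS = 1e-8


@dataclass
class PhenoConfig:
    """Preparation parameters.

    iqr_k: Tukey fence multiplier (1.5 = the usual convention).
    lambda_grid: candidate Box-Cox exponents; default [-2, 2] step 0.01.
    max_missing_fraction: traits missing in more than this fraction of
    individuals are dropped before testing (default 0.25).
    adjust_columns: covariate columns used for outlier adjustment; default
    ("age", "sex") when present, else all covariate columns.
    """

    iqr_k: float = 1.5
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 10)
    )
    max_missing_fraction: float = 0.25
    adjust_columns: tuple[str, ...] | None = None


@dataclass
class PhenotypeMatrix:
    """Prepared traits: raw values, Box-Cox lambda, transformed values, masks."""

    raw: pd.DataFrame
    transformed: pd.DataFrame
    lambda_: pd.Series
    outlier_mask: pd.DataFrame
    missing_mask: pd.DataFrame
    dropped_traits: list[str]


def flag_outliers_iqr(
    y: np.ndarray, covars: np.ndarray, k: float = 1.5
) -> np.ndarray:
    """Flag outliers of covariate-adjusted residuals with Tukey IQR fences.

    Least-squares residuals of ``y`` on an intercept plus ``covars`` are
    computed over non-missing rows; the mask is True where the residual lies
    outside [Q1 - k*IQR, Q3 + k*IQR]. Values exactly at a fence are kept.
    """
    y = np.asarray(y, dtype=float)
    covars = np.atleast_2d(np.asarray(covars, dtype=float))
    if covars.shape[0] != y.shape[0]:
        covars = covars.T
    obs = np.isfinite(y) & np.isfinite(covars).all(axis=1)
    if obs.sum() < 10:
        raise ValueError("flag_outliers_iqr: need >= 10 non-missing values")
    X = np.column_stack([np.ones(int(obs.sum())), covars[obs]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "flag_outliers_iqr: degenerate covariates (rank-deficient design)"
        )
    coef, *_ = np.linalg.lstsq(X, y[obs], rcond=None)
    resid = y[obs] - X @ coef
    q1, q3 = np.percentile(resid, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    mask = np.zeros_like(y, dtype=bool)
    mask[obs] = (resid < lo) | (resid > hi)
    return mask


def boxcox_loglik(y: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Box-Cox profile log-likelihood for normality at each candidate lambda.

    llf(lam) = (lam - 1) * sum(log y) - n/2 * log(sigma^2_lam), with
    sigma^2_lam the MLE variance of the transformed sample. Vectorized over
    the grid; y must be positive and finite.
    """
    y = np.asarray(y, dtype=float)
    lams = np.asarray(lams, dtype=float)
    n = y.size
    ly = np.log(y)
    sly = ly.sum()
    out = np.empty(lams.size)
    # grid transform via exp(lam * log y); log branch near lam = 0
    for i, lam in enumerate(lams):
        if abs(lam) < LOG_BRANCH_EPS:
            z = ly
        else:
            z = (np.exp(lam * ly) - 1.0) / lam
        var = z.var()
        out[i] = (lam - 1.0) * sly - 0.5 * n * np.log(var)
    return out


def boxcox_transform(y: np.ndarray, lam: float) -> np.ndarray:
    """(y^lam - 1)/lam, or log y on the |lam| < 1e-8 branch."""
    y = np.asarray(y, dtype=float)
    if abs(lam) < LOG_BRANCH_EPS:
        return np.log(y)
    return special.boxcox(y, lam)


def boxcox_fit(
    y: np.ndarray, grid: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Select lambda* on a grid by profile likelihood and transform.

    Non-missing values must all be positive (no silent shifting: shift the
    trait yourself if it has non-positive support). Returns
    ``(lambda*, z)`` with ``z`` the transformed values standardized to zero
    mean and unit variance; missing entries stay NaN.
    """
    y = np.asarray(y, dtype=float)
    obs = np.isfinite(y)
    vals = y[obs]
    if vals.size == 0:
        raise ValueError("boxcox_fit: no non-missing values")
    if np.any(vals <= 0):
        raise ValueError(
            "boxcox_fit: non-positive values present; Box-Cox requires a "
            "positive trait (apply a location shift before calling)"
        )
    if grid is None:
        grid = PhenoConfig().lambda_grid
    llf = boxcox_loglik(vals, grid)
    lam = float(grid[int(np.argmax(llf))])
    z = boxcox_transform(vals, lam)
    z = (z - z.mean()) / z.std()
    out = np.full_like(y, np.nan)
    out[obs] = z
    return lam, out


def prepare_all(
    raw: pd.DataFrame,
    covars: pd.DataFrame,
    cfg: PhenoConfig = PhenoConfig(),
) -> PhenotypeMatrix:
    """Per-trait outlier exclusion and Box-Cox normalization.

    ``raw`` and ``covars`` must share their sample index. Traits missing in
    more than ``cfg.max_missing_fraction`` of individuals are dropped and
    logged; each retained trait gets an independent lambda.
    """
    if not raw.index.equals(covars.index):
        raise ValueError("prepare_all: raw and covars sample indices differ")
    if cfg.adjust_columns is not None:
        adj_cols = list(cfg.adjust_columns)
    else:
        named = [c for c in ("age", "sex") if c in covars.columns]
        adj_cols = named if named else list(covars.columns)
    adj = covars[adj_cols].to_numpy(dtype=float)

    dropped: list[str] = []
    keep: list[str] = []
    lam_map: dict[str, float] = {}
    transformed = {}
    outlier = {}
    for trait in raw.columns:
        y = raw[trait].to_numpy(dtype=float)
        frac_missing = float(np.mean(~np.isfinite(y)))
        if frac_missing > cfg.max_missing_fraction:
            dropped.append(trait)
            logger.info(
                "prepare_all: dropping trait %s (%.1f%% missing)",
                trait,
                100 * frac_missing,
            )
            continue
        mask = flag_outliers_iqr(y, adj, k=cfg.iqr_k)
        y_clean = np.where(mask, np.nan, y)
        lam, z = boxcox_fit(y_clean, cfg.lambda_grid)
        keep.append(trait)
        lam_map[trait] = lam
        transformed[trait] = z
        outlier[trait] = mask
    transformed_df = pd.DataFrame(transformed, index=raw.index, columns=keep)
    outlier_df = pd.DataFrame(outlier, index=raw.index, columns=keep)
    return PhenotypeMatrix(
        raw=raw[keep],
        transformed=transformed_df,
        lambda_=pd.Series(lam_map, name="lambda"),
        outlier_mask=outlier_df,
        missing_mask=raw[keep].isna(),
        dropped_traits=dropped,
    )
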