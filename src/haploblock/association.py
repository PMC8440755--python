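"""The three haplotype association tests and Bonferroni accounting.

All three tests are built on the Gaussian linear model

    Y = b0 + X b + (haplotype dosages) g + e

with Y a prepared (Box-Cox transformed, standardized) trait, X covariates
(age, sex, genetic PCs) and e i.i.d. Gaussian.

block-test    F-test of the nested pair (intercept + X) vs (intercept + X +
              all m alternative dosages of the block): H0 g = 0.
complete-test per-haplotype t-test of g_j within the full block model.
single-test   per-haplotype t-test in a model with only that haplotype's
              dosage, run for j = 0..m — the reference included via its
              dosage 2 - rowsum(H).

Rows with a missing phenotype, missing covariates, or missing phased alleles
in the block are dropped listwise per (phenotype, block) pair; n_used is
recorded per result so multiple-testing accounting is exact. Collinear
dosage columns are pruned deterministically (rarer haplotype dropped) with
tolerance 1e-8 x the design's largest singular value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import HaplotypeBlock
from .haplotypes import BlockHaplotypes, genome_enumeration, reference_dosage
from .io_formats import RESULT_COLUMNS, PhasedPanel

logger = logging.getLogger(__name__)

TEST_FAMILIES = ("block", "complete", "single")


@dataclass
class AssociationResult:
    """One emitted statistic: an F (block test) or t (per-haplotype tests)."""

    phenotype: str
    chrom: str
    block_start_bp: int
    block_end_bp: int
    test: str  # block | complete | single | snp
    haplotype_index: int | None  # None for block test; 0..m otherwise
    haplotype_string: str | None
    statistic: float
    df1: int | None  # numerator df (F only)
    df2: int  # residual df
    p_raw: float
    p_corrected: float | None
    n_used: int

    @property
    def df_label(self) -> str:
        return f"{self.df1};{self.df2}" if self.df1 is not None else str(self.df2)


@dataclass
class TestAccounting:
    """Per-family hypothesis counts and Bonferroni thresholds."""

    n_t: dict[str, int]
    alpha: float

    def threshold(self, family: str) -> float:
        return self.alpha / self.n_t[family]


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / N_T."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# linear-model core

class _Fit:
    """QR least-squares fit with coefficient covariance."""

    __slots__ = ("coef", "rss", "cov_unscaled", "n", "k")

    def __init__(self, X: np.ndarray, y: np.ndarray):
        q, r = np.linalg.qr(X)
        self.coef = np.linalg.solve(r, q.T @ y)
        resid = y - X @ self.coef
        self.rss = float(resid @ resid)
        rinv = np.linalg.solve(r, np.eye(r.shape[0]))
        self.cov_unscaled = rinv @ rinv.T
        self.n, self.k = X.shape


def _prune_collinear(
    base: np.ndarray, cols: np.ndarray, tol_factor: float = 1e-8
) -> list[int]:
    """Indices of ``cols`` columns that add rank beyond ``base``.

    Columns are visited in the given order (descending haplotype frequency),
    so a later, rarer duplicate is the one dropped. A column is kept when
    its residual after projection on the running basis exceeds
    ``tol_factor`` times the largest singular value of [base | cols].
    """
    if cols.shape[1] == 0:
        return []
    full = np.column_stack([base, cols])
    smax = np.linalg.svd(full, compute_uv=False)[0]
    tol = tol_factor * smax
    q, _ = np.linalg.qr(base)
    basis = [q[:, i] for i in range(q.shape[1])]
    kept: list[int] = []
    for j in range(cols.shape[1]):
        v = cols[:, j].astype(float)
        for b in basis:
            v = v - (b @ v) * b
        nrm = np.linalg.norm(v)
        if nrm > tol:
            kept.append(j)
            basis.append(v / nrm)
    return kept


def _complete_rows(
    y: np.ndarray, X: np.ndarray, bh: BlockHaplotypes
) -> np.ndarray:
    return (
        np.isfinite(y)
        & np.isfinite(X).all(axis=1)
        & bh.valid_mask
    )


def _as_cov_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    return X.reshape(len(X), -1)


def _result(bh: BlockHaplotypes, **kw) -> AssociationResult:
    b = bh.block
    return AssociationResult(
        chrom=b.chrom, block_start_bp=b.start_bp, block_end_bp=b.end_bp, **kw
    )


def block_test(
    y: np.ndarray,
    X,
    bh: BlockHaplotypes,
    phenotype: str = "y",
) -> AssociationResult | None:
    """Nested-model F-test of all of a block's haplotype dosages.

    Returns None (untestable) for monomorphic blocks or when every dosage
    column is collinear with the covariates. Raises on insufficient
    residual degrees of freedom.
    """
    if not bh.testable:
        return None
    y = np.asarray(y, dtype=float)
    X = _as_cov_array(X)
    rows = _complete_rows(y, X, bh)
    n = int(rows.sum())
    yv, Xv, Hv = y[rows], X[rows], bh.H[rows].astype(float)
    p = Xv.shape[1]
    base = np.column_stack([np.ones(n), Xv])
    kept = _prune_collinear(base, Hv)
    m_eff = len(kept)
    if m_eff == 0:
        logger.info("block_test: block %s untestable after collinearity pruning",
                    bh.block.start_bp)
        return None
    if n <= 1 + p + m_eff:
        raise ValueError(
            f"block_test: insufficient residual df (n={n}, p={p}, m_eff={m_eff})"
        )
    fit0 = _Fit(base, yv)
    fit1 = _Fit(np.column_stack([base, Hv[:, kept]]), yv)
    df2 = n - 1 - p - m_eff
    f = ((fit0.rss - fit1.rss) / m_eff) / (fit1.rss / df2)
    p_raw = float(stats.f.sf(f, m_eff, df2))
    return _result(
        bh,
        phenotype=phenotype,
        test="block",
        haplotype_index=None,
        haplotype_string=None,
        statistic=float(f),
        df1=m_eff,
        df2=df2,
        p_raw=p_raw,
        p_corrected=None,
        n_used=n,
    )


def complete_test(
    y: np.ndarray,
    X,
    bh: BlockHaplotypes,
    phenotype: str = "y",
) -> list[AssociationResult]:
    """Per-haplotype t-tests within the full block model (one joint fit).

    Collinear dosage columns yield no result (logged).
    """
    if not bh.testable:
        return []
    y = np.asarray(y, dtype=float)
    X = _as_cov_array(X)
    rows = _complete_rows(y, X, bh)
    n = int(rows.sum())
    yv, Xv, Hv = y[rows], X[rows], bh.H[rows].astype(float)
    p = Xv.shape[1]
    base = np.column_stack([np.ones(n), Xv])
    kept = _prune_collinear(base, Hv)
    if len(kept) < bh.m:
        logger.warning(
            "complete_test: dropped %d collinear haplotype column(s) in block %s",
            bh.m - len(kept),
            bh.block.start_bp,
        )
    if not kept:
        return []
    m_eff = len(kept)
    if n <= 1 + p + m_eff:
        raise ValueError("complete_test: insufficient residual df")
    fit = _Fit(np.column_stack([base, Hv[:, kept]]), yv)
    df2 = n - 1 - p - m_eff
    sigma2 = fit.rss / df2
    out = []
    for pos, j in enumerate(kept):
        idx = 1 + p + pos
        se = np.sqrt(sigma2 * fit.cov_unscaled[idx, idx])
        t = fit.coef[idx] / se
        out.append(
            _result(
                bh,
                phenotype=phenotype,
                test="complete",
                haplotype_index=j + 1,
                haplotype_string=bh.haplotype_strings[j + 1],
                statistic=float(t),
                df1=None,
                df2=df2,
                p_raw=float(2 * stats.t.sf(abs(t), df2)),
                p_corrected=None,
                n_used=n,
            )
        )
    return out


def _single_dosage_test(
    yv: np.ndarray, base: np.ndarray, d: np.ndarray
) -> tuple[float, int] | None:
    """t-statistic of one dosage column added to the base design."""
    if np.ptp(d) == 0:
        return None
    n, k0 = base.shape
    if n <= k0 + 1:
        raise ValueError("single test: insufficient residual df")
    fit = _Fit(np.column_stack([base, d]), yv)
    df2 = n - k0 - 1
    sigma2 = fit.rss / df2
    se = np.sqrt(sigma2 * fit.cov_unscaled[-1, -1])
    return float(fit.coef[-1] / se), df2


def single_test(
    y: np.ndarray,
    X,
    bh: BlockHaplotypes,
    phenotype: str = "y",
) -> list[AssociationResult]:
    """Separate one-dosage models for every haplotype j = 0..m.

    j = 0 tests the reference via its dosage 2 - rowsum(H); the intercept
    then absorbs the mean effect of all other haplotypes. Haplotypes with a
    constant dosage over the analyzed rows are untestable (logged).
    """
    if not bh.testable:
        return []
    y = np.asarray(y, dtype=float)
    X = _as_cov_array(X)
    rows = _complete_rows(y, X, bh)
    n = int(rows.sum())
    yv, Xv = y[rows], X[rows]
    base = np.column_stack([np.ones(n), Xv])
    ref = reference_dosage(bh)[rows]
    out = []
    for j in range(bh.m + 1):
        d = ref if j == 0 else bh.H[rows, j - 1].astype(float)
        res = _single_dosage_test(yv, base, d)
        if res is None:
            logger.info(
                "single_test: haplotype %d of block %s has constant dosage",
                j,
                bh.block.start_bp,
            )
            continue
        t, df2 = res
        out.append(
            _result(
                bh,
                phenotype=phenotype,
                test="single",
                haplotype_index=j,
                haplotype_string=bh.haplotype_strings[j],
                statistic=t,
                df1=None,
                df2=df2,
                p_raw=float(2 * stats.t.sf(abs(t), df2)),
                p_corrected=None,
                n_used=n,
            )
        )
    return out


def single_snp_test(
    y: np.ndarray,
    X,
    dosage: np.ndarray,
    phenotype: str = "y",
    chrom: str = ".",
    pos_bp: int = 0,
    snp_id: str = ".",
) -> AssociationResult | None:
    """Classical additive single-SNP test (dosage = alternate-allele count).

    Same model as :func:`single_test` with a SNP dosage vector; a
    monomorphic SNP is untestable (returns None).
    """
    y = np.asarray(y, dtype=float)
    X = _as_cov_array(X)
    dosage = np.asarray(dosage, dtype=float)
    rows = np.isfinite(y) & np.isfinite(X).all(axis=1) & np.isfinite(dosage)
    n = int(rows.sum())
    base = np.column_stack([np.ones(n), X[rows]])
    res = _single_dosage_test(y[rows], base, dosage[rows])
    if res is None:
        return None
    t, df2 = res
    return AssociationResult(
        phenotype=phenotype,
        chrom=chrom,
        block_start_bp=pos_bp,
        block_end_bp=pos_bp,
        test="snp",
        haplotype_index=None,
        haplotype_string=snp_id,
        statistic=t,
        df1=None,
        df2=df2,
        p_raw=float(2 * stats.t.sf(abs(t), df2)),
        p_corrected=None,
        n_used=n,
    )


def bonferroni_correct(
    results: Sequence[AssociationResult], alpha: float = 0.05
) -> tuple[list[AssociationResult], TestAccounting]:
    """Attach p_corrected = min(1, p * N_T) per test family.

    N_T is the number of statistics actually emitted in each family, so the
    accounting matches the results exactly.
    """
    if not results:
        raise ValueError("bonferroni_correct: empty result set")
    n_t: dict[str, int] = {}
    for r in results:
        n_t[r.test] = n_t.get(r.test, 0) + 1
    corrected = [
        replace(r, p_corrected=min(1.0, r.p_raw * n_t[r.test])) for r in results
    ]
    return corrected, TestAccounting(n_t=n_t, alpha=alpha)


# ---------------------------------------------------------------------------
# genome-scale driver

def genome_scan(
    panel: PhasedPanel,
    blocks: Iterable[HaplotypeBlock],
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None,
    tests: Sequence[str] = TEST_FAMILIES,
    alpha: float = 0.05,
    min_carrier_count: int = 1,
) -> tuple[list[AssociationResult], TestAccounting]:
    """Run the selected test families for every (phenotype, block) pair."""
    unknown = set(tests) - set(TEST_FAMILIES)
    if unknown:
        raise ValueError(f"unknown test families: {sorted(unknown)}")
    if covariates is not None:
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.empty((len(phenotypes), 0))
    results: list[AssociationResult] = []
    for bh in genome_enumeration(panel, blocks, min_carrier_count):
        if not bh.testable:
            continue
        for trait in phenotypes.columns:
            y = phenotypes[trait].to_numpy(dtype=float)
            if "block" in tests:
                r = block_test(y, X, bh, phenotype=trait)
                if r is not None:
                    results.append(r)
            if "complete" in tests:
                results.extend(complete_test(y, X, bh, phenotype=trait))
            if "single" in tests:
                results.extend(single_test(y, X, bh, phenotype=trait))
    if not results:
        return [], TestAccounting(n_t={}, alpha=alpha)
    return bonferroni_correct(results, alpha=alpha)


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Results as a DataFrame in the results-TSV column order."""
    rows = [
        {
            "phenotype": r.phenotype,
            "chrom": r.chrom,
            "block_start_bp": r.block_start_bp,
            "block_end_bp": r.block_end_bp,
            "test": r.test,
            "haplotype_index": r.haplotype_index,
            "haplotype_string": r.haplotype_string,
            "statistic": r.statistic,
            "df": r.df_label,
            "p": r.p_raw,
            "p_corrected": r.p_corrected,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def min_p_per_block(results: pd.DataFrame) -> pd.DataFrame:
    """Lowest p per (phenotype, block) — the join key for SNP comparisons."""
    return (
        results.groupby(["phenotype", "chrom", "block_start_bp"], sort=False)["p"]
        .min()
        .reset_index()
    )
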