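"""Permutation-based false-positive-rate audits under three null scenarios.

Permuting a phenotype against the genotypes produces a realistic null in
which every significant statistic is a false positive. Three scenarios keep
or break the correlation structures of the data:

per_block   a fresh permutation per haplotype block — inter-block LD is
            destroyed, within-block structure kept. Run with the full
            covariate model. FPR_p = N_FP / N_{t,p} per phenotype.
genome      one permutation shared by all blocks per run (default 25 runs) —
            genome-wide LD kept. Run on covariate-residualized phenotypes,
            so the per-test fits need no covariates. FPR_p per phenotype
            per run.
pooled      genome-scenario statistics pooled across phenotypes per run:
            FPR_T = N_FP / N_T with N_T the total statistic count. A run is
            flagged when FPR_T >= 1/N_T, i.e. when it has any false
            positive; without inflation about 5% of runs should be flagged
            at family threshold alpha/N_T.

All randomness flows from a counter-based seed sequence with per-(run,
block) substreams, so results are bit-identical for a given plan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import association as assoc
from .blocks import HaplotypeBlock
from .haplotypes import BlockHaplotypes, enumerate_block
from .io_formats import PhasedPanel

SCENARIOS = ("per_block", "genome", "pooled")


@dataclass
class PermutationPlan:
    """What to permute and how often.

    threshold_mode (per_block scenario): "per_phenotype" tests each
    phenotype at alpha / N_{t,p}; "family" uses the family-wide alpha / N_T
    across the selected phenotypes.
    """

    scenario: str = "genome"
    seed: int = 0
    n_runs: int = 25
    alpha: float = 0.05
    tests: Sequence[str] = assoc.TEST_FAMILIES
    threshold_mode: str = "per_phenotype"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class FprResult:
    """One FPR measurement (per phenotype, or pooled across them)."""

    scenario: str
    run: int
    phenotype: str  # trait name or "pooled"
    test: str
    n_fp: int
    denominator: int
    fpr: float
    threshold: float
    exceeds: bool  # FPR >= 1/denominator, i.e. any false positive
    seed: int


def residualize(y: np.ndarray, X) -> np.ndarray:
    """Least-squares residuals of y on an intercept plus X.

    The returned vector is orthogonal to every covariate column and to the
    intercept; subsequent null tests can then omit the covariates.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float).reshape(len(y), -1)
    obs = np.isfinite(y) & np.isfinite(X).all(axis=1)
    D = np.column_stack([np.ones(int(obs.sum())), X[obs]])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("residualize: rank-deficient covariate matrix")
    coef, *_ = np.linalg.lstsq(D, y[obs], rcond=None)
    out = np.full_like(y, np.nan)
    out[obs] = y[obs] - D @ coef
    return out


def _run_block_tests(
    y: np.ndarray, X: np.ndarray, bh: BlockHaplotypes, tests: Sequence[str]
) -> list[assoc.AssociationResult]:
    out: list[assoc.AssociationResult] = []
    if "block" in tests:
        r = assoc.block_test(y, X, bh)
        if r is not None:
            out.append(r)
    if "complete" in tests:
        out.extend(assoc.complete_test(y, X, bh))
    if "single" in tests:
        out.extend(assoc.single_test(y, X, bh))
    return out


def _substream(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *path)))


def run_scenario_per_block(
    panel: PhasedPanel,
    blocks: Sequence[HaplotypeBlock],
    phenotypes: pd.DataFrame,
    covariates,
    plan: PermutationPlan,
) -> list[FprResult]:
    """Scenario 1: an independent permutation per block, full covariate model.

    The same per-block permutation order is applied to every selected
    phenotype (shared substreams), so phenotype columns stay comparable.
    """
    X = np.asarray(covariates, dtype=float).reshape(len(phenotypes), -1)
    per_pheno: dict[tuple[str, str], list[float]] = {}
    for run in range(plan.n_runs):
        for bi, block in enumerate(blocks):
            bh = enumerate_block(panel, block)
            if not bh.testable:
                continue
            perm = _substream(plan.seed, run, bi).permutation(len(phenotypes))
            for trait in phenotypes.columns:
                y = phenotypes[trait].to_numpy(dtype=float)[perm]
                for r in _run_block_tests(y, X, bh, plan.tests):
                    per_pheno.setdefault((trait, r.test), []).append(r.p_raw)
    results: list[FprResult] = []
    family_n = {
        t: sum(len(v) for (ph, tt), v in per_pheno.items() if tt == t)
        for t in plan.tests
    }
    for (trait, test), pvals in sorted(per_pheno.items()):
        n_tp = len(pvals)
        denom = n_tp if plan.threshold_mode == "per_phenotype" else family_n[test]
        thr = plan.alpha / denom
        n_fp = int(np.sum(np.asarray(pvals) < thr))
        results.append(
            FprResult(
                scenario="per_block",
                run=0,
                phenotype=trait,
                test=test,
                n_fp=n_fp,
                denominator=n_tp,
                fpr=n_fp / n_tp,
                threshold=thr,
                exceeds=n_fp >= 1,
                seed=plan.seed,
            )
        )
    return results


def run_scenario_genome(
    panel: PhasedPanel,
    blocks: Sequence[HaplotypeBlock],
    y_star: pd.DataFrame,
    plan: PermutationPlan,
) -> tuple[list[FprResult], dict[tuple[int, str, str], np.ndarray]]:
    """Scenario 2: one permutation per run shared by all blocks.

    ``y_star`` holds covariate-residualized phenotypes (see
    :func:`residualize`); tests are fit without covariates. Returns per-
    (run, phenotype) FPR results plus the raw p-values per (run, phenotype,
    test) for pooling and Q-Q summaries.
    """
    n = len(y_star)
    X0 = np.empty((n, 0))
    bhs = [bh for bh in (enumerate_block(panel, b) for b in blocks) if bh.testable]
    results: list[FprResult] = []
    pstore: dict[tuple[int, str, str], np.ndarray] = {}
    for run in range(plan.n_runs):
        perm = _substream(plan.seed, run).permutation(n)
        collected: dict[tuple[str, str], list[float]] = {}
        for bh in bhs:
            for trait in y_star.columns:
                y = y_star[trait].to_numpy(dtype=float)[perm]
                for r in _run_block_tests(y, X0, bh, plan.tests):
                    collected.setdefault((trait, r.test), []).append(r.p_raw)
        family_n = {
            t: sum(len(v) for (ph, tt), v in collected.items() if tt == t)
            for t in plan.tests
        }
        for (trait, test), pvals in sorted(collected.items()):
            arr = np.asarray(pvals)
            pstore[(run, trait, test)] = arr
            n_tp = arr.size
            thr = plan.alpha / family_n[test]
            n_fp = int(np.sum(arr < thr))
            results.append(
                FprResult(
                    scenario="genome",
                    run=run,
                    phenotype=trait,
                    test=test,
                    n_fp=n_fp,
                    denominator=n_tp,
                    fpr=n_fp / n_tp,
                    threshold=thr,
                    exceeds=n_fp >= 1,
                    seed=plan.seed,
                )
            )
    return results, pstore


def pool_scenario(
    pstore: dict[tuple[int, str, str], np.ndarray],
    plan: PermutationPlan,
) -> list[FprResult]:
    """Scenario 3: pool genome-scenario statistics across phenotypes per run.

    FPR_T = N_FP / N_T at threshold alpha / N_T; a run is flagged when
    FPR_T >= 1/N_T (it contains at least one false positive).
    """
    if not pstore:
        raise ValueError("pool_scenario: no stored p-values")
    runs = sorted({k[0] for k in pstore})
    tests = sorted({k[2] for k in pstore})
    traits_per_run = {
        run: sorted({k[1] for k in pstore if k[0] == run}) for run in runs
    }
    ref = traits_per_run[runs[0]]
    if any(traits_per_run[r] != ref for r in runs):
        raise ValueError("pool_scenario: mismatched run sets across phenotypes")
    out: list[FprResult] = []
    for run in runs:
        for test in tests:
            pooled = np.concatenate(
                [pstore[(run, tr, test)] for tr in ref if (run, tr, test) in pstore]
            )
            n_t = pooled.size
            thr = plan.alpha / n_t
            n_fp = int(np.sum(pooled < thr))
            fpr = n_fp / n_t
            out.append(
                FprResult(
                    scenario="pooled",
                    run=run,
                    phenotype="pooled",
                    test=test,
                    n_fp=n_fp,
                    denominator=n_t,
                    fpr=fpr,
                    threshold=thr,
                    exceeds=fpr >= 1.0 / n_t,
                    seed=plan.seed,
                )
            )
    return out


def fpr_report(results: Iterable[FprResult]) -> pd.DataFrame:
    """Tabular FPR report: per-run rows plus per-test summary columns."""
    rows = pd.DataFrame([vars(r) for r in results])
    if rows.empty:
        raise ValueError("fpr_report: no results")
    summary = (
        rows.groupby(["scenario", "test"], sort=False)
        .agg(
            n_runs=("run", "nunique"),
            mean_tests_per_run=("denominator", "mean"),
            mean_threshold=("threshold", "mean"),
            mean_fpr=("fpr", "mean"),
            mean_n_fp=("n_fp", "mean"),
            n_exceeding=("exceeds", "sum"),
            prop_exceeding=("exceeds", "mean"),
            min_fpr=("fpr", "min"),
            max_fpr=("fpr", "max"),
        )
        .reset_index()
    )
    return summary


def qq_summary(
    pstore_or_pvals, n_quantiles: int = 200
) -> pd.DataFrame:
    """Aggregated Q-Q hull over permutation runs.

    Accepts either a mapping run -> p-value array (or the pstore of
    :func:`run_scenario_genome`, grouped by run) or a single p-value array.
    Returns expected -log10 p quantiles with min/median/max observed values
    across runs.
    """
    if isinstance(pstore_or_pvals, dict):
        by_run: dict[int, list[np.ndarray]] = {}
        for key, arr in pstore_or_pvals.items():
            run = key[0] if isinstance(key, tuple) else key
            by_run.setdefault(run, []).append(np.asarray(arr, dtype=float))
        run_arrays = [np.concatenate(v) for _, v in sorted(by_run.items())]
    else:
        run_arrays = [np.asarray(pstore_or_pvals, dtype=float)]
    if not run_arrays or any(a.size == 0 for a in run_arrays):
        raise ValueError("qq_summary: empty p-value set")
    probs = (np.arange(n_quantiles) + 0.5) / n_quantiles
    expected = -np.log10(probs)
    obs = np.stack(
        [
            -np.log10(np.quantile(np.sort(arr), probs, method="inverted_cdf"))
            for arr in run_arrays
        ]
    )
    return pd.DataFrame(
        {
            "expected_neglog10p": expected,
            "observed_min": obs.min(axis=0),
            "observed_median": np.median(obs, axis=0),
            "observed_max": obs.max(axis=0),
        }
    )
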