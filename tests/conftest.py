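"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from haploblock.blocks import HaplotypeBlock
from haploblock.io_formats import PhasedPanel, SnpRecord

settings.register_profile("fixed", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("fixed")


def panel_from_haplotypes(ind_haps: list[tuple[str, str]], chrom: str = "1",
                          start_bp: int = 100, spacing: int = 100) -> PhasedPanel:
    """Build a panel from per-individual (copyA, copyB) allele strings.

    '.' in a string marks a missing allele.
    """
    n_snps = len(ind_haps[0][0])
    snps = [
        SnpRecord(chrom, start_bp + i * spacing, f"s{i + 1}", "A", "C")
        for i in range(n_snps)
    ]
    code = {"0": 0, "1": 1, ".": -1}
    alleles = np.array(
        [
            [[code[a[i]], code[b[i]]] for i in range(n_snps)]
            for a, b in ind_haps
        ],
        dtype=np.int8,
    ).transpose(0, 1, 2)
    sample_ids = [f"ind{k + 1}" for k in range(len(ind_haps))]
    return PhasedPanel(snps, sample_ids, alleles)


def whole_panel_block(panel: PhasedPanel) -> HaplotypeBlock:
    """A block spanning every SNP of a single-chromosome panel."""
    return HaplotypeBlock(
        chrom=panel.snps[0].chrom,
        snp_start=0,
        snp_end=panel.n_snps - 1,
        start_bp=panel.snps[0].pos_bp,
        end_bp=panel.snps[-1].pos_bp,
        l_cm=0.0,
        n_snps=panel.n_snps,
    )


# ---------------------------------------------------------------------------
# independent normal-equations oracle (kept free of the package's QR path)

def ne_fit(D: np.ndarray, y: np.ndarray):
    """OLS by explicit normal equations: coef, RSS, unscaled covariance."""
    xtx = D.T @ D
    coef = np.linalg.solve(xtx, D.T @ y)
    resid = y - D @ coef
    return coef, float(resid @ resid), np.linalg.inv(xtx)


def ne_block_f(y, X, H):
    """Nested-model F statistic and p from normal equations."""
    from scipy import stats

    n = len(y)
    base = np.column_stack([np.ones(n), X])
    full = np.column_stack([base, H])
    _, rss0, _ = ne_fit(base, y)
    _, rss1, _ = ne_fit(full, y)
    m = H.shape[1]
    df2 = n - full.shape[1]
    f = ((rss0 - rss1) / m) / (rss1 / df2)
    return f, float(stats.f.sf(f, m, df2))


def ne_t_tests(y, X, H):
    """Per-column t statistics of H within the full model, from normal equations."""
    from scipy import stats

    n = len(y)
    full = np.column_stack([np.ones(n), X, H])
    coef, rss, cov = ne_fit(full, y)
    df2 = n - full.shape[1]
    sigma2 = rss / df2
    k0 = 1 + X.shape[1]
    out = []
    for j in range(H.shape[1]):
        se = np.sqrt(sigma2 * cov[k0 + j, k0 + j])
        t = coef[k0 + j] / se
        out.append((float(t), float(2 * stats.t.sf(abs(t), df2))))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
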