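"""Per-block haplotype enumeration and the additive count matrix H.

Each individual contributes its two phased allele strings over a block's
SNPs. The reference haplotype h0 is the most common string (ties broken by
the lexicographically smallest string); the count matrix H is N x m with
H[i, j] the number of copies (0/1/2) of the j-th alternative haplotype
carried by individual i, alternatives ordered by descending carrier count.
For every valid individual, copies of h0 plus the row sum of H equal 2.

Individuals with any missing allele inside a block are excluded from that
block only (valid_mask False); their H rows are zero and ignored downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .blocks import HaplotypeBlock
from .io_formats import PhasedPanel

logger = logging.getLogger(__name__)


@dataclass
class BlockHaplotypes:
    """Observed haplotypes of one block and their additive dosages.

    ``haplotype_strings[0]`` is the reference h0; ``haplotype_strings[1:]``
    are the m alternatives in descending-count order, matching the columns
    of ``H``. ``counts`` are chromosome-copy tallies over valid individuals.
    """

    block: HaplotypeBlock
    haplotype_strings: list[str]
    counts: np.ndarray  # chromosome counts, aligned to haplotype_strings
    H: np.ndarray  # (N, m) int8
    valid_mask: np.ndarray  # (N,) bool

    @property
    def h0(self) -> str:
        return self.haplotype_strings[0]

    @property
    def m(self) -> int:
        return len(self.haplotype_strings) - 1

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def testable(self) -> bool:
        return self.m >= 1

    def frequencies(self) -> np.ndarray:
        """Sample frequencies of all haplotypes (reference first)."""
        return self.counts / self.counts.sum()


def enumerate_block(
    panel: PhasedPanel, block: HaplotypeBlock, min_carrier_count: int = 1
) -> BlockHaplotypes:
    """Tally the haplotypes of one block and build its count matrix.

    ``min_carrier_count`` (default 1, i.e. no filter) excludes individuals
    carrying an alternative haplotype seen in fewer carriers than the
    threshold; exclusion preserves diploid conservation among the rest.
    A monomorphic block returns m=0 and is flagged untestable.
    """
    if block.snp_end >= panel.n_snps:
        raise ValueError("block indices outside panel")
    sub = panel.alleles[:, block.snp_slice, :]  # (N, n_snps, 2)
    n_ind = sub.shape[0]
    valid = ~(sub < 0).any(axis=(1, 2))
    chroms = sub[valid].transpose(0, 2, 1).reshape(-1, block.n_snps)
    if chroms.shape[0] == 0:
        return BlockHaplotypes(
            block,
            [],
            np.zeros(0, dtype=int),
            np.zeros((n_ind, 0), dtype=np.int8),
            valid,
        )
    uniq, inverse, cnt = np.unique(
        chroms, axis=0, return_inverse=True, return_counts=True
    )
    strings = ["".join(str(int(a)) for a in row) for row in uniq]
    # descending count, ties by lexicographically smallest string
    order = sorted(range(len(strings)), key=lambda k: (-cnt[k], strings[k]))
    rank = np.empty(len(order), dtype=int)
    for new, old in enumerate(order):
        rank[old] = new
    # per-individual copy counts of every distinct haplotype
    per_ind = inverse.reshape(-1, 2)
    n_valid = per_ind.shape[0]
    full = np.zeros((n_valid, len(strings)), dtype=np.int8)
    rows = np.repeat(np.arange(n_valid), 2)
    np.add.at(full, (rows, rank[per_ind.ravel()]), 1)

    strings_sorted = [strings[k] for k in order]
    counts_sorted = cnt[order].astype(int)

    if min_carrier_count > 1 and len(strings_sorted) > 1:
        carriers = (full[:, 1:] > 0).sum(axis=0)
        rare = np.flatnonzero(carriers < min_carrier_count) + 1
        if rare.size:
            drop_ind = (full[:, rare] > 0).any(axis=1)
            logger.info(
                "enumerate_block: excluding %d carriers of %d rare haplotypes",
                int(drop_ind.sum()),
                rare.size,
            )
            keep_ids = np.flatnonzero(valid)[~drop_ind]
            new_valid = np.zeros_like(valid)
            new_valid[keep_ids] = True
            return enumerate_block(
                _mask_panel_rows(panel, new_valid), block, min_carrier_count=1
            )

    H = np.zeros((n_ind, len(strings_sorted) - 1), dtype=np.int8)
    H[valid] = full[:, 1:]
    return BlockHaplotypes(block, strings_sorted, counts_sorted, H, valid)


def _mask_panel_rows(panel: PhasedPanel, keep: np.ndarray) -> PhasedPanel:
    """Panel copy where excluded individuals' alleles are set missing."""
    alleles = panel.alleles.copy()
    alleles[~keep] = -1
    return PhasedPanel(panel.snps, panel.sample_ids, alleles)


def reference_dosage(bh: BlockHaplotypes) -> np.ndarray:
    """Copies of h0 per individual: 2 - rowsum(H); NaN where invalid."""
    d = 2.0 - bh.H.sum(axis=1)
    d[~bh.valid_mask] = np.nan
    return d


def genome_enumeration(
    panel: PhasedPanel,
    blocks: Iterable[HaplotypeBlock],
    min_carrier_count: int = 1,
) -> Iterator[BlockHaplotypes]:
    """Lazily enumerate every block of a panel."""
    for block in blocks:
        yield enumerate_block(panel, block, min_carrier_count=min_carrier_count)


def enumeration_summary(bhs: Iterable[BlockHaplotypes]) -> dict:
    """Global tallies over testable blocks.

    ``total_haplotypes`` counts distinct haplotypes including references;
    ``m_distribution`` maps m (alternative count) to block count.
    """
    total = 0
    n_blocks = 0
    n_untestable = 0
    m_dist: dict[int, int] = {}
    for bh in bhs:
        if not bh.testable:
            n_untestable += 1
            continue
        n_blocks += 1
        total += bh.m + 1
        m_dist[bh.m] = m_dist.get(bh.m, 0) + 1
    return {
        "n_testable_blocks": n_blocks,
        "n_untestable_blocks": n_untestable,
        "total_haplotypes": total,
        "m_distribution": dict(sorted(m_dist.items())),
    }
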