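"""Haplotype-block segmentation from genetic-map coordinates.

Blocks are maximal runs of consecutive SNPs whose pairwise consecutive cM
gaps are all <= delta; a gap strictly greater than delta starts a new block.
Runs shorter than the minimum block size (default 2 SNPs) are dropped.
Blocks never span chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SnpRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlockConfig:
    """Segmentation parameters.

    delta_cm is the maximum cM gap tolerated between consecutive SNPs inside
    a block (default 0.001 cM, a compromise between block length and phase
    reliability); min_snps_per_block drops degenerate runs.
    """

    delta_cm: float = 0.001
    min_snps_per_block: int = 2

    def __post_init__(self) -> None:
        if self.delta_cm <= 0:
            raise ValueError("delta_cm must be > 0")
        if self.min_snps_per_block < 2:
            raise ValueError("min_snps_per_block must be >= 2")


@dataclass(frozen=True)
class HaplotypeBlock:
    """A run of consecutive SNPs treated as inherited without recombination.

    ``snp_start``/``snp_end`` are inclusive indices into the panel's SNP
    list; ``l_cm`` is the genetic length, cM(last) - cM(first).
    """

    chrom: str
    snp_start: int
    snp_end: int
    start_bp: int
    end_bp: int
    l_cm: float
    n_snps: int

    @property
    def snp_slice(self) -> slice:
        return slice(self.snp_start, self.snp_end + 1)


def segment_blocks(
    cm: np.ndarray, snps: list[SnpRecord], cfg: BlockConfig = BlockConfig()
) -> list[HaplotypeBlock]:
    """Partition each chromosome's SNP run into haplotype blocks.

    ``cm`` is the per-SNP cM vector aligned to ``snps`` (non-decreasing
    within each chromosome). Returns retained blocks in genomic order;
    dropped short runs are counted in the log.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.shape != (len(snps),):
        raise ValueError(
            f"cm length {cm.shape} does not match {len(snps)} SNPs"
        )
    blocks: list[HaplotypeBlock] = []
    n_dropped = 0
    start = 0
    for i in range(1, len(snps) + 1):
        boundary = i == len(snps) or (
            snps[i].chrom != snps[i - 1].chrom
            or cm[i] - cm[i - 1] > cfg.delta_cm
        )
        if not boundary:
            continue
        n = i - start
        if n >= cfg.min_snps_per_block:
            blocks.append(
                HaplotypeBlock(
                    chrom=snps[start].chrom,
                    snp_start=start,
                    snp_end=i - 1,
                    start_bp=snps[start].pos_bp,
                    end_bp=snps[i - 1].pos_bp,
                    l_cm=float(cm[i - 1] - cm[start]),
                    n_snps=n,
                )
            )
        else:
            n_dropped += 1
        start = i
    if n_dropped:
        logger.info(
            "segment_blocks: dropped %d runs shorter than %d SNPs",
            n_dropped,
            cfg.min_snps_per_block,
        )
    return blocks


def block_stats(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    """Per-chromosome block summary: counts, SNP-run sizes, L(h) distribution."""
    if not blocks:
        raise ValueError("block_stats: empty block list")
    df = pd.DataFrame(
        {
            "chrom": [b.chrom for b in blocks],
            "n_snps": [b.n_snps for b in blocks],
            "l_cm": [b.l_cm for b in blocks],
        }
    )
    rows = []
    for chrom, grp in df.groupby("chrom", sort=False):
        rows.append(
            {
                "chrom": chrom,
                "n_blocks": len(grp),
                "n_snps_min": int(grp.n_snps.min()),
                "n_snps_median": float(grp.n_snps.median()),
                "n_snps_max": int(grp.n_snps.max()),
                "l_cm_min": float(grp.l_cm.min()),
                "l_cm_median": float(grp.l_cm.median()),
                "l_cm_max": float(grp.l_cm.max()),
            }
        )
    return pd.DataFrame(rows)


def blocks_to_frame(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    """One row per block (1-based inclusive bp coordinates)."""
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in blocks],
            "start_bp": [b.start_bp for b in blocks],
            "end_bp": [b.end_bp for b in blocks],
            "n_snps": [b.n_snps for b in blocks],
            "l_cm": [b.l_cm for b in blocks],
        }
    )


def write_blocks_bed(blocks: list[HaplotypeBlock], path: str) -> None:
    """BED export (0-based half-open, converted from 1-based inclusive)."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start_bp - 1}\t{b.end_bp}\tn_snps={b.n_snps}\n")
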