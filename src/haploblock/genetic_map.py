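"""Genetic-map coordinates: bp -> cM via linear interpolation.

A :class:`GeneticMap` holds the (bp, cM) anchors of one chromosome. Positions
inside the anchored range are linearly interpolated between the two flanking
anchors (i.e. using the local recombination rate in cM/bp); positions before
the first or after the last anchor are linearly extrapolated with the
whole-chromosome mean rate, applied on both flanks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io_formats import PhasedPanel


@dataclass(frozen=True)
class GeneticMap:
    """Monotone bp -> cM mapping for one chromosome."""

    pos_bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.pos_bp, dtype=float)
        cm = np.asarray(self.cm, dtype=float)
        if pos.ndim != 1 or pos.shape != cm.shape:
            raise ValueError("pos_bp and cm must be 1-d arrays of equal length")
        if pos.size < 2:
            raise ValueError("a genetic map needs at least 2 anchors")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("anchor positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("anchor cM must be non-decreasing")
        object.__setattr__(self, "pos_bp", pos)
        object.__setattr__(self, "cm", cm)

    @classmethod
    def from_anchors(cls, anchors: list[tuple[int, float]]) -> "GeneticMap":
        if len(anchors) < 2:
            raise ValueError("a genetic map needs at least 2 anchors")
        pos, cm = zip(*anchors)
        return cls(np.asarray(pos, float), np.asarray(cm, float))

    @property
    def whole_chrom_rate(self) -> float:
        """Mean recombination rate over the chromosome, cM per bp."""
        return (self.cm[-1] - self.cm[0]) / (self.pos_bp[-1] - self.pos_bp[0])

    def cm_at(self, pos: float | np.ndarray) -> np.ndarray | float:
        """cM coordinate(s) for base-pair position(s).

        Flat (zero-rate) segments interpolate flat; out-of-range positions
        use whole-chromosome linear extrapolation.
        """
        p = np.asarray(pos, dtype=float)
        out = np.interp(p, self.pos_bp, self.cm)
        rate = self.whole_chrom_rate
        left = p < self.pos_bp[0]
        right = p > self.pos_bp[-1]
        out = np.where(left, self.cm[0] - rate * (self.pos_bp[0] - p), out)
        out = np.where(right, self.cm[-1] + rate * (p - self.pos_bp[-1]), out)
        return float(out) if np.isscalar(pos) or out.ndim == 0 else out


def cm_at(gmap: GeneticMap, pos_bp: float | np.ndarray):
    """Functional alias for :meth:`GeneticMap.cm_at`."""
    return gmap.cm_at(pos_bp)


def annotate_panel(
    maps: Mapping[str, GeneticMap], panel: PhasedPanel
) -> np.ndarray:
    """cM coordinate for every panel SNP, aligned to panel SNP order.

    Every chromosome present in the panel must have a map; within each
    chromosome the result is non-decreasing (positions are strictly
    increasing and each map is monotone).
    """
    missing = [c for c in panel.chromosomes() if c not in maps]
    if missing:
        raise ValueError(f"no genetic map for chromosome(s): {', '.join(missing)}")
    out = np.empty(panel.n_snps, dtype=float)
    for chrom in panel.chromosomes():
        idx = [i for i, r in enumerate(panel.snps) if r.chrom == chrom]
        pos = np.array([panel.snps[i].pos_bp for i in idx], dtype=float)
        out[idx] = maps[chrom].cm_at(pos)
    return out
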