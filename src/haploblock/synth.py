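"""Synthetic phased panels, genetic maps, covariates and phenotypes.

The generator emulates the data a haplotype association study consumes:
per-block haplotype pools with specified frequencies from which each
individual's two chromosome copies are drawn i.i.d., a monotone genetic map
constructed so block segmentation at the configured delta recovers the
designed blocks exactly, age/sex-like covariates, and quantitative traits

    y = b0 + X b + sum_j gamma_j * dosage_j + e,   e ~ N(0, sd^2),

optionally pushed through an inverse power transform with exponent lambda0
to produce positive, skewed raw traits that exercise the Box-Cox machinery.

Blocks are simulated independently (no inter-block LD) unless
``inter_block_copy`` is set, in which case each block's chromosome draws are
copied from the previous block's draws with the given probability,
inducing the long-range correlation the genome-permutation null preserves.

Defaults model a modest cohort: 500 individuals, ages uniform on 45-73,
48% male, 10 three-SNP blocks with three-haplotype pools, unit noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .blocks import BlockConfig
from .genetic_map import GeneticMap
from .io_formats import PhasedPanel, SnpRecord


@dataclass(frozen=True)
class BlockSpec:
    """One designed block: its SNP count and haplotype pool."""

    n_snps: int
    pool: dict[str, float]  # haplotype string -> frequency

    def __post_init__(self) -> None:
        if abs(sum(self.pool.values()) - 1.0) > 1e-9:
            raise ValueError(
                f"pool frequencies sum to {sum(self.pool.values())}, not 1"
            )
        for h in self.pool:
            if len(h) != self.n_snps or set(h) - {"0", "1"}:
                raise ValueError(f"bad haplotype string {h!r} for {self.n_snps} SNPs")


def default_blocks(n_blocks: int = 10) -> list[BlockSpec]:
    """Three-SNP blocks with a common/middling/rare three-haplotype pool."""
    return [
        BlockSpec(3, {"000": 0.55, "010": 0.30, "111": 0.15})
        for _ in range(n_blocks)
    ]


@dataclass
class SimSpec:
    """Study-design parameters for one synthetic dataset."""

    n_individuals: int = 500
    blocks: list[BlockSpec] = field(default_factory=default_blocks)
    chrom: str = "1"
    snp_spacing_bp: int = 1000
    intra_gap_cm: float = 0.0002  # <= delta: SNPs stay in one block
    inter_gap_cm: float = 0.01  # > delta: separates designed blocks
    delta_cm: float = 0.001
    age_range: tuple[float, float] = (45.0, 73.0)
    male_fraction: float = 0.48
    age_effect: float = 0.0
    sex_effect: float = 0.0
    n_traits: int = 1
    effects: dict[tuple[int, str], float] = field(default_factory=dict)
    intercept: float = 0.0
    noise_sd: float = 1.0
    lambda0: float | None = None  # inverse Box-Cox warp exponent
    inter_block_copy: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intra_gap_cm > self.delta_cm:
            raise ValueError("intra_gap_cm must be <= delta_cm")
        if self.inter_gap_cm <= self.delta_cm:
            raise ValueError("inter_gap_cm must be > delta_cm")


@dataclass
class SimTruth:
    """Ground truth stored alongside a simulated dataset."""

    effects: dict[tuple[int, str], float]
    intercept: float
    age_effect: float
    sex_effect: float
    noise_sd: float
    lambda0: float | None
    block_snp_ranges: list[tuple[int, int]]


def simulate_panel(
    spec: SimSpec, rng: np.random.Generator | None = None
) -> tuple[PhasedPanel, GeneticMap]:
    """Draw a phased panel and build its exactly-recoverable genetic map.

    The map anchors every SNP position, with intra-block cM gaps of
    ``intra_gap_cm`` (<= delta) and inter-block gaps of ``inter_gap_cm``
    (> delta), so :func:`haploblock.blocks.segment_blocks` at ``delta_cm``
    returns exactly the designed blocks.
    """
    rng = rng or np.random.default_rng(spec.seed)
    snps: list[SnpRecord] = []
    cm_anchors: list[float] = []
    pos = 10_000
    cm = 0.0
    hap_cols: list[np.ndarray] = []
    prev_draw: np.ndarray | None = None
    for bi, bspec in enumerate(spec.blocks):
        pool = sorted(bspec.pool.items())
        strings = [h for h, _ in pool]
        freqs = np.array([f for _, f in pool])
        draw = rng.choice(len(strings), size=(spec.n_individuals, 2), p=freqs)
        if spec.inter_block_copy > 0 and prev_draw is not None:
            copy = rng.random(spec.n_individuals) < spec.inter_block_copy
            draw[copy] = prev_draw[copy]
        prev_draw = draw
        alleles = np.array(
            [[int(c) for c in s] for s in strings], dtype=np.int8
        )  # (n_pool, n_snps)
        hap_cols.append(alleles[draw].transpose(0, 2, 1))  # (N, n_snps, 2)
        for k in range(bspec.n_snps):
            if snps:
                gap_cm = spec.intra_gap_cm if k > 0 else spec.inter_gap_cm
                pos += spec.snp_spacing_bp
                cm += gap_cm
            snps.append(
                SnpRecord(spec.chrom, pos, f"snp{len(snps) + 1}", "A", "G")
            )
            cm_anchors.append(cm)
    alleles = np.concatenate(hap_cols, axis=1)
    sample_ids = [f"ind{i + 1}" for i in range(spec.n_individuals)]
    panel = PhasedPanel(snps, sample_ids, alleles)
    gmap = GeneticMap(
        np.array([s.pos_bp for s in snps], dtype=float),
        np.array(cm_anchors, dtype=float),
    )
    return panel, gmap


def block_config(spec: SimSpec) -> BlockConfig:
    return BlockConfig(delta_cm=spec.delta_cm)


def simulate_covariates(
    spec: SimSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Age (uniform on the configured range) and sex (0/1, balanced-ish)."""
    rng = rng or np.random.default_rng(spec.seed + 1)
    age = rng.uniform(*spec.age_range, size=spec.n_individuals)
    sex = (rng.random(spec.n_individuals) < spec.male_fraction).astype(float)
    return pd.DataFrame(
        {"age": age, "sex": sex},
        index=[f"ind{i + 1}" for i in range(spec.n_individuals)],
    )


def _block_snp_ranges(spec: SimSpec) -> list[tuple[int, int]]:
    out = []
    start = 0
    for b in spec.blocks:
        out.append((start, start + b.n_snps - 1))
        start += b.n_snps
    return out


def simulate_phenotypes(
    panel: PhasedPanel,
    spec: SimSpec,
    covars: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate traits with additive haplotype effects and known truth.

    ``spec.effects`` maps (block index, haplotype string) to the effect per
    copy. With ``lambda0`` set, the linear trait z is warped to the positive
    scale via the inverse power transform (1 + lambda0*z)^(1/lambda0)
    (exp(z) at lambda0 = 0); Box-Cox at lambda0 then recovers z. The warp
    raises when 1 + lambda0*z <= 0 for some individual — increase the
    intercept (location) in the spec.
    """
    from .haplotypes import enumerate_block
    from .blocks import HaplotypeBlock

    rng = rng or np.random.default_rng(spec.seed + 2)
    n = spec.n_individuals
    ranges = _block_snp_ranges(spec)
    base = (
        spec.intercept
        + spec.age_effect * covars["age"].to_numpy()
        + spec.sex_effect * covars["sex"].to_numpy()
    )
    genetic = np.zeros(n)
    for (bi, hap), gamma in spec.effects.items():
        s, e = ranges[bi]
        block = HaplotypeBlock(
            chrom=spec.chrom,
            snp_start=s,
            snp_end=e,
            start_bp=panel.snps[s].pos_bp,
            end_bp=panel.snps[e].pos_bp,
            l_cm=0.0,
            n_snps=e - s + 1,
        )
        bh = enumerate_block(panel, block)
        if hap not in bh.haplotype_strings:
            raise ValueError(
                f"effect haplotype {hap!r} not observed in block {bi}"
            )
        j = bh.haplotype_strings.index(hap)
        if j == 0:
            dosage = 2.0 - bh.H.sum(axis=1)
        else:
            dosage = bh.H[:, j - 1].astype(float)
        genetic += gamma * dosage
    traits = {}
    for t in range(spec.n_traits):
        z = base + genetic + rng.normal(0.0, spec.noise_sd, size=n)
        if spec.lambda0 is not None:
            if abs(spec.lambda0) < 1e-12:
                y = np.exp(z)
            else:
                arg = 1.0 + spec.lambda0 * z
                if np.any(arg <= 0):
                    raise ValueError(
                        "inverse Box-Cox warp hit non-positive values; "
                        "increase the intercept (location shift) in the spec"
                    )
                y = special.inv_boxcox(z, spec.lambda0)
        else:
            y = z
        traits[f"trait{t + 1}"] = y
    raw = pd.DataFrame(traits, index=covars.index)
    truth = SimTruth(
        effects=dict(spec.effects),
        intercept=spec.intercept,
        age_effect=spec.age_effect,
        sex_effect=spec.sex_effect,
        noise_sd=spec.noise_sd,
        lambda0=spec.lambda0,
        block_snp_ranges=ranges,
    )
    return raw, truth


def simulate_study(
    spec: SimSpec,
) -> tuple[PhasedPanel, GeneticMap, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Convenience wrapper: panel + map + covariates + phenotypes + truth."""
    rng = np.random.default_rng(spec.seed)
    panel, gmap = simulate_panel(spec, rng)
    covars = simulate_covariates(spec, np.random.default_rng(spec.seed + 1))
    raw, truth = simulate_phenotypes(
        panel, spec, covars, np.random.default_rng(spec.seed + 2)
    )
    return panel, gmap, covars, raw, truth
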