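"""Readers and writers for the on-disk formats the pipeline touches.

Everything downstream of this module consumes only in-memory domain types:
:class:`PhasedPanel` for phased genotypes, plain ``(pos_bp, cM)`` anchor lists
for genetic maps, and pandas DataFrames for phenotype/covariate tables and
association results.

Phased genotypes can arrive either as a VCF with phased ``GT`` fields or as a
SHAPEIT-style ``.haps``/``.sample`` pair; both readers produce identical
panels on equivalent content. Positions are 1-based throughout, as in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing allele in :attr:`PhasedPanel.alleles`.
MISSING = -1

#: Tokens read as missing values in phenotype/covariate tables.
NA_TOKENS = ("NA", "NaN", "nan", ".", "")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP: chromosome, 1-based position, id and alleles."""

    chrom: str
    pos_bp: int
    snp_id: str
    ref_allele: str
    alt_allele: str


@dataclass
class PhasedPanel:
    """Phased genotypes for N individuals at S biallelic SNPs.

    ``alleles`` has shape (N, S, 2); the last axis holds the two phased
    chromosome copies, coded 0 (reference), 1 (alternate) or :data:`MISSING`.
    """

    snps: list[SnpRecord]
    sample_ids: list[str]
    alleles: np.ndarray  # int8, shape (N, S, 2)

    def __post_init__(self) -> None:
        n, s = len(self.sample_ids), len(self.snps)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (n, s, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} inconsistent with "
                f"{n} samples x {s} SNPs x 2 phases"
            )
        self._check_positions()

    def _check_positions(self) -> None:
        last: dict[str, int] = {}
        for rec in self.snps:
            prev = last.get(rec.chrom)
            if prev is not None and rec.pos_bp <= prev:
                raise FormatError(
                    f"SNP positions not strictly increasing on chromosome "
                    f"{rec.chrom}: {prev} then {rec.pos_bp}"
                )
            last[rec.chrom] = rec.pos_bp

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for rec in self.snps:
            seen.setdefault(rec.chrom, None)
        return list(seen)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhasedPanel):
            return NotImplemented
        return (
            self.snps == other.snps
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.alleles, other.alleles)
        )


def _in_region(chrom: str, pos: int, region: tuple | None) -> bool:
    if region is None:
        return True
    if len(region) == 1:
        return chrom == region[0]
    rchrom, start, end = region
    return chrom == rchrom and start <= pos <= end


def read_phased_vcf(path: str, region: tuple | None = None) -> PhasedPanel:
    """Read a VCF with phased GT fields into a :class:`PhasedPanel`.

    Multiallelic and non-SNP records are skipped (counted in the log).
    A fully-called genotype written with the unphased separator ``/`` raises
    :class:`FormatError` naming the record and sample; genotypes containing a
    missing allele are kept as missing (their phase is undefined).

    Parameters
    ----------
    region:
        Optional ``(chrom,)`` or ``(chrom, start_bp, end_bp)`` filter,
        1-based inclusive.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if not _in_region(var.CHROM, var.POS, region):
            continue
        gts = var.genotypes  # list of [a0, a1, ..., phased]
        col = np.empty((len(samples), 2), dtype=np.int8)
        for i, g in enumerate(gts):
            if len(g) != 3:
                raise FormatError(
                    f"non-diploid genotype at {var.CHROM}:{var.POS} "
                    f"for sample {samples[i]}"
                )
            a0, a1, phased = g
            if a0 < 0 or a1 < 0:
                col[i] = (MISSING, MISSING)
                continue
            if not phased:
                raise FormatError(
                    f"unphased genotype at {var.CHROM}:{var.POS} "
                    f"({var.ID or '.'}) for sample {samples[i]}"
                )
            col[i] = (a0, a1)
        snps.append(
            SnpRecord(var.CHROM, var.POS, var.ID or ".", var.REF, var.ALT[0])
        )
        cols.append(col)
    vcf.close()
    if n_skipped:
        logger.info("read_phased_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if cols:
        alleles = np.stack(cols, axis=1)
    else:
        alleles = np.empty((len(samples), 0, 2), dtype=np.int8)
    return PhasedPanel(snps, samples, alleles)


def write_phased_vcf(panel: PhasedPanel, path: str) -> None:
    """Write a panel as a minimal phased VCF (GT field only)."""
    code = {0: "0", 1: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in panel.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for v, rec in enumerate(panel.snps):
            gts = "\t".join(
                f"{code[int(a)]}|{code[int(b)]}" for a, b in panel.alleles[:, v, :]
            )
            fh.write(
                f"{rec.chrom}\t{rec.pos_bp}\t{rec.snp_id}\t{rec.ref_allele}\t"
                f"{rec.alt_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_haps_sample(haps_path: str, sample_path: str) -> PhasedPanel:
    """Read a SHAPEIT-style ``.haps`` + ``.sample`` pair.

    The haps file has five leading columns (chrom, id, pos, allele0, allele1)
    followed by 2N allele columns; the sample file lists N individuals, with
    the usual two header lines tolerated.
    """
    sample_ids = _read_sample_ids(sample_path)
    n = len(sample_ids)
    snps: list[SnpRecord] = []
    rows: list[np.ndarray] = []
    with open(haps_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5 + 2 * n:
                raise FormatError(
                    f"{haps_path}:{lineno}: expected {5 + 2 * n} columns "
                    f"(5 + 2x{n} samples), found {len(parts)}"
                )
            chrom, snp_id, pos, a0, a1 = parts[:5]
            snps.append(SnpRecord(chrom, int(pos), snp_id, a0, a1))
            vals = [MISSING if tok in ("?", ".", "-1") else int(tok) for tok in parts[5:]]
            if any(v not in (0, 1, MISSING) for v in vals):
                raise FormatError(f"{haps_path}:{lineno}: allele codes must be 0/1")
            rows.append(np.asarray(vals, dtype=np.int8))
    if rows:
        # row layout: sample1_hapA sample1_hapB sample2_hapA ...
        alleles = np.stack(rows, axis=0).reshape(len(rows), n, 2).transpose(1, 0, 2)
    else:
        alleles = np.empty((n, 0, 2), dtype=np.int8)
    return PhasedPanel(snps, sample_ids, alleles)


def _read_sample_ids(sample_path: str) -> list[str]:
    with open(sample_path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{sample_path}: empty sample file")
    # SHAPEIT dialect: header line (ID_1 ID_2 ...) then a '0 0 0' type line
    if lines[0][0].upper() in ("ID_1", "ID"):
        lines = lines[1:]
        if lines and set(lines[0]) <= {"0", "D", "B", "C", "P"}:
            lines = lines[1:]
    return [ln[1] if len(ln) > 1 else ln[0] for ln in lines]


def write_haps_sample(panel: PhasedPanel, haps_path: str, sample_path: str) -> None:
    """Write a panel in the ``.haps``/``.sample`` dialect."""
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for sid in panel.sample_ids:
            fh.write(f"{sid} {sid} 0\n")
    code = {0: "0", 1: "1", MISSING: "?"}
    with open(haps_path, "w") as fh:
        for v, rec in enumerate(panel.snps):
            vals = " ".join(
                f"{code[int(a)]} {code[int(b)]}" for a, b in panel.alleles[:, v, :]
            )
            fh.write(
                f"{rec.chrom} {rec.snp_id} {rec.pos_bp} "
                f"{rec.ref_allele} {rec.alt_allele} {vals}\n"
            )


def read_genetic_map(path: str) -> list[tuple[int, float]]:
    """Read a HapMap/1000G-style 3-column genetic map.

    Columns are position (bp), local rate (ignored) and cumulative map
    position (cM); a non-numeric header line is tolerated. Returns anchors
    sorted by bp. Duplicate positions with identical cM are collapsed;
    decreasing cM or duplicate bp with differing cM raise :class:`FormatError`.
    """
    anchors: list[tuple[int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            try:
                pos = int(float(parts[0]))
                cm = float(parts[-1])
            except (ValueError, IndexError):
                if lineno == 1:
                    continue  # header
                raise FormatError(f"{path}:{lineno}: unparseable map line")
            anchors.append((pos, cm))
    if not anchors:
        raise FormatError(f"{path}: no anchors")
    anchors.sort(key=lambda a: a[0])
    out: list[tuple[int, float]] = []
    for pos, cm in anchors:
        if out:
            ppos, pcm = out[-1]
            if pos == ppos:
                if cm != pcm:
                    raise FormatError(
                        f"{path}: duplicate position {pos} with differing cM "
                        f"({pcm} vs {cm})"
                    )
                continue
            if cm < pcm:
                raise FormatError(
                    f"{path}: corrupt map, cM decreases from {pcm} to {cm} "
                    f"at position {pos}"
                )
        out.append((pos, cm))
    return out


def read_table(
    path: str,
    kind: str = "phenotype",
    sample_order: Sequence[str] | None = None,
    na_tokens: Sequence[str] = NA_TOKENS,
) -> pd.DataFrame:
    """Read a TSV phenotype or covariate table, indexed by sample id.

    The first column is the sample id; remaining columns must be numeric
    (configurable NA tokens allowed). If ``sample_order`` is given, rows are
    re-aligned to it; samples absent from the file produce all-NaN rows and
    are counted in the log.
    """
    if kind not in ("phenotype", "covariate"):
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        index_col=0,
    )
    df.index = df.index.astype(str)
    na = set(na_tokens)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            tok = raw.strip()
            if tok in na:
                out.iloc[i, j] = np.nan
                continue
            try:
                out.iloc[i, j] = float(tok)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {raw!r} at row {df.index[i]!r}, "
                    f"column {col!r}"
                ) from None
    if sample_order is not None:
        missing = [s for s in sample_order if s not in out.index]
        if missing:
            logger.info(
                "read_table(%s): %d requested samples absent, rows filled NaN",
                path,
                len(missing),
            )
        out = out.reindex(list(sample_order))
    return out


def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a sample-indexed table as TSV (inverse of :func:`read_table`)."""
    df.to_csv(path, sep="\t", index_label="sample_id")


#: Column order of the results TSV.
RESULT_COLUMNS = [
    "phenotype",
    "chrom",
    "block_start_bp",
    "block_end_bp",
    "test",
    "haplotype_index",
    "haplotype_string",
    "statistic",
    "df",
    "p",
    "p_corrected",
]


def write_results(results: pd.DataFrame, path: str) -> None:
    """Write association results as TSV, one row per emitted statistic."""
    results.reindex(columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "df": str, "haplotype_string": str}
    )
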