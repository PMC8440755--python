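"""Discovery/replication accounting for association hits.

A replication table has one row per (block, phenotype) association and, per
test family, a discovery cell and a replication cell. Each cell is either a
Bonferroni-corrected p-value (the association was significant), ``ns`` (not
significant) or ``nt`` (not tested, e.g. because the discovery cell was not
significant). The replication rate of a family is the fraction of its
significant discovery cells whose replication cell is also significant; the
phenotype-level rate aggregates hits of the same trait across blocks (a
trait counts as replicated when any of its hits replicates).

A packaged example table from a published genome-wide sulcal-opening study
ships with the module (three haplotype-test families over 29 hits).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: Cell tokens meaning "no p-value here".
NOT_SIGNIFICANT = "ns"
NOT_TESTED = "nt"

FAMILIES = ("block", "complete", "single")


def load_replication_table(path: str | None = None) -> pd.DataFrame:
    """Load a replication table; default is the packaged example."""
    if path is None:
        ref = resources.files("haploblock.data").joinpath("replication_table.tsv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", dtype=str)
    return pd.read_csv(path, sep="\t", dtype=str)


def _is_significant(cell: str) -> bool:
    tok = str(cell).strip().lower()
    if tok in (NOT_SIGNIFICANT, NOT_TESTED, "nan", ""):
        return False
    float(tok)  # raises on malformed cells
    return True


def summarize_replication(
    table: pd.DataFrame, families: tuple[str, ...] = FAMILIES
) -> pd.DataFrame:
    """Replication rates per test family, at hit and phenotype level.

    Returns one row per family with discovery counts, replicated counts and
    the two percentage rates (rounded to 2 decimals).
    """
    rows = []
    for fam in families:
        disc = table[f"{fam}_disc"].map(_is_significant)
        rep = table[f"{fam}_rep"].map(_is_significant)
        hits_disc = int(disc.sum())
        hits_rep = int((disc & rep).sum())
        phen_disc = table.loc[disc, "phenotype"].nunique()
        phen_rep = table.loc[disc & rep, "phenotype"].nunique()
        rows.append(
            {
                "test": fam,
                "hits_discovery": hits_disc,
                "hits_replicated": hits_rep,
                "hit_replication_pct": round(100.0 * hits_rep / hits_disc, 2)
                if hits_disc
                else np.nan,
                "phenotypes_discovery": phen_disc,
                "phenotypes_replicated": phen_rep,
                "phenotype_replication_pct": round(
                    100.0 * phen_rep / phen_disc, 2
                )
                if phen_disc
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
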