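"""Bait-normalized spectral abundance (SAF / BNSAF) from spectral counts.

Interaction strength between an affinity-purified bait (TFIIB) and a
co-purified prey protein is quantified per replicate as

    SAF   = spectral count / protein length (aa)
    BNSAF = SAF(prey) / SAF(bait)

The bait ratio cancels any run-level constant (instrument depth,
loading), so SAF needs no run-total renormalization; the bait's own
BNSAF is identically 1.  Strains are compared per protein with a paired
two-sided t-test over replicate BNSAFs, and reported grouped by protein
complex (CF1A, CPF, Rat1, general transcription factors).
"""

from __future__ import annotations

import logging
import os
import re
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Count columns are named "<strain>_<fraction>_<replicate>", e.g. "WT_chromatin_1".
COUNT_COLUMN_RE = re.compile(r"^(?P<strain>[^_]+)_(?P<fraction>[^_]+)_(?P<replicate>\d+)$")
META_COLUMNS = ["protein_id", "length", "complex"]


def load_spectral_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Load a spectral-count TSV (protein_id, length, complex, count columns)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if not count_columns(df):
        raise ValueError(f"{path}: no '<strain>_<fraction>_<rep>' count columns found")
    return df


def count_columns(table: pd.DataFrame, strain: Optional[str] = None,
                  fraction: Optional[str] = None) -> list[str]:
    """Count columns of the table, optionally restricted by strain/fraction,
    ordered by replicate index."""
    cols = []
    for c in table.columns:
        m = COUNT_COLUMN_RE.match(str(c))
        if not m:
            continue
        if strain is not None and m["strain"] != strain:
            continue
        if fraction is not None and m["fraction"] != fraction:
            continue
        cols.append((int(m["replicate"]), c))
    return [c for _, c in sorted(cols)]


def compute_saf(spectral_count: float, protein_length: float) -> float:
    """Spectral abundance factor: count / protein length (aa)."""
    if protein_length <= 0:
        raise ValueError("protein length must be positive")
    return spectral_count / protein_length


def saf_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate SAF for every protein (same shape as the count columns)."""
    cols = count_columns(table)
    if (table["length"] <= 0).any():
        raise ValueError("protein lengths must be positive")
    return pd.concat(
        [table[META_COLUMNS], table[cols].div(table["length"], axis=0)], axis=1
    )


def compute_bnsaf(
    table: pd.DataFrame,
    bait_id: str,
    strain: Optional[str] = None,
    fraction: Optional[str] = None,
) -> pd.DataFrame:
    """BNSAF per protein x replicate: SAF(protein) / SAF(bait).

    Replicates in which the bait has zero spectral counts are excluded
    with a warning (the ratio is undefined there).
    """
    saf = saf_table(table)
    cols = count_columns(table, strain=strain, fraction=fraction)
    bait_rows = saf[saf["protein_id"] == bait_id]
    if bait_rows.empty:
        raise ValueError(f"bait {bait_id!r} not found in table")
    bait = bait_rows.iloc[0]
    ratio_cols = {}
    for c in cols:
        if bait[c] <= 0:
            logger.warning("bait has zero counts in %s; replicate excluded", c)
            continue
        ratio_cols[c] = saf[c] / bait[c]
    return pd.concat([saf[META_COLUMNS], pd.DataFrame(ratio_cols)], axis=1)


def compare_bnsaf(
    table: pd.DataFrame,
    bait_id: str,
    fraction: str = "chromatin",
    wt_strain: str = "WT",
    mut_strain: str = "mut",
) -> pd.DataFrame:
    """Per-protein strain comparison of BNSAF in one fraction.

    Replicates are paired by index (to the minimum count, with a
    warning on mismatch).  Reports per-strain mean BNSAF and SE, the
    percent change 100*(1 - mut/wt), and the paired two-sided t-test
    p-value; rows carry the complex label for grouped reporting.
    """
    bn_wt = compute_bnsaf(table, bait_id, strain=wt_strain, fraction=fraction)
    bn_mut = compute_bnsaf(table, bait_id, strain=mut_strain, fraction=fraction)
    cols_wt = count_columns(bn_wt, strain=wt_strain, fraction=fraction)
    cols_mut = count_columns(bn_mut, strain=mut_strain, fraction=fraction)
    n = min(len(cols_wt), len(cols_mut))
    if len(cols_wt) != len(cols_mut):
        logger.warning("unpaired replicate counts (%d vs %d); pairing first %d",
                       len(cols_wt), len(cols_mut), n)
    if n < 2:
        raise ValueError("need at least 2 paired replicates per strain")
    cols_wt, cols_mut = cols_wt[:n], cols_mut[:n]
    rows = []
    for i in range(len(table)):
        wt = bn_wt.iloc[i][cols_wt].to_numpy(dtype=float)
        mut = bn_mut.iloc[i][cols_mut].to_numpy(dtype=float)
        mean_wt, mean_mut = float(wt.mean()), float(mut.mean())
        pct = 100.0 * (1.0 - mean_mut / mean_wt) if mean_wt > 0 else np.nan
        diff = mut - wt
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(stats.ttest_rel(mut, wt).pvalue)
        rows.append({
            "protein_id": table.iloc[i]["protein_id"],
            "complex": table.iloc[i]["complex"],
            "mean_bnsaf_wt": mean_wt,
            "mean_bnsaf_mut": mean_mut,
            "se_bnsaf_wt": float(wt.std(ddof=1) / np.sqrt(n)),
            "se_bnsaf_mut": float(mut.std(ddof=1) / np.sqrt(n)),
            "percent_change": pct,
            "p_value": p,
            "n_replicates": n,
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["complex", "protein_id"]).reset_index(drop=True)


def complex_summary(per_protein: pd.DataFrame) -> pd.DataFrame:
    """Per-complex aggregation of the per-protein BNSAF comparison."""
    return (
        per_protein.groupby("complex")
        .agg(
            n_proteins=("protein_id", "size"),
            mean_percent_change=("percent_change", "mean"),
            min_p=("p_value", "min"),
            max_p=("p_value", "max"),
        )
        .reset_index()
    )
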