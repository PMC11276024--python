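"""ChIP and transcription run-on (TRO) signal normalization.

ChIP occupancy of a termination factor at an amplicon is the factor's
IP/input ratio further normalized by the matched RNA polymerase II
IP/input ratio at the same region, so changes in polymerase density do
not masquerade as changes in factor recruitment:

    occupancy = (IP / input) / (PolII_IP / PolII_input)

TRO nascent-RNA signal is reported relative to the 18S rRNA control of
the same reaction.  Strain comparisons report the mean per strain, the
percent decline 100*(1 - mut/wt), a two-tailed Welch t-test p-value,
and the dispersion convention of each assay (SE for ChIP, SD for TRO;
both are emitted).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def chip_occupancy(ip_signal: float, input_signal: float,
                   polii_ip: float, polii_input: float) -> float:
    """RNAPII-normalized ChIP occupancy (ratio of IP/input ratios)."""
    for name, v in (("ip_signal", ip_signal), ("input_signal", input_signal),
                    ("polii_ip", polii_ip), ("polii_input", polii_input)):
        if v <= 0:
            raise ValueError(f"measurement rejected: {name} must be positive, got {v}")
    return (ip_signal / input_signal) / (polii_ip / polii_input)


def tro_signal(signal: float, control_18s: float) -> float:
    """Nascent-RNA signal relative to the 18S control."""
    if control_18s <= 0:
        raise ValueError(f"measurement rejected: control_18s must be positive, got {control_18s}")
    if signal < 0:
        raise ValueError("measurement rejected: signal must be non-negative")
    return signal / control_18s


@dataclass(frozen=True)
class OccupancyComparison:
    """Strain comparison of replicate-level normalized signals."""

    mean_wt: float
    mean_mut: float
    percent_change: float  # 100 * (1 - mut/wt); positive = decline in mutant
    p_value: float
    sd_wt: float
    sd_mut: float
    se_wt: float
    se_mut: float
    n_wt: int
    n_mut: int


def compare_occupancy(
    wt: Sequence[float], mut: Sequence[float]
) -> OccupancyComparison:
    """Two-tailed Welch comparison of normalized signals between strains."""
    wt = np.asarray(wt, dtype=float)
    mut = np.asarray(mut, dtype=float)
    if wt.size < 2 or mut.size < 2:
        raise ValueError("need at least 2 replicates per strain")
    mean_wt, mean_mut = float(wt.mean()), float(mut.mean())
    if np.array_equal(np.sort(wt), np.sort(mut)):
        p = 1.0
    else:
        p = float(stats.ttest_ind(mut, wt, equal_var=False).pvalue)
        if np.isnan(p):  # zero variance in both groups, unequal means
            p = 0.0
    pct = 100.0 * (1.0 - mean_mut / mean_wt) if mean_wt != 0 else np.nan
    return OccupancyComparison(
        mean_wt=mean_wt,
        mean_mut=mean_mut,
        percent_change=pct,
        p_value=p,
        sd_wt=float(wt.std(ddof=1)),
        sd_mut=float(mut.std(ddof=1)),
        se_wt=float(wt.std(ddof=1) / np.sqrt(wt.size)),
        se_mut=float(mut.std(ddof=1) / np.sqrt(mut.size)),
        n_wt=int(wt.size),
        n_mut=int(mut.size),
    )


# ---------------------------------------------------------------------------
# Table-level reports

CHIP_COLUMNS = ["factor", "gene_id", "amplicon", "strain", "replicate",
                "ip_signal", "input_signal", "polii_ip", "polii_input"]
TRO_COLUMNS = ["gene_id", "primer", "strain", "replicate", "signal", "control_18s"]


def load_chip_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CHIP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def load_tro_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def chip_report(table: pd.DataFrame, wt_strain: str = "WT",
                mut_strain: str = "mut") -> pd.DataFrame:
    """Per (factor, gene, amplicon) strain comparison of ChIP occupancy.

    Rows with non-positive signals are rejected (logged with reason),
    matching the validity contract of a qPCR quantity.
    """
    occ = []
    for _, r in table.iterrows():
        try:
            val = chip_occupancy(r["ip_signal"], r["input_signal"],
                                 r["polii_ip"], r["polii_input"])
        except ValueError as exc:
            logger.warning("rejected ChIP row (%s/%s/%s rep %s): %s",
                           r["factor"], r["gene_id"], r["amplicon"], r["replicate"], exc)
            continue
        occ.append({**r[["factor", "gene_id", "amplicon", "strain", "replicate"]],
                    "occupancy": val})
    occ_df = pd.DataFrame(occ)
    return _grouped_comparison(occ_df, ["factor", "gene_id", "amplicon"],
                               "occupancy", wt_strain, mut_strain)


def tro_report(table: pd.DataFrame, wt_strain: str = "WT",
               mut_strain: str = "mut") -> pd.DataFrame:
    """Per (gene, primer) strain comparison of 18S-normalized TRO signal."""
    vals = []
    for _, r in table.iterrows():
        try:
            v = tro_signal(r["signal"], r["control_18s"])
        except ValueError as exc:
            logger.warning("rejected TRO row (%s/%s rep %s): %s",
                           r["gene_id"], r["primer"], r["replicate"], exc)
            continue
        vals.append({**r[["gene_id", "primer", "strain", "replicate"]],
                     "normalized_signal": v})
    df = pd.DataFrame(vals)
    return _grouped_comparison(df, ["gene_id", "primer"], "normalized_signal",
                               wt_strain, mut_strain)


def _grouped_comparison(df: pd.DataFrame, keys: list[str], value: str,
                        wt_strain: str, mut_strain: str) -> pd.DataFrame:
    rows = []
    for key, sub in df.groupby(keys, sort=True):
        wt = sub.loc[sub["strain"] == wt_strain, value].to_numpy(dtype=float)
        mut = sub.loc[sub["strain"] == mut_strain, value].to_numpy(dtype=float)
        cmp = compare_occupancy(wt, mut)
        key = key if isinstance(key, tuple) else (key,)
        rows.append({**dict(zip(keys, key)), **cmp.__dict__})
    return pd.DataFrame(rows)
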