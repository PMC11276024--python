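"""Readthrough index (RTI) computation, strain comparison and summaries.

The readthrough index of a gene in one sample is the ratio of nascent
3'-end read counts in a window downstream of the poly(A) site to the
counts in a matched upstream window:

    RTI = reads(+51..+500) / reads(-500..-51)

Both windows are 450 nt wide; the 50 nt immediately flanking the
poly(A) site on either side are excluded so that imprecise cleavage-
site annotation and the pile-up at the site itself do not contaminate
either window.  Efficient termination gives RTI near 0; polymerases
reading through the poly(A) signal inflate the downstream window and
hence the RTI.

Per-gene strain comparison follows the replicate-level design: an RTI
per replicate, a per-strain mean over replicates, a one-sided Welch
t-test for an RTI increase in the mutant, and a defective call when the
log2 RTI ratio (mutant/WT) exceeds a fold-change threshold at p below
alpha.  Raw p-values drive the call (no multiplicity correction); a
Benjamini-Hochberg column is emitted for reference only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, GeneSet
from .signal import SignalTrack, cds_mean_density, window_count

logger = logging.getLogger(__name__)

#: Inclusive strand-aware offset windows around the poly(A) site (nt).
UPSTREAM_WINDOW = (-500, -51)
DOWNSTREAM_WINDOW = (51, 500)

#: Defaults of the defective-call criteria.
DEFAULT_LFC_THRESHOLD = 1.0  # log2(mutant/WT) > 1, i.e. at least 2-fold
DEFAULT_ALPHA = 0.05

#: Eligibility defaults.
MIN_DENSITY = 1.0  # reads per nt over the CDS
MIN_EXPRESSED_SAMPLES = 3
MIN_REPLICATES_PER_STRAIN = 2
MIN_TOTAL_SAMPLES = 5


@dataclass(frozen=True)
class RTIRecord:
    """One gene x one sample: window counts and readthrough index."""

    gene_id: str
    sample_id: str
    strain: str
    replicate: int
    upstream_count: int
    downstream_count: int
    rti: Optional[float]  # None when the upstream window is empty


@dataclass(frozen=True)
class GeneComparison:
    """Per-gene strain comparison of mean replicate RTIs."""

    gene_id: str
    mean_rti_wt: Optional[float]
    mean_rti_mut: Optional[float]
    log2_ratio: Optional[float]
    p_value: Optional[float]
    defective: Optional[bool]  # None = undetermined (eligibility not met)
    n_wt: int = 0
    n_mut: int = 0


def compute_rti(
    track: SignalTrack,
    gene: GeneModel,
    upstream_window: tuple[int, int] = UPSTREAM_WINDOW,
    downstream_window: tuple[int, int] = DOWNSTREAM_WINDOW,
    pseudocount: float = 0.0,
) -> RTIRecord:
    """Readthrough index of one gene in one sample.

    A zero upstream window yields a missing RTI (recorded, not an
    error); an optional pseudocount added to both windows is available
    but off by default.
    """
    up = window_count(track, gene, *upstream_window)
    down = window_count(track, gene, *downstream_window)
    denom = up + pseudocount
    rti = (down + pseudocount) / denom if denom > 0 else None
    return RTIRecord(
        gene_id=gene.gene_id,
        sample_id=track.sample_id,
        strain=track.strain,
        replicate=track.replicate,
        upstream_count=up,
        downstream_count=down,
        rti=rti,
    )


def compute_rti_table(
    tracks: Iterable[SignalTrack],
    genes: GeneSet,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """RTI of every gene in every sample, as a tidy table."""
    rows = [
        compute_rti(t, g, pseudocount=pseudocount).__dict__
        for t in tracks
        for g in genes
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "sample_id", "strain", "replicate",
            "upstream_count", "downstream_count", "rti",
        ],
    )


def expression_filter(
    tracks: Iterable[SignalTrack],
    genes: GeneSet,
    min_density: float = MIN_DENSITY,
    min_samples: int = MIN_EXPRESSED_SAMPLES,
) -> GeneSet:
    """Keep genes expressed at >= ``min_density`` reads/nt over the CDS in
    at least ``min_samples`` samples (pooled across strains)."""
    tracks = list(tracks)
    kept = []
    for g in genes:
        n_ok = sum(cds_mean_density(t, g) >= min_density for t in tracks)
        if n_ok >= min_samples:
            kept.append(g)
    logger.info(
        "expression filter (>=%.3g reads/nt in >=%d samples): %d -> %d genes",
        min_density, min_samples, len(genes), len(kept),
    )
    return GeneSet(kept, genome=genes.genome)


# ---------------------------------------------------------------------------
# Per-gene strain comparison


def compare_gene_rti(
    gene_id: str,
    wt_rtis: Sequence[Optional[float]],
    mut_rtis: Sequence[Optional[float]],
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    min_per_strain: int = MIN_REPLICATES_PER_STRAIN,
    min_total: int = MIN_TOTAL_SAMPLES,
) -> GeneComparison:
    """Compare one gene's replicate RTIs between strains.

    Eligibility requires non-missing RTIs in at least ``min_per_strain``
    replicates of each strain and ``min_total`` overall; otherwise the
    gene is emitted with ``defective=None`` (undetermined) and no
    p-value.  The test is one-sided Welch (mutant mean greater).
    """
    wt = np.asarray([x for x in wt_rtis if x is not None and not math.isnan(x)], dtype=float)
    mut = np.asarray([x for x in mut_rtis if x is not None and not math.isnan(x)], dtype=float)
    mean_wt = float(wt.mean()) if wt.size else None
    mean_mut = float(mut.mean()) if mut.size else None
    if wt.size < min_per_strain or mut.size < min_per_strain or wt.size + mut.size < min_total:
        return GeneComparison(gene_id, mean_wt, mean_mut, None, None, None,
                              n_wt=wt.size, n_mut=mut.size)
    log2_ratio = _log2_ratio(mean_mut, mean_wt)
    res = stats.ttest_ind(mut, wt, equal_var=False, alternative="greater")
    p = float(res.pvalue)
    if math.isnan(p):  # zero variance in both strains with equal means
        p = 0.5 if mean_mut == mean_wt else (0.0 if mean_mut > mean_wt else 1.0)
    defective = bool(log2_ratio is not None and log2_ratio > lfc_threshold and p < alpha)
    return GeneComparison(gene_id, mean_wt, mean_mut, log2_ratio, p, defective,
                          n_wt=wt.size, n_mut=mut.size)


def _log2_ratio(mean_mut: Optional[float], mean_wt: Optional[float]) -> Optional[float]:
    if mean_mut is None or mean_wt is None:
        return None
    if mean_wt == 0:
        return math.inf if mean_mut > 0 else None
    if mean_mut == 0:
        return -math.inf
    return math.log2(mean_mut / mean_wt)


def compare_strains(
    rti_table: pd.DataFrame,
    wt_strain: str = "WT",
    mut_strain: str = "mut",
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    min_per_strain: int = MIN_REPLICATES_PER_STRAIN,
    min_total: int = MIN_TOTAL_SAMPLES,
) -> pd.DataFrame:
    """Per-gene comparison table from a tidy RTI table.

    Adds a Benjamini-Hochberg ``p_adj`` column for reference; the
    defective call uses the raw p-value.
    """
    rows = []
    for gene_id, sub in rti_table.groupby("gene_id", sort=True):
        wt = sub.loc[sub["strain"] == wt_strain, "rti"].tolist()
        mut = sub.loc[sub["strain"] == mut_strain, "rti"].tolist()
        wt = [None if pd.isna(x) else float(x) for x in wt]
        mut = [None if pd.isna(x) else float(x) for x in mut]
        rows.append(
            compare_gene_rti(
                gene_id, wt, mut,
                lfc_threshold=lfc_threshold, alpha=alpha,
                min_per_strain=min_per_strain, min_total=min_total,
            ).__dict__
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "mean_rti_wt", "mean_rti_mut", "log2_ratio",
                 "p_value", "defective", "n_wt", "n_mut"],
    )
    df["p_adj"] = _bh_adjust(df["p_value"])
    return df


def _bh_adjust(p: pd.Series) -> pd.Series:
    from statsmodels.stats.multitest import multipletests

    out = pd.Series(np.nan, index=p.index)
    mask = p.notna()
    if mask.any():
        out.loc[mask] = multipletests(p[mask].to_numpy(), method="fdr_bh")[1]
    return out


def defective_fraction(comparisons: pd.DataFrame) -> tuple[float, int, int]:
    """(fraction, n_defective, n_determined) over genes with a determined call."""
    determined = comparisons[comparisons["defective"].notna()]
    n = len(determined)
    if n == 0:
        raise ValueError("no genes with a determined defective status")
    n_def = int(determined["defective"].sum())
    return n_def / n, n_def, n


# ---------------------------------------------------------------------------
# Strain-level summaries


@dataclass(frozen=True)
class StrainSummary:
    """Gene-level RTI distribution summary for one strain."""

    strain: str
    mean_rti: float
    median_rti: float
    q1: float
    q3: float
    n_genes: int
    mean_comparison_p: Optional[float] = None  # paired two-sided t across genes
    median_comparison_p: Optional[float] = None  # Welch two-sided across genes


def strain_summaries(
    rti_table: pd.DataFrame,
    wt_strain: str = "WT",
    mut_strain: str = "mut",
) -> dict[str, StrainSummary]:
    """Per-strain mean/median/quartile summaries of per-gene mean RTIs.

    The mean comparison is a paired two-sided t-test across genes
    (genes pair the strains); the distribution comparison is an
    unpaired two-sided Welch t-test across genes.  With a single strain
    present, that strain's summary is returned without p-values.
    """
    per_gene = (
        rti_table.dropna(subset=["rti"])
        .groupby(["strain", "gene_id"])["rti"]
        .mean()
        .rename("mean_rti")
        .reset_index()
    )
    strains = sorted(per_gene["strain"].unique())
    values = {s: per_gene.loc[per_gene["strain"] == s].set_index("gene_id")["mean_rti"]
              for s in strains}
    for s, v in values.items():
        if len(v) < 2:
            raise ValueError(f"strain {s}: need at least 2 genes for a summary")
    mean_p = median_p = None
    if wt_strain in values and mut_strain in values:
        common = values[wt_strain].index.intersection(values[mut_strain].index)
        if len(common) >= 2:
            a = values[mut_strain].loc[common].to_numpy()
            b = values[wt_strain].loc[common].to_numpy()
            if np.allclose(a, b):
                mean_p = 1.0
            else:
                mean_p = float(stats.ttest_rel(a, b).pvalue)
        full_a = values[mut_strain].to_numpy()
        full_b = values[wt_strain].to_numpy()
        if np.array_equal(np.sort(full_a), np.sort(full_b)):
            median_p = 1.0
        else:
            median_p = float(stats.ttest_ind(full_a, full_b, equal_var=False).pvalue)
    out = {}
    for s in strains:
        v = values[s].to_numpy()
        out[s] = StrainSummary(
            strain=s,
            mean_rti=float(v.mean()),
            median_rti=float(np.median(v)),
            q1=float(np.percentile(v, 25)),
            q3=float(np.percentile(v, 75)),
            n_genes=int(v.size),
            mean_comparison_p=mean_p,
            median_comparison_p=median_p,
        )
    return out


# ---------------------------------------------------------------------------
# Feature association


def associate_rti(values: pd.Series, feature: pd.Series) -> dict:
    """Association between per-gene RTI statistics and a gene feature.

    ``values`` holds a per-gene numeric statistic (e.g. mutant mean RTI
    or log2 RTI ratio) indexed by gene_id; ``feature`` a per-gene
    feature on the same (or overlapping) index.

    Categorical feature (two classes): per-class summaries plus a
    two-sided Welch p.  Numeric feature: Spearman rank correlation and
    p.  Degenerate inputs (one class, constant feature, too few genes)
    raise ``ValueError``.
    """
    common = values.index.intersection(feature.index)
    v = values.loc[common].astype(float)
    f = feature.loc[common]
    mask = v.notna() & f.notna()
    v, f = v[mask], f[mask]
    if pd.api.types.is_numeric_dtype(f):
        if len(v) < 3:
            raise ValueError("numeric association needs at least 3 genes")
        if f.nunique() < 2:
            raise ValueError("feature is constant; association undefined")
        rho, p = stats.spearmanr(f.to_numpy(), v.to_numpy())
        return {"kind": "numeric", "rho": float(rho), "p_value": float(p), "n": int(len(v))}
    classes = sorted(f.astype(str).unique())
    if len(classes) < 2:
        raise ValueError("feature has a single class; association undefined")
    if len(classes) > 2:
        raise ValueError("categorical association supports exactly two classes")
    groups = {c: v[f.astype(str) == c].to_numpy() for c in classes}
    for c, g in groups.items():
        if g.size < 2:
            raise ValueError(f"class {c}: need at least 2 genes")
    a, b = groups[classes[0]], groups[classes[1]]
    if np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return {
        "kind": "categorical",
        "classes": {
            c: {"n": int(g.size), "mean": float(g.mean()), "median": float(np.median(g))}
            for c, g in groups.items()
        },
        "p_value": p,
    }
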