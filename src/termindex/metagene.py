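"""Metagene profiles around the poly(A) site and the readthrough heatmap.

Each gene's per-nucleotide 3'-end signal over offsets -200..+200 from
the poly(A) site is normalized to that gene's mean CDS read density, so
highly expressed genes do not dominate the average.  Per-gene profiles
are first averaged across replicates, then averaged across genes with a
standard error band.

The heatmap matrix holds, per gene x replicate x offset, the difference
between the CDS-normalized mutant and wild-type densities; rows are
ordered by increasing readthrough phenotype (per-gene log2 RTI ratio),
so termination-defective genes collect at the bottom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GeneSet
from .signal import SignalTrack, cds_mean_density

logger = logging.getLogger(__name__)

DEFAULT_HALF_WINDOW = 200


def _offset_counts(track: SignalTrack, gene: GeneModel, half_window: int) -> np.ndarray:
    """Counts at offsets -hw..+hw in transcription orientation."""
    lo = gene.offset_to_genomic(-half_window)
    hi = gene.offset_to_genomic(half_window)
    arr = track.counts(gene.chrom, gene.strand, min(lo, hi), max(lo, hi)).astype(float)
    return arr if gene.strand == "+" else arr[::-1]


def _gene_profile(
    tracks: Sequence[SignalTrack], gene: GeneModel, half_window: int
) -> Optional[np.ndarray]:
    """Replicate-averaged CDS-normalized profile for one gene.

    Returns ``None`` (gene excluded, warned) when any replicate has
    zero CDS density — the normalization is undefined there.
    """
    per_rep = []
    for t in tracks:
        dens = cds_mean_density(t, gene)
        if dens <= 0:
            logger.warning("%s: zero CDS density in %s; gene excluded", gene.gene_id, t.sample_id)
            return None
        per_rep.append(_offset_counts(t, gene, half_window) / dens)
    return np.mean(per_rep, axis=0)


@dataclass
class MetageneProfile:
    """Per-offset mean +/- SE of CDS-normalized density for one strain."""

    strain: str
    offsets: np.ndarray  # -hw..+hw, length 2*hw + 1
    mean: np.ndarray
    se: np.ndarray
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean, "se": self.se}
        ).assign(strain=self.strain, n_genes=self.n_genes)


def metagene_profile(
    tracks: Sequence[SignalTrack],
    genes: GeneSet,
    half_window: int = DEFAULT_HALF_WINDOW,
    strain: Optional[str] = None,
) -> MetageneProfile:
    """Average CDS-normalized 3'-end density around the poly(A) site.

    ``tracks`` are the replicates of one strain.  Per gene, the profile
    is normalized by each replicate's CDS mean density and averaged
    across replicates; the returned mean and standard error are taken
    across genes at each offset.
    """
    if not tracks:
        raise ValueError("at least one track required")
    strain = strain if strain is not None else tracks[0].strain
    profiles = []
    for g in genes:
        p = _gene_profile(tracks, g, half_window)
        if p is not None:
            profiles.append(p)
    if not profiles:
        raise ValueError("no gene with positive CDS density in every replicate")
    mat = np.vstack(profiles)
    mean = mat.mean(axis=0)
    if mat.shape[0] > 1:
        se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    else:
        se = np.zeros(mat.shape[1])
    offsets = np.arange(-half_window, half_window + 1)
    return MetageneProfile(strain=strain, offsets=offsets, mean=mean, se=se,
                           n_genes=mat.shape[0])


def readthrough_heatmap(
    wt_tracks: Sequence[SignalTrack],
    mut_tracks: Sequence[SignalTrack],
    genes: GeneSet,
    comparisons: pd.DataFrame,
    half_window: int = DEFAULT_HALF_WINDOW,
) -> pd.DataFrame:
    """Gene x (replicate x offset) matrix of mutant - WT normalized density.

    Replicates are paired across strains by replicate index (up to the
    minimum count, with a warning on mismatch).  Rows are ordered by
    ascending per-gene log2 RTI ratio taken from ``comparisons``; the
    ordering key is kept as the first column.
    """
    n_rep = min(len(wt_tracks), len(mut_tracks))
    if len(wt_tracks) != len(mut_tracks):
        logger.warning(
            "unmatched replicate counts (%d WT, %d mutant); pairing first %d",
            len(wt_tracks), len(mut_tracks), n_rep,
        )
    wt_tracks = sorted(wt_tracks, key=lambda t: t.replicate)[:n_rep]
    mut_tracks = sorted(mut_tracks, key=lambda t: t.replicate)[:n_rep]
    order = comparisons.set_index("gene_id")["log2_ratio"]
    offsets = np.arange(-half_window, half_window + 1)
    rows = {}
    keys = {}
    for g in genes:
        if g.gene_id not in order.index:
            continue
        vals = []
        ok = True
        for wt_t, mut_t in zip(wt_tracks, mut_tracks):
            dens_wt = cds_mean_density(wt_t, g)
            dens_mut = cds_mean_density(mut_t, g)
            if dens_wt <= 0 or dens_mut <= 0:
                logger.warning("%s: zero CDS density; excluded from heatmap", g.gene_id)
                ok = False
                break
            vals.append(
                _offset_counts(mut_t, g, half_window) / dens_mut
                - _offset_counts(wt_t, g, half_window) / dens_wt
            )
        if ok:
            rows[g.gene_id] = np.concatenate(vals)
            keys[g.gene_id] = order.loc[g.gene_id]
    columns = [
        f"rep{r + 1}_off{o:+d}" for r in range(n_rep) for o in offsets
    ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    df.insert(0, "log2_ratio", pd.Series(keys))
    df.index.name = "gene_id"
    # ascending readthrough phenotype, NaN/inf-stable
    return df.sort_values("log2_ratio", kind="mergesort")


# ---------------------------------------------------------------------------
# Rendering (optional figures)


def plot_metagene(profiles: Sequence[MetageneProfile], path: str) -> None:
    """Line plot with SE bands, one line per strain."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        ax.plot(p.offsets, p.mean, label=f"{p.strain} (n={p.n_genes})")
        ax.fill_between(p.offsets, p.mean - p.se, p.mean + p.se, alpha=0.3)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("offset from poly(A) site (nt)")
    ax.set_ylabel("CDS-normalized 3'-end density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix: pd.DataFrame, path: str) -> None:
    """Diverging-scale heatmap of the mutant - WT density matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.drop(columns=["log2_ratio"]).to_numpy(dtype=float)
    lim = np.nanpercentile(np.abs(data), 99) or 1.0
    fig, ax = plt.subplots(figsize=(7, 5))
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim,
                   interpolation="nearest")
    ax.set_xlabel("replicate x offset")
    ax.set_ylabel("genes (increasing readthrough phenotype)")
    fig.colorbar(im, ax=ax, label="mutant - WT normalized density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
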