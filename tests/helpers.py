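"""Independent textbook-formula oracles and small fixture builders.

The t-test oracles are coded directly from the definitional formulas
(statistic, Welch-Satterthwaite degrees of freedom, Student-t tail) so
they stay independent of the scipy code paths used by the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import t as t_dist

from termindex import GeneModel, SignalTrack


def welch_t_oracle(a, b, alternative: str = "two-sided") -> float:
    """Unequal-variance t-test p-value for mean(a) vs mean(b).

    ``alternative='greater'`` tests mean(a) > mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    if alternative == "greater":
        return float(t_dist.sf(t, df))
    if alternative == "two-sided":
        return float(2.0 * t_dist.sf(abs(t), df))
    raise ValueError(alternative)


def paired_t_oracle(a, b) -> float:
    """Two-sided paired t-test p-value (differences a - b)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    return float(2.0 * t_dist.sf(abs(t), n - 1))


def brute_force_window_count(track: SignalTrack, gene: GeneModel,
                             from_offset: int, to_offset: int) -> int:
    """Explicit per-offset loop over strand-aware genomic positions."""
    total = 0
    for off in range(from_offset, to_offset + 1):
        if gene.strand == "+":
            pos = gene.polya_site + off
        else:
            pos = gene.polya_site - off
        if pos >= 1:
            total += int(track.counts(gene.chrom, gene.strand, pos, pos)[0])
    return total


def make_gene(gene_id="gene1", chrom="chrI", strand="+", polya=2000,
              body=1500, promoter_class=None) -> GeneModel:
    """Gene whose body (CDS = transcript) ends at the poly(A) site."""
    if strand == "+":
        return GeneModel(gene_id, chrom, strand, cds_start=polya - body + 1,
                         cds_end=polya, polya_site=polya,
                         promoter_class=promoter_class,
                         tx_start=polya - body + 1, tx_end=polya)
    return GeneModel(gene_id, chrom, strand, cds_start=polya,
                     cds_end=polya + body - 1, polya_site=polya,
                     promoter_class=promoter_class,
                     tx_start=polya, tx_end=polya + body - 1)


def random_sparse_track(rng: np.random.Generator, chrom="chrI", strand="+",
                        span=4000, n_positions=200, max_count=5,
                        sample_id="s1", strain="WT", replicate=1) -> SignalTrack:
    track = SignalTrack(sample_id=sample_id, strain=strain, replicate=replicate)
    positions = rng.integers(1, span + 1, size=n_positions)
    counts = rng.integers(1, max_count + 1, size=n_positions)
    for p, c in zip(positions, counts):
        track.add(chrom, strand, int(p), int(c))
    return track
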