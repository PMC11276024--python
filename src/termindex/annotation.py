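"""Gene-model I/O and structural gene filters.

Gene models anchor every downstream window on the annotated poly(A)
site (the mRNA 3' cleavage position).  Coordinates are 1-based
inclusive throughout, following the GFF3 convention; strand-aware
offsets place position 0 at the poly(A) nucleotide with positive
offsets running downstream in the direction of transcription.

Two structural filters protect the readthrough windows from signal
bleeding in from neighbouring transcription units in a compact genome:
a minimum distance from the poly(A) site to the next gene downstream on
the same strand, and a minimum mRNA length.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns of the tabular gene format (order matters; extra columns tolerated).
GENE_TSV_COLUMNS = [
    "gene_id",
    "chrom",
    "strand",
    "cds_start",
    "cds_end",
    "polya_site",
    "promoter_class",
]

_OPTIONAL_TSV_COLUMNS = ["tx_start", "tx_end"]


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be parsed."""


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene anchored at its poly(A) site.

    Parameters
    ----------
    gene_id : str
        Unique gene identifier.
    chrom : str
        Chromosome name.
    strand : str
        ``"+"`` or ``"-"``.
    cds_start, cds_end : int
        1-based inclusive CDS bounds (``cds_start <= cds_end`` regardless
        of strand).
    polya_site : int
        1-based genomic coordinate of the annotated mRNA 3' end, the
        reference point (offset 0) for every window.
    promoter_class : str, optional
        ``"TATA"``, ``"TATA-less"`` or ``None`` (unknown); accepted as
        annotation input, never inferred.
    tx_start, tx_end : int, optional
        Annotated transcript bounds (including UTRs) when the annotation
        provides them; used for mRNA length, with CDS fallback.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    polya_site: int
    promoter_class: Optional[str] = None
    tx_start: Optional[int] = None
    tx_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.cds_start > self.cds_end:
            raise ValueError(f"{self.gene_id}: cds_start > cds_end")
        if min(self.cds_start, self.polya_site) < 1:
            raise ValueError(f"{self.gene_id}: coordinates must be positive")
        # The poly(A) site sits downstream of the CDS in the strand sense.
        if self.strand == "+" and self.polya_site < self.cds_end:
            raise ValueError(f"{self.gene_id}: polya_site upstream of CDS end on + strand")
        if self.strand == "-" and self.polya_site > self.cds_start:
            raise ValueError(f"{self.gene_id}: polya_site upstream of CDS end on - strand")

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def mrna_length(self) -> int:
        """Strand-aware span from transcript start to the poly(A) site.

        Falls back to the CDS length when transcript bounds are absent
        (annotations without UTRs).
        """
        if self.strand == "+":
            if self.tx_start is not None:
                return self.polya_site - self.tx_start + 1
        else:
            if self.tx_end is not None:
                return self.tx_end - self.polya_site + 1
        return self.cds_length

    @property
    def span(self) -> tuple[int, int]:
        """Leftmost/rightmost genomic coordinate covered by the gene."""
        coords = [self.cds_start, self.cds_end, self.polya_site]
        if self.tx_start is not None:
            coords.append(self.tx_start)
        if self.tx_end is not None:
            coords.append(self.tx_end)
        return min(coords), max(coords)

    def offset_to_genomic(self, offset: int) -> int:
        """Map a strand-aware offset from the poly(A) site to a genomic position."""
        return self.polya_site + offset if self.strand == "+" else self.polya_site - offset


@dataclass
class GeneSet:
    """Ordered collection of :class:`GeneModel` with unique ids."""

    genes: list[GeneModel] = field(default_factory=list)
    genome: str = ""

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene_ids: {dup}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def subset(self, gene_ids: Iterable[str]) -> "GeneSet":
        keep = set(gene_ids)
        return GeneSet([g for g in self.genes if g.gene_id in keep], genome=self.genome)

    def sorted(self) -> "GeneSet":
        return GeneSet(
            sorted(self.genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)),
            genome=self.genome,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "cds_start": g.cds_start,
                    "cds_end": g.cds_end,
                    "polya_site": g.polya_site,
                    "promoter_class": g.promoter_class if g.promoter_class else "",
                    "tx_start": g.tx_start if g.tx_start is not None else "",
                    "tx_end": g.tx_end if g.tx_end is not None else "",
                }
            )
        return pd.DataFrame(rows, columns=GENE_TSV_COLUMNS + _OPTIONAL_TSV_COLUMNS)

    def to_tsv(self, path: str | os.PathLike) -> None:
        """Write the tabular gene format, deterministically ordered."""
        self.sorted().to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Loading


def load_gene_models(path: str | os.PathLike, genome: str = "") -> GeneSet:
    """Load gene models from GFF3 or the tabular gene format.

    The poly(A) site is taken from the annotated mRNA 3' end when an
    mRNA feature is present; otherwise the strand-aware CDS end is used
    (and the fallback is logged).  Records without a strand are rejected
    with a warning tally.
    """
    path = os.fspath(path)
    with open(path) as fh:
        head = fh.read(2048)
    if head.startswith("##gff-version") or path.endswith((".gff", ".gff3")):
        return _load_gff3(path, genome=genome)
    return _load_gene_tsv(path, genome=genome)


def _load_gene_tsv(path: str, genome: str = "") -> GeneSet:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return GeneSet([], genome=genome)
    missing = [c for c in GENE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationParseError(f"{path}: missing columns {missing}")
    genes: list[GeneModel] = []
    rejected = 0
    for i, row in df.iterrows():
        line_no = i + 2  # 1-based, after header
        strand = str(row["strand"]).strip()
        if strand not in ("+", "-"):
            rejected += 1
            continue
        try:
            genes.append(
                GeneModel(
                    gene_id=str(row["gene_id"]),
                    chrom=str(row["chrom"]),
                    strand=strand,
                    cds_start=int(row["cds_start"]),
                    cds_end=int(row["cds_end"]),
                    polya_site=int(row["polya_site"]),
                    promoter_class=_none_if_blank(row.get("promoter_class")),
                    tx_start=_int_or_none(row.get("tx_start")),
                    tx_end=_int_or_none(row.get("tx_end")),
                )
            )
        except (ValueError, TypeError) as exc:
            raise AnnotationParseError(f"{path}, line {line_no}: {exc}") from exc
    if rejected:
        logger.warning("%s: rejected %d records with missing strand", path, rejected)
    return GeneSet(genes, genome=genome)


def _load_gff3(path: str, genome: str = "") -> GeneSet:
    _validate_gff3_lines(path)
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return GeneSet([], genome=genome)
    genes: list[GeneModel] = []
    rejected = 0
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.strand not in ("+", "-"):
            rejected += 1
            continue
        mrnas = list(db.children(feat, featuretype="mRNA"))
        cds = list(db.children(feat, featuretype="CDS"))
        if cds:
            cds_start = min(c.start for c in cds)
            cds_end = max(c.end for c in cds)
        else:
            cds_start, cds_end = feat.start, feat.end
        tx_start = tx_end = None
        if mrnas:
            tx_start = min(m.start for m in mrnas)
            tx_end = max(m.end for m in mrnas)
            polya = tx_end if feat.strand == "+" else tx_start
        else:
            polya = cds_end if feat.strand == "+" else cds_start
            logger.info("%s: no mRNA feature, poly(A) site from CDS end", feat.id)
        promoter = feat.attributes.get("promoter_class", [None])[0]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                strand=feat.strand,
                cds_start=cds_start,
                cds_end=cds_end,
                polya_site=polya,
                promoter_class=promoter,
                tx_start=tx_start,
                tx_end=tx_end,
            )
        )
    if rejected:
        logger.warning("%s: rejected %d genes with missing strand", path, rejected)
    return GeneSet(genes, genome=genome)


def _validate_gff3_lines(path: str) -> None:
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise AnnotationParseError(
                    f"{path}, line {line_no}: expected 9 tab-separated fields"
                )


def _none_if_blank(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    s = str(v).strip()
    return s or None


def _int_or_none(v) -> Optional[int]:
    s = _none_if_blank(v)
    return int(float(s)) if s is not None else None


# ---------------------------------------------------------------------------
# Structural filters


def write_gff3(genes: GeneSet, path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (gene/mRNA/CDS features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.sorted():
            lo, hi = g.span
            tx_lo = g.tx_start if g.tx_start is not None else min(g.cds_start, g.polya_site)
            tx_hi = g.tx_end if g.tx_end is not None else max(g.cds_end, g.polya_site)
            attrs = f"ID={g.gene_id}"
            if g.promoter_class:
                attrs += f";promoter_class={g.promoter_class}"
            fh.write(f"{g.chrom}\tsim\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\t{attrs}\n")
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{tx_lo}\t{tx_hi}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tsim\tCDS\t{g.cds_start}\t{g.cds_end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
            )


def downstream_neighbor_distance(gene: GeneModel, genes: GeneSet) -> Optional[int]:
    """Distance (nt) from the poly(A) site to the nearest coordinate of the
    next same-strand gene downstream; ``None`` when no such neighbor exists.

    Downstream is the strand sense of transcription.  A same-strand gene
    overlapping the poly(A) site yields distance 0.
    """
    best: Optional[int] = None
    for other in genes:
        if other.gene_id == gene.gene_id:
            continue
        if other.chrom != gene.chrom or other.strand != gene.strand:
            continue
        lo, hi = other.span
        if gene.strand == "+":
            if hi <= gene.polya_site:
                continue  # entirely upstream
            d = max(lo - gene.polya_site, 0)
        else:
            if lo >= gene.polya_site:
                continue
            d = max(gene.polya_site - hi, 0)
        if best is None or d < best:
            best = d
    return best


def filter_by_neighbor_distance(genes: GeneSet, min_dist: int = 500) -> GeneSet:
    """Keep genes whose poly(A) site is >= ``min_dist`` nt from the next
    same-strand gene downstream (genes with no such neighbor are kept).

    Only the downstream side is checked: the readthrough windows extend
    only downstream of the poly(A) site.
    """
    kept = [
        g
        for g in genes
        if (d := downstream_neighbor_distance(g, genes)) is None or d >= min_dist
    ]
    logger.info("neighbor-distance filter (>=%d nt): %d -> %d genes", min_dist, len(genes), len(kept))
    return GeneSet(kept, genome=genes.genome)


def filter_by_length(genes: GeneSet, min_len: int = 500) -> GeneSet:
    """Keep genes with mRNA length >= ``min_len`` nt (boundary inclusive)."""
    kept = [g for g in genes if g.mrna_length >= min_len]
    logger.info("length filter (>=%d nt): %d -> %d genes", min_len, len(genes), len(kept))
    return GeneSet(kept, genome=genes.genome)
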