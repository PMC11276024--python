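"""Strand-specific 3'-end signal tracks and windowed counting.

A :class:`SignalTrack` stores, per chromosome and strand, the number of
nascent-transcript 3' ends mapped to each nucleotide.  Run-on
sequencing reads report the position of the engaged polymerase via the
3'-most aligned base, so 3'-end counting (not full read coverage) is
the stored signal; a coverage mode exists for exploratory use but all
readthrough statistics operate on 3'-end counts.

Windows are expressed as strand-aware offsets from a gene's poly(A)
site: offset 0 is the poly(A) nucleotide and positive offsets run
downstream in the direction of transcription.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import GeneModel

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass
class SignalTrack:
    """Per-nucleotide 3'-end read counts for one sample.

    Counts are stored in dense per-(chromosome, strand) arrays indexed
    by 1-based position (array index ``pos - 1``); positions beyond an
    array are count 0.
    """

    sample_id: str
    strain: str = ""
    replicate: int = 0
    _data: dict[tuple[str, str], np.ndarray] = field(default_factory=dict, repr=False)

    def _array(self, chrom: str, strand: str, min_size: int = 0) -> np.ndarray:
        key = (chrom, strand)
        arr = self._data.get(key)
        if arr is None:
            arr = np.zeros(max(min_size, 1024), dtype=np.int64)
            self._data[key] = arr
        elif arr.size < min_size:
            new = np.zeros(max(min_size, 2 * arr.size), dtype=np.int64)
            new[: arr.size] = arr
            self._data[key] = new
            arr = new
        return self._data[key]

    def add(self, chrom: str, strand: str, pos: int, count: int = 1) -> None:
        """Add ``count`` reads at 1-based position ``pos``."""
        self._array(chrom, strand, pos)[pos - 1] += count

    def add_range(self, chrom: str, strand: str, start: int, values: np.ndarray) -> None:
        """Add an array of counts at 1-based positions ``start..start+len-1``."""
        end = start + len(values) - 1
        self._array(chrom, strand, end)[start - 1 : end] += values

    def set_interval(self, chrom: str, strand: str, start: int, end: int, count: int) -> None:
        """Set counts over the 1-based inclusive range ``start..end``."""
        self._array(chrom, strand, end)[start - 1 : end] = count

    def counts(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Counts over the 1-based inclusive range, zero-padded at bounds.

        ``start`` may be < 1 and ``end`` may exceed the stored extent;
        out-of-bounds positions contribute 0.
        """
        if end < start:
            raise ValueError("end < start")
        n = end - start + 1
        out = np.zeros(n, dtype=np.int64)
        arr = self._data.get((chrom, strand))
        if arr is None:
            return out
        lo = max(start, 1)
        hi = min(end, arr.size)
        if hi >= lo:
            out[lo - start : hi - start + 1] = arr[lo - 1 : hi]
        return out

    def window_sum(self, chrom: str, strand: str, start: int, end: int) -> int:
        return int(self.counts(chrom, strand, start, end).sum())

    def total(self) -> int:
        return int(sum(a.sum() for a in self._data.values()))

    def scaled(self, factor: int) -> "SignalTrack":
        """Track with every count multiplied by a positive integer factor."""
        if factor <= 0:
            raise ValueError("factor must be positive")
        t = SignalTrack(self.sample_id, self.strain, self.replicate)
        t._data = {k: a * factor for k, a in self._data.items()}
        return t

    def chrom_strand_keys(self) -> list[tuple[str, str]]:
        return sorted(self._data)


# ---------------------------------------------------------------------------
# bedGraph I/O (UCSC standard: 0-based half-open intervals)


def load_track(
    plus_file: str | os.PathLike,
    minus_file: str | os.PathLike,
    sample_id: str = "",
    strain: str = "",
    replicate: int = 0,
) -> SignalTrack:
    """Load a strand pair of bedGraph files into a :class:`SignalTrack`.

    Minus-strand values may be deposited as negative magnitudes (a
    common dialect); the sign is stripped.  Non-integer values are
    rounded with a warning tally; overlapping intervals with
    conflicting values raise ``ValueError``.
    """
    track = SignalTrack(sample_id=sample_id or os.path.basename(os.fspath(plus_file)),
                        strain=strain, replicate=replicate)
    for path, strand in ((plus_file, "+"), (minus_file, "-")):
        _read_bedgraph_into(track, os.fspath(path), strand)
    return track


def _read_bedgraph_into(track: SignalTrack, path: str, strand: str) -> None:
    # per-chromosome mask of already-assigned values (-1 = unassigned),
    # used to flag overlapping intervals with conflicting values
    assigned: dict[str, np.ndarray] = {}
    n_records = 0
    n_rounded = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}, line {line_no}: expected 4 bedGraph fields")
            chrom, start0, end0, raw = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            value = abs(raw)
            count = int(round(value))
            if count != value:
                n_rounded += 1
            # bedGraph is 0-based half-open; store 1-based inclusive.
            start1, end1 = start0 + 1, end0
            if end1 < start1:
                raise ValueError(f"{path}, line {line_no}: empty or inverted interval")
            mask = assigned.get(chrom)
            if mask is None or mask.size < end1:
                new = np.full(max(end1, 1024, 0 if mask is None else 2 * mask.size), -1,
                              dtype=np.int64)
                if mask is not None:
                    new[: mask.size] = mask
                assigned[chrom] = mask = new
            seen = mask[start1 - 1 : end1]
            if np.any((seen >= 0) & (seen != count)):
                raise ValueError(
                    f"{path}, line {line_no}: overlapping intervals with conflicting values"
                )
            mask[start1 - 1 : end1] = count
            if count:
                track.set_interval(chrom, strand, start1, end1, count)
            n_records += 1
    if n_rounded:
        logger.warning("%s: rounded %d non-integer values", path, n_rounded)
    logger.info("%s: loaded %d bedGraph records on %s strand", path, n_records, strand)


def write_bedgraph(track: SignalTrack, plus_file: str | os.PathLike,
                   minus_file: str | os.PathLike) -> None:
    """Write the track as a bedGraph strand pair (run-length encoded,
    positive values on both strands)."""
    for path, strand in ((plus_file, "+"), (minus_file, "-")):
        with open(path, "w") as fh:
            for (chrom, s), arr in sorted(track._data.items()):
                if s != strand:
                    continue
                _write_rle(fh, chrom, arr)


def _write_rle(fh, chrom: str, arr: np.ndarray) -> None:
    (nz,) = np.nonzero(arr)
    if nz.size == 0:
        return
    end = int(nz[-1]) + 1
    a = arr[:end]
    change = np.nonzero(np.diff(a))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [end]))
    for s, e in zip(starts, ends):
        v = int(a[s])
        if v:
            # array index s is 0-based == bedGraph start; e is half-open end
            fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# Sample sheets


@dataclass
class SampleSheet:
    """Sample table mapping files to strain x replicate."""

    rows: pd.DataFrame

    REQUIRED = ["sample_id", "strain", "replicate", "plus_file", "minus_file"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns {missing}")
        pairs = list(zip(self.rows["strain"], self.rows["replicate"]))
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (strain, replicate) pairs in sample sheet")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "strain": str})
        return cls(df)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def load_tracks(self, base_dir: str | os.PathLike = ".") -> list[SignalTrack]:
        base = os.fspath(base_dir)
        tracks = []
        for _, r in self.rows.iterrows():
            tracks.append(
                load_track(
                    os.path.join(base, r["plus_file"]),
                    os.path.join(base, r["minus_file"]),
                    sample_id=str(r["sample_id"]),
                    strain=str(r["strain"]),
                    replicate=int(r["replicate"]),
                )
            )
        return tracks


# ---------------------------------------------------------------------------
# BAM input


def track_from_alignments(
    bam_path: str | os.PathLike,
    sample_id: str = "",
    strain: str = "",
    replicate: int = 0,
    protocol: str = "forward",
    exclude_duplicates: bool = True,
    mode: str = "3prime",
) -> SignalTrack:
    """Build a signal track from an indexed BAM.

    In the default ``"3prime"`` mode each primary, mapped (and by
    default non-duplicate) alignment contributes one count at its
    strand-aware 3'-most aligned position; ``"coverage"`` mode counts
    every aligned position instead (exploratory only — the readthrough
    statistics are defined on 3'-end counts).  ``protocol`` declares
    whether the read strand equals the transcript strand (``"forward"``)
    or is reversed (``"reverse"``).
    """
    import pysam

    if protocol not in ("forward", "reverse"):
        raise ValueError("protocol must be 'forward' or 'reverse'")
    if mode not in ("3prime", "coverage"):
        raise ValueError("mode must be '3prime' or 'coverage'")
    bam = pysam.AlignmentFile(os.fspath(bam_path), "rb")
    try:
        bam.check_index()
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"{bam_path}: BAM index required") from exc
    track = SignalTrack(sample_id=sample_id or os.path.basename(os.fspath(bam_path)),
                        strain=strain, replicate=replicate)
    skipped = 0
    counted = 0
    for read in bam.fetch():
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            skipped += 1
            continue
        if exclude_duplicates and read.is_duplicate:
            skipped += 1
            continue
        read_strand = "-" if read.is_reverse else "+"
        if protocol == "reverse":
            read_strand = "-" if read_strand == "+" else "+"
        if mode == "coverage":
            span = read.reference_end - read.reference_start
            track.add_range(read.reference_name, read_strand,
                            read.reference_start + 1,
                            np.ones(span, dtype=np.int64))
        else:
            # 3'-most aligned base in read orientation
            pos = read.reference_end if not read.is_reverse else read.reference_start + 1
            track.add(read.reference_name, read_strand, pos)
        counted += 1
    bam.close()
    logger.info("%s: counted %d alignments, skipped %d", bam_path, counted, skipped)
    return track


# ---------------------------------------------------------------------------
# Window primitives


def window_count(
    track: SignalTrack, gene: GeneModel, from_offset: int, to_offset: int
) -> int:
    """Total 3'-end counts over an inclusive strand-aware offset window.

    Offsets are relative to the gene's poly(A) site (0 = the poly(A)
    nucleotide, positive downstream).  Windows extending past
    chromosome bounds are truncated (outside positions count 0).
    """
    if from_offset > to_offset:
        raise ValueError("from_offset > to_offset")
    a = gene.offset_to_genomic(from_offset)
    b = gene.offset_to_genomic(to_offset)
    lo, hi = min(a, b), max(a, b)
    if lo < 1:
        logger.debug("%s: window truncated at chromosome start", gene.gene_id)
    return track.window_sum(gene.chrom, gene.strand, lo, hi)


def cds_mean_density(track: SignalTrack, gene: GeneModel) -> float:
    """Mean 3'-end reads per nucleotide over the CDS (the expression value)."""
    total = track.window_sum(gene.chrom, gene.strand, gene.cds_start, gene.cds_end)
    return total / gene.cds_length
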