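"""Transcript models, longest-isoform selection and coordinate arithmetic.

All internal coordinates are 0-based, half-open.  GTF input is read in its
native 1-based closed convention and converted on the way in; BED output is
written 0-based half-open.  Exons of a :class:`TranscriptModel` are stored in
*transcript orientation* (5'->3' of the mRNA), so the first exon of a
minus-strand transcript is the one with the highest genomic coordinates.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils


class GTFParseError(ValueError):
    """Raised for malformed annotation input."""


class Segment(str, enum.Enum):
    """Transcript segment labels of a coding mRNA."""

    FIVE_UTR = "5UTR"
    CDS = "CDS"
    THREE_UTR = "3UTR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TranscriptModel:
    """One gene isoform with transcript-relative CDS segmentation.

    Parameters
    ----------
    exons
        Genomic intervals (0-based half-open), ordered 5'->3' in transcript
        orientation: ascending genomic coordinates on ``+``, descending on
        ``-``.
    cds_start_tx, cds_end_tx
        Transcript-relative CDS span (0-based half-open); both ``None`` for a
        non-coding transcript.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_tx: int | None = None
    cds_end_tx: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        for start, end in self.exons:
            if not 0 <= start < end:
                raise ValueError(
                    f"{self.transcript_id}: bad exon interval [{start}, {end})"
                )
        genomic = sorted(self.exons)
        for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(
                f"{self.transcript_id}: exons not in transcript orientation"
            )
        coding = (self.cds_start_tx is not None, self.cds_end_tx is not None)
        if coding[0] != coding[1]:
            raise ValueError(
                f"{self.transcript_id}: cds_start_tx/cds_end_tx must both be set"
            )
        if self.is_coding:
            if not 0 <= self.cds_start_tx < self.cds_end_tx <= self.length_tx:
                raise ValueError(
                    f"{self.transcript_id}: CDS [{self.cds_start_tx}, "
                    f"{self.cds_end_tx}) outside transcript [0, {self.length_tx})"
                )

    @property
    def length_tx(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start_tx is not None

    @property
    def utr5_len(self) -> int:
        self._require_coding()
        return self.cds_start_tx

    @property
    def cds_len(self) -> int:
        self._require_coding()
        return self.cds_end_tx - self.cds_start_tx

    @property
    def utr3_len(self) -> int:
        self._require_coding()
        return self.length_tx - self.cds_end_tx

    def _require_coding(self) -> None:
        if not self.is_coding:
            raise ValueError(f"{self.transcript_id} is non-coding")


def segment_of(tm: TranscriptModel, pos: int) -> Segment:
    """Label a transcript position as 5'UTR, CDS or 3'UTR (half-open bounds)."""
    tm._require_coding()
    if not 0 <= pos < tm.length_tx:
        raise ValueError(
            f"position {pos} outside transcript [0, {tm.length_tx}) of "
            f"{tm.transcript_id}"
        )
    if pos < tm.cds_start_tx:
        return Segment.FIVE_UTR
    if pos < tm.cds_end_tx:
        return Segment.CDS
    return Segment.THREE_UTR


def longest_isoform(models: Sequence[TranscriptModel]) -> TranscriptModel:
    """Pick the longest isoform of one gene; ties go to the smallest id."""
    if not models:
        raise ValueError("empty isoform list")
    gene_ids = {m.gene_id for m in models}
    if len(gene_ids) != 1:
        raise ValueError(f"isoforms of multiple genes passed: {sorted(gene_ids)}")
    return min(models, key=lambda m: (-m.length_tx, m.transcript_id))


def longest_isoforms(models: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """One longest isoform per gene, ordered by gene_id."""
    by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
    for m in models:
        by_gene[m.gene_id].append(m)
    return [longest_isoform(by_gene[g]) for g in sorted(by_gene)]


def genomic_to_transcript(tm: TranscriptModel, gpos: int) -> int:
    """Map an exonic genomic position to its transcript coordinate."""
    offset = 0
    for start, end in tm.exons:
        if start <= gpos < end:
            if tm.strand == "+":
                return offset + (gpos - start)
            return offset + (end - 1 - gpos)
        offset += end - start
    raise ValueError(
        f"genomic position {gpos} is not exonic in {tm.transcript_id}"
    )


def transcript_to_genomic(tm: TranscriptModel, tpos: int) -> int:
    """Inverse of :func:`genomic_to_transcript`."""
    if not 0 <= tpos < tm.length_tx:
        raise ValueError(
            f"transcript position {tpos} outside [0, {tm.length_tx})"
        )
    offset = 0
    for start, end in tm.exons:
        size = end - start
        if tpos < offset + size:
            within = tpos - offset
            if tm.strand == "+":
                return start + within
            return end - 1 - within
        offset += size
    raise AssertionError("unreachable")  # pragma: no cover


def transcript_interval_to_genomic(
    tm: TranscriptModel, t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Project a transcript interval onto genomic blocks (ascending order)."""
    if not 0 <= t_start < t_end <= tm.length_tx:
        raise ValueError(f"bad transcript interval [{t_start}, {t_end})")
    blocks = []
    offset = 0
    for start, end in tm.exons:
        size = end - start
        lo = max(t_start, offset)
        hi = min(t_end, offset + size)
        if lo < hi:
            if tm.strand == "+":
                blocks.append((start + (lo - offset), start + (hi - offset)))
            else:
                blocks.append((end - (hi - offset), end - (lo - offset)))
        offset += size
    return sorted(blocks)


_REQUIRED_ATTRS = ("gene_id", "transcript_id")


def _prescan_gtf(path: Path) -> None:
    # gffutils does not report line numbers for missing attributes, so
    # validate the two required ones up front.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if fields[2] not in ("exon", "CDS"):
                continue
            for attr in _REQUIRED_ATTRS:
                if attr not in fields[8]:
                    raise GTFParseError(
                        f"{path}:{lineno}: {fields[2]} feature missing "
                        f"required attribute {attr!r}"
                    )


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon/CDS features of a GTF into transcript models.

    Coordinates are converted from GTF 1-based closed intervals to internal
    0-based half-open ones; minus-strand exons are reordered into transcript
    orientation.  Each CDS feature must fall inside a single exon of its
    transcript.
    """
    path = Path(path)
    _prescan_gtf(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    cds: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_id = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes["gene_id"][0]
        meta[tx_id] = (gene_id, feat.seqid, feat.strand)
        interval = (feat.start - 1, feat.end)  # to 0-based half-open
        (exons if feat.featuretype == "exon" else cds)[tx_id].append(interval)

    models = []
    for tx_id in sorted(exons):
        gene_id, chrom, strand = meta[tx_id]
        genomic = sorted(exons[tx_id])
        ordered = tuple(genomic if strand == "+" else genomic[::-1])
        base = TranscriptModel(tx_id, gene_id, chrom, strand, ordered)
        cds_start_tx = cds_end_tx = None
        if tx_id in cds:
            t_coords = []
            for c_start, c_end in cds[tx_id]:
                if not any(s <= c_start and c_end <= e for s, e in ordered):
                    raise GTFParseError(
                        f"{tx_id}: CDS [{c_start}, {c_end}) not contained in "
                        "any exon"
                    )
                t_coords.append(genomic_to_transcript(base, c_start))
                t_coords.append(genomic_to_transcript(base, c_end - 1))
            cds_start_tx = min(t_coords)
            cds_end_tx = max(t_coords) + 1
        models.append(
            TranscriptModel(
                tx_id, gene_id, chrom, strand, ordered, cds_start_tx, cds_end_tx
            )
        )
    return models
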