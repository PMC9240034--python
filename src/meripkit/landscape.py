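"""Methylation landscape: metagene profile, segment distribution, DRACH motif.

The metagene profile places each peak summit on a normalized transcript
coordinate in which the 5'UTR maps to [0, 1), the CDS to [1, 2) and the
3'UTR to [2, 3], each segment rescaled to unit length, and reports a
histogram normalized to unit area.  The motif test asks whether peak
neighbourhoods carry the DRACH consensus ([AGT][AG]AC[ACT]) more often than
width-matched windows sampled from the same transcriptome.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peakcall import PeakSet
from .transcript_model import Segment, TranscriptModel, segment_of

logger = logging.getLogger(__name__)

DRACH_RE = re.compile(r"[AGT][AG]AC[ACT]")
DEFAULT_BINS_PER_SEGMENT = 33
DEFAULT_FLANK = 50


@dataclass
class MetageneProfile:
    """Peak density along the normalized 5'UTR/CDS/3'UTR coordinate."""

    bin_edges: np.ndarray  # length 3*bins+1, spanning [0, 3]
    density: np.ndarray    # integrates to 1
    counts: np.ndarray
    bins_per_segment: int
    n_used: int
    n_skipped: int

    @property
    def bin_width(self) -> float:
        return 1.0 / self.bins_per_segment

    @property
    def modal_coordinate(self) -> float:
        """Midpoint of the highest-density bin."""
        i = int(np.argmax(self.density))
        return float((self.bin_edges[i] + self.bin_edges[i + 1]) / 2.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "count": self.counts,
                "density": self.density,
            }
        )


def normalized_position(tm: TranscriptModel, pos: int) -> float:
    """Map a transcript position to the segment-normalized [0, 3] scale."""
    seg = segment_of(tm, pos)
    if seg is Segment.FIVE_UTR:
        return pos / tm.utr5_len
    if seg is Segment.CDS:
        return 1.0 + (pos - tm.cds_start_tx) / tm.cds_len
    return 2.0 + (pos - tm.cds_end_tx) / tm.utr3_len


def _usable(tm: TranscriptModel | None, tx_id: str) -> bool:
    if tm is None:
        logger.warning("peak on unknown transcript %s skipped", tx_id)
        return False
    if not tm.is_coding:
        logger.warning("peak on non-coding transcript %s skipped", tx_id)
        return False
    if min(tm.utr5_len, tm.cds_len, tm.utr3_len) == 0:
        logger.warning(
            "transcript %s has a zero-length segment; skipped", tx_id
        )
        return False
    return True


def _model_map(models) -> Mapping[str, TranscriptModel]:
    if isinstance(models, Mapping):
        return models
    return {tm.transcript_id: tm for tm in models}


def metagene_profile(
    peaks: PeakSet,
    models,
    bins_per_segment: int = DEFAULT_BINS_PER_SEGMENT,
    unit: str = "summit",
) -> MetageneProfile:
    """Histogram of peak positions on the normalized transcript.

    Each peak contributes its summit (default) or, with ``unit="footprint"``,
    one equal share per covered base.  Peaks on non-coding transcripts or on
    transcripts with an empty segment are skipped with a warning.
    """
    if unit not in ("summit", "footprint"):
        raise ValueError("unit must be 'summit' or 'footprint'")
    if bins_per_segment < 1:
        raise ValueError("bins_per_segment must be >= 1")
    tms = _model_map(models)
    coords: list[float] = []
    weights: list[float] = []
    n_used = n_skipped = 0
    for peak in peaks:
        tm = tms.get(peak.transcript_id)
        if not _usable(tm, peak.transcript_id):
            n_skipped += 1
            continue
        n_used += 1
        if unit == "summit":
            coords.append(normalized_position(tm, peak.summit))
            weights.append(1.0)
        else:
            span = range(peak.start, min(peak.end, tm.length_tx))
            w = 1.0 / len(span)
            for pos in span:
                coords.append(normalized_position(tm, pos))
                weights.append(w)
    if n_used == 0:
        raise ValueError("no usable peaks for metagene profile")
    edges = np.linspace(0.0, 3.0, 3 * bins_per_segment + 1)
    counts, _ = np.histogram(
        np.clip(coords, 0.0, np.nextafter(3.0, 0.0)), bins=edges,
        weights=weights,
    )
    width = 1.0 / bins_per_segment
    density = counts / (counts.sum() * width)
    return MetageneProfile(edges, density, counts, bins_per_segment,
                           n_used, n_skipped)


def segment_distribution(peaks: PeakSet, models) -> dict[Segment, float]:
    """Fraction of peak summits per transcript segment (sums to 1)."""
    tms = _model_map(models)
    counts = {seg: 0 for seg in Segment}
    total = 0
    for peak in peaks:
        tm = tms.get(peak.transcript_id)
        if not _usable(tm, peak.transcript_id):
            continue
        counts[segment_of(tm, peak.summit)] += 1
        total += 1
    if total == 0:
        raise ValueError("no usable peaks for segment distribution")
    return {seg: counts[seg] / total for seg in Segment}


@dataclass
class MotifEnrichment:
    """DRACH occurrence around peak summits vs transcriptome background."""

    n_peaks: int
    n_with_motif: int
    observed_rate: float
    expected_rate: float
    p_value: float
    n_background: int
    flank: int


def drach_enrichment(
    peaks: PeakSet,
    sequences: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    n_background: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MotifEnrichment:
    """Test DRACH enrichment in summit +/- flank windows.

    Observed rate: fraction of peaks whose summit window (clipped at the
    transcript ends, with a log message) contains at least one DRACH match.
    Expected rate: same statistic over ``n_background`` width-matched
    windows drawn uniformly over all eligible start positions of the
    supplied transcriptome.  One-sided exact binomial p-value.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    width = 2 * flank + 1
    n_hit = 0
    n_clipped = 0
    for peak in peaks:
        seq = sequences.get(peak.transcript_id)
        if seq is None:
            raise KeyError(f"no sequence for {peak.transcript_id}")
        seq = seq.upper()
        lo = peak.summit - flank
        hi = peak.summit + flank + 1
        if lo < 0 or hi > len(seq):
            n_clipped += 1
            lo, hi = max(lo, 0), min(hi, len(seq))
        if DRACH_RE.search(seq[lo:hi]):
            n_hit += 1
    if n_clipped:
        logger.info("%d motif window(s) clipped at transcript bounds",
                    n_clipped)

    tx_ids = sorted(sequences)
    seqs = [sequences[t].upper() for t in tx_ids]
    n_starts = np.array([max(len(s) - width + 1, 1) for s in seqs])
    cum = np.cumsum(n_starts)
    draws = rng.integers(0, cum[-1], size=n_background)
    tx_idx = np.searchsorted(cum, draws, side="right")
    offsets = draws - (cum[tx_idx] - n_starts[tx_idx])
    bg_hits = 0
    for i, off in zip(tx_idx, offsets):
        if DRACH_RE.search(seqs[i][off:off + width]):
            bg_hits += 1
    expected = bg_hits / n_background

    observed = n_hit / len(peaks)
    p_bg = min(max(expected, 0.0), 1.0)
    p_value = stats.binomtest(
        n_hit, len(peaks), p_bg, alternative="greater"
    ).pvalue
    return MotifEnrichment(
        n_peaks=len(peaks),
        n_with_motif=n_hit,
        observed_rate=observed,
        expected_rate=expected,
        p_value=float(p_value),
        n_background=n_background,
        flank=flank,
    )
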