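"""Sliding-window m6A peak calling on the longest isoform.

The procedure scans each transcript with a 100-nt window advanced in 10-nt
steps, drops windows whose read counts fall below 1/20 of the transcript's
top window in *both* the IP and the input library, tests each remaining
window for IP-over-input enrichment with a one-sided Fisher exact test
against the library totals, controls the FDR with Benjamini-Hochberg across
all tested windows, and merges adjacent significant windows into peaks.
Genotype differential methylation is a per-peak Fisher exact test of the
IP/input balance between the two genotypes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .transcript_model import TranscriptModel

logger = logging.getLogger(__name__)

COORD_COLUMNS = ("transcript_id", "window_start", "window_end")
_SAMPLE_RE = re.compile(r"^(IP|input)_(.+)_rep(\d+)$")

DEFAULT_WINDOW = 100
DEFAULT_STEP = 10
DEFAULT_EXCLUSION_FRACTION = 1.0 / 20.0


@dataclass(frozen=True)
class SampleInfo:
    """Parsed identity of one count column: assay x condition x replicate."""

    assay: str  # "IP" or "input"
    condition: str
    replicate: int


class WindowTable:
    """Per-window read counts for IP/input libraries across samples.

    Wraps a DataFrame with columns ``transcript_id``, ``window_start``,
    ``window_end`` plus one integer count column per sample, named
    ``{assay}_{condition}_rep{n}`` (e.g. ``IP_WT_rep1``).
    """

    def __init__(self, df: pd.DataFrame, window: int = DEFAULT_WINDOW,
                 step: int = DEFAULT_STEP):
        missing = [c for c in COORD_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"window table missing columns {missing}")
        samples = {}
        for col in df.columns:
            if col in COORD_COLUMNS:
                continue
            m = _SAMPLE_RE.match(col)
            if m is None:
                raise ValueError(
                    f"unrecognized sample column {col!r}; expected "
                    "'IP_<condition>_rep<N>' or 'input_<condition>_rep<N>'"
                )
            samples[col] = SampleInfo(m.group(1), m.group(2), int(m.group(3)))
        if not samples:
            raise ValueError("window table has no sample columns")
        counts = df[list(samples)]
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts in window table")
        self.df = df.reset_index(drop=True)
        self.samples: dict[str, SampleInfo] = samples
        self.window = window
        self.step = step

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_columns(self) -> list[str]:
        return list(self.samples)

    @property
    def conditions(self) -> list[str]:
        return sorted({s.condition for s in self.samples.values()})

    def columns_for(self, assay: str | None = None,
                    condition: str | None = None) -> list[str]:
        return [
            c for c, s in self.samples.items()
            if (assay is None or s.assay == assay)
            and (condition is None or s.condition == condition)
        ]

    def library_totals(self) -> pd.Series:
        """Reads per sample column, summed over all windows."""
        return self.df[self.sample_columns].sum()

    def pooled(self, assay: str, condition: str | None = None) -> np.ndarray:
        """Counts summed over replicates (and conditions unless given)."""
        cols = self.columns_for(assay, condition)
        if not cols:
            raise ValueError(
                f"no {assay} columns" +
                (f" for condition {condition!r}" if condition else "")
            )
        return self.df[cols].sum(axis=1).to_numpy()

    @classmethod
    def read_tsv(cls, path: str | Path, window: int = DEFAULT_WINDOW,
                 step: int = DEFAULT_STEP) -> "WindowTable":
        return cls(pd.read_csv(path, sep="\t"), window=window, step=step)

    def write_tsv(self, path: str | Path) -> None:
        from .io import atomic_write

        with atomic_write(path) as fh:
            self.df.to_csv(fh, sep="\t", index=False)


@dataclass(frozen=True)
class Peak:
    """A merged run of significant windows on one transcript."""

    transcript_id: str
    start: int
    end: int
    summit: int
    p_value: float
    q_value: float
    log2_enrichment: float
    n_windows: int
    member_starts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("peak start must be < end")
        if not self.start <= self.summit < self.end:
            raise ValueError("summit outside peak")
        for v in (self.p_value, self.q_value):
            if not 0.0 <= v <= 1.0:
                raise ValueError("p/q outside [0, 1]")
        if self.q_value < self.p_value - 1e-12:
            raise ValueError("q must be >= p")


@dataclass
class PeakSet:
    """Called peaks plus run provenance (thresholds, counts tested)."""

    peaks: list[Peak]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": p.transcript_id,
                    "start": p.start,
                    "end": p.end,
                    "summit": p.summit,
                    "p_value": p.p_value,
                    "q_value": p.q_value,
                    "log2_enrichment": p.log2_enrichment,
                    "n_windows": p.n_windows,
                    "member_starts": ",".join(map(str, p.member_starts)),
                }
                for p in self.peaks
            ],
            columns=[
                "transcript_id", "start", "end", "summit", "p_value",
                "q_value", "log2_enrichment", "n_windows", "member_starts",
            ],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       provenance: dict | None = None) -> "PeakSet":
        peaks = []
        for r in df.itertuples(index=False):
            raw = getattr(r, "member_starts", "")
            members = tuple(
                int(x) for x in str(raw).split(",")
                if x not in ("", "nan")
            )
            peaks.append(
                Peak(
                    r.transcript_id, int(r.start), int(r.end), int(r.summit),
                    float(r.p_value), float(r.q_value),
                    float(r.log2_enrichment), int(r.n_windows), members,
                )
            )
        return cls(peaks, provenance or {})

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PeakSet":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls.from_dataframe(df)

    def write_tsv(self, path: str | Path) -> None:
        from .io import atomic_write

        with atomic_write(path) as fh:
            self.to_dataframe().to_csv(fh, sep="\t", index=False)


def make_windows(length_tx: int, window: int = DEFAULT_WINDOW,
                 step: int = DEFAULT_STEP) -> np.ndarray:
    """Sliding-window starts/ends for one transcript (0-based half-open).

    Windows start at 0, step, 2*step, ... while they fit; a transcript
    shorter than the window yields one whole-transcript window.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if length_tx <= 0:
        raise ValueError("length_tx must be positive")
    if length_tx < window:
        return np.array([[0, length_tx]], dtype=int)
    starts = np.arange(0, length_tx - window + 1, step, dtype=int)
    return np.column_stack([starts, starts + window])


def windows_for_models(models: Sequence[TranscriptModel],
                       window: int = DEFAULT_WINDOW,
                       step: int = DEFAULT_STEP) -> pd.DataFrame:
    """Window coordinate frame for a set of transcripts."""
    frames = []
    for tm in models:
        w = make_windows(tm.length_tx, window, step)
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": tm.transcript_id,
                    "window_start": w[:, 0],
                    "window_end": w[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def exclusion_filter(
    wt: WindowTable,
    fraction: float = DEFAULT_EXCLUSION_FRACTION,
    mode: str = "both",
) -> tuple[WindowTable, pd.DataFrame]:
    """Drop low-count windows relative to each transcript's top window.

    Per transcript, replicate-summed IP and input counts define thresholds
    ``fraction * max(IP)`` and ``fraction * max(input)``.  Under the default
    ``mode="both"`` a window is excluded iff its count is strictly below the
    threshold in *both* assays; ``mode="either"`` excludes on a single
    failure.  A window exactly at a threshold is retained.  Transcripts with
    all-zero counts lose all their windows (with a warning).

    Returns the filtered table and a per-transcript threshold log.
    """
    if mode not in ("both", "either"):
        raise ValueError(f"mode must be 'both' or 'either', got {mode!r}")
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    ip = pd.Series(wt.pooled("IP"), index=wt.df.index)
    inp = pd.Series(wt.pooled("input"), index=wt.df.index)
    tx = wt.df["transcript_id"]
    thr_ip = tx.map(ip.groupby(tx).max()) * fraction
    thr_inp = tx.map(inp.groupby(tx).max()) * fraction
    below_ip = ip < thr_ip
    below_inp = inp < thr_inp
    excluded = (below_ip & below_inp) if mode == "both" else (below_ip | below_inp)

    all_zero = (ip.groupby(tx).max() == 0) & (inp.groupby(tx).max() == 0)
    dead = all_zero[all_zero].index
    if len(dead):
        logger.warning(
            "%d transcript(s) with all-zero counts: all windows excluded",
            len(dead),
        )
        excluded |= tx.isin(dead)

    log = pd.DataFrame(
        {
            "transcript_id": ip.groupby(tx).max().index,
            "threshold_ip": (ip.groupby(tx).max() * fraction).to_numpy(),
            "threshold_input": (inp.groupby(tx).max() * fraction).to_numpy(),
        }
    )
    kept = WindowTable(
        wt.df.loc[~excluded].reset_index(drop=True), wt.window, wt.step
    )
    return kept, log


def window_enrichment_tests(
    ip_counts: np.ndarray,
    input_counts: np.ndarray,
    ip_total: int,
    input_total: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-sided Fisher exact test for IP enrichment per window.

    The 2x2 table per window is ``[[ip, ip_total - ip], [input,
    input_total - input]]``; the one-sided (IP-enriched) Fisher p-value is
    the upper hypergeometric tail.  log2 enrichment is the ratio of
    library-normalized rates with a 0.5 pseudocount (reporting only; the
    test itself is exact on raw counts).
    """
    ip = np.asarray(ip_counts, dtype=np.int64)
    inp = np.asarray(input_counts, dtype=np.int64)
    if (ip < 0).any() or (inp < 0).any():
        raise ValueError("negative counts")
    if ip_total < (ip.max(initial=0)) or input_total < (inp.max(initial=0)):
        raise ValueError("count exceeds library total")
    if ip_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be positive")
    p = stats.hypergeom.sf(
        ip - 1, ip_total + input_total, ip + inp, ip_total
    )
    p = np.minimum(p, 1.0)
    log2_enr = np.log2(
        ((ip + 0.5) / ip_total) / ((inp + 0.5) / input_total)
    )
    return p, log2_enr


def window_enrichment_test(
    ip_count: int, input_count: int, ip_total: int, input_total: int
) -> tuple[float, float]:
    """Scalar form of :func:`window_enrichment_tests`."""
    p, lfc = window_enrichment_tests(
        np.array([ip_count]), np.array([input_count]), ip_total, input_total
    )
    return float(p[0]), float(lfc[0])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def merge_windows(windows: pd.DataFrame,
                  q_threshold: float = 0.05) -> list[Peak]:
    """Merge overlapping/bookended significant windows into peaks.

    ``windows`` needs columns transcript_id, window_start, window_end,
    p_value, q_value, log2_enrichment.  Peak p/q are the minima over merged
    windows; the summit is the midpoint of the minimum-p window (first such
    window on ties); the reported enrichment is that window's.
    """
    sig = windows[windows["q_value"] <= q_threshold]
    peaks: list[Peak] = []
    for tx_id, grp in sig.groupby("transcript_id", sort=True):
        grp = grp.sort_values(["window_start", "window_end"], kind="stable")
        run: list[pd.Series] = []
        run_end = None
        for _, row in grp.iterrows():
            if run and row.window_start > run_end:
                peaks.append(_finish_peak(tx_id, run))
                run = []
            run.append(row)
            run_end = row.window_end if run_end is None or len(run) == 1 \
                else max(run_end, row.window_end)
        if run:
            peaks.append(_finish_peak(tx_id, run))
    return peaks


def _finish_peak(tx_id: str, run: list[pd.Series]) -> Peak:
    start = int(min(r.window_start for r in run))
    end = int(max(r.window_end for r in run))
    best = min(run, key=lambda r: r.p_value)
    summit = int((best.window_start + best.window_end) // 2)
    return Peak(
        transcript_id=tx_id,
        start=start,
        end=end,
        summit=summit,
        p_value=float(min(r.p_value for r in run)),
        q_value=float(min(r.q_value for r in run)),
        log2_enrichment=float(best.log2_enrichment),
        n_windows=len(run),
        member_starts=tuple(int(r.window_start) for r in run),
    )


def call_peaks(
    wt: WindowTable,
    q_threshold: float = 0.05,
    exclusion_fraction: float = DEFAULT_EXCLUSION_FRACTION,
    exclusion_mode: str = "both",
) -> PeakSet:
    """Full peak-calling pass: exclusion filter, per-window one-sided Fisher
    test of pooled IP vs pooled input against library totals, BH correction
    across all tested windows, and merging of significant windows.

    Replicates (and conditions, when several are present) are pooled before
    testing.  Library totals are the column sums of the *unfiltered* table.
    """
    if len(wt) == 0:
        return PeakSet([], {"n_windows": 0, "n_tested": 0, "n_significant": 0})
    totals = wt.library_totals()
    ip_total = int(totals[wt.columns_for("IP")].sum())
    input_total = int(totals[wt.columns_for("input")].sum())
    kept, thresholds = exclusion_filter(wt, exclusion_fraction, exclusion_mode)
    if len(kept) == 0:
        return PeakSet(
            [],
            {
                "n_windows": len(wt), "n_tested": 0, "n_significant": 0,
                "ip_total": ip_total, "input_total": input_total,
            },
        )
    ip = kept.pooled("IP")
    inp = kept.pooled("input")
    p, log2_enr = window_enrichment_tests(ip, inp, ip_total, input_total)
    q = bh_adjust(p)
    tested = kept.df[list(COORD_COLUMNS)].copy()
    tested["ip_count"] = ip
    tested["input_count"] = inp
    tested["p_value"] = p
    tested["q_value"] = q
    tested["log2_enrichment"] = log2_enr
    peaks = merge_windows(tested, q_threshold)
    provenance = {
        "window": wt.window,
        "step": wt.step,
        "q_threshold": q_threshold,
        "exclusion_fraction": exclusion_fraction,
        "exclusion_mode": exclusion_mode,
        "n_windows": len(wt),
        "n_tested": len(kept),
        "n_significant": int((q <= q_threshold).sum()),
        "ip_total": ip_total,
        "input_total": input_total,
        "thresholds": thresholds,
        "tested_windows": tested,
    }
    return PeakSet(peaks, provenance)


def differential_methylation(
    peaks: PeakSet,
    wt: WindowTable,
    condition_ref: str = "WT",
    condition_alt: str = "KO",
) -> pd.DataFrame:
    """Per-peak differential methylation between two genotypes.

    For each peak, IP and input counts of its member windows (the merged
    significant windows; windows contained in the peak span when members
    are unknown) are summed per genotype (replicates pooled) and tested
    with a two-sided Fisher exact test on ``[[IP_alt, input_alt], [IP_ref,
    input_ref]]``; BH correction runs across peaks.  The reported effect is
    the log2 ratio of depth-normalized IP/input odds, alt over ref, with a
    0.5 pseudocount; positive values mean higher methylation in the
    alternative (knockout) genotype.

    Library depths are estimated from the *background* — windows outside
    every peak — so that the methylation signal under comparison does not
    leak into its own normalization (the composition bias familiar from
    differential occupancy analysis).  If no background window exists the
    full library totals are used.
    """
    for cond in (condition_ref, condition_alt):
        if not wt.columns_for("IP", cond) or not wt.columns_for("input", cond):
            raise ValueError(f"window table lacks IP/input columns for {cond!r}")

    in_peak = pd.Series(False, index=wt.df.index)
    for peak in peaks:
        in_peak |= (
            (wt.df["transcript_id"] == peak.transcript_id)
            & (wt.df["window_start"] < peak.end)
            & (wt.df["window_end"] > peak.start)
        )
    background = wt.df.loc[~in_peak, wt.sample_columns]
    totals = background.sum() if len(background) else wt.library_totals()

    def _totals(assay: str, cond: str) -> float:
        return float(totals[wt.columns_for(assay, cond)].sum())

    t_ip_ref = _totals("IP", condition_ref)
    t_in_ref = _totals("input", condition_ref)
    t_ip_alt = _totals("IP", condition_alt)
    t_in_alt = _totals("input", condition_alt)

    ip_ref = pd.Series(wt.pooled("IP", condition_ref), index=wt.df.index)
    in_ref = pd.Series(wt.pooled("input", condition_ref), index=wt.df.index)
    ip_alt = pd.Series(wt.pooled("IP", condition_alt), index=wt.df.index)
    in_alt = pd.Series(wt.pooled("input", condition_alt), index=wt.df.index)

    rows = []
    for peak in peaks:
        on_tx = wt.df["transcript_id"] == peak.transcript_id
        if peak.member_starts:
            mask = on_tx & wt.df["window_start"].isin(peak.member_starts)
        else:
            mask = (
                on_tx
                & (wt.df["window_start"] >= peak.start)
                & (wt.df["window_end"] <= peak.end)
            )
        a_ip = int(ip_alt[mask].sum())
        a_in = int(in_alt[mask].sum())
        r_ip = int(ip_ref[mask].sum())
        r_in = int(in_ref[mask].sum())
        _, p = stats.fisher_exact([[a_ip, a_in], [r_ip, r_in]])
        log2_ratio = (
            np.log2(((a_ip + 0.5) / t_ip_alt) / ((a_in + 0.5) / t_in_alt))
            - np.log2(((r_ip + 0.5) / t_ip_ref) / ((r_in + 0.5) / t_in_ref))
        )
        rows.append(
            {
                "transcript_id": peak.transcript_id,
                "start": peak.start,
                "end": peak.end,
                "summit": peak.summit,
                f"ip_{condition_alt}": a_ip,
                f"input_{condition_alt}": a_in,
                f"ip_{condition_ref}": r_ip,
                f"input_{condition_ref}": r_in,
                "log2_ratio": float(log2_ratio),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "start", "end", "summit",
            f"ip_{condition_alt}", f"input_{condition_alt}",
            f"ip_{condition_ref}", f"input_{condition_ref}",
            "log2_ratio", "p_value",
        ],
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out
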