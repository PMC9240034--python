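"""Synthetic data with planted ground truth for every pipeline stage.

The generator builds a small transcriptome (sequences + annotation), plants
DRACH-centered methylation sites — by default biased toward the stop-codon
neighbourhood, where m6A concentrates in real data — and emits:

* MeRIP window counts: negative-binomial IP/input libraries in which windows
  overlapping a planted site carry a fold enrichment in IP, amplified
  further in the knockout genotype at designated target genes (the
  demethylase-loss phenotype);
* actinomycin-D decay time courses whose first-order decay rates differ by
  genotype at target genes, alongside a stable reference species;
* qPCR Ct tables with a planted fold-change;
* a gene x sample expression count matrix with planted up/down genes.

Every generator is a pure function of its :class:`SimConfig` (whose seed is
mandatory); independent substreams per stage keep each table reproducible
on its own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import peakcall
from .peakcall import WindowTable
from .transcript_model import TranscriptModel, transcript_interval_to_genomic

_BASES = np.array(list("ACGT"))
# DRACH = [AGT][AG]AC[ACT]
_D, _R, _H = list("AGT"), list("AG"), list("ACT")

# per-stage RNG substream tags
_S_TRANSCRIPTOME, _S_MERIP, _S_DECAY, _S_QPCR, _S_EXPR = range(5)


class SimConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data generators."""

    seed: int
    # transcriptome
    n_genes: int = 50
    utr5_range: tuple[int, int] = (100, 300)
    cds_range: tuple[int, int] = (300, 1200)
    utr3_range: tuple[int, int] = (200, 800)
    n_sites_per_gene: int = 1
    frac_stop_proximal: float = 0.8
    n_targets: int = 5
    # MeRIP counts
    site_enrichment: float = 4.0
    ko_effect: float = 2.0
    window: int = 100
    step: int = 10
    window_depth: float = 30.0   # mean input reads per full window
    nb_dispersion: float = 0.005
    merip_replicates: int = 2
    expr_log_sd: float = 0.5     # lognormal spread of expression weights
    conditions: tuple[str, str] = ("WT", "KO")
    # decay
    # the chase spans >= 2 half-lives of the slowest (4 h) transcript
    decay_timepoints: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0)
    decay_noise_cv: float = 0.1
    decay_ref_noise_cv: float = 0.02  # rRNA reference: abundant and stable
    decay_replicates: int = 5
    halflife_wt: float = 4.0
    halflife_ko: float = 2.0
    # qPCR
    qpcr_fold: float = 4.0
    qpcr_noise_sd: float = 0.1
    qpcr_replicates: int = 5
    # expression matrix
    expr_n_genes: int = 2000
    expr_replicates: int = 3
    expr_mean_log: float = 5.0
    expr_sd_log: float = 1.5
    expr_de_frac: float = 0.05
    expr_de_log2fc: float = 2.0
    expr_dispersion: float = 0.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimConfigError("seed is mandatory")
        for name in ("n_genes", "n_sites_per_gene", "merip_replicates",
                     "decay_replicates", "qpcr_replicates", "expr_n_genes",
                     "expr_replicates"):
            if getattr(self, name) < 1:
                raise SimConfigError(f"{name} must be >= 1")
        for name in ("site_enrichment", "ko_effect", "window_depth",
                     "halflife_wt", "halflife_ko", "qpcr_fold"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be > 0")
        for name in ("utr5_range", "cds_range", "utr3_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise SimConfigError(f"{name} must satisfy 0 < lo <= hi")
        if not 0.0 <= self.frac_stop_proximal <= 1.0:
            raise SimConfigError("frac_stop_proximal must lie in [0, 1]")
        if 0.0 not in self.decay_timepoints:
            raise SimConfigError("decay_timepoints must include 0")
        if self.n_targets > self.n_genes:
            raise SimConfigError("n_targets exceeds n_genes")
        if self.nb_dispersion < 0 or self.expr_dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        min_len = self.utr5_range[0] + self.cds_range[0] + self.utr3_range[0]
        if self.n_sites_per_gene * 10 > min_len:
            raise SimConfigError(
                "n_sites_per_gene too large for the shortest transcript"
            )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class GeneTruth:
    """Planted ground truth for one simulated gene."""

    gene_id: str
    transcript_id: str
    sites: tuple[int, ...]          # transcript coords of DRACH centers
    is_target: bool
    halflife: dict | None = None    # genotype -> hours (targets only)


@dataclass
class SimTruth:
    """All planted truths of one simulated study."""

    genes: list[GeneTruth]
    de_labels: dict[str, str] = field(default_factory=dict)

    def by_transcript(self) -> dict[str, GeneTruth]:
        return {g.transcript_id: g for g in self.genes}

    @property
    def targets(self) -> list[GeneTruth]:
        return [g for g in self.genes if g.is_target]

    def to_json(self, path: str | Path) -> None:
        from .io import atomic_write

        payload = {
            "genes": [asdict(g) for g in self.genes],
            "de_labels": self.de_labels,
        }
        with atomic_write(path) as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genes = [
            GeneTruth(
                gene_id=g["gene_id"],
                transcript_id=g["transcript_id"],
                sites=tuple(g["sites"]),
                is_target=g["is_target"],
                halflife=g["halflife"],
            )
            for g in payload["genes"]
        ]
        return cls(genes, payload.get("de_labels", {}))


@dataclass
class SimTranscriptome:
    """Sequences + models + truth emitted by :func:`simulate_transcriptome`."""

    models: list[TranscriptModel]
    sequences: dict[str, str]
    truth: SimTruth

    def write_fasta(self, path: str | Path) -> None:
        from .io import write_fasta

        write_fasta(self.sequences, path)

    def write_gtf(self, path: str | Path) -> None:
        from .io import write_gtf

        write_gtf(self.models, path)


def _draw_site_positions(rng, n_sites, utr5, cds, utr3, frac_stop) -> list[int]:
    length = utr5 + cds + utr3
    cds_end = utr5 + cds
    lo_stop = cds_end - max(int(round(0.2 * cds)), 5)
    hi_stop = cds_end + max(int(round(0.2 * utr3)), 5)
    positions: list[int] = []
    for _ in range(n_sites):
        for _attempt in range(200):
            if rng.random() < frac_stop:
                pos = int(rng.integers(lo_stop, hi_stop))
            else:
                pos = int(rng.integers(2, length - 3))
            pos = min(max(pos, 2), length - 4)
            if all(abs(pos - q) >= 6 for q in positions):
                positions.append(pos)
                break
        else:
            raise SimConfigError("could not place non-overlapping sites")
    return sorted(positions)


def _drach_5mer(rng) -> str:
    return (
        rng.choice(_D) + rng.choice(_R) + "A" + "C" + rng.choice(_H)
    )


def simulate_transcriptome(cfg: SimConfig) -> SimTranscriptome:
    """Generate sequences, annotation and per-gene planted sites.

    Each gene gets one transcript with segment lengths drawn uniformly from
    the configured ranges (CDS rounded to a codon multiple), one to three
    exons, a random strand, and DRACH 5-mers written at every planted site
    (the recorded site position is the center of the 5-mer).  Targets are a
    random subset of genes; they carry genotype-specific half-lives.
    """
    rng = cfg.rng(_S_TRANSCRIPTOME)
    target_idx = set(
        rng.choice(cfg.n_genes, size=cfg.n_targets, replace=False).tolist()
    )
    models: list[TranscriptModel] = []
    sequences: dict[str, str] = {}
    genes: list[GeneTruth] = []
    cursor = 1000
    chrom = "chrS"
    for i in range(cfg.n_genes):
        gene_id = f"G{i + 1:04d}"
        tx_id = f"T{i + 1:04d}"
        utr5 = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
        cds = int(rng.integers(cfg.cds_range[0], cfg.cds_range[1] + 1))
        cds -= cds % 3
        utr3 = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))
        length = utr5 + cds + utr3

        seq = rng.choice(_BASES, size=length)
        sites = _draw_site_positions(
            rng, cfg.n_sites_per_gene, utr5, cds, utr3, cfg.frac_stop_proximal
        )
        for pos in sites:
            seq[pos - 2:pos + 3] = list(_drach_5mer(rng))
        sequences[tx_id] = "".join(seq)

        n_exons = int(rng.integers(1, 4))
        if n_exons > 1:
            cuts = sorted(
                rng.choice(np.arange(1, length), size=n_exons - 1,
                           replace=False).tolist()
            )
        else:
            cuts = []
        bounds = [0, *cuts, length]
        exon_lens = [b - a for a, b in zip(bounds, bounds[1:])]
        strand = "+" if rng.random() < 0.5 else "-"
        genomic_order = exon_lens if strand == "+" else exon_lens[::-1]
        intervals = []
        pos = cursor
        for ln in genomic_order:
            intervals.append((pos, pos + ln))
            pos += ln + int(rng.integers(100, 501))
        cursor = pos + 500
        exons = tuple(intervals if strand == "+" else intervals[::-1])

        models.append(
            TranscriptModel(
                tx_id, gene_id, chrom, strand, exons,
                cds_start_tx=utr5, cds_end_tx=utr5 + cds,
            )
        )
        is_target = i in target_idx
        genes.append(
            GeneTruth(
                gene_id=gene_id,
                transcript_id=tx_id,
                sites=tuple(sites),
                is_target=is_target,
                halflife=(
                    {"WT": cfg.halflife_wt, "KO": cfg.halflife_ko}
                    if is_target else None
                ),
            )
        )
    return SimTranscriptome(models, sequences, SimTruth(genes))


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB counts with variance mean + dispersion * mean**2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_merip_counts(
    tr: SimTranscriptome, cfg: SimConfig
) -> WindowTable:
    """IP/input window counts per genotype x replicate.

    Input window means are ``window_depth`` scaled by a per-gene lognormal
    expression weight and the window length; IP means additionally carry
    ``site_enrichment`` at site-overlapping windows, times ``ko_effect`` in
    the knockout genotype at target genes.  Counts are negative binomial
    with the configured dispersion.
    """
    rng = cfg.rng(_S_MERIP)
    coords = peakcall.windows_for_models(tr.models, cfg.window, cfg.step)
    by_tx = tr.truth.by_transcript()

    weights = np.exp(
        rng.normal(-0.5 * cfg.expr_log_sd**2, cfg.expr_log_sd,
                   size=len(tr.models))
    )
    weight_of = {
        tm.transcript_id: w for tm, w in zip(tr.models, weights)
    }

    tx = coords["transcript_id"].to_numpy()
    ws = coords["window_start"].to_numpy()
    we = coords["window_end"].to_numpy()
    wlen = we - ws
    base_mean = (
        cfg.window_depth
        * np.array([weight_of[t] for t in tx])
        * wlen / cfg.window
    )
    overlaps_site = np.zeros(len(coords), dtype=bool)
    on_target = np.zeros(len(coords), dtype=bool)
    for i, (t, s, e) in enumerate(zip(tx, ws, we)):
        g = by_tx[t]
        if any(s <= pos < e for pos in g.sites):
            overlaps_site[i] = True
            on_target[i] = g.is_target

    df = coords.copy()
    wt_cond, ko_cond = cfg.conditions
    for cond in cfg.conditions:
        ip_mult = np.where(overlaps_site, cfg.site_enrichment, 1.0)
        if cond == ko_cond:
            ip_mult = np.where(
                overlaps_site & on_target, ip_mult * cfg.ko_effect, ip_mult
            )
        for rep in range(1, cfg.merip_replicates + 1):
            df[f"IP_{cond}_rep{rep}"] = _nb_draw(
                rng, base_mean * ip_mult, cfg.nb_dispersion
            )
            df[f"input_{cond}_rep{rep}"] = _nb_draw(
                rng, base_mean, cfg.nb_dispersion
            )
    return WindowTable(df, window=cfg.window, step=cfg.step)


def _lognormal_noise(rng, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size=size)


def simulate_decay(truth: SimTruth, cfg: SimConfig) -> pd.DataFrame:
    """Actinomycin-D chase time courses for target genes, both genotypes.

    ``value(t) = A0 * 2**(-t / halflife) * noise``; the reference species
    (an 18S rRNA stand-in, untouched by transcription inhibition on these
    time scales) is constant in expectation.
    """
    rng = cfg.rng(_S_DECAY)
    times = np.asarray(cfg.decay_timepoints, dtype=float)
    rows = []
    a0, ref0 = 100.0, 1000.0
    for g in truth.targets:
        for cond in cfg.conditions:
            hl = g.halflife[cond]
            for rep in range(1, cfg.decay_replicates + 1):
                vals = (
                    a0 * np.exp2(-times / hl)
                    * _lognormal_noise(rng, cfg.decay_noise_cv, len(times))
                )
                refs = ref0 * _lognormal_noise(
                    rng, cfg.decay_ref_noise_cv, len(times)
                )
                for t, v, r in zip(times, vals, refs):
                    rows.append(
                        {
                            "gene": g.gene_id, "genotype": cond,
                            "replicate": rep, "time_h": t,
                            "value": v, "reference_value": r,
                        }
                    )
    return pd.DataFrame(rows, columns=list(
        ("gene", "genotype", "replicate", "time_h", "value",
         "reference_value")
    ))


def simulate_qpcr(truth: SimTruth, cfg: SimConfig) -> pd.DataFrame:
    """Ct tables with a planted fold-change at target genes.

    ``Ct = baseline - log2(relative abundance) + N(0, sd)``; the reference
    gene (Gapdh stand-in) has equal abundance in both groups.
    """
    rng = cfg.rng(_S_QPCR)
    wt_cond, ko_cond = cfg.conditions
    rows = []
    for g in truth.genes:
        baseline = 24.0
        for cond in cfg.conditions:
            abundance = cfg.qpcr_fold if (g.is_target and cond == ko_cond) \
                else 1.0
            for rep in range(1, cfg.qpcr_replicates + 1):
                rows.append(
                    {
                        "gene": g.gene_id,
                        "group": cond,
                        "replicate": rep,
                        "ct_target": baseline - np.log2(abundance)
                        + rng.normal(0.0, cfg.qpcr_noise_sd),
                        "ct_ref": 18.0
                        + rng.normal(0.0, cfg.qpcr_noise_sd),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class ExpressionSim:
    """Expression matrix with planted differential-expression truth."""

    counts: pd.DataFrame            # gene x sample
    lengths: pd.Series              # effective lengths, nt
    conditions: dict[str, str]      # sample -> condition
    labels: pd.Series               # gene -> {up, down, ns} planted truth
    log2_fc: pd.Series              # planted effects


def simulate_expression(cfg: SimConfig) -> ExpressionSim:
    """Gene x sample NB count matrix with planted up/down genes.

    A fraction ``expr_de_frac`` of genes (half up, half down) carries a
    ``expr_de_log2fc`` shift in the second condition; the rest are null.
    """
    rng = cfg.rng(_S_EXPR)
    n = cfg.expr_n_genes
    genes = [f"EG{i + 1:05d}" for i in range(n)]
    mu = rng.lognormal(cfg.expr_mean_log, cfg.expr_sd_log, size=n)
    lengths = pd.Series(
        rng.integers(500, 5001, size=n), index=genes, name="length"
    )

    n_de = int(round(cfg.expr_de_frac * n))
    n_up = n_de // 2
    de_idx = rng.choice(n, size=n_de, replace=False)
    lfc = np.zeros(n)
    lfc[de_idx[:n_up]] = cfg.expr_de_log2fc
    lfc[de_idx[n_up:]] = -cfg.expr_de_log2fc

    cond1, cond2 = cfg.conditions
    cols, data, cond_map = [], [], {}
    for cond in (cond1, cond2):
        shift = 2.0 ** lfc if cond == cond2 else np.ones(n)
        for rep in range(1, cfg.expr_replicates + 1):
            name = f"{cond}_rep{rep}"
            cols.append(name)
            cond_map[name] = cond
            data.append(_nb_draw(rng, mu * shift, cfg.expr_dispersion))
    counts = pd.DataFrame(
        np.column_stack(data), index=genes, columns=cols
    )
    counts.index.name = "gene"
    labels = pd.Series(
        np.where(lfc > 0, "up", np.where(lfc < 0, "down", "ns")),
        index=genes, name="label",
    )
    return ExpressionSim(
        counts=counts,
        lengths=lengths,
        conditions=cond_map,
        labels=labels,
        log2_fc=pd.Series(lfc, index=genes, name="log2_fc"),
    )


def site_recovery(
    peaks: "peakcall.PeakSet", truth: SimTruth
) -> dict[str, float]:
    """Score called peaks against planted sites.

    A site counts as recovered when any peak on its transcript overlaps its
    position; a peak is a false call when it overlaps no planted site of
    its transcript.  Returns sensitivity and the false-discovery proportion
    together with the raw tallies.
    """
    by_tx = truth.by_transcript()
    n_sites = sum(len(g.sites) for g in truth.genes)
    recovered = 0
    false_peaks = 0
    for g in truth.genes:
        tx_peaks = [p for p in peaks if p.transcript_id == g.transcript_id]
        for pos in g.sites:
            if any(p.start <= pos < p.end for p in tx_peaks):
                recovered += 1
    for p in peaks:
        g = by_tx.get(p.transcript_id)
        sites = g.sites if g else ()
        if not any(p.start <= pos < p.end for pos in sites):
            false_peaks += 1
    n_peaks = len(peaks)
    return {
        "n_sites": n_sites,
        "n_recovered": recovered,
        "sensitivity": recovered / n_sites if n_sites else float("nan"),
        "n_peaks": n_peaks,
        "n_false_peaks": false_peaks,
        "fdp": false_peaks / n_peaks if n_peaks else 0.0,
    }
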