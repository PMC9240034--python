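"""File contracts: atomic writes, FASTA/GTF/BED/bedGraph/GMT, run manifests.

All outputs are written through a temp-then-rename contract so a failed
stage never leaves a partial file behind.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peakcall import PeakSet
from .transcript_model import TranscriptModel, transcript_interval_to_genomic


@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a temp file in the target directory, rename on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with atomic_write(path) as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_gtf(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Emit exon and CDS features in GTF (1-based closed) coordinates."""
    with atomic_write(path) as fh:
        for tm in models:
            attrs = (
                f'gene_id "{tm.gene_id}"; transcript_id "{tm.transcript_id}";'
            )
            for start, end in sorted(tm.exons):
                fh.write(
                    f"{tm.chrom}\tmeripkit\texon\t{start + 1}\t{end}\t.\t"
                    f"{tm.strand}\t.\t{attrs}\n"
                )
            if tm.is_coding:
                for start, end in transcript_interval_to_genomic(
                    tm, tm.cds_start_tx, tm.cds_end_tx
                ):
                    fh.write(
                        f"{tm.chrom}\tmeripkit\tCDS\t{start + 1}\t{end}\t.\t"
                        f"{tm.strand}\t.\t{attrs}\n"
                    )


def write_peaks_bed(peaks: PeakSet, path: str | Path) -> None:
    """Transcript-space BED6+2 (summit, n_windows as extra columns)."""
    with atomic_write(path) as fh:
        for i, p in enumerate(peaks, start=1):
            score = int(round(min(-10 * _log10(p.q_value), 1000)))
            fh.write(
                f"{p.transcript_id}\t{p.start}\t{p.end}\tpeak_{i}\t{score}\t"
                f"+\t{p.summit}\t{p.n_windows}\n"
            )


def write_peaks_genomic_bed(
    peaks: PeakSet, models: Mapping[str, TranscriptModel] | Sequence,
    path: str | Path,
) -> None:
    """Genome-projected BED6: one line per contiguous genomic block."""
    if not isinstance(models, Mapping):
        models = {tm.transcript_id: tm for tm in models}
    with atomic_write(path) as fh:
        for i, p in enumerate(peaks, start=1):
            tm = models.get(p.transcript_id)
            if tm is None:
                raise KeyError(f"no model for {p.transcript_id}")
            score = int(round(min(-10 * _log10(p.q_value), 1000)))
            end = min(p.end, tm.length_tx)
            for j, (g_start, g_end) in enumerate(
                transcript_interval_to_genomic(tm, p.start, end), start=1
            ):
                fh.write(
                    f"{tm.chrom}\t{g_start}\t{g_end}\tpeak_{i}.{j}\t{score}\t"
                    f"{tm.strand}\n"
                )


def write_bedgraph(windows: pd.DataFrame, path: str | Path,
                   value_column: str = "log2_enrichment") -> None:
    """Transcript-space bedGraph of a per-window statistic."""
    with atomic_write(path) as fh:
        for r in windows.itertuples(index=False):
            fh.write(
                f"{r.transcript_id}\t{r.window_start}\t{r.window_end}\t"
                f"{getattr(r, value_column):.6g}\n"
            )


def _log10(p: float) -> float:
    import math

    return math.log10(p) if p > 0 else -300.0


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description "
                    "and >= 1 gene"
                )
            sets[fields[0]] = fields[2:]
    return sets


def read_conditions(path: str | Path) -> dict[str, str]:
    """Sample-to-condition map from a two-column TSV (sample, condition)."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]], df[cols[1]]))


def write_conditions(conditions: Mapping[str, str], path: str | Path) -> None:
    with atomic_write(path) as fh:
        fh.write("sample\tcondition\n")
        for sample, cond in conditions.items():
            fh.write(f"{sample}\t{cond}\n")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, parameters: Mapping,
                   inputs: Iterable[str | Path] = ()) -> None:
    """Run manifest: package version, parameters, input checksums.

    Deliberately timestamp-free so identical runs produce identical bytes.
    """
    from . import __version__

    manifest = {
        "meripkit_version": __version__,
        "parameters": dict(parameters),
        # keyed by basename so identical runs in different directories
        # produce identical manifests
        "inputs": {
            Path(p).name: sha256_of(p) for p in inputs
        },
    }
    with atomic_write(path) as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
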