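"""Expression quantification, a stand-in differential test, and gene sets.

TPM converts raw counts to length-normalized transcripts-per-million (every
column sums to 1e6).  Size factors follow the median-of-ratios scheme
(per-sample median of count ratios to the geometric-mean pseudo-reference
over genes detected in all samples).  The differential test is deliberately
simple and fully characterized: a per-gene two-sided Welch t test on
log2(size-factor-normalized count + 0.5), with BH correction; it is *not* a
negative-binomial GLM, and its calibration is established by its own
simulation tests.  DEG classification applies literal thresholds: raw
p <= alpha and |log2 fold-change| >= 1.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peakcall import bh_adjust


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from a gene x sample count matrix.

    ``rate = count / (length/1000)``, scaled so each column sums to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index[:5].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    rates = counts.div(lengths / 1000.0, axis=0)
    col_sums = rates.sum(axis=0)
    if (col_sums == 0).any():
        dead = col_sums[col_sums == 0].index.tolist()
        raise ValueError(f"all-zero sample(s): {dead}")
    return rates.div(col_sums, axis=1) * 1e6


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors per sample.

    The pseudo-reference is the per-gene geometric mean across samples;
    factors are the per-sample median ratio to it, over genes with nonzero
    counts in every sample.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    detected = counts[(counts > 0).all(axis=1)]
    if detected.empty:
        raise ValueError(
            "no gene has nonzero counts in all samples; cannot compute "
            "size factors"
        )
    log_geomean = np.log(detected).mean(axis=1)
    ratios = np.log(detected).sub(log_geomean, axis=0)
    return np.exp(ratios.median(axis=0))


def _condition_arrays(
    counts: pd.DataFrame, conditions: Mapping[str, str]
) -> tuple[str, str, list[str], list[str]]:
    missing = [s for s in counts.columns if s not in conditions]
    if missing:
        raise ValueError(f"samples without condition label: {missing}")
    levels = list(dict.fromkeys(conditions[s] for s in counts.columns))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {sorted(levels)}")
    cond1, cond2 = levels  # first-appearance order: reference first
    g1 = [s for s in counts.columns if conditions[s] == cond1]
    g2 = [s for s in counts.columns if conditions[s] == cond2]
    return cond1, cond2, g1, g2


def de_test(
    counts: pd.DataFrame,
    conditions: Mapping[str, str],
    condition_pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression between two conditions.

    Welch t on ``log2(count / size_factor + 0.5)``; the reported log2
    fold-change is condition2 minus condition1 on that scale (by default
    condition1 is the condition of the first sample column, so column order
    encodes reference vs treatment; override with ``condition_pair``).  Requires
    >= 2 replicates per condition.  Returns a frame indexed by gene with
    log2_fc, p_value and BH q_value.
    """
    if condition_pair is None:
        cond1, cond2, g1, g2 = _condition_arrays(counts, conditions)
    else:
        cond1, cond2 = condition_pair
        g1 = [s for s in counts.columns if conditions.get(s) == cond1]
        g2 = [s for s in counts.columns if conditions.get(s) == cond2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 replicates per condition")
    sf = size_factors(counts[g1 + g2])
    norm = counts[g1 + g2].div(sf, axis=1)
    logn = np.log2(norm + 0.5)
    x1 = logn[g1].to_numpy()
    x2 = logn[g2].to_numpy()
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # constant genes trip scipy's moment precision warning; they are
        # mapped to p = 1 below
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        _, p = stats.ttest_ind(x2, x1, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance degenerate genes
    log2_fc = x2.mean(axis=1) - x1.mean(axis=1)
    out = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p_value": p,
            "q_value": bh_adjust(p),
        },
        index=counts.index,
    )
    out.index.name = "gene"
    out.attrs["condition_pair"] = (cond1, cond2)
    return out


def classify_deg(
    results: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    use_adjusted: bool = False,
) -> pd.Series:
    """Label genes up/down/ns by the literal significance thresholds.

    ``up`` iff p <= alpha and log2_fc >= lfc_threshold; ``down`` iff
    p <= alpha and log2_fc <= -lfc_threshold; otherwise ``ns``.  Boundaries
    are inclusive.  The raw p-value is used by default; set
    ``use_adjusted=True`` to threshold the BH q-value instead.
    """
    pcol = "q_value" if use_adjusted else "p_value"
    for col in (pcol, "log2_fc"):
        if col not in results.columns:
            raise ValueError(f"results missing column {col!r}")
    p = results[pcol]
    fc = results["log2_fc"]
    cls = pd.Series("ns", index=results.index, name="class")
    cls[(p <= alpha) & (fc >= lfc_threshold)] = "up"
    cls[(p <= alpha) & (fc <= -lfc_threshold)] = "down"
    return cls


def geneset_enrichment(
    deg_genes: Iterable[str],
    universe: Iterable[str],
    sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    For a universe of M genes, a set of K and a DEG list of n, the p-value
    is the upper tail P(overlap >= k); BH correction runs across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    deg = set(deg_genes)
    stray = deg - universe
    if stray:
        raise ValueError(f"DEG genes outside universe, e.g. {sorted(stray)[:5]}")
    rows = []
    for name in sorted(sets):
        members = set(sets[name])
        stray = members - universe
        if stray:
            raise ValueError(
                f"set {name!r} has genes outside universe, "
                f"e.g. {sorted(stray)[:5]}"
            )
        k = len(members & deg)
        p = stats.hypergeom.sf(k - 1, len(universe), len(members), len(deg))
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "n_deg": len(deg),
                "overlap": k,
                "p_value": float(min(p, 1.0)),
            }
        )
    out = pd.DataFrame(
        rows, columns=["set", "set_size", "n_deg", "overlap", "p_value"]
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out
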