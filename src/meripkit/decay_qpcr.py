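"""qPCR relative quantification and actinomycin-D decay analysis.

Relative expression follows the ddCt rule (2 to the minus delta-delta-Ct,
with Ct differences taken against a reference gene and a calibrator
sample).  Decay time courses are first normalized to a stable reference
species (an 18S rRNA stand-in) and then to the t = 0 h point, giving a
residual fraction; a log-linear least-squares fit of ln(fraction) on time
yields the first-order decay rate k and half-life ln2/k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DECAY_COLUMNS = ("gene", "genotype", "replicate", "time_h", "value",
                 "reference_value")


def ddct(
    ct_target,
    ct_ref,
    calibrator_target,
    calibrator_ref,
):
    """Relative expression by the delta-delta-Ct method.

    ``2 ** -((ct_target - ct_ref) - (calibrator_target - calibrator_ref))``;
    one PCR cycle corresponds to a factor of two, so a target Ct one cycle
    below the calibrator (references equal) doubles the output.
    """
    arrays = [np.asarray(a, dtype=float)
              for a in (ct_target, ct_ref, calibrator_target, calibrator_ref)]
    if any(not np.isfinite(a).all() for a in arrays):
        raise ValueError("non-finite Ct value")
    ct_t, ct_r, cal_t, cal_r = arrays
    out = 2.0 ** (-((ct_t - ct_r) - (cal_t - cal_r)))
    return float(out) if out.ndim == 0 else out


def ddct_table(
    ct: pd.DataFrame,
    condition_ref: str = "WT",
    condition_alt: str = "KO",
) -> pd.DataFrame:
    """Per-gene relative expression (alt vs ref) from a Ct table.

    Expects columns gene, group, replicate, ct_target, ct_ref.  Per sample,
    ``dCt = ct_target - ct_ref``; the calibrator is the reference group's
    mean dCt, so the reported fold change is ``2 ** -(mean dCt_alt - mean
    dCt_ref)``.  A two-tailed Welch t test on the per-sample dCt values
    provides the p-value; BH correction runs across genes.
    """
    needed = {"gene", "group", "ct_target", "ct_ref"}
    missing = needed - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    rows = []
    for gene, grp in ct.groupby("gene", sort=True):
        dct = grp["ct_target"] - grp["ct_ref"]
        ref = dct[grp["group"] == condition_ref]
        alt = dct[grp["group"] == condition_alt]
        if ref.empty or alt.empty:
            raise ValueError(f"gene {gene}: missing group measurements")
        fold = 2.0 ** (-(alt.mean() - ref.mean()))
        if len(ref) > 1 and len(alt) > 1:
            p = float(stats.ttest_ind(alt, ref, equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append({
            "gene": gene,
            f"n_{condition_ref}": len(ref),
            f"n_{condition_alt}": len(alt),
            "fold_change": float(fold),
            "log2_fold_change": float(np.log2(fold)),
            "p_value": p,
        })
    out = pd.DataFrame(rows)
    from .peakcall import bh_adjust

    valid = out["p_value"].notna()
    out["q_value"] = np.nan
    if valid.any():
        out.loc[valid, "q_value"] = bh_adjust(out.loc[valid, "p_value"])
    return out


def _validate_decay_table(df: pd.DataFrame) -> None:
    missing = [c for c in DECAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"decay table missing columns {missing}")


def normalize_decay(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``fraction`` column: reference-normalized abundance over t = 0.

    Per (gene, genotype, replicate) series: ``ratio = value /
    reference_value`` and ``fraction(t) = ratio(t) / ratio(0)``.  Requires a
    t = 0 row and strictly positive reference values in every series; the
    fraction at t = 0 is exactly 1 by construction.
    """
    _validate_decay_table(df)
    if (df["reference_value"] <= 0).any():
        raise ValueError("non-positive reference_value")
    out = df.copy()
    ratio = out["value"] / out["reference_value"]
    out["_ratio"] = ratio
    keys = ["gene", "genotype", "replicate"]

    def _norm(grp: pd.DataFrame) -> pd.Series:
        at0 = grp.loc[grp["time_h"] == 0, "_ratio"]
        if at0.empty:
            raise ValueError(
                f"series {tuple(grp[keys].iloc[0])} lacks a t=0 measurement"
            )
        return grp["_ratio"] / at0.mean()

    parts = [
        _norm(grp) for _, grp in out.groupby(keys, sort=False)
    ]
    out["fraction"] = pd.concat(parts).reindex(out.index)
    return out.drop(columns="_ratio")


@dataclass
class DecayFit:
    """Log-linear first-order decay fit."""

    k: float               # decay rate, per hour (positive when decaying)
    half_life: float       # ln2 / k; +inf for a non-decaying series
    intercept: float       # fitted ln(fraction) at t = 0
    r_squared: float
    se_k: float
    n_points: int
    non_decaying: bool

    def __post_init__(self) -> None:
        if self.k > 0 and np.isfinite(self.half_life):
            assert abs(self.half_life * self.k - np.log(2.0)) < 1e-9


def fit_halflife(time_h, fraction) -> DecayFit:
    """Fit ln(fraction) = a - k t by ordinary least squares.

    The intercept is free: multiplicative noise in the t = 0 measurement is
    absorbed there rather than forced into the slope.  A non-decaying series
    (slope >= 0) is reported with k <= 0 and an infinite half-life, not an
    exception.
    """
    t = np.asarray(time_h, dtype=float)
    f = np.asarray(fraction, dtype=float)
    if t.shape != f.shape or t.ndim != 1:
        raise ValueError("time_h and fraction must be equal-length 1-D")
    if len(np.unique(t)) < 3:
        raise ValueError("need measurements at >= 3 distinct timepoints")
    if (f <= 0).any():
        raise ValueError("fractions must be > 0 for the log-linear fit")
    res = stats.linregress(t, np.log(f))
    k = -res.slope
    non_decaying = k <= 0
    return DecayFit(
        k=float(k),
        half_life=float(np.log(2.0) / k) if k > 0 else float("inf"),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        se_k=float(res.stderr),
        n_points=len(t),
        non_decaying=bool(non_decaying),
    )


def fit_halflives(df: pd.DataFrame, per_replicate: bool = False) -> pd.DataFrame:
    """Half-life fits per (gene, genotype) from a normalized decay table.

    Replicate series are pooled into one regression by default; with
    ``per_replicate=True`` each replicate is fitted separately.
    """
    if "fraction" not in df.columns:
        df = normalize_decay(df)
    keys = ["gene", "genotype"] + (["replicate"] if per_replicate else [])
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        fit = fit_halflife(grp["time_h"], grp["fraction"])
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.update(
            k=fit.k, half_life_h=fit.half_life, intercept=fit.intercept,
            r_squared=fit.r_squared, se_k=fit.se_k, n_points=fit.n_points,
            non_decaying=fit.non_decaying,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class StabilityComparison:
    """Genotype comparison of one gene's decay behaviour."""

    per_timepoint: pd.DataFrame  # time_h, mean_ref, mean_alt, t_stat, p_value
    halflife_ref: float
    halflife_alt: float
    difference: float            # alt - ref; negative = destabilized in alt
    ci_low: float
    ci_high: float
    n_boot: int


def compare_stability(
    ref: pd.DataFrame,
    alt: pd.DataFrame,
    n_boot: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> StabilityComparison:
    """Compare residual-fraction decay between two genotypes of one gene.

    Per timepoint (t > 0), a two-tailed Welch t test on the replicate
    residual fractions; on top, the half-life difference alt - ref with a
    percentile bootstrap CI obtained by resampling replicate series with
    replacement within each genotype and refitting the pooled regression.
    Negative differences mean the transcript is destabilized in the
    alternative genotype.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    groups = []
    for df in (ref, alt):
        if "fraction" not in df.columns:
            df = normalize_decay(df)
        groups.append(df)
    ref, alt = groups

    times = sorted(set(ref["time_h"]) & set(alt["time_h"]))
    rows = []
    for t in times:
        if t == 0:
            continue
        a = ref.loc[ref["time_h"] == t, "fraction"].to_numpy()
        b = alt.loc[alt["time_h"] == t, "fraction"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >= 2 replicates per group at t={t}")
        stat, p = stats.ttest_ind(b, a, equal_var=False)
        rows.append(
            {
                "time_h": t, "mean_ref": a.mean(), "mean_alt": b.mean(),
                "t_stat": float(stat), "p_value": float(p),
            }
        )

    hl_ref = fit_halflife(ref["time_h"], ref["fraction"]).half_life
    hl_alt = fit_halflife(alt["time_h"], alt["fraction"]).half_life
    diff = hl_alt - hl_ref

    def _boot_halflife(df: pd.DataFrame) -> float:
        reps = df["replicate"].unique()
        take = rng.choice(reps, size=len(reps), replace=True)
        parts = [df[df["replicate"] == r] for r in take]
        pooled = pd.concat(parts)
        return fit_halflife(pooled["time_h"], pooled["fraction"]).half_life

    boot = np.array(
        [_boot_halflife(alt) - _boot_halflife(ref) for _ in range(n_boot)]
    )
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    return StabilityComparison(
        per_timepoint=pd.DataFrame(rows),
        halflife_ref=float(hl_ref),
        halflife_alt=float(hl_alt),
        difference=float(diff),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
    )
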