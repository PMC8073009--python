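"""Relative fitness from pooled barcoded competition counts.

In a pooled competition the log2 ratio of UMI-collapsed barcode counts for a
strain pair changes linearly with the number of generations; the slope is
the relative fitness coefficient s (relative growth rate 1 + s). This module
implements the slope estimator with Poisson counting-noise error bars,
timepoint-bootstrap slope ranges, the closed-form least-squares design
precision, the isogenic-pair precision audit, control background
subtraction, a bootstrap rescue-significance test, and index cross-talk
quantification from spike-in matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LN2 = math.log(2.0)

COUNT_COLUMNS = [
    "experiment",
    "condition",
    "timepoint",
    "generations",
    "barcode",
    "genotype",
    "count",
]


# --------------------------------------------------------------- containers
@dataclass
class FitnessEstimate:
    """Least-squares slope of log2 barcode ratio vs. generations."""

    s: float
    intercept: float
    ci95: tuple[float, float]
    boot_range: tuple[float, float]
    n_timepoints: int
    dropped_timepoints: int = 0
    stderr: float = float("nan")

    def __post_init__(self) -> None:
        lo, hi = self.boot_range
        if not (lo - 1e-12 <= self.s <= hi + 1e-12):
            raise ValueError("bootstrap range must bracket the point estimate")


@dataclass
class DesignParams:
    sigma_log2r: float
    n_t: int
    tgen_tot: float

    def __post_init__(self) -> None:
        if self.n_t < 2:
            raise ValueError("need at least two sampling points")
        if self.tgen_tot <= 0:
            raise ValueError("total generations must be positive")


# ------------------------------------------------------------ UMI collapse
def collapse_umis(reads: pd.DataFrame, umi_length: int | None = None):
    """Collapse a (sample, barcode, UMI) read table to molecule counts.

    The count for each (sample, barcode) is the number of distinct UMI
    strings (exact-string collapse). Rows whose UMI length differs from
    ``umi_length`` (default: the length of the first UMI) are skipped and
    reported.

    Returns ``(counts, errors)``: a DataFrame with columns
    sample/barcode/count, and a DataFrame of skipped rows.
    """
    if reads.empty:
        empty = pd.DataFrame(columns=["sample", "barcode", "count"])
        return empty, reads.copy()
    umis = reads["umi"].astype(str)
    if umi_length is None:
        umi_length = len(umis.iloc[0])
    ok = umis.str.len() == umi_length
    errors = reads.loc[~ok].copy()
    counts = (
        reads.loc[ok]
        .groupby(["sample", "barcode"], sort=True)["umi"]
        .nunique()
        .rename("count")
        .reset_index()
    )
    return counts, errors


# -------------------------------------------------------- generations axis
def generations_from_dilution(factor) -> np.ndarray | float:
    """Generations per transfer, -log2(dilution factor).

    ``factor`` is the dilution factor in (0, 1), e.g. 70 ul into 16 ml is
    70e-3 / 16 ~ 0.00437 and gives about 7.8 generations.
    """
    arr = np.asarray(factor, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("dilution factor must be in (0, 1)")
    out = -np.log2(arr)
    return float(out) if np.isscalar(factor) else out


def generations_axis(dilution_factors) -> np.ndarray:
    """Cumulative generations at each harvest (harvest 0 at Tgen = 0)."""
    incs = np.atleast_1d(generations_from_dilution(dilution_factors))
    return np.concatenate([[0.0], np.cumsum(incs)])


# ------------------------------------------------------- ratio trajectories
def poisson_log2_error(n1, n2):
    """Poisson counting-noise s.d. of a log2 count ratio.

    sigma_r = (1/ln 2) * sqrt(1/N1 + 1/N2), from error propagation on
    independent Poisson counts.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(divide="ignore"):
        return np.sqrt(1.0 / n1 + 1.0 / n2) / LN2


def ratio_trajectory(
    counts: pd.DataFrame, barcode1: str, barcode2: str, condition=None
) -> pd.DataFrame:
    """Log2 count-ratio trajectory for one strain pair.

    Timepoints where either strain has a zero count are retained in the
    output with ``usable = False`` (the fit drops and flags them).
    """
    df = counts
    if condition is not None:
        df = df[df["condition"] == condition]
    a = df[df["barcode"] == barcode1].set_index("timepoint")
    b = df[df["barcode"] == barcode2].set_index("timepoint")
    common = a.index.intersection(b.index).sort_values()
    n1 = a.loc[common, "count"].to_numpy(dtype=float)
    n2 = b.loc[common, "count"].to_numpy(dtype=float)
    tgen = a.loc[common, "generations"].to_numpy(dtype=float)
    usable = (n1 > 0) & (n2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log2(n1 / n2)
    return pd.DataFrame(
        {
            "timepoint": common,
            "generations": tgen,
            "log2_ratio": r,
            "sigma_r": poisson_log2_error(n1, n2),
            "n1": n1,
            "n2": n2,
            "usable": usable,
        }
    )


# ------------------------------------------------------------- slope fits
def fit_relative_fitness(
    traj: pd.DataFrame, n_boot: int = 200, seed: int | None = 0
) -> FitnessEstimate:
    """OLS slope of log2 ratio vs. generations with a bootstrap range.

    Timepoints with a zero count in either strain (``usable == False``) are
    dropped and counted in ``dropped_timepoints``. The 95% CI is t-based on
    the slope standard error; the bootstrap range is the min/max slope over
    ``n_boot`` refits on timepoints resampled with replacement.
    """
    df = traj
    dropped = 0
    if "usable" in df.columns:
        dropped = int((~df["usable"]).sum())
        df = df[df["usable"]]
    x = df["generations"].to_numpy(dtype=float)
    y = df["log2_ratio"].to_numpy(dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    dropped += int((~finite).sum())
    x, y = x[finite], y[finite]
    if len(x) < 2 or len(np.unique(x)) < 2:
        raise ValueError("need at least two usable timepoints with distinct generations")

    if np.allclose(y, y[0]):
        return FitnessEstimate(
            s=0.0,
            intercept=float(y[0]),
            ci95=(0.0, 0.0),
            boot_range=(0.0, 0.0),
            n_timepoints=len(x),
            dropped_timepoints=dropped,
            stderr=0.0,
        )

    res = stats.linregress(x, y)
    slope, intercept, se = float(res.slope), float(res.intercept), float(res.stderr)
    if len(x) > 2 and np.isfinite(se):
        tcrit = stats.t.ppf(0.975, len(x) - 2)
        ci = (slope - tcrit * se, slope + tcrit * se)
    else:
        ci = (-np.inf, np.inf)

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), size=len(x))
        if len(np.unique(x[idx])) < 2:
            continue
        boots.append(np.polyfit(x[idx], y[idx], 1)[0])
    if boots:
        lo, hi = min(min(boots), slope), max(max(boots), slope)
    else:
        lo = hi = slope
    return FitnessEstimate(
        s=slope,
        intercept=intercept,
        ci95=ci,
        boot_range=(float(lo), float(hi)),
        n_timepoints=len(x),
        dropped_timepoints=dropped,
        stderr=se,
    )


def design_precision(params: DesignParams) -> float:
    """Closed-form s.d. of the least-squares slope under iid ratio noise.

    For n_t evenly spaced samplings spanning Tgen_tot generations with iid
    log2-ratio noise of s.d. sigma_log2r,

        sigma_sLS = sigma_log2r * sqrt(12 (n_t - 1) / (n_t (n_t + 1))) / Tgen_tot,

    the exact standard error of the OLS slope for that design.
    """
    p = params
    return p.sigma_log2r * math.sqrt(12.0 * (p.n_t - 1) / (p.n_t * (p.n_t + 1))) / p.tgen_tot


# ------------------------------------------------------------- audits
def isogenic_precision(s_values) -> dict:
    """Precision audit from same-genotype (isogenic) strain pairs.

    Returns the s.d. across pairs (sigma_s), the median absolute s, the
    measurement resolution defined as +/- 2 sigma_s, and the raw values.
    """
    arr = np.asarray(list(s_values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two isogenic pairs")
    sigma = float(np.std(arr, ddof=1))
    return {
        "sigma_s": sigma,
        "median_abs_s": float(np.median(np.abs(arr))),
        "resolution": 2.0 * sigma,
        "n_pairs": int(arr.size),
        "values": arr,
    }


def subtract_background(s_values, control_mean: float):
    """Subtract the mean control-genotype fitness: s_adj = s - <s_control>."""
    arr = np.asarray(s_values, dtype=float)
    out = arr - float(control_mean)
    return float(out) if np.isscalar(s_values) else out


def rescue_significance(
    focal,
    background,
    n_resample: int = 100_000,
    seed: int | None = 0,
    direction: str = "greater",
) -> float:
    """Bootstrap-subsampling test for a shift between two sets of fitness differences.

    Repeatedly draws ``len(focal)`` values with replacement from the
    background set and from the focal set and compares the medians. The
    p-value is the fraction of draws in which the background median is more
    extreme than the focal median (``direction='greater'``: background
    median >= focal median; ``'less'``: <=).
    """
    f = np.asarray(list(focal), dtype=float)
    b = np.asarray(list(background), dtype=float)
    if f.size == 0 or b.size == 0:
        raise ValueError("focal and background sets must be non-empty")
    rng = np.random.default_rng(seed)
    n_f = f.size
    fm = np.median(rng.choice(f, size=(n_resample, n_f), replace=True), axis=1)
    bm = np.median(rng.choice(b, size=(n_resample, n_f), replace=True), axis=1)
    if direction == "greater":
        hits = bm >= fm
    elif direction == "less":
        hits = bm <= fm
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return float(hits.mean())


def crosstalk_rates(matrix, expected_positions) -> dict:
    """Index cross-talk fractions from a spike-in count matrix.

    ``matrix`` is (PCR1 index x PCR2 index) read counts; ``expected_positions``
    are (row, col) cells where spike-ins were actually added. Columns with no
    expected cell correspond to pools the spike-in never entered, so any read
    there is inter-pool cross-talk; within expected columns, reads at wrong
    rows are intra-pool cross-talk.
    """
    m = np.asarray(matrix, dtype=float)
    expected = set((int(r), int(c)) for r, c in expected_positions)
    total = m.sum()
    if total == 0:
        raise ValueError("empty spike-in matrix")
    expected_cols = {c for _, c in expected}
    inter = sum(m[:, c].sum() for c in range(m.shape[1]) if c not in expected_cols)
    in_expected_cols = sum(m[:, c].sum() for c in expected_cols)
    correct = sum(m[r, c] for r, c in expected)
    intra = in_expected_cols - correct
    return {
        "inter_pool": float(inter / total),
        "intra_pool": float(intra / in_expected_cols) if in_expected_cols else 0.0,
        "correct_fraction": float(correct / total),
    }


# ----------------------------------------------------- per-genotype report
def genotype_report(
    counts: pd.DataFrame,
    reference_genotype: str,
    n_boot: int = 200,
    seed: int = 0,
    min_count: int = 0,
) -> pd.DataFrame:
    """Fit all (strain, reference) pairs per condition and summarize per genotype.

    Every barcode of every non-reference genotype is compared against every
    reference barcode; the per-genotype summary is the median s with 25th and
    75th percentiles across pairs (the field's usual reporting convention).
    """
    rows = []
    rng = np.random.default_rng(seed)
    for condition, sub in counts.groupby("condition"):
        refs = sub.loc[sub["genotype"] == reference_genotype, "barcode"].unique()
        others = sub[sub["genotype"] != reference_genotype]
        for genotype, gsub in others.groupby("genotype"):
            for bc in gsub["barcode"].unique():
                for ref in refs:
                    traj = ratio_trajectory(sub, bc, ref)
                    traj.loc[(traj["n1"] < min_count) | (traj["n2"] < min_count), "usable"] = False
                    try:
                        est = fit_relative_fitness(
                            traj, n_boot=n_boot, seed=int(rng.integers(2**31))
                        )
                    except ValueError:
                        continue
                    rows.append(
                        {
                            "condition": condition,
                            "genotype": genotype,
                            "barcode": bc,
                            "reference_barcode": ref,
                            "s": est.s,
                            "s_min": est.boot_range[0],
                            "s_max": est.boot_range[1],
                            "n_timepoints": est.n_timepoints,
                            "dropped": est.dropped_timepoints,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_genotypes(pair_estimates: pd.DataFrame) -> pd.DataFrame:
    """Median s with interquartile bars per (condition, genotype)."""
    return (
        pair_estimates.groupby(["condition", "genotype"])["s"]
        .agg(
            s_median="median",
            s_q25=lambda v: float(np.percentile(v, 25)),
            s_q75=lambda v: float(np.percentile(v, 75)),
            n_pairs="count",
        )
        .reset_index()
    )
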