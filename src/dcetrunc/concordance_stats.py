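"""Agreement statistics for paired ATC-vs-FTC parameter estimates.

Lin's concordance correlation coefficient measures agreement with the
identity line,

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2),

with moments in the population (1/n) convention; it satisfies
CCC <= |r| with equality only when the pairs already lie on a line
through the origin of the identity.  The module also provides ROI means
with voxelwise t-based 95% CIs, the absolute average percent error with
its CI, a paired across-patient significance test (Wilcoxon signed-rank
by default), the assembled concordance table, and the census of patients
meeting a CCC cut-off at each truncation length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceTable",
    "CutoffCensus",
    "ccc",
    "pearson_r",
    "mean_abs_pct_error",
    "roi_summary",
    "paired_test",
    "build_concordance_table",
    "cutoff_census",
]


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient of paired vectors.

    Undefined (both inputs constant with equal means) raises
    ``ValueError`` rather than returning silently.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two aligned 1-D vectors of length >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    sx = x.var()
    sy = y.var()
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    denom = sx + sy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both vectors constant with equal means")
    return float(2.0 * sxy / denom)


def pearson_r(x, y) -> float:
    """Pearson correlation; zero-variance inputs raise ``ValueError``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two aligned 1-D vectors of length >= 2")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("Pearson r undefined for constant input")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std()))


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    mean = float(np.mean(values))
    n = values.size
    if n < 2:
        return mean, mean, mean
    se = float(np.std(values, ddof=1) / np.sqrt(n))
    q = stats.t.ppf(0.5 + level / 2.0, n - 1)
    return mean, mean - q * se, mean + q * se


def roi_summary(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean over the ROI with a voxelwise t-based confidence interval."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    return _t_ci(v, level)


def mean_abs_pct_error(atc_vals, ftc_vals, level: float = 0.95):
    """Mean over voxels of ``100 |atc - ftc| / |ftc|`` with a t-based CI.

    Voxels whose gold-standard value is exactly zero are excluded; the
    count of exclusions is returned last.
    """
    a = np.asarray(atc_vals, dtype=float)
    f = np.asarray(ftc_vals, dtype=float)
    if a.shape != f.shape:
        raise ValueError("paired vectors must align")
    ok = f != 0
    n_excluded = int((~ok).sum())
    if not np.any(ok):
        raise ValueError("all voxels excluded (zero gold-standard values)")
    err = 100.0 * np.abs(a[ok] - f[ok]) / np.abs(f[ok])
    mean, lo, hi = _t_ci(err, level)
    return mean, lo, hi, n_excluded


def paired_test(ftc_means, atc_means, method: str = "wilcoxon") -> float:
    """Two-sided paired significance test across patients.

    Defaults to the Wilcoxon signed-rank test (no normality assumption at
    n = 15); a paired t-test is available.  All-equal pairs are a
    degenerate case and return p = 1.
    """
    f = np.asarray(ftc_means, dtype=float)
    a = np.asarray(atc_means, dtype=float)
    if f.shape != a.shape or f.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    d = a - f
    if np.all(d == 0):
        return 1.0
    if method == "wilcoxon":
        return float(stats.wilcoxon(a, f, alternative="two-sided").pvalue)
    if method == "ttest":
        return float(stats.ttest_rel(a, f).pvalue)
    raise ValueError(f"unknown method {method!r}")


class ConcordanceTable(pd.DataFrame):
    """Per-(patient, model, param, ATC) agreement summary (a DataFrame)."""

    @property
    def _constructor(self):
        return ConcordanceTable


def build_concordance_table(
    paired_tables: pd.DataFrame | list,
    test_method: str = "wilcoxon",
    min_voxels: int = 2,
) -> ConcordanceTable:
    """Assemble the agreement table from tidy paired estimates.

    Accepts one tidy table or a list of :class:`PairedEstimates` /
    DataFrames with columns (patient, model, atc_n, voxel, param,
    value_atc, value_ftc, kept).  Only kept voxels enter.  CCC-undefined
    cells are recorded as NaN.  The across-patient paired test is run per
    (model, param, atc_n) on the patient ROI means and merged onto each
    row.
    """
    if isinstance(paired_tables, list):
        frames = [
            p.table if hasattr(p, "table") else p for p in paired_tables
        ]
        tidy = pd.concat(frames, ignore_index=True)
    else:
        tidy = paired_tables
    tidy = tidy[tidy["kept"]]

    rows = []
    for (patient, model, param, atc_n), g in tidy.groupby(
        ["patient", "model", "param", "atc_n"], sort=True
    ):
        a = g["value_atc"].to_numpy(dtype=float)
        f = g["value_ftc"].to_numpy(dtype=float)
        if a.size < min_voxels:
            continue
        mean, lo, hi = roi_summary(a)
        err, err_lo, err_hi, _ = mean_abs_pct_error(a, f)
        try:
            c = ccc(a, f)
        except ValueError:
            c = np.nan
        try:
            r = pearson_r(a, f)
        except ValueError:
            r = np.nan
        rows.append(
            {
                "patient": patient,
                "model": model,
                "param": param,
                "atc_n": atc_n,
                "roi_mean": mean,
                "ci_low": lo,
                "ci_high": hi,
                "mean_abs_pct_err": err,
                "err_ci_low": err_lo,
                "err_ci_high": err_hi,
                "ccc": c,
                "pearson_r": r,
                "n_voxels": a.size,
            }
        )
    table = pd.DataFrame(rows)

    # cohort-level paired test on patient ROI means of ATC vs FTC values
    pvals = {}
    ftc_means = tidy.groupby(["patient", "model", "param", "atc_n"]).agg(
        ftc_mean=("value_ftc", "mean"), atc_mean=("value_atc", "mean")
    )
    for (model, param, atc_n), g in ftc_means.groupby(["model", "param", "atc_n"]):
        if len(g) >= 3:
            try:
                pvals[(model, param, atc_n)] = paired_test(
                    g["ftc_mean"], g["atc_mean"], method=test_method
                )
            except ValueError:
                pvals[(model, param, atc_n)] = np.nan
    table["p_paired"] = [
        pvals.get((m, p, n), np.nan)
        for m, p, n in zip(table["model"], table["param"], table["atc_n"])
    ]
    return ConcordanceTable(table)


@dataclass(frozen=True)
class CutoffCensus:
    """How many patients meet a CCC cut-off at each truncation length."""

    cutoff: float
    param: str
    counts: dict  # atc_n -> number of patients with ccc >= cutoff
    shortest_atc: int | None  # shortest ATC achieving the maximum count
    max_count: int
    ccc_mean: float  # mean of CCCs at that ATC
    ccc_sd: float
    n_undefined: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"atc_n": list(self.counts), "n_meeting": list(self.counts.values())}
        )


def cutoff_census(table: pd.DataFrame, param: str, cutoff: float, model: str | None = None) -> CutoffCensus:
    """Census of patients whose CCC meets ``cutoff`` (>=) per ATC.

    Returns per-ATC counts, the shortest ATC attaining the maximum count,
    and the mean/SD of the CCCs at that ATC.  Undefined (NaN) CCCs are
    excluded and counted.
    """
    sub = table[table["param"] == param]
    if model is not None:
        sub = sub[sub["model"] == model]
    n_undefined = int(sub["ccc"].isna().sum())
    sub = sub.dropna(subset=["ccc"])
    counts = {
        int(n): int((g["ccc"] >= cutoff).sum())
        for n, g in sub.groupby("atc_n", sort=True)
    }
    if not counts:
        return CutoffCensus(cutoff, param, {}, None, 0, np.nan, np.nan, n_undefined)
    max_count = max(counts.values())
    shortest = next(n for n in sorted(counts) if counts[n] == max_count)
    at = sub[sub["atc_n"] == shortest]["ccc"].to_numpy(dtype=float)
    return CutoffCensus(
        cutoff=cutoff,
        param=param,
        counts=counts,
        shortest_atc=int(shortest),
        max_count=int(max_count),
        ccc_mean=float(np.mean(at)),
        ccc_sd=float(np.std(at, ddof=1)) if at.size > 1 else 0.0,
        n_undefined=n_undefined,
    )
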