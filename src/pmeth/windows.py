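"""Fixed-window methylation tracks: tiling, smoothing, densities, correlation.

A *window track* is a DataFrame with columns ``chrom, start, end, mean_meth,
n_cpgs``: non-overlapping abutting windows, ascending within chromosome.
``mean_meth`` is the unweighted mean of per-site methylation fractions of
covered CpGs in the window and is NaN ("missing") for windows with fewer
than the minimum number of informative CpG sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

WINDOW_COLUMNS = ["chrom", "start", "end", "mean_meth", "n_cpgs"]


def window_methylation(
    calls: pd.DataFrame,
    window_size: int,
    min_cpgs: int = 20,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Average per-site methylation fractions in non-overlapping windows.

    Windows with fewer than ``min_cpgs`` CpG sites carrying methylation
    information are reported with ``mean_meth`` NaN.  The last, partial
    window of each chromosome is kept if it meets the filter.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if min_cpgs < 1:
        raise ValueError("min_cpgs must be >= 1")
    if calls.empty:
        return pd.DataFrame(columns=WINDOW_COLUMNS)

    informative = calls[calls["fraction"].notna()]
    parts = []
    chroms = (
        list(chrom_sizes) if chrom_sizes is not None
        else list(pd.unique(calls["chrom"]))
    )
    by_chrom = dict(tuple(informative.groupby("chrom", sort=False)))
    for chrom in chroms:
        grp = by_chrom.get(chrom)
        if chrom_sizes is not None:
            n_win = int(np.ceil(chrom_sizes[chrom] / window_size))
        elif grp is not None and len(grp):
            n_win = int(grp["pos"].max() // window_size) + 1
        else:
            continue
        n = np.zeros(n_win, dtype=np.int64)
        s = np.zeros(n_win, dtype=float)
        if grp is not None and len(grp):
            idx = (grp["pos"].to_numpy() // window_size).astype(np.int64)
            keep = idx < n_win
            np.add.at(n, idx[keep], 1)
            np.add.at(s, idx[keep], grp["fraction"].to_numpy()[keep])
        mean = np.full(n_win, np.nan)
        ok = n >= min_cpgs
        mean[ok] = s[ok] / n[ok]
        starts = np.arange(n_win, dtype=np.int64) * window_size
        ends = starts + window_size
        if chrom_sizes is not None:
            ends = np.minimum(ends, chrom_sizes[chrom])
        parts.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "mean_meth": mean, "n_cpgs": n}
            )
        )
    if not parts:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def global_methylation(calls: pd.DataFrame) -> float:
    """Read-weighted global methylation: sum(meth_reads) / sum(total_reads).

    Falls back to the unweighted site mean (with a warning) when read
    counts are unavailable (fraction-dialect input).
    """
    totals = calls["total_reads"]
    if totals.isna().any() or not len(calls):
        if len(calls):
            warnings.warn(
                "read counts unavailable; global methylation computed as "
                "unweighted site mean"
            )
            return float(calls["fraction"].mean())
        raise ValueError("empty call set")
    denom = totals.sum()
    if denom == 0:
        raise ValueError("no aligned reads")
    return float(calls["meth_reads"].sum() / denom)


def running_median(values, width: int = 15) -> np.ndarray:
    """Centered running median, NaN-aware, truncated neighborhoods at ends.

    ``width`` must be odd.  Missing values are ignored within each
    neighborhood; an all-missing neighborhood stays missing.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd and >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window=width, center=True, min_periods=1).median().to_numpy()


def kernel_smooth(
    track: pd.DataFrame, bandwidth: float | None = None
) -> pd.DataFrame:
    """Nadaraya-Watson Gaussian-kernel smoothing of a window track.

    Evaluated at window centers over the non-missing windows of each
    chromosome.  Windows with no data within one bandwidth stay missing,
    so smoothing never invents values across coverage gaps.  Default
    bandwidth is three windows' worth of bp.
    """
    out = track.copy().reset_index(drop=True)
    if bandwidth is None:
        if not len(track):
            return out
        bandwidth = 3.0 * float(track["end"].iloc[0] - track["start"].iloc[0])
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    smoothed = np.full(len(out), np.nan)
    for chrom, grp in out.groupby("chrom", sort=False):
        centers = (grp["start"].to_numpy() + grp["end"].to_numpy()) / 2.0
        vals = grp["mean_meth"].to_numpy()
        ok = ~np.isnan(vals)
        if not ok.any():
            continue
        oc, ov = centers[ok], vals[ok]
        d = (centers[:, None] - oc[None, :]) / bandwidth
        w = np.exp(-0.5 * d * d)
        nearest = np.min(np.abs(centers[:, None] - oc[None, :]), axis=1)
        num = w @ ov
        den = w.sum(axis=1)
        est = np.where((den > 0) & (nearest <= bandwidth), num / np.maximum(den, 1e-300), np.nan)
        smoothed[grp.index.to_numpy()] = est
    out["mean_meth"] = smoothed
    return out


@dataclass
class MethylationDensity:
    """Kernel density summary of window methylation on a 0-100% scale."""

    grid: np.ndarray
    density: np.ndarray | None
    median: float
    iqr: float
    bimodal: bool
    peaks: np.ndarray
    point_mass: bool = False


def methylation_density(
    track: pd.DataFrame, grid_step: float = 0.5, trough_depth: float = 0.15
) -> MethylationDensity:
    """Gaussian KDE (Silverman bandwidth) of window methylation in percent.

    The bimodality flag is an operational surrogate for a visual call: true
    iff the density has >= 2 local maxima separated by a trough whose height
    is below ``(1 - trough_depth)`` times the lower of the two peaks.
    """
    vals = track["mean_meth"].dropna().to_numpy() * 100.0
    if len(vals) < 2:
        raise ValueError("need at least 2 non-missing windows")
    grid = np.arange(0.0, 100.0 + grid_step, grid_step)
    med = float(np.median(vals))
    q1, q3 = np.percentile(vals, [25, 75])
    if np.ptp(vals) < 1e-12:
        return MethylationDensity(
            grid=grid, density=None, median=med, iqr=float(q3 - q1),
            bimodal=False, peaks=np.array([med]), point_mass=True,
        )
    kde = stats.gaussian_kde(vals, bw_method="silverman")
    dens = kde(grid)
    area = np.trapezoid(dens, grid)
    dens = dens / area
    # local maxima; tiny ripples below 2% of the mode are not peaks
    pk, _ = signal.find_peaks(dens, height=0.02 * dens.max())
    bimodal = False
    for i in range(len(pk)):
        for j in range(i + 1, len(pk)):
            lo, hi = pk[i], pk[j]
            trough = dens[lo:hi + 1].min()
            lower_peak = min(dens[lo], dens[hi])
            if trough < (1.0 - trough_depth) * lower_peak:
                bimodal = True
    return MethylationDensity(
        grid=grid, density=dens, median=med, iqr=float(q3 - q1),
        bimodal=bimodal, peaks=grid[pk],
    )


def correlate_tracks(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, int]:
    """Pearson correlation of two window tracks on a shared grid.

    Only windows non-missing in both tracks contribute.  Returns (r, n).
    """
    merged = a.merge(b, on=["chrom", "start"], suffixes=("_a", "_b"))
    x = merged["mean_meth_a"].to_numpy()
    y = merged["mean_meth_b"].to_numpy()
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        raise ValueError("fewer than 3 shared non-missing windows")
    r = stats.pearsonr(x[ok], y[ok]).statistic
    return float(r), n


def write_window_track(track: pd.DataFrame, path) -> None:
    """Export a window track as bedGraph (missing windows omitted)."""
    out = track.dropna(subset=["mean_meth"])
    out[["chrom", "start", "end", "mean_meth"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6f"
    )
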