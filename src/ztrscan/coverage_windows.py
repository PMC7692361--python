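"""Per-window coverage statistics from per-site depth tables.

Depth tables are expected in the samtools-depth dialect (chrom, 1-based pos,
depth) and are assumed to be pre-screened for mapping quality upstream
(MQ >= 60 is an input contract, not recomputed here).  Sites more than three
times deeper than the genome-wide mean are removed, the chromosome is tiled
into consecutive non-overlapping windows (default 50 kb), windows with less
than 60% of their span covered are flagged excluded, and per-window mean
depth is normalized against a baseline window set.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["read_depth", "site_filter", "window_coverage", "normalize_coverage"]

DEPTH_COLUMNS = ["chrom", "pos", "depth"]


def read_depth(path) -> pd.DataFrame:
    """Read a 3-column samtools-depth TSV (chrom, 1-based pos, depth)."""
    return pd.read_csv(path, sep="\t", names=DEPTH_COLUMNS,
                       dtype={"chrom": str, "pos": np.int64, "depth": np.int64})


def site_filter(sites: pd.DataFrame, genome_mean_depth: float | None = None,
                max_fold: float = 3.0) -> tuple[pd.DataFrame, int]:
    """Remove sites with depth strictly greater than ``max_fold`` x mean.

    The mean is computed over the whole input table (all chromosomes present)
    when not supplied.  Equality retains: a site at exactly 3x the mean stays.
    Returns the retained table and the number of sites removed.
    """
    if sites.empty:
        warnings.warn("site_filter: empty depth table")
        return sites.copy(), 0
    if genome_mean_depth is None:
        genome_mean_depth = float(sites["depth"].mean())
    if genome_mean_depth <= 0:
        raise ValueError("genome mean depth must be > 0")
    keep = sites["depth"].to_numpy() <= max_fold * genome_mean_depth
    removed = int((~keep).sum())
    return sites.loc[keep].reset_index(drop=True), removed


def window_coverage(sites: pd.DataFrame, window_size: int = 50_000,
                    chrom_lengths: dict[str, int] | None = None,
                    min_covered_fraction: float = 0.6) -> pd.DataFrame:
    """Tile each chromosome into fixed windows and summarize retained sites.

    Windows start at coordinate 0; the trailing partial window is dropped.
    ``n_covered`` counts retained sites in the window; ``mean_depth`` is the
    arithmetic mean over those sites only (absent sites are not zero-filled).
    Windows with ``n_covered`` strictly below ``min_covered_fraction`` of the
    window span are marked ``excluded``.
    """
    out = []
    chroms = sites["chrom"].unique() if not sites.empty else []
    if chrom_lengths:
        chroms = list(chrom_lengths)
    for chrom in chroms:
        sub = sites[sites["chrom"] == chrom]
        if chrom_lengths and chrom in chrom_lengths:
            length = chrom_lengths[chrom]
        else:
            length = int(sub["pos"].max()) if len(sub) else 0
        n_win = length // window_size
        if n_win == 0:
            warnings.warn(f"window_coverage: chromosome {chrom} shorter than one window")
            continue
        pos0 = sub["pos"].to_numpy() - 1
        depth = sub["depth"].to_numpy()
        inside = pos0 < n_win * window_size
        widx = pos0[inside] // window_size
        counts = np.bincount(widx, minlength=n_win)
        sums = np.bincount(widx, weights=depth[inside], minlength=n_win)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        starts = np.arange(n_win) * window_size
        out.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + window_size,
            "n_covered": counts,
            "mean_depth": means,
            "excluded": counts < min_covered_fraction * window_size,
        }))
    if not out:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_covered",
                                     "mean_depth", "excluded"])
    return pd.concat(out, ignore_index=True)


def normalize_coverage(windows: pd.DataFrame,
                       baseline: pd.Series | np.ndarray | None = None) -> pd.DataFrame:
    """Add ``norm_cov`` = mean_depth / median baseline mean_depth.

    ``baseline`` is a boolean mask over ``windows`` rows selecting the
    normalization set (declared autosomal windows where available, else PAR
    windows, else all windows of the chromosome — choosing that set is the
    caller's responsibility).  When omitted, all non-excluded windows are the
    baseline.  The median baseline ``norm_cov`` is exactly 1 by construction.
    """
    win = windows.copy()
    if baseline is None:
        mask = ~win["excluded"].to_numpy()
    else:
        mask = np.asarray(baseline, dtype=bool) & ~win["excluded"].to_numpy()
    if not mask.any():
        raise ValueError("normalize_coverage: empty baseline window set")
    denom = float(np.nanmedian(win.loc[mask, "mean_depth"]))
    if denom == 0 or np.isnan(denom):
        raise ValueError("normalize_coverage: baseline median depth is zero")
    win["norm_cov"] = win["mean_depth"] / denom
    win.attrs["baseline_median_depth"] = denom
    win.attrs["baseline_n_windows"] = int(mask.sum())
    return win
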