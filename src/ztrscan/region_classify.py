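"""Window and region classification from coverage + SNP-density signatures.

The diagnostic signatures, with coverage normalized so that a two-copy
(autosome-like) window sits at 1.0 in each sex:

* **ZTR** — both sexes at full (two-copy) coverage, female SNP density
  elevated over background, male density not elevated.  The W-derived copy
  co-maps onto the Z reference, doubling female coverage back to autosome
  level and planting female-only heterozygosity from Z-W divergence.
* **PAR** — full coverage in both sexes, neither density elevated.
* **Z_DUP** — male normalized coverage >= 1.5 (two extra Z copies) and both
  sexes' densities elevated by paralogous sequence variants.
* **HEMIZYGOUS_Z** — female at half coverage, male at full, no female
  density elevation.

Density elevation is judged against a per-sex background level ``lambda_bg``
(median window density over baseline windows): a window is elevated when its
density >= max(k * lambda_bg, lambda_bg + 3 * sqrt(lambda_bg)), k = 3 by
default.  Merged region calls bridge single interior excluded/unclassified
windows, absorb interior hemizygous runs inside ZTR envelopes as candidate
W-deletions, and demote runs shorter than ``min_run`` windows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClassifyParams",
    "RegionCall",
    "estimate_background_density",
    "is_elevated",
    "classify_windows",
    "merge_calls",
    "rank_sum_test",
]

LABELS = ("ZTR", "PAR", "Z_DUP", "HEMIZYGOUS_Z", "AUTOSOME_LIKE", "UNCLASSIFIED")

# exact rank-sum enumeration is used when the number of group assignments is
# below this cap (covers all min(n,m) <= 8 balanced cases)
_EXACT_ENUM_CAP = 200_000


@dataclass
class ClassifyParams:
    """Thresholds for window classification (all config-exposed)."""

    cov_full: tuple[float, float] = (0.8, 1.25)
    cov_hemi: tuple[float, float] = (0.35, 0.65)
    cov_dup_male_min: float = 1.5
    density_elevation_factor: float = 3.0
    min_run: int = 2
    lambda_bg_f: float | None = None
    lambda_bg_m: float | None = None

    def __post_init__(self):
        if self.density_elevation_factor <= 1:
            raise ValueError("density_elevation_factor must be > 1")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


@dataclass
class RegionCall:
    """A merged run of windows with one label and its evidence."""

    chrom: str
    start: int
    end: int
    label: str
    n_windows: int
    evidence: dict = field(default_factory=dict)
    interior_candidates: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def estimate_background_density(windows: pd.DataFrame,
                                baseline_mask: np.ndarray) -> tuple[float, float]:
    """Per-sex background density: median window SNP density over baseline."""
    mask = np.asarray(baseline_mask, dtype=bool) & ~windows["excluded"].to_numpy()
    if not mask.any():
        raise ValueError("empty baseline window set for background density")
    lam_f = float(np.median(windows.loc[mask, "snp_density_f"]))
    lam_m = float(np.median(windows.loc[mask, "snp_density_m"]))
    return lam_f, lam_m


def is_elevated(density: float, lam_bg: float, k: float = 3.0) -> bool:
    """Density elevation rule: >= max(k*lam, lam + 3*sqrt(lam))."""
    return density >= max(k * lam_bg, lam_bg + 3.0 * math.sqrt(max(lam_bg, 0.0)))


def classify_windows(f_windows: pd.DataFrame, m_windows: pd.DataFrame,
                     params: ClassifyParams,
                     baseline_chroms: set[str] = frozenset()) -> pd.DataFrame:
    """Label each retained window; the two sex tables must share one grid.

    Windows on chromosomes in ``baseline_chroms`` are labelled AUTOSOME_LIKE
    by declaration (position on a baseline chromosome, not signature).
    Returns one merged table with per-sex coverage/density columns and a
    ``label`` column; excluded windows keep the label ``EXCLUDED``.
    """
    for col in ("chrom", "start", "end"):
        if not (f_windows[col].to_numpy() == m_windows[col].to_numpy()).all():
            raise ValueError("classify_windows: mismatched window grids")
    if params.lambda_bg_f is None or params.lambda_bg_m is None:
        raise ValueError("classify_windows: background densities not set "
                         "(use estimate_background_density)")
    win = f_windows[["chrom", "start", "end", "n_covered"]].copy()
    win["excluded"] = f_windows["excluded"].to_numpy() | m_windows["excluded"].to_numpy()
    win["f_norm_cov"] = f_windows["norm_cov"].to_numpy()
    win["m_norm_cov"] = m_windows["norm_cov"].to_numpy()
    win["f_density"] = f_windows["snp_density_f"].to_numpy()
    win["m_density"] = m_windows["snp_density_m"].to_numpy()

    labels = []
    for row in win.itertuples():
        if row.excluded:
            labels.append("EXCLUDED")
            continue
        if row.chrom in baseline_chroms:
            labels.append("AUTOSOME_LIKE")
            continue
        labels.append(_label_one(row, params))
    win["label"] = labels
    return win


def _in(x: float, interval: tuple[float, float]) -> bool:
    return interval[0] <= x <= interval[1]


def _label_one(row, p: ClassifyParams) -> str:
    k = p.density_elevation_factor
    f_elev = is_elevated(row.f_density, p.lambda_bg_f, k)
    m_elev = is_elevated(row.m_density, p.lambda_bg_m, k)
    f_full = _in(row.f_norm_cov, p.cov_full)
    m_full = _in(row.m_norm_cov, p.cov_full)
    if row.m_norm_cov >= p.cov_dup_male_min and f_elev and m_elev:
        return "Z_DUP"
    if f_full and m_full and f_elev and not m_elev:
        return "ZTR"
    if f_full and m_full and not f_elev and not m_elev:
        return "PAR"
    if _in(row.f_norm_cov, p.cov_hemi) and m_full and not f_elev:
        return "HEMIZYGOUS_Z"
    return "UNCLASSIFIED"


def merge_calls(labelled: pd.DataFrame, params: ClassifyParams) -> list[RegionCall]:
    """Merge per-window labels into region calls.

    Steps, per chromosome: (1) bridge single interior EXCLUDED/UNCLASSIFIED
    windows whose two neighbours agree; (2) absorb interior HEMIZYGOUS_Z runs
    flanked by ZTR runs into a single ZTR envelope, recording them as
    candidate W-deletions; (3) demote runs shorter than ``min_run`` windows
    to UNCLASSIFIED.
    """
    calls: list[RegionCall] = []
    for chrom, sub in labelled.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        labels = list(sub["label"])
        # (1) bridge isolated excluded/unclassified interior windows
        for i in range(1, len(labels) - 1):
            if labels[i] in ("EXCLUDED", "UNCLASSIFIED") and \
                    labels[i - 1] == labels[i + 1] and \
                    labels[i - 1] not in ("EXCLUDED", "UNCLASSIFIED"):
                labels[i] = labels[i - 1]
        runs = _runs(labels)
        # (2) ZTR envelopes with interior hemizygous candidate deletions
        runs = _absorb_interior(runs)
        # (3) min_run demotion, then rebuild calls
        merged: list[tuple[str, int, int, list[tuple[int, int]]]] = []
        for label, s, e, cands in runs:
            if label not in ("EXCLUDED",) and (e - s) < params.min_run:
                label = "UNCLASSIFIED"
            if merged and merged[-1][0] == label:
                prev = merged.pop()
                merged.append((label, prev[1], e, prev[3] + cands))
            else:
                merged.append((label, s, e, cands))
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for label, s, e, cands in merged:
            if label == "EXCLUDED":
                continue
            evidence = _evidence(sub.iloc[s:e])
            calls.append(RegionCall(
                chrom=chrom, start=int(starts[s]), end=int(ends[e - 1]),
                label=label, n_windows=e - s, evidence=evidence,
                interior_candidates=[(int(starts[a]), int(ends[b - 1]))
                                     for a, b in cands],
            ))
    return calls


def _runs(labels: list[str]) -> list[tuple[str, int, int, list]]:
    runs = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        runs.append((labels[i], i, j, []))
        i = j
    return runs


def _absorb_interior(runs):
    """Collapse ZTR / HEMIZYGOUS_Z / ZTR run triplets into ZTR envelopes."""
    changed = True
    while changed:
        changed = False
        for i in range(1, len(runs) - 1):
            lab, s, e, _ = runs[i]
            if lab == "HEMIZYGOUS_Z" and runs[i - 1][0] == "ZTR" and runs[i + 1][0] == "ZTR":
                left, right = runs[i - 1], runs[i + 1]
                cands = left[3] + [(s, e)] + right[3]
                runs[i - 1:i + 2] = [("ZTR", left[1], right[2], cands)]
                changed = True
                break
    return runs


def _evidence(windows: pd.DataFrame) -> dict:
    w = windows[windows["label"] != "EXCLUDED"]
    if w.empty:
        return {}
    return {
        "f_norm_cov": float(w["f_norm_cov"].mean()),
        "m_norm_cov": float(w["m_norm_cov"].mean()),
        "f_density": float(w["f_density"].mean()),
        "m_density": float(w["m_density"].mean()),
    }


# ---------------------------------------------------------------------------
# Wilcoxon / Mann-Whitney rank-sum test
# ---------------------------------------------------------------------------


def rank_sum_test(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test of two samples; returns (U of sample a, p-value).

    Exact p by enumeration of all group assignments of the pooled values
    (handles ties) when min(n, m) <= 8 and the number of assignments is
    tractable; otherwise a tie-corrected normal approximation with
    continuity correction.  ``alternative`` is "greater"/"less" (about
    sample ``a``) or "two-sided".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test: both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"bad alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("rank_sum_test: all values tied; p = 1")
        return float(a.size * b.size / 2), 1.0
    u_obs = _u_statistic(a, b)
    n, m = a.size, b.size
    if min(n, m) <= 8 and math.comb(n + m, min(n, m)) <= _EXACT_ENUM_CAP:
        p = _exact_p(pooled, n, u_obs, alternative)
    else:
        p = _normal_p(a, b, u_obs, alternative)
    return u_obs, float(min(p, 1.0))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #(a_i > b_j) + 0.5 * #ties."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_p(pooled: np.ndarray, n: int, u_obs: float, alternative: str) -> float:
    total = pooled.size
    idx = np.fromiter(
        (i for comb in combinations(range(total), n) for i in comb),
        dtype=np.int64).reshape(-1, n)
    mask = np.zeros((len(idx), total), dtype=bool)
    mask[np.arange(len(idx))[:, None], idx] = True
    a_vals = pooled[idx]
    b_vals = np.broadcast_to(pooled, (len(idx), total))[~mask].reshape(len(idx), total - n)
    gt = (a_vals[:, :, None] > b_vals[:, None, :]).sum(axis=(1, 2))
    eq = (a_vals[:, :, None] == b_vals[:, None, :]).sum(axis=(1, 2))
    us = gt + 0.5 * eq
    eps = 1e-9
    p_ge = float((us >= u_obs - eps).mean())
    p_le = float((us <= u_obs + eps).mean())
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def _normal_p(a: np.ndarray, b: np.ndarray, u_obs: float, alternative: str) -> float:
    """Tie-corrected normal approximation with continuity correction and an
    Edgeworth kurtosis term (the null U distribution is platykurtic;
    excess kurtosis -(6/5)(n^2+m^2+nm+n+m)/(nm(N+1)) without ties)."""
    n, m = a.size, b.size
    nm = n + m
    mu = n * m / 2.0
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (nm * (nm - 1.0)))
    var = n * m / 12.0 * ((nm + 1.0) - tie_term)
    if var <= 0:
        return 1.0
    sd = math.sqrt(var)
    g2 = -1.2 * (n * n + m * m + n * m + n + m) / (n * m * (nm + 1.0))

    def cdf(z: float) -> float:
        val = float(stats.norm.cdf(z)
                    - stats.norm.pdf(z) * (g2 / 24.0) * (z ** 3 - 3.0 * z))
        return min(max(val, 1e-300), 1.0 - 1e-16)

    if alternative == "greater":
        return 1.0 - cdf((u_obs - mu - 0.5) / sd)
    if alternative == "less":
        return cdf((u_obs - mu + 0.5) / sd)
    z = (abs(u_obs - mu) - 0.5) / sd
    return 2.0 * (1.0 - cdf(z))
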