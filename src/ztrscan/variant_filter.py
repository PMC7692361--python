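"""GATK-style hard filtering, allele-fraction screening and SNP density.

A record fails when FS > 10.0, QD < 2.0, MQ < 50.0, SOR > 1.5,
MQRankSum < -1.5 or ReadPosRankSum < -8.0; missing annotations leave the
corresponding criterion unapplied.  SNPs are additionally failed when two or
more of them fall within any 10-bp span (the cluster rule); indels share the
numeric criteria but are exempt from the cluster rule and never counted in
SNP density.  Heterozygous calls from a single individual are then required
to show an allele fraction in [0.3, 0.7] — the expectation for one diploid
heterozygote is 0.5, with tolerance for sampling noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .synthetic_data import HARD_FILTER_FIELDS

__all__ = [
    "HardFilterThresholds",
    "read_vcf",
    "hard_filter",
    "allele_fraction_filter",
    "snp_density",
    "density_ratio",
]


@dataclass(frozen=True)
class HardFilterThresholds:
    fs_max: float = 10.0
    qd_min: float = 2.0
    mq_min: float = 50.0
    sor_max: float = 1.5
    mq_rank_sum_min: float = -1.5
    read_pos_rank_sum_min: float = -8.0
    cluster_window: int = 10
    cluster_size: int = 2


def read_vcf(path, sex: str | None = None) -> pd.DataFrame:
    """Load a single-sample VCF into the flat variant table used internally.

    Allele fraction is derived from the FORMAT/AD field of the first sample;
    records without AD get a missing allele fraction.  Multi-allelic records
    are not supported (first ALT taken, with a warning).
    """
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None:
                continue
            if len(rec.alts) > 1:
                warnings.warn(f"multi-allelic record at {rec.chrom}:{rec.pos}; taking first ALT")
            alt = rec.alts[0]
            row = {
                "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alt,
                "vtype": "SNP" if len(rec.ref) == 1 and len(alt) == 1 else "INDEL",
                "sex": sex,
            }
            for key in HARD_FILTER_FIELDS:
                val = rec.info.get(key)
                row[key] = float(val) if val is not None else np.nan
            af = np.nan
            ad_ref = ad_alt = np.nan
            if samples:
                ad = rec.samples[samples[0]].get("AD")
                if ad is not None and ad[0] is not None:
                    ad_ref, ad_alt = int(ad[0]), int(ad[1])
                    total = ad_ref + ad_alt
                    af = ad_alt / total if total > 0 else np.nan
            row.update(ad_ref=ad_ref, ad_alt=ad_alt, allele_fraction=af)
            rows.append(row)
    cols = ["chrom", "pos", "ref", "alt", "vtype", "sex", "ad_ref", "ad_alt",
            "allele_fraction", *HARD_FILTER_FIELDS]
    return pd.DataFrame(rows, columns=cols)


def hard_filter(records: pd.DataFrame,
                thresholds: HardFilterThresholds = HardFilterThresholds()) -> pd.DataFrame:
    """Annotate records with filter reasons; returns a copy with columns
    ``filter`` ("PASS" or semicolon-joined reasons) and ``pass_`` (bool).

    Requires records sorted by (chrom, pos); raises otherwise.
    """
    if len(records) and not records.groupby("chrom", sort=False)["pos"].apply(
            lambda s: s.is_monotonic_increasing).all():
        raise ValueError("hard_filter: records must be sorted by (chrom, pos)")
    t = thresholds
    rec = records.copy()
    n = len(rec)
    reasons: list[list[str]] = [[] for _ in range(n)]

    def apply(col, fails, reason):
        vals = rec[col].to_numpy(dtype=float)
        mask = np.zeros(n, dtype=bool)
        ok = ~np.isnan(vals)
        mask[ok] = fails(vals[ok])
        for i in np.flatnonzero(mask):
            reasons[i].append(reason)

    if n:
        apply("FS", lambda v: v > t.fs_max, "FS")
        apply("QD", lambda v: v < t.qd_min, "QD")
        apply("MQ", lambda v: v < t.mq_min, "MQ")
        apply("SOR", lambda v: v > t.sor_max, "SOR")
        apply("MQRankSum", lambda v: v < t.mq_rank_sum_min, "MQRankSum")
        apply("ReadPosRankSum", lambda v: v < t.read_pos_rank_sum_min, "ReadPosRankSum")

        # cluster rule: any SNP within (cluster_window) bp of another SNP
        is_snp = (rec["vtype"] == "SNP").to_numpy()
        for chrom in rec["chrom"].unique():
            idx = np.flatnonzero((rec["chrom"] == chrom).to_numpy() & is_snp)
            if len(idx) < t.cluster_size:
                continue
            pos = rec["pos"].to_numpy()[idx]
            near_prev = np.zeros(len(idx), dtype=bool)
            near_prev[1:] = np.diff(pos) <= t.cluster_window
            near = near_prev | np.concatenate([near_prev[1:], [False]])
            for i in idx[near]:
                reasons[i].append("cluster")

    rec["filter"] = ["PASS" if not r else ";".join(r) for r in reasons]
    rec["pass_"] = [not r for r in reasons]
    return rec


def allele_fraction_filter(records: pd.DataFrame, lo: float = 0.3,
                           hi: float = 0.7) -> tuple[pd.DataFrame, int]:
    """Retain hard-filter PASS records with allele fraction in [lo, hi].

    Bounds are inclusive.  PASS records lacking an allele fraction are
    dropped; their count is returned (and warned about) alongside the
    retained table.
    """
    if "pass_" not in records.columns:
        raise ValueError("run hard_filter before allele_fraction_filter")
    passed = records[records["pass_"]]
    af = passed["allele_fraction"].to_numpy(dtype=float)
    missing = np.isnan(af)
    n_missing = int(missing.sum())
    if n_missing:
        warnings.warn(f"allele_fraction_filter: {n_missing} PASS records without AD dropped")
    keep = ~missing & (af >= lo) & (af <= hi)
    return passed.loc[keep].reset_index(drop=True), n_missing


def snp_density(records: pd.DataFrame, windows: pd.DataFrame,
                sex: str) -> pd.DataFrame:
    """Merge retained-SNP counts per window into the window table.

    Only ``vtype == "SNP"`` records count.  Density is defined as the SNP
    count per window (the window is the unit).  Adds columns
    ``snp_count_<s>`` and ``snp_density_<s>`` where ``<s>`` is ``f``/``m``.
    """
    s = {"female": "f", "male": "m"}.get(sex, sex)
    win = windows.copy()
    counts = np.zeros(len(win), dtype=np.int64)
    snps = records[records["vtype"] == "SNP"]
    for chrom, sub in snps.groupby("chrom"):
        wmask = (win["chrom"] == chrom).to_numpy()
        if not wmask.any():
            continue
        idx = np.flatnonzero(wmask)
        starts = win["start"].to_numpy()[idx]
        size = int(win["end"].to_numpy()[idx][0] - starts[0])
        pos0 = sub["pos"].to_numpy() - 1
        wi = pos0 // size
        valid = (wi >= starts[0] // size) & (wi < starts[0] // size + len(idx))
        c = np.bincount(wi[valid] - starts[0] // size, minlength=len(idx))
        counts[idx] += c
    win[f"snp_count_{s}"] = counts
    win[f"snp_density_{s}"] = counts.astype(float)
    return win


def density_ratio(windows: pd.DataFrame) -> pd.DataFrame:
    """Female/male SNP-density ratio per window; infinite where male = 0."""
    win = windows.copy()
    f = win["snp_density_f"].to_numpy(dtype=float)
    m = win["snp_density_m"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(m > 0, f / m, np.inf)
    ratio = np.where((m == 0) & (f == 0), np.nan, ratio)
    win["fm_density_ratio"] = ratio
    win["fm_ratio_infinite"] = (m == 0) & (f > 0)
    return win
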