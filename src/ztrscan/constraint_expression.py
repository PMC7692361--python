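"""Evolutionary constraint and expression context of surviving ZTR genes.

Three independent lines of evidence about why a transposed gene survives on
the W chromosome:

1. **dN/dS (omega)** by Nei-Gojobori (1986) counting.  Synonymous and
   nonsynonymous sites are the per-codon fractions of the three possible
   changes at each position (changes creating a stop codon count as
   nonsynonymous, so S + N = 3 x codons exactly); multi-hit codons average
   their substitution counts over all minimal mutational pathways, excluding
   pathways through stop codons when a stop-free pathway exists.  Proportions
   are Jukes-Cantor corrected, d = -(3/4) ln(1 - (4/3) p), flagged saturated
   when p >= 3/4.  Branch-specific rates on a (Z, W, outgroup) triplet use
   parsimony polarization: at each Z/W-differing codon the copy matching the
   outgroup is taken as ancestral and the substitutions are assigned to the
   other copy's branch; codons where all three differ are reported as
   unpolarized.  This counting estimator stands in for a maximum-likelihood
   branch model, which is well justified at the low divergence of young
   transposed regions.

2. **Haploinsufficiency percentile** of a gene's score against a background
   score distribution (e.g. all Z-linked genes): the fraction of background
   genes with score <= the query's, as a dosage-sensitivity rank.

3. **Expression profile**: replicate-averaged TPM per (gene, species,
   tissue, sex), reported as log(1 + mean TPM), with a female-gonad bias
   flag when the female-gonad mean is at least ``bias_fold_threshold`` times
   every other condition mean in that species.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "NGCounts",
    "BranchRates",
    "ng86_pairwise",
    "branch_rates",
    "hi_percentile",
    "expression_profile",
    "jukes_cantor",
    "codon_syn_sites",
    "codon_path_counts",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = _TABLE.forward_table
STOP_CODONS = frozenset(_TABLE.stop_codons)


@dataclass
class NGCounts:
    """NG86 pairwise counting result."""

    S: float
    N: float
    sd: float
    nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    omega: float | None
    saturated: bool = False

    @property
    def omega_defined(self) -> bool:
        return self.omega is not None


@dataclass
class BranchRates:
    """Per-branch substitution counts and rates from polarized counting."""

    branch: str
    sd: float
    nd: float
    S: float
    N: float
    dS: float | None
    dN: float | None
    omega: float | None
    n_codons: int
    unpolarized_codons: int = 0

    @property
    def omega_defined(self) -> bool:
        return self.omega is not None


@lru_cache(maxsize=None)
def codon_syn_sites(codon: str) -> float:
    """Synonymous site count of one codon: per-position fraction of the three
    possible changes that preserve the amino acid (stop targets nonsynonymous)."""
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = _AA[codon]
    syn = 0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if _AA.get(alt) == aa:
                syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(sd, nd) between two sense codons, averaged over minimal pathways.

    Pathways stepping through a stop codon are excluded; when every pathway
    passes through a stop (possible for some 2-3 step pairs), all pathways
    are used so that the difference count is conserved.
    """
    if c1 in STOP_CODONS or c2 in STOP_CODONS:
        raise ValueError("stop codon encountered")
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = c1
        steps = []
        blocked = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if _AA.get(a) is not None and _AA.get(b) is not None and _AA[a] == _AA[b]:
                sd += 1
            else:
                nd += 1
    k = len(usable)
    return sd / k, nd / k


def _codons(seq: str) -> list[str]:
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    return abs(-0.75 * math.log(1.0 - (4.0 / 3.0) * p))


def ng86_pairwise(seq_a: str, seq_b: str) -> NGCounts:
    """Nei-Gojobori (1986) counting between two equal-length coding sequences."""
    ca, cb = _codons(seq_a), _codons(seq_b)
    if len(ca) != len(cb):
        raise ValueError("sequences differ in length")
    S = sd = nd = 0.0
    for a, b in zip(ca, cb):
        S += (codon_syn_sites(a) + codon_syn_sites(b)) / 2.0
        s, n = codon_path_counts(a, b)
        sd += s
        nd += n
    N = 3.0 * len(ca) - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    saturated = dS is None or dN is None
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return NGCounts(S=S, N=N, sd=sd, nd=nd, pS=pS, pN=pN, dS=dS, dN=dN,
                    omega=omega, saturated=saturated)


def branch_rates(alignment: Mapping[str, str], z: str = "Z", w: str = "W",
                 outgroup: str = "outgroup") -> dict[str, BranchRates]:
    """Polarized branch-specific NG86 rates for the Z and W branches.

    ``alignment`` maps taxon name to an equal-length gap-free in-frame
    sequence.  Returns BranchRates for ``"Z"`` and ``"W"``; unpolarized
    codons (all three sequences differ) are excluded from both branches and
    reported in ``unpolarized_codons``.
    """
    zc, wc, oc = (_codons(alignment[k]) for k in (z, w, outgroup))
    if not len(zc) == len(wc) == len(oc):
        raise ValueError("alignment sequences differ in length")
    S = 0.0
    counts = {"Z": [0.0, 0.0], "W": [0.0, 0.0]}
    unpolarized = 0
    unpol_sd = unpol_nd = 0.0
    for a, b, o in zip(zc, wc, oc):
        S += (codon_syn_sites(a) + codon_syn_sites(b)) / 2.0
        if a == b:
            continue
        if b == o:  # W matches outgroup: change happened on the Z branch
            s, n = codon_path_counts(o, a)
            counts["Z"][0] += s
            counts["Z"][1] += n
        elif a == o:  # Z matches outgroup: change happened on the W branch
            s, n = codon_path_counts(o, b)
            counts["W"][0] += s
            counts["W"][1] += n
        else:
            unpolarized += 1
            s, n = codon_path_counts(a, b)
            unpol_sd += s
            unpol_nd += n
    n_codons = len(zc)
    N = 3.0 * n_codons - S
    n_diff = sum(1 for a, b in zip(zc, wc) if a != b)
    if n_diff and unpolarized / n_diff > 0.2:
        warnings.warn(f"{unpolarized}/{n_diff} Z-W differing codons unpolarized; "
                      "branch assignment unreliable")
    out = {}
    for branch in ("Z", "W"):
        sd, nd = counts[branch]
        pS = sd / S if S > 0 else 0.0
        pN = nd / N if N > 0 else 0.0
        dS = jukes_cantor(pS)
        dN = jukes_cantor(pN)
        omega = None
        if dS is not None and dN is not None and dS > 0:
            omega = dN / dS
        out[branch] = BranchRates(branch=branch, sd=sd, nd=nd, S=S, N=N,
                                  dS=dS, dN=dN, omega=omega, n_codons=n_codons,
                                  unpolarized_codons=unpolarized)
    out["unpolarized"] = BranchRates(
        branch="unpolarized", sd=unpol_sd, nd=unpol_nd, S=S, N=N,
        dS=None, dN=None, omega=None, n_codons=n_codons,
        unpolarized_codons=unpolarized)
    return out


# ---------------------------------------------------------------------------
# Haploinsufficiency percentiles
# ---------------------------------------------------------------------------


def hi_percentile(scores: Mapping[str, float] | pd.DataFrame,
                  background_genes: Sequence[str],
                  query_genes: Sequence[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentile rank of each query gene's haploinsufficiency score.

    percentile = 100 * #(background scores <= query score) / #background.
    Returns (per-query table, background ECDF table).  Query genes missing
    from the score table are reported with a missing percentile.
    """
    if isinstance(scores, pd.DataFrame):
        scores = dict(zip(scores["gene"], scores["score"]))
    bg = np.array([scores[g] for g in background_genes if g in scores], dtype=float)
    if bg.size == 0:
        raise ValueError("hi_percentile: empty background")
    if np.any((bg < 0) | (bg > 1)):
        raise ValueError("haploinsufficiency scores must lie in [0, 1]")
    rows = []
    for g in query_genes:
        if g not in scores:
            rows.append({"gene": g, "score": np.nan, "percentile": np.nan,
                         "missing": True})
            continue
        s = scores[g]
        pct = 100.0 * (bg <= s).sum() / bg.size
        rows.append({"gene": g, "score": s, "percentile": pct, "missing": False})
    xs = np.sort(bg)
    ecdf = pd.DataFrame({"score": xs, "ecdf": np.arange(1, xs.size + 1) / xs.size})
    return pd.DataFrame(rows), ecdf


# ---------------------------------------------------------------------------
# Expression profiling
# ---------------------------------------------------------------------------


def expression_profile(expression: pd.DataFrame,
                       bias_fold_threshold: float = 2.0,
                       gonad_tissue: str = "gonad"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-averaged log1p expression matrix and female-gonad bias flags.

    Returns ``(matrix, bias)``: ``matrix`` has genes as rows and
    (species, tissue, sex) columns holding log(1 + mean TPM), NaN for absent
    conditions; ``bias`` has one row per (gene, species) with the gonad-bias
    flag — true iff the female-gonad mean TPM is at least
    ``bias_fold_threshold`` times the maximum mean over all other conditions.
    """
    req = {"species", "tissue", "sex", "replicate", "gene", "tpm"}
    if not req.issubset(expression.columns):
        raise ValueError(f"expression table missing columns {req - set(expression.columns)}")
    if (expression["tpm"] < 0).any():
        raise ValueError("negative TPM values")
    means = (expression.groupby(["gene", "species", "tissue", "sex"], sort=True)["tpm"]
             .mean().reset_index())
    means["log1p_tpm"] = np.log1p(means["tpm"])
    matrix = means.pivot_table(index="gene", columns=["species", "tissue", "sex"],
                               values="log1p_tpm")
    rows = []
    for (gene, sp), sub in means.groupby(["gene", "species"]):
        gonad = sub[(sub["tissue"] == gonad_tissue) & (sub["sex"] == "female")]
        if gonad.empty:
            rows.append({"gene": gene, "species": sp, "gonad_bias": None,
                         "gonad_mean_tpm": np.nan, "max_other_tpm": np.nan})
            continue
        gmean = float(gonad["tpm"].iloc[0])
        others = sub.drop(gonad.index)
        max_other = float(others["tpm"].max()) if len(others) else 0.0
        rows.append({
            "gene": gene, "species": sp,
            "gonad_bias": bool(gmean >= bias_fold_threshold * max_other),
            "gonad_mean_tpm": gmean, "max_other_tpm": max_other,
        })
    return matrix, pd.DataFrame(rows)
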