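"""Synthetic sequencing summaries with planted truth for ZTR detection.

This module emulates the statistical structure that the detection pipeline
assumes for a female-heterogametic (ZW) genome sequenced in one female and
one male individual:

* **Depth.** Per-site read depth is Poisson(c * D) where ``D`` is the haploid
  sequencing depth and ``c`` the copy number of the site in that sample.
  Copy numbers per region class: autosome-like and pseudoautosomal (PAR)
  regions are diploid in both sexes (c=2); the hemizygous Z is c=1 in females
  and c=2 in males; a Z-transposed region (ZTR) is c=2 in both sexes because
  the W-derived female reads co-map onto the Z reference; inside a W-deletion
  nested in a ZTR the female drops back to c=1; a Z-linked duplication (Z_DUP)
  is c=2 in females and c=4 in males.

* **Heterozygosity.** Background polymorphism appears at rate ``pi`` per bp in
  both sexes everywhere.  Z-W divergence sites appear at rate ``d`` per bp in
  the female only, inside ZTRs (outside W-deletions); paralogous sequence
  variants appear at ``dup_psv_rate`` in both sexes inside Z_DUP regions.
  Allele fractions are Beta-binomial centred on 0.5 (a single heterozygous
  diploid individual).  Small indels on the W copy occur at ``indel_rate``
  inside ZTRs.

* **Variant annotations.** Each emitted record carries GATK-style INFO fields
  (FS, QD, MQ, SOR, MQRankSum, ReadPosRankSum) drawn from distributions that
  pass the downstream hard filters, except a ``fail_fraction`` of records
  that each violate exactly one criterion (so filter bookkeeping is testable).

Only summaries are simulated (depth tables, VCFs); no read-level FASTQ/BAM
output, no sequencing-error model, no recombination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Data import CodonTable

__all__ = [
    "RegionSpec",
    "GeneSpec",
    "SimLayout",
    "SimParams",
    "SimReference",
    "LayoutError",
    "simulate_reference",
    "simulate_depth",
    "simulate_variants",
    "simulate_codon_alignment",
    "simulate_expression",
    "simulate_hi_scores",
    "write_fasta",
    "write_gff3",
    "write_depth",
    "write_vcf",
    "write_truth",
    "copy_number",
]

REGION_CLASSES = ("AUTOSOME_LIKE", "HEMIZYGOUS_Z", "PAR", "ZTR", "Z_DUP")
SEXES = ("female", "male")
BASES = np.array(list("ACGT"))

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD_TABLE.forward_table))

HARD_FILTER_FIELDS = ("FS", "QD", "MQ", "SOR", "MQRankSum", "ReadPosRankSum")


class LayoutError(ValueError):
    """Raised when a simulation layout violates its structural invariants."""


# ---------------------------------------------------------------------------
# Layout / parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionSpec:
    """One region of the simulated chromosome (0-based half-open)."""

    start: int
    end: int
    region_class: str

    def __post_init__(self):
        if self.region_class not in REGION_CLASSES:
            raise LayoutError(f"unknown region class {self.region_class!r}")
        if not 0 <= self.start < self.end:
            raise LayoutError(f"bad region interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneSpec:
    """A gene model placed on the simulated chromosome.

    ``cds`` holds 0-based half-open phase-0 coding segments in genomic order;
    their total length must be divisible by 3.  ``planted_fate`` controls the
    generator: ``"intact"`` genes receive only synonymous Z-W divergence in
    their CDS and no indels; ``"pseudogene_frameshift"`` genes get exactly one
    planted 1-bp frameshift deletion in the middle of their CDS.
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    cds: tuple[tuple[int, int], ...] = ()
    planted_fate: str = "intact"

    def __post_init__(self):
        if self.strand not in "+-":
            raise LayoutError(f"gene {self.name}: bad strand {self.strand!r}")
        total = sum(e - s for s, e in self.cds)
        if total % 3 != 0:
            raise LayoutError(f"gene {self.name}: CDS length {total} not divisible by 3")
        prev_end = self.start
        for s, e in self.cds:
            if s < prev_end or e > self.end or s >= e:
                raise LayoutError(f"gene {self.name}: CDS segments overlap or escape gene body")
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class SimLayout:
    """Region layout of one simulated chromosome.

    Regions must tile ``[0, chrom_length)`` without overlap, on window-size
    boundaries so that every full window has exactly one truth label.
    ``w_deletions`` are intervals nested inside ZTR regions marking spans lost
    from the W copy after the transposition.
    """

    chrom_name: str = "chrZ"
    chrom_length: int = 10_000_000
    window_size: int = 50_000
    regions: list[RegionSpec] = field(default_factory=list)
    w_deletions: list[tuple[int, int]] = field(default_factory=list)
    genes: list[GeneSpec] = field(default_factory=list)

    def validate(self) -> None:
        regs = sorted(self.regions, key=lambda r: r.start)
        if not regs:
            raise LayoutError("layout has no regions")
        if regs[0].start != 0 or regs[-1].end != self.chrom_length:
            raise LayoutError("regions do not span the chromosome")
        for a, b in zip(regs, regs[1:]):
            if a.end != b.start:
                raise LayoutError(f"regions not contiguous at {a.end} vs {b.start}")
        for r in regs:
            if r.start % self.window_size or r.end % self.window_size:
                if r.end != self.chrom_length:
                    raise LayoutError(
                        f"region boundary {r.start}/{r.end} not aligned to window size"
                    )
        ztrs = [r for r in regs if r.region_class == "ZTR"]
        for ds, de in self.w_deletions:
            hosts = [r for r in ztrs if r.start <= ds and de <= r.end]
            if len(hosts) != 1:
                raise LayoutError(f"w_deletion [{ds}, {de}) not nested in exactly one ZTR")
        for g in self.genes:
            if g.start < 0 or g.end > self.chrom_length:
                raise LayoutError(f"gene {g.name} out of chromosome bounds")
        self.regions = regs

    @property
    def n_windows(self) -> int:
        return self.chrom_length // self.window_size

    def window_labels(self) -> list[str]:
        """One truth label per full window (trailing partial window dropped)."""
        labels = []
        for i in range(self.n_windows):
            mid = i * self.window_size + self.window_size // 2
            labels.append(self.region_at(mid).region_class)
        return labels

    def region_at(self, pos: int) -> RegionSpec:
        for r in self.regions:
            if r.start <= pos < r.end:
                return r
        raise LayoutError(f"position {pos} outside layout")

    def in_w_deletion(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.w_deletions)


@dataclass
class SimParams:
    """Generator parameters (rates per bp; depth in reads per haploid copy).

    Defaults match the study conditions the detection pipeline is screened
    under: haploid depth 15x, young-ZTR Z-W divergence d = 0.002/bp far above
    background heterozygosity pi = 1e-4/bp, duplication PSV rate matching d,
    and 5% of variant records planted to violate one hard-filter criterion.
    """

    haploid_depth: float = 15.0
    zw_divergence: float = 0.002
    indel_rate: float = 2e-5
    background_het: float = 1e-4
    dup_psv_rate: float = 0.002
    fail_fraction: float = 0.05
    af_beta: float = 50.0  # Beta(b, b) allele-fraction noise around 0.5
    overdispersion: float = 0.0  # gamma-Poisson mixing variance (0 = pure Poisson)
    seed: int = 0

    def __post_init__(self):
        for name in ("haploid_depth", "zw_divergence", "indel_rate",
                     "background_het", "dup_psv_rate", "fail_fraction",
                     "overdispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def copy_number(region_class: str, sex: str, in_deletion: bool = False) -> int:
    """Copy number of a site in one sample, by region class and sex."""
    if sex not in SEXES:
        raise ValueError(f"unknown sex label {sex!r}")
    if region_class in ("AUTOSOME_LIKE", "PAR"):
        return 2
    if region_class == "HEMIZYGOUS_Z":
        return 1 if sex == "female" else 2
    if region_class == "ZTR":
        if sex == "female":
            return 1 if in_deletion else 2
        return 2
    if region_class == "Z_DUP":
        return 2 if sex == "female" else 4
    raise LayoutError(f"unknown region class {region_class!r}")


def _rng(params: SimParams, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(params.seed) & 0x7FFFFFFF, *stream])


# ---------------------------------------------------------------------------
# Reference sequence and gene models
# ---------------------------------------------------------------------------


@dataclass
class SimReference:
    """A simulated reference chromosome plus its planted truth."""

    layout: SimLayout
    params: SimParams
    sequence: str
    truth: dict


def simulate_reference(layout: SimLayout, params: SimParams) -> SimReference:
    """Generate the reference sequence, gene CDSs and planted truth.

    Gene coding segments are overwritten with a valid open reading frame
    (ATG ... sense codons ... TAA) so that downstream translation-based gene
    fate calls have a well-defined truth.
    """
    layout.validate()
    rng = _rng(params, 0)
    base_bytes = np.frombuffer(b"ACGT", dtype="S1")
    seq = base_bytes[rng.integers(0, 4, size=layout.chrom_length)]
    for gene in layout.genes:
        coding = _make_orf(gene.cds_length, rng)
        if gene.strand == "-":
            coding = _revcomp(coding)
            # distribute so transcription order (right to left) reads the ORF
        offset = 0
        for s, e in gene.cds:
            seg = coding[offset:offset + (e - s)]
            seq[s:e] = np.frombuffer(seg.encode(), dtype="S1")
            offset += e - s
    sequence = seq.tobytes().decode("ascii")

    truth = {
        "chrom": layout.chrom_name,
        "chrom_length": layout.chrom_length,
        "window_size": layout.window_size,
        "window_labels": layout.window_labels(),
        "regions": [[r.start, r.end, r.region_class] for r in layout.regions],
        "w_deletions": [list(d) for d in layout.w_deletions],
        "gene_fates": {g.name: _planted_fate(g, layout) for g in layout.genes},
    }
    return SimReference(layout=layout, params=params, sequence=sequence, truth=truth)


def _planted_fate(gene: GeneSpec, layout: SimLayout) -> str:
    inside = [d for d in layout.w_deletions
              if d[0] <= gene.start and gene.end <= d[1]]
    if inside:
        return "deleted"
    if any(gene.start < e and s < gene.end for s, e in layout.w_deletions):
        return "partial_deletion"
    if gene.planted_fate == "pseudogene_frameshift":
        return "pseudogene"
    return "intact"


def _make_orf(length: int, rng: np.random.Generator) -> str:
    """An ORF of `length` bp: ATG + sense codons + TAA, no internal stops."""
    n_codons = length // 3
    if n_codons < 2:
        raise LayoutError("CDS too short for an ORF")
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Depth tables
# ---------------------------------------------------------------------------


def simulate_depth(layout: SimLayout, params: SimParams, sex: str) -> pd.DataFrame:
    """Per-site depth table (samtools-depth dialect: chrom, 1-based pos, depth).

    Depth is Poisson(c*D) per site (optionally gamma-overdispersed); sites
    drawing depth 0 are absent from the table, as they are from a coverage-only
    depth report.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex label {sex!r}")
    layout.validate()
    rng = _rng(params, 1, SEXES.index(sex))
    depth = np.empty(layout.chrom_length, dtype=np.int32)
    for region in layout.regions:
        c = copy_number(region.region_class, sex)
        mean = c * params.haploid_depth
        n = region.length
        lam = np.full(n, mean)
        if region.region_class == "ZTR" and sex == "female":
            for ds, de in layout.w_deletions:
                if region.start <= ds and de <= region.end:
                    lam[ds - region.start:de - region.start] = params.haploid_depth
        if params.overdispersion > 0:
            shape = 1.0 / params.overdispersion
            lam = lam * rng.gamma(shape, 1.0 / shape, size=n)
        depth[region.start:region.end] = rng.poisson(lam)
    pos = np.arange(1, layout.chrom_length + 1, dtype=np.int64)
    keep = depth > 0
    n = int(keep.sum())
    return pd.DataFrame({
        "chrom": pd.Categorical.from_codes(np.zeros(n, dtype=np.int8),
                                           categories=[layout.chrom_name]),
        "pos": pos[keep],
        "depth": depth[keep],
    })


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


def _poisson_positions(rng, start, end, rate) -> np.ndarray:
    """Positions of a homogeneous Poisson process on [start, end) (0-based)."""
    n = rng.poisson(rate * (end - start))
    if n == 0:
        return np.empty(0, dtype=np.int64)
    pos = start + rng.integers(0, end - start, size=n)
    return np.unique(pos)


def _cds_index(genes: Sequence[GeneSpec]) -> list[tuple[int, int, GeneSpec]]:
    out = []
    for g in genes:
        for s, e in g.cds:
            out.append((s, e, g))
    out.sort(key=lambda t: t[0])
    return out


def _find_cds(cds_index, pos: int):
    for s, e, g in cds_index:
        if s <= pos < e:
            return s, e, g
        if s > pos:
            break
    return None


def _codon_coords(gene: GeneSpec, pos: int) -> tuple[list[int], int]:
    """Genomic positions of the codon containing `pos`, and the index of `pos`
    within that codon, in translation order."""
    coding_positions: list[int] = []
    for s, e in gene.cds:
        coding_positions.extend(range(s, e))
    if gene.strand == "-":
        coding_positions = coding_positions[::-1]
    idx = coding_positions.index(pos)
    c0 = (idx // 3) * 3
    return coding_positions[c0:c0 + 3], idx % 3


def _synonymize(seq: np.ndarray, gene: GeneSpec, pos: int,
                rng: np.random.Generator) -> tuple[int, str] | None:
    """Move/choose a substitution within the codon at `pos` so it is synonymous.

    Returns (genomic position, alt base on the + strand) or None if the codon
    admits no synonymous change (e.g. ATG, TGG).
    """
    codon_pos, _ = _codon_coords(gene, pos)
    codon = "".join(seq[p] for p in codon_pos)
    if gene.strand == "-":
        codon = _revcomp(codon)
    aa = _STANDARD_TABLE.forward_table.get(codon)
    if aa is None:
        return None
    options = []
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt_codon = codon[:i] + b + codon[i + 1:]
            if _STANDARD_TABLE.forward_table.get(alt_codon) == aa:
                options.append((i, b))
    if not options:
        return None
    i, b = options[rng.integers(len(options))]
    if gene.strand == "+":
        gpos = codon_pos[i]
        alt = b
    else:
        gpos = codon_pos[i]  # codon_pos already in translation order
        alt = _revcomp(b)
    return gpos, alt


def simulate_variants(reference: SimReference, sex: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the called-variant table for one sex.

    Returns ``(records, provenance)``. ``records`` has one row per variant
    with REF/ALT, the six hard-filter annotations, allele depths and allele
    fraction; ``provenance`` records the planted origin of each record
    (``background`` / ``divergence`` / ``dup_psv`` / ``w_indel``) and the
    hard-filter criterion it was planted to violate, if any.

    Divergence SNPs that fall inside the CDS of a gene whose planted fate is
    not a pseudogene are made synonymous (or dropped when the codon admits no
    synonymous change), so planted gene fates stay true under pseudo-sequence
    translation.  Genes planted as frameshift pseudogenes receive one 1-bp
    deletion near the middle of their CDS.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex label {sex!r}")
    layout, params = reference.layout, reference.params
    rng = _rng(params, 2, SEXES.index(sex))
    seq = reference.sequence  # plain string; per-record slicing is cheap
    cds_index = _cds_index(layout.genes)

    entries: list[dict] = []  # pos(0-based), class, is_indel

    # background polymorphism, both sexes, everywhere
    for p in _poisson_positions(rng, 0, layout.chrom_length, params.background_het):
        entries.append({"pos0": int(p), "origin": "background", "indel": False})
    # duplication PSVs, both sexes
    for region in layout.regions:
        if region.region_class == "Z_DUP":
            for p in _poisson_positions(rng, region.start, region.end, params.dup_psv_rate):
                entries.append({"pos0": int(p), "origin": "dup_psv", "indel": False})
    if sex == "female":
        for region in layout.regions:
            if region.region_class != "ZTR":
                continue
            # Z-W divergence SNPs outside W-deletions
            for p in _poisson_positions(rng, region.start, region.end, params.zw_divergence):
                if not layout.in_w_deletion(int(p)):
                    entries.append({"pos0": int(p), "origin": "divergence", "indel": False})
            # W-copy indels, kept out of CDS so they cannot silently flip fates
            for p in _poisson_positions(rng, region.start, region.end, params.indel_rate):
                p = int(p)
                if layout.in_w_deletion(p) or _find_cds(cds_index, p) or p + 4 >= region.end:
                    continue
                entries.append({"pos0": p, "origin": "w_indel", "indel": True})
        # planted frameshifts
        for g in layout.genes:
            if g.planted_fate != "pseudogene_frameshift":
                continue
            coding = []
            for s, e in g.cds:
                coding.extend(range(s, e))
            third = len(coding) // 3
            p = int(coding[third + int(rng.integers(third))])
            entries.append({"pos0": p, "origin": "w_indel_planted", "indel": True})

    # de-duplicate positions (priority: planted > divergence > rest)
    prio = {"w_indel_planted": 0, "divergence": 1, "w_indel": 2, "dup_psv": 3, "background": 4}
    entries.sort(key=lambda e: (e["pos0"], prio[e["origin"]]))
    dedup: list[dict] = []
    for e in entries:
        if dedup and dedup[-1]["pos0"] == e["pos0"]:
            continue
        dedup.append(e)

    rows = []
    prov = []
    for e in dedup:
        p = e["pos0"]
        origin = e["origin"]
        if e["indel"]:
            ref, alt = _draw_indel(seq, p, rng)
            if ref is None:
                continue
            if origin == "w_indel_planted":  # force a 1-bp frameshift deletion
                ref, alt = seq[p] + seq[p + 1], seq[p]
            vtype = "INDEL"
        else:
            ref = seq[p]
            if origin == "divergence":
                hit = _find_cds(cds_index, p)
                if hit and hit[2].planted_fate != "pseudogene_frameshift":
                    syn = _synonymize(seq, hit[2], p, rng)
                    if syn is None:
                        continue
                    p, alt = syn
                    ref = seq[p]
                else:
                    alt = _other_base(ref, rng)
            else:
                alt = _other_base(ref, rng)
            vtype = "SNP"

        region = layout.region_at(p)
        c = copy_number(region.region_class, sex, layout.in_w_deletion(p))
        total = max(int(rng.poisson(c * params.haploid_depth)), 2)
        frac = rng.beta(params.af_beta, params.af_beta)
        ad_alt = int(rng.binomial(total, frac))
        ad_alt = min(max(ad_alt, 1), total - 1)  # heterozygous call has both alleles
        info, planted_fail = _draw_annotations(rng, params.fail_fraction)
        rows.append({
            "chrom": layout.chrom_name, "pos": p + 1, "ref": ref, "alt": alt,
            "vtype": vtype, "sex": sex,
            "ad_ref": total - ad_alt, "ad_alt": ad_alt,
            "allele_fraction": ad_alt / total, **info,
        })
        prov.append({
            "chrom": layout.chrom_name, "pos": p + 1,
            "origin": "w_indel" if origin == "w_indel_planted" else origin,
            "planted_fail": planted_fail or "",
        })

    records = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "vtype", "sex", "ad_ref", "ad_alt",
        "allele_fraction", *HARD_FILTER_FIELDS])
    provenance = pd.DataFrame(prov, columns=["chrom", "pos", "origin", "planted_fail"])
    if len(records):
        order = np.argsort(records["pos"].to_numpy(), kind="stable")
        records = records.iloc[order].reset_index(drop=True)
        provenance = provenance.iloc[order].reset_index(drop=True)
    return records, provenance


def _other_base(ref: str, rng) -> str:
    alts = [b for b in "ACGT" if b != ref]
    return alts[rng.integers(3)]


def _draw_indel(seq, p, rng):
    size = int(rng.integers(1, 4))
    if p + size + 1 >= len(seq):
        return None, None
    if rng.random() < 0.5:  # deletion of `size` bases after the anchor
        ref = "".join(seq[p:p + size + 1])
        alt = seq[p]
    else:  # insertion of `size` random bases after the anchor
        ref = seq[p]
        alt = ref + "".join(BASES[rng.integers(0, 4, size=size)])
    return ref, alt


# distributions that satisfy / violate the downstream hard filters
_PASS_DRAWS = {
    "FS": lambda rng: rng.uniform(0.0, 8.0),
    "QD": lambda rng: rng.uniform(10.0, 35.0),
    "MQ": lambda rng: rng.uniform(55.0, 60.0),
    "SOR": lambda rng: rng.uniform(0.2, 1.3),
    "MQRankSum": lambda rng: rng.uniform(-1.2, 1.2),
    "ReadPosRankSum": lambda rng: rng.uniform(-2.0, 2.0),
}
_FAIL_DRAWS = {
    "FS": lambda rng: rng.uniform(10.5, 40.0),
    "QD": lambda rng: rng.uniform(0.0, 1.9),
    "MQ": lambda rng: rng.uniform(30.0, 49.5),
    "SOR": lambda rng: rng.uniform(1.6, 4.0),
    "MQRankSum": lambda rng: rng.uniform(-6.0, -1.6),
    "ReadPosRankSum": lambda rng: rng.uniform(-14.0, -8.5),
}


def _draw_annotations(rng, fail_fraction):
    info = {k: float(f(rng)) for k, f in _PASS_DRAWS.items()}
    planted = None
    if fail_fraction > 0 and rng.random() < fail_fraction:
        planted = HARD_FILTER_FIELDS[int(rng.integers(len(HARD_FILTER_FIELDS)))]
        info[planted] = float(_FAIL_DRAWS[planted](rng))
    return info, planted


# ---------------------------------------------------------------------------
# Codon alignments under branch-specific omega
# ---------------------------------------------------------------------------


@dataclass
class CodonSimResult:
    """Alignment of the tips plus realized substitution counts per branch."""

    alignment: dict[str, str]
    truth: dict[str, dict[str, int]]
    n_codons: int


def simulate_codon_alignment(
    n_codons: int,
    branches: Mapping[str, tuple[float, float]],
    seed: int,
    one_hit_per_codon: bool = True,
) -> CodonSimResult:
    """Evolve a gap-free in-frame alignment on the rooted tree ((Z,W),outgroup).

    ``branches`` maps branch names (must include ``"Z"``, ``"W"`` and
    ``"outgroup"``; ``"ancestor"`` for the internal Z/W-stem branch is
    optional, default length 0) to ``(length, omega)``.  Branch length is the
    expected number of neutral mutation attempts per nucleotide site.  Each
    attempt at a site proposes a random alternative base; proposals that
    create a stop codon are rejected, synonymous proposals are always
    accepted, and nonsynonymous proposals are accepted with probability
    ``omega`` — so the realized dN/dS on a branch equals its ``omega``.

    With ``one_hit_per_codon`` (the default, matching the young-divergence
    regime the detector targets) at most one substitution is realized per
    codon per branch, which keeps realized counts and minimal-path counts
    identical.
    """
    required = {"Z", "W", "outgroup"}
    missing = required - set(branches)
    if missing:
        raise ValueError(f"branches missing {sorted(missing)}")
    for name, (length, omega) in branches.items():
        if length < 0 or omega < 0:
            raise ValueError(f"branch {name}: length and omega must be >= 0")
    if n_codons < 50:
        warnings.warn("n_codons < 50: substitution-rate estimates will be unstable")

    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 3])
    root = [SENSE_CODONS[i] for i in rng.choice(len(SENSE_CODONS), size=n_codons)]

    def evolve(parent: list[str], length: float, omega: float):
        child = list(parent)
        hit = np.zeros(len(child), dtype=bool)
        counts = {"syn": 0, "nonsyn": 0}
        n_attempts = rng.poisson(length * 3 * len(child))
        for _ in range(n_attempts):
            site = int(rng.integers(3 * len(child)))
            ci, off = divmod(site, 3)
            if one_hit_per_codon and hit[ci]:
                continue
            codon = child[ci]
            alt = _other_base(codon[off], rng)
            new = codon[:off] + alt + codon[off + 1:]
            if new in STOP_CODONS:
                continue
            syn = _STANDARD_TABLE.forward_table[new] == _STANDARD_TABLE.forward_table[codon]
            if syn or rng.random() < omega:
                child[ci] = new
                hit[ci] = True
                counts["syn" if syn else "nonsyn"] += 1
        return child, counts

    truth = {}
    out_seq, truth["outgroup"] = evolve(root, *branches["outgroup"])
    anc_len, anc_om = branches.get("ancestor", (0.0, 1.0))
    anc_seq, truth["ancestor"] = evolve(root, anc_len, anc_om)
    z_seq, truth["Z"] = evolve(anc_seq, *branches["Z"])
    w_seq, truth["W"] = evolve(anc_seq, *branches["W"])

    alignment = {
        "Z": "".join(z_seq),
        "W": "".join(w_seq),
        "outgroup": "".join(out_seq),
    }
    return CodonSimResult(alignment=alignment, truth=truth, n_codons=n_codons)


# ---------------------------------------------------------------------------
# Expression and haploinsufficiency inputs
# ---------------------------------------------------------------------------


def simulate_expression(
    genes: Sequence[str],
    biased_genes: Sequence[str] = (),
    tissues: Sequence[str] = ("gonad", "brain", "liver", "heart"),
    species: Sequence[str] = ("species1",),
    n_replicates: int = 2,
    base_tpm: float = 20.0,
    bias_fold: float = 10.0,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format TPM table with replicates.

    Genes in ``biased_genes`` get a female-gonad mean expression at
    ``bias_fold`` times their mean in every other (tissue, sex) condition,
    emulating ovary-restricted expression; all other genes are flat across
    conditions.  Replicates are lognormal around the condition mean with
    coefficient of variation ``noise_cv``.
    """
    if "gonad" not in tissues:
        raise ValueError("tissues must include a gonad tissue for bias flagging")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 4])
    sigma = np.sqrt(np.log(1 + noise_cv ** 2))
    rows = []
    for sp in species:
        for gene in genes:
            base = base_tpm * rng.lognormal(0.0, 0.3)
            for tissue in tissues:
                for sex in SEXES:
                    mean = base
                    if gene in biased_genes:
                        mean = base * bias_fold if (tissue == "gonad" and sex == "female") else base
                    for rep in range(1, n_replicates + 1):
                        tpm = mean * rng.lognormal(-sigma ** 2 / 2, sigma)
                        rows.append((sp, tissue, sex, rep, gene, float(tpm)))
    return pd.DataFrame(rows, columns=["species", "tissue", "sex", "replicate", "gene", "tpm"])


def simulate_hi_scores(
    background_genes: Sequence[str],
    high_genes: Sequence[str] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic haploinsufficiency score table (gene, score in [0,1]).

    Background genes draw from Beta(2, 4); genes in ``high_genes`` draw from
    Beta(12, 2), placing them in the dosage-sensitive upper tail.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 5])
    rows = [(g, float(rng.beta(2, 4))) for g in background_genes if g not in set(high_genes)]
    rows += [(g, float(rng.beta(12, 2))) for g in high_genes]
    return pd.DataFrame(rows, columns=["gene", "score"])


# ---------------------------------------------------------------------------
# Writers (plain-text external formats)
# ---------------------------------------------------------------------------


def write_fasta(name: str, sequence: str, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


def write_gff3(layout: SimLayout, path) -> None:
    """Gene models as GFF3 (1-based inclusive) with gene/mRNA/CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {layout.chrom_name} 1 {layout.chrom_length}\n")
        for g in sorted(layout.genes, key=lambda g: g.start):
            c, src = layout.chrom_name, "ztrscan_sim"
            fh.write(f"{c}\t{src}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID=gene:{g.name};Name={g.name}\n")
            fh.write(f"{c}\t{src}\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID=mrna:{g.name};Parent=gene:{g.name}\n")
            segs = g.cds if g.strand == "+" else tuple(reversed(g.cds))
            phase = 0
            for s, e in segs:
                fh.write(f"{c}\t{src}\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                         f"ID=cds:{g.name};Parent=mrna:{g.name}\n")
                phase = (3 - ((e - s) - phase) % 3) % 3


def write_depth(depth: pd.DataFrame, path) -> None:
    depth.to_csv(path, sep="\t", header=False, index=False)


VCF_HEADER_LINES = [
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias (Fisher)">',
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio strand bias">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank-sum">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
]


def write_vcf(records: pd.DataFrame, path, contigs: Mapping[str, int],
              sample: str = "sample", filters: pd.Series | None = None) -> None:
    """Write a variant table as VCF v4.2 (uncompressed text).

    ``filters``, if given, populates the FILTER column (``PASS`` or
    semicolon-joined fail reasons); otherwise FILTER is ``.``.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for line in VCF_HEADER_LINES:
            fh.write(line + "\n")
        if filters is not None:
            fh.write('##FILTER=<ID=lowqual,Description="Failed hard filters">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
        recs = records.sort_values(["chrom", "pos"], kind="stable")
        for i, row in recs.iterrows():
            info = ";".join(f"{k}={row[k]:.3f}" for k in HARD_FILTER_FIELDS
                            if pd.notna(row[k]))
            filt = "." if filters is None else (filters.loc[i] or "PASS")
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t{filt}\t"
                     f"{info}\tGT:AD\t0/1:{row.ad_ref},{row.ad_alt}\n")


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True, default_flow_style=None)
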