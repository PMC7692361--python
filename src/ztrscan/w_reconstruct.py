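"""W-linked ZTR pseudo-sequence reconstruction and W-deletion accounting.

The W haplotype of a young Z-transposed region is approximated by
substituting the female PASS heterozygous alternate alleles (SNPs and
indels) into the Z reference over the ZTR envelope — the alternate allele is
assigned to the W copy, which is unphased but appropriate while Z-W
divergence dwarfs polymorphism.  A piecewise coordinate map tracks indel
offsets so gene coordinates can be lifted from Z to the W pseudo-sequence.
W-deletions are coverage-defined at window resolution: interior hemizygous
runs inside a ZTR envelope of at least ``min_run`` windows.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .region_classify import RegionCall

__all__ = [
    "CoordMap",
    "WPseudoSequence",
    "WDeletionSet",
    "build_w_pseudosequence",
    "call_w_deletions",
    "liftover",
    "derive_variants",
    "left_normalize",
]


@dataclass
class CoordMap:
    """Piecewise-monotone Z -> W-pseudo position map over one ZTR envelope.

    ``breakpoints`` holds (z_threshold, cumulative_offset) pairs, meaning the
    offset applies to Z positions >= z_threshold (0-based, chromosome
    coordinates).  Positions inside the REF span of an applied deletion
    variant have no image and are reported as unmappable.
    """

    interval: tuple[int, int]
    breakpoints: list[tuple[int, int]] = field(default_factory=list)
    deleted_spans: list[tuple[int, int]] = field(default_factory=list)

    def offset_at(self, zpos: int) -> int:
        i = bisect.bisect_right([b[0] for b in self.breakpoints], zpos)
        return self.breakpoints[i - 1][1] if i else 0

    def z_to_w(self, zpos: int) -> int | None:
        """Map one Z position to the W pseudo-sequence (None if deleted)."""
        s, e = self.interval
        if not s <= zpos < e:
            raise ValueError(f"position {zpos} outside ZTR envelope [{s}, {e})")
        for ds, de in self.deleted_spans:
            if ds <= zpos < de:
                return None
        return zpos - s + self.offset_at(zpos)

    def w_bound(self, zpos: int) -> int:
        """W coordinate of an interval boundary: positions inside a removed
        indel span collapse onto the span's right edge."""
        for ds, de in self.deleted_spans:
            if ds <= zpos < de:
                zpos = de
                break
        return zpos - self.interval[0] + self.offset_at(zpos)

    def to_frame(self) -> pd.DataFrame:
        rows = [(z, z - self.interval[0] + off, off) for z, off in self.breakpoints]
        return pd.DataFrame(rows, columns=["z_pos", "w_pos", "cumulative_offset"])


@dataclass
class WPseudoSequence:
    sequence: str
    applied_variants: pd.DataFrame
    skipped_variants: int
    coord_map: CoordMap
    source_interval: tuple[int, int]


@dataclass
class WDeletionSet:
    deletions: list[tuple[int, int]]
    envelope: tuple[int, int]

    @property
    def total_deleted(self) -> int:
        return sum(e - s for s, e in self.deletions)

    @property
    def envelope_length(self) -> int:
        return self.envelope[1] - self.envelope[0]

    @property
    def retained_length(self) -> int:
        return self.envelope_length - self.total_deleted

    def summary(self) -> dict:
        return {
            "envelope_bp": self.envelope_length,
            "deleted_bp": self.total_deleted,
            "retained_bp": self.retained_length,
            "retained_mb": round(self.retained_length / 1e6, 1),
            "n_deletions": len(self.deletions),
        }


def build_w_pseudosequence(reference: str, interval: tuple[int, int],
                           variants: pd.DataFrame) -> WPseudoSequence:
    """Apply sorted female PASS variants to the Z reference over ``interval``.

    Alternate alleles are substituted left to right; a variant whose REF span
    intersects an already-applied span is skipped (leftmost wins) and counted.
    REF alleles are checked against the reference; a mismatch raises with the
    offending position.  Output length equals the interval length plus the
    summed signed indel lengths of applied variants, exactly.
    """
    s, e = interval
    if not 0 <= s < e <= len(reference):
        raise ValueError(f"interval [{s}, {e}) outside reference")
    v = variants.sort_values("pos", kind="stable").reset_index(drop=True)
    pieces: list[str] = []
    breakpoints: list[tuple[int, int]] = []
    applied_idx: list[int] = []
    skipped = 0
    cursor = s  # next unconsumed Z position
    offset = 0
    for i, row in v.iterrows():
        z0 = int(row.pos) - 1
        ref, alt = str(row.ref), str(row.alt)
        if z0 < s or z0 + len(ref) > e:
            raise ValueError(f"variant at {row.pos} outside interval [{s}, {e})")
        if z0 < cursor:  # overlaps an already-applied span
            skipped += 1
            continue
        if reference[z0:z0 + len(ref)] != ref:
            raise ValueError(
                f"REF mismatch at {row.chrom if 'chrom' in v.columns else '?'}:"
                f"{row.pos}: expected {reference[z0:z0 + len(ref)]!r}, got {ref!r}")
        pieces.append(reference[cursor:z0])
        pieces.append(alt)
        cursor = z0 + len(ref)
        delta = len(alt) - len(ref)
        if delta != 0:
            offset += delta
            breakpoints.append((cursor, offset))
        applied_idx.append(i)
    pieces.append(reference[cursor:e])
    seq = "".join(pieces)
    removed = [(int(r.pos), len(r.ref) - len(r.alt))
               for r in v.loc[applied_idx].itertuples()
               if len(r.ref) > len(r.alt)]
    # bases removed by a deletion variant (anchor base kept) have no W image
    deleted_spans = [(p, p + d) for p, d in removed]  # pos is 1-based anchor
    cmap = CoordMap(interval=(s, e), breakpoints=breakpoints,
                    deleted_spans=deleted_spans)
    applied = v.loc[applied_idx].reset_index(drop=True)
    assert len(seq) == (e - s) + sum(
        len(a) - len(r) for r, a in zip(applied["ref"], applied["alt"]))
    return WPseudoSequence(sequence=seq, applied_variants=applied,
                           skipped_variants=skipped, coord_map=cmap,
                           source_interval=(s, e))


def call_w_deletions(ztr_call: RegionCall, min_run: int = 2,
                     window_size: int = 50_000) -> WDeletionSet:
    """Turn interior hemizygous candidate runs of a ZTR call into W-deletions.

    Candidates shorter than ``min_run`` windows are ignored.  Deletion
    intervals are window-aligned Z coordinates; retained length is the
    envelope length minus the summed deletion lengths (exact bookkeeping).
    """
    if ztr_call.label != "ZTR":
        raise ValueError("call_w_deletions expects a ZTR region call")
    dels = [(s, e) for s, e in sorted(ztr_call.interior_candidates)
            if (e - s) >= min_run * window_size]
    return WDeletionSet(deletions=dels, envelope=(ztr_call.start, ztr_call.end))


def liftover(coord_map: CoordMap, z_interval: tuple[int, int],
             deletions: WDeletionSet | None = None) -> tuple[tuple[int, int] | None, str]:
    """Map a Z interval through the coordinate map.

    Returns ``(w_interval, status)`` with status ``"ok"``, ``"partial"``
    (interval truncated against a coverage-defined W-deletion) or
    ``"deleted"`` (interval wholly inside one, w_interval None).  Small
    indel variants applied during reconstruction shift or shrink the mapped
    interval but never mark it partial.  Raises when the interval escapes
    the ZTR envelope.
    """
    zs, ze = z_interval
    s, e = coord_map.interval
    if not (s <= zs < ze <= e):
        raise ValueError(f"interval [{zs}, {ze}) outside ZTR envelope [{s}, {e})")
    status = "ok"
    del_spans = list(deletions.deletions) if deletions else []
    for ds, de in del_spans:
        if ds <= zs and ze <= de:
            return None, "deleted"
        if zs < de and ds < ze:  # partial overlap: truncate
            status = "partial"
            if ds <= zs:
                zs = de
            elif ze <= de:
                ze = ds
            else:  # deletion strictly interior: keep the larger flank
                zs, ze = (zs, ds) if (ds - zs) >= (ze - de) else (de, ze)
    w_start = coord_map.w_bound(zs)
    w_end = coord_map.w_bound(ze)
    return (w_start, max(w_end, w_start)), status


# ---------------------------------------------------------------------------
# Variant re-derivation (independent route, via exact alignment)
# ---------------------------------------------------------------------------


def derive_variants(z_seq: str, w_seq: str, chrom: str = "chr",
                    z_offset: int = 0) -> pd.DataFrame:
    """Re-derive the variant set separating two sequences by exact alignment.

    Uses a global gap-affine alignment (substitutions cheaper than an
    insertion-deletion pair; gap extension cheaper than gap opening, so
    multi-base indels stay consolidated) and converts the alignment into
    VCF-style records: one SNP per mismatch column, indels anchored on the
    preceding reference base and left-normalized.  ``z_offset`` is the
    0-based chromosome coordinate of ``z_seq[0]``.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(z_seq, w_seq)[0]
    z_blocks, w_blocks = aln.aligned
    rows = []
    prev_z = prev_w = 0
    for (zs, ze), (ws, we) in zip(z_blocks, w_blocks):
        if zs > prev_z:  # bases present in Z only: deletion on W
            anchor = prev_z - 1
            if anchor < 0:
                raise ValueError("leading indel without an anchor base")
            rows.append((anchor, z_seq[anchor:zs], z_seq[anchor]))
        if ws > prev_w:  # bases present in W only: insertion on W
            anchor = zs - 1
            if anchor < 0:
                raise ValueError("leading indel without an anchor base")
            rows.append((anchor, z_seq[anchor], z_seq[anchor] + w_seq[prev_w:ws]))
        for k in range(ze - zs):
            if z_seq[zs + k] != w_seq[ws + k]:
                rows.append((zs + k, z_seq[zs + k], w_seq[ws + k]))
        prev_z, prev_w = ze, we
    if len(z_seq) > prev_z:
        anchor = prev_z - 1
        rows.append((anchor, z_seq[anchor:], z_seq[anchor]))
    if len(w_seq) > prev_w:
        anchor = len(z_seq) - 1
        rows.append((anchor, z_seq[anchor], z_seq[anchor] + w_seq[prev_w:]))
    out = []
    for pos0, ref, alt in rows:
        pos0, ref, alt = left_normalize(z_seq, pos0, ref, alt)
        out.append({"chrom": chrom, "pos": z_offset + pos0 + 1, "ref": ref, "alt": alt,
                    "vtype": "SNP" if len(ref) == len(alt) == 1 else "INDEL"})
    df = pd.DataFrame(out, columns=["chrom", "pos", "ref", "alt", "vtype"])
    return df.sort_values("pos", kind="stable").reset_index(drop=True)


def left_normalize(seq: str, pos0: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align an indel against ``seq`` (0-based ``pos0``), VCF-style.

    Trims shared trailing bases, then shifts left while the representation is
    equivalent.  SNPs are returned unchanged.
    """
    if len(ref) == len(alt) == 1:
        return pos0, ref, alt
    ref_l, alt_l = list(ref), list(alt)
    while len(ref_l) > 1 and len(alt_l) > 1 and ref_l[-1] == alt_l[-1]:
        ref_l.pop()
        alt_l.pop()
    while pos0 > 0 and ref_l[-1] == alt_l[-1] and min(len(ref_l), len(alt_l)) == 1:
        prev = seq[pos0 - 1]
        ref_l = [prev] + ref_l[:-1]
        alt_l = [prev] + alt_l[:-1]
        pos0 -= 1
        while len(ref_l) > 1 and len(alt_l) > 1 and ref_l[-1] == alt_l[-1]:
            ref_l.pop()
            alt_l.pop()
        if ref_l[-1] != alt_l[-1]:
            break
    return pos0, "".join(ref_l), "".join(alt_l)
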