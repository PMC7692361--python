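"""Gene fate on the W copy of a Z-transposed region.

Each transposed gene is classified as ``deleted`` (gene body wholly inside a
W-deletion), ``partial_deletion`` (any overlap with a deletion, even if the
residual ORF could be intact), ``pseudogene`` (frameshift when the net indel
length inside the CDS is not a multiple of 3, and/or a premature in-frame
stop before the annotated terminal codon), or ``intact``.  The W CDS is
obtained by lifting the Z gene model through the pseudo-sequence coordinate
map and translating with the standard genetic code — a coordinate-liftover
substitute for homology-based gene prediction, justified by the low Z-W
divergence of young transposed regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gffutils
import pandas as pd
from Bio.Seq import Seq

from .w_reconstruct import WDeletionSet, WPseudoSequence, liftover

__all__ = [
    "GeneModel",
    "GeneFate",
    "read_gff3",
    "intersect_gene_deletions",
    "assess_orf",
    "classify_gene_fates",
    "summarize_fates",
]

FATES = ("intact", "partial_deletion", "deleted", "pseudogene")


@dataclass(frozen=True)
class GeneModel:
    """Gene with ordered CDS segments; coordinates 0-based half-open."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: tuple[tuple[int, int], ...]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass(frozen=True)
class GeneFate:
    name: str
    fate: str
    pseudogene_cause: str = "NA"  # frameshift | premature_stop | both | NA
    detail: str = ""

    def __post_init__(self):
        if (self.fate == "pseudogene") != (self.pseudogene_cause != "NA"):
            raise ValueError("pseudogene_cause set iff fate is pseudogene")


def read_gff3(path) -> list[GeneModel]:
    """Load gene models (gene + CDS features) from a GFF3 file."""
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        name = g.attributes.get("Name", [g.id.split(":")[-1]])[0]
        cds = sorted((c.start - 1, c.end) for c in db.children(g, featuretype="CDS"))
        genes.append(GeneModel(name=name, chrom=g.seqid, start=g.start - 1,
                               end=g.end, strand=g.strand, cds=tuple(cds)))
    genes.sort(key=lambda g: g.start)
    return genes


def intersect_gene_deletions(genes: list[GeneModel], deletions: WDeletionSet,
                             envelope: tuple[int, int] | None = None
                             ) -> dict[str, GeneFate | None]:
    """Provisional fates from deletion overlap; None means 'assess the ORF'."""
    env = envelope or deletions.envelope
    out: dict[str, GeneFate | None] = {}
    for gene in genes:
        if gene.end <= env[0] or gene.start >= env[1]:
            warnings.warn(f"gene {gene.name} outside ZTR envelope; skipped")
            continue
        covering = [d for d in deletions.deletions
                    if d[0] <= gene.start and gene.end <= d[1]]
        if covering:
            out[gene.name] = GeneFate(gene.name, "deleted",
                                      detail=f"inside deletion {covering[0]}")
            continue
        touching = [d for d in deletions.deletions
                    if gene.start < d[1] and d[0] < gene.end]
        if touching:
            out[gene.name] = GeneFate(gene.name, "partial_deletion",
                                      detail=f"overlaps deletion {touching[0]}")
            continue
        out[gene.name] = None
    return out


def assess_orf(gene: GeneModel, wps: WPseudoSequence,
               deletions: WDeletionSet | None = None,
               z_reference: str | None = None) -> GeneFate:
    """Translate the lifted W CDS and call frameshift / premature stop.

    ``z_reference``, when given, is used for an input sanity check: the Z CDS
    of a complete gene model must itself translate without internal stops.
    """
    if z_reference is not None:
        z_prot = _translate_cds(z_reference, gene.cds, gene.strand,
                                offset=0)
        if "*" in z_prot[:-1]:
            warnings.warn(f"gene {gene.name}: Z CDS has an internal stop "
                          "(input gene model suspect)")

    w_segments = []
    z_len = 0
    for s, e in gene.cds:
        try:
            w_iv, status = liftover(wps.coord_map, (s, e), deletions)
        except ValueError:
            return GeneFate(gene.name, "partial_deletion",
                            detail=f"CDS segment [{s},{e}) escapes envelope")
        if status != "ok" or w_iv is None:
            return GeneFate(gene.name, "partial_deletion",
                            detail=f"CDS segment [{s},{e}) unliftable ({status})")
        w_segments.append(w_iv)
        z_len += e - s

    w_len = sum(e - s for s, e in w_segments)
    frameshift = (w_len - z_len) % 3 != 0

    w_cds = "".join(wps.sequence[s:e] for s, e in w_segments)
    if gene.strand == "-":
        w_cds = str(Seq(w_cds).reverse_complement())
    # translate complete codons only (a frameshifted CDS has a ragged tail)
    prot = str(Seq(w_cds[:len(w_cds) - len(w_cds) % 3]).translate())
    premature = "*" in prot[:-1]

    if frameshift and premature:
        return GeneFate(gene.name, "pseudogene", "both",
                        f"net indel {w_len - z_len} bp; stop at codon {prot.index('*') + 1}")
    if frameshift:
        return GeneFate(gene.name, "pseudogene", "frameshift",
                        f"net indel length {w_len - z_len} bp in CDS")
    if premature:
        return GeneFate(gene.name, "pseudogene", "premature_stop",
                        f"in-frame stop at codon {prot.index('*') + 1} of {len(prot)}")
    return GeneFate(gene.name, "intact")


def _translate_cds(reference: str, cds, strand: str, offset: int) -> str:
    s = "".join(reference[a - offset:b - offset] for a, b in cds)
    if strand == "-":
        s = str(Seq(s).reverse_complement())
    return str(Seq(s[:len(s) - len(s) % 3]).translate())


def classify_gene_fates(genes: list[GeneModel], wps: WPseudoSequence,
                        deletions: WDeletionSet,
                        z_reference: str | None = None) -> list[GeneFate]:
    """Full per-gene pipeline: deletion intersection, then ORF assessment."""
    provisional = intersect_gene_deletions(genes, deletions)
    by_name = {g.name: g for g in genes}
    fates = []
    for name, fate in provisional.items():
        if fate is None:
            fate = assess_orf(by_name[name], wps, deletions, z_reference)
        fates.append(fate)
    return fates


def summarize_fates(fates_by_lineage: dict[str, list[GeneFate]]) -> tuple[pd.DataFrame, dict]:
    """Per-lineage and pooled fate counts with survival accounting.

    Returns a tidy count table and a totals dict with ``total_genes``,
    ``functional`` (intact count), ``survival_fraction`` and
    ``percent_lost`` (rounded to the nearest integer).
    """
    if not fates_by_lineage:
        raise ValueError("summarize_fates: need at least one fate list")
    rows = []
    for lineage, fates in fates_by_lineage.items():
        counts = {f: 0 for f in FATES}
        for fate in fates:
            counts[fate.fate] += 1
        n = len(fates)
        rows.append({
            "lineage": lineage, "n_genes": n, **counts,
            "survival_fraction": counts["intact"] / n if n else float("nan"),
            "percent_lost": round(100 * (n - counts["intact"]) / n) if n else 0,
        })
    table = pd.DataFrame(rows)
    total = int(table["n_genes"].sum())
    functional = int(table["intact"].sum())
    totals = {
        "total_genes": total,
        "functional": functional,
        "survival_fraction": functional / total if total else float("nan"),
        "percent_lost": round(100 * (total - functional) / total) if total else 0,
    }
    return table, totals
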