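"""Construction of the epistasis candidate marker set.

Homology hits against a curated list of trait-related genes are filtered at
strict identity/length thresholds, mapped to on-array markers through gene
intervals, and unioned with the GWAS-significant genic markers.  The
bookkeeping mirrors the published accounting style: the "related" row
excludes markers/genes already in the GWAS row, the overlap is reported
separately, and the total row is the union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from soyepi.datatypes import GeneAnnotation, HomologyHit, MarkerInfo


@dataclass
class MarkerSet:
    """The curated union, with provenance per marker."""

    #: marker_id -> one of "gwas_significant", "homology_derived", "both"
    provenance: dict[str, str]
    n_gwas: int
    n_homology: int
    n_overlap: int

    @property
    def marker_ids(self) -> list[str]:
        return sorted(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)


def filter_homology_hits(
    hits: Iterable[HomologyHit],
    min_identity: float = 80.0,
    min_length: int = 70,
    strict: bool = True,
) -> list[HomologyHit]:
    """Keep hits passing the identity/length thresholds.

    Thresholds are strict (">") by default, matching the published options;
    set ``strict=False`` for ">=" sensitivity analyses.  Hits are
    deduplicated to unique (query, subject) pairs keeping the best e-value.
    """
    if strict:
        kept = [
            h for h in hits
            if h.percent_identity > min_identity and h.alignment_length > min_length
        ]
    else:
        kept = [
            h for h in hits
            if h.percent_identity >= min_identity and h.alignment_length >= min_length
        ]
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in kept:
        key = (h.query_gene, h.subject_gene)
        if key not in best or h.e_value < best[key].e_value:
            best[key] = h
    return [best[k] for k in sorted(best)]


def snp_to_gene(
    markers: Sequence[MarkerInfo] | Sequence[tuple[str, str, int]],
    annotation: Sequence[GeneAnnotation],
) -> dict[str, list[str]]:
    """Map markers into gene intervals (1-based closed containment).

    Returns gene_id -> list of contained marker ids; markers outside every
    gene are unmapped.  A marker inside overlapping genes is assigned to all
    of them.
    """
    triples = [
        (m.marker_id, m.chromosome, m.position) if isinstance(m, MarkerInfo) else m
        for m in markers
    ]
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chromosome, []).append(g)
    mapping: dict[str, list[str]] = {}
    for marker_id, chrom, pos in triples:
        for g in by_chrom.get(chrom, ()):
            if g.start <= pos <= g.end:
                mapping.setdefault(g.gene_id, []).append(marker_id)
    return mapping


def build_marker_set(
    homology_markers: Iterable[str],
    significant_genic_markers: Iterable[str],
) -> MarkerSet:
    """Union of homology-derived and GWAS-significant marker id sets,
    deduplicated by marker id, with provenance recorded."""
    hom = set(homology_markers)
    sig = set(significant_genic_markers)
    provenance = {}
    for m in hom | sig:
        if m in hom and m in sig:
            provenance[m] = "both"
        elif m in sig:
            provenance[m] = "gwas_significant"
        else:
            provenance[m] = "homology_derived"
    return MarkerSet(
        provenance=provenance,
        n_gwas=len(sig),
        n_homology=len(hom),
        n_overlap=len(hom & sig),
    )


def summarize_counts(
    gwas_genes: Iterable[str],
    gwas_markers: Iterable[str],
    related_genes: Iterable[str],
    related_markers: Iterable[str],
    source_gene_counts: tuple[int, int] | None = None,
    corresponding_gene_counts: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Accounting table for the marker-set construction.

    Rows: ``gwas`` (significant genes/markers), ``related`` (homology-derived
    genes/markers, *excluding* those already significant — the excluded
    overlap is reported in ``overlap_*``), ``total`` (union).  The optional
    source/corresponding gene counts are pass-through columns for the
    upstream literature-derived lists, which are inputs rather than computed
    quantities.
    """
    gw_g, gw_m = set(gwas_genes), set(gwas_markers)
    re_g, re_m = set(related_genes), set(related_markers)
    overlap_g = gw_g & re_g
    overlap_m = gw_m & re_m
    rows = {
        "gwas": {
            "genes_on_array": len(gw_g),
            "markers_on_array": len(gw_m),
            "overlap_genes": 0,
            "overlap_markers": 0,
        },
        "related": {
            "genes_on_array": len(re_g - gw_g),
            "markers_on_array": len(re_m - gw_m),
            "overlap_genes": len(overlap_g),
            "overlap_markers": len(overlap_m),
        },
        "total": {
            "genes_on_array": len(gw_g | re_g),
            "markers_on_array": len(gw_m | re_m),
            "overlap_genes": len(overlap_g),
            "overlap_markers": len(overlap_m),
        },
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    if source_gene_counts is not None:
        table["source_genes"] = [
            source_gene_counts[0], source_gene_counts[1], sum(source_gene_counts),
        ]
    if corresponding_gene_counts is not None:
        table["corresponding_genes"] = [
            corresponding_gene_counts[0], corresponding_gene_counts[1],
            sum(corresponding_gene_counts),
        ]
    return table
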