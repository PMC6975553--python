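"""Readers and writers for the standard formats the pipeline consumes.

Genotypes come from VCF (biallelic SNPs only), phenotypes from delimited
text, gene models from BED or GFF3, homology evidence from 12-column BLAST
tabular output.  All results leave the pipeline as plain TSV with a fixed
column order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from soyepi.datatypes import (
    VALID_ALLELES,
    GeneAnnotation,
    GenotypeMatrix,
    HomologyHit,
    MarkerInfo,
    PhenotypeVector,
)

log = logging.getLogger(__name__)

MISSING_POLICIES = ("error", "drop_marker", "mode_impute")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    missing_policy: str = "error",
    strict: bool = False,
) -> GenotypeMatrix:
    """Load a VCF into a dosage matrix.

    Multiallelic or non-SNP records are skipped (or rejected when
    ``strict=True``); a count of skipped records is logged.  Missing
    genotype calls are handled according to ``missing_policy``:

    ``error``
        raise (the default: the study data were imputed upstream),
    ``drop_marker``
        remove any marker with at least one missing call,
    ``mode_impute``
        replace missing calls with the marker's most frequent dosage.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    markers: list[MarkerInfo] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    n_dropped_missing = 0

    for variant in vcf:
        alts = variant.ALT
        ref = variant.REF
        if len(alts) != 1 or len(ref) != 1 or len(alts[0]) != 1 \
                or ref not in VALID_ALLELES or alts[0] not in VALID_ALLELES:
            if strict:
                raise ValueError(
                    f"{path}: non-biallelic-SNP record at {variant.CHROM}:{variant.POS}"
                )
            n_skipped += 1
            continue
        gts = np.asarray(variant.genotypes, dtype=int)  # (n, 3): a0, a1, phased
        alleles = gts[:, :2]
        missing = (alleles < 0).any(axis=1)
        dosage = alleles.clip(min=0).sum(axis=1)
        if missing.any():
            if missing_policy == "error":
                raise ValueError(
                    f"{path}: missing genotype at {variant.CHROM}:{variant.POS} "
                    "(missing_policy='error')"
                )
            if missing_policy == "drop_marker":
                n_dropped_missing += 1
                continue
            observed = dosage[~missing]
            mode = np.bincount(observed, minlength=3).argmax() if observed.size else 0
            dosage = dosage.copy()
            dosage[missing] = mode
        marker_id = variant.ID or f"{variant.CHROM}_{variant.POS}"
        markers.append(
            MarkerInfo(
                marker_id=marker_id,
                chromosome=variant.CHROM,
                position=variant.POS,
                ref_allele=ref,
                alt_allele=alts[0],
            )
        )
        columns.append(dosage.astype(np.int8))

    if n_skipped:
        log.info("read_genotypes(%s): skipped %d non-biallelic-SNP records", path, n_skipped)
    if n_dropped_missing:
        log.info("read_genotypes(%s): dropped %d markers with missing calls", path, n_dropped_missing)
    if not markers:
        raise ValueError(f"{path}: no usable biallelic SNP records")

    dosages = np.column_stack(columns)
    return GenotypeMatrix(sample_ids=sample_ids, markers=markers, dosages=dosages)


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 file (GT only, unphased)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(m.chromosome for m in genotypes.markers):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j, m in enumerate(genotypes.markers):
            calls = "\t".join(gt_strings[int(d)] for d in genotypes.dosages[:, j])
            fh.write(
                f"{m.chromosome}\t{m.position}\t{m.marker_id}\t{m.ref_allele}\t"
                f"{m.alt_allele}\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(
    path: str | Path,
    id_column: str = "sample_id",
    value_column: str = "dtf",
    sep: str = "\t",
) -> PhenotypeVector:
    """Read a delimited phenotype table (header required, order preserved)."""
    table = pd.read_csv(path, sep=sep)
    for col in (id_column, value_column):
        if col not in table.columns:
            raise KeyError(f"{path}: column {col!r} not found")
    ids = table[id_column].astype(str).tolist()
    if table[id_column].duplicated().any():
        dups = table[id_column][table[id_column].duplicated()].tolist()
        raise ValueError(f"{path}: duplicated sample ids {dups[:5]}")
    values = pd.to_numeric(table[value_column], errors="raise").to_numpy(dtype=float)
    return PhenotypeVector(sample_ids=ids, values=values)


def write_phenotypes(phenotypes: PhenotypeVector, path: str | Path,
                     id_column: str = "sample_id", value_column: str = "dtf") -> None:
    pd.DataFrame({id_column: phenotypes.sample_ids,
                  value_column: phenotypes.values}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based
    closed); both are normalized to the internal 1-based closed convention
    and returned sorted by (chromosome, start)."""
    path = Path(path)
    text = path.read_text()
    genes: list[GeneAnnotation] = []
    if path.suffix.lower() in (".gff", ".gff3"):
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: GFF3 line with <9 columns")
            if parts[2] != "gene":
                continue
            attrs = dict(
                kv.partition("=")[::2] for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name") or f"gene_{lineno}"
            genes.append(
                GeneAnnotation(gene_id, parts[0], int(parts[3]), int(parts[4]))
            )
    else:  # BED
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with <3 columns")
            name = parts[3] if len(parts) > 3 else f"gene_{lineno}"
            # BED start is 0-based: shift to 1-based closed
            genes.append(
                GeneAnnotation(name, parts[0], int(parts[1]) + 1, int(parts[2]))
            )
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return genes


def write_gene_annotation_bed(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# homology hits
# ---------------------------------------------------------------------------

def read_homology_table(path: str | Path) -> list[HomologyHit]:
    """Parse 12-column BLAST tabular output (outfmt 6), no filtering."""
    hits: list[HomologyHit] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise ValueError(f"{path}:{lineno}: expected 12 tab-separated columns")
        try:
            hits.append(
                HomologyHit(
                    query_gene=parts[0],
                    subject_gene=parts[1],
                    percent_identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    e_value=float(parts[10]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
    return hits


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

ASSOC_COLUMNS = [
    "marker_id", "chromosome", "position", "effect", "se",
    "p_value", "neglog10_p", "maf", "significant",
]
INTERACTION_COLUMNS = [
    "group", "kind", "posterior", "marker_id", "chromosome", "position",
    "gene_id", "p_min", "p_max",
]
WINDOW_COLUMNS = ["chromosome", "window_start", "window_end", "value", "n_sites", "truncated"]


def write_association_results(results: Iterable, path: str | Path) -> None:
    """Association table; doubles as the Manhattan/QQ plot source table."""
    rows = [
        {
            "marker_id": r.marker_id, "chromosome": r.chromosome,
            "position": r.position, "effect": r.effect, "se": r.se,
            "p_value": r.p_value, "neglog10_p": r.neglog10_p,
            "maf": r.maf, "significant": r.significant,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=ASSOC_COLUMNS).to_csv(path, sep="\t", index=False)


def write_interaction_groups(groups: Iterable, path: str | Path) -> None:
    """One row per marker per interaction group (group / position / gene /
    pairwise p-value range layout)."""
    rows = []
    for i, g in enumerate(groups, start=1):
        for marker_id, chrom, pos, gene in zip(
            g.marker_ids, g.chromosomes, g.positions, g.gene_ids
        ):
            rows.append(
                {
                    "group": f"G{i}", "kind": g.kind, "posterior": g.posterior,
                    "marker_id": marker_id, "chromosome": chrom, "position": pos,
                    "gene_id": gene, "p_min": g.p_min, "p_max": g.p_max,
                }
            )
    pd.DataFrame(rows, columns=INTERACTION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_window_stats(windows: Iterable, path: str | Path) -> None:
    rows = [
        {
            "chromosome": w.chromosome, "window_start": w.start,
            "window_end": w.end, "value": w.value, "n_sites": w.n_sites,
            "truncated": w.truncated,
        }
        for w in windows
    ]
    pd.DataFrame(rows, columns=WINDOW_COLUMNS).to_csv(path, sep="\t", index=False)


def write_matrix(sample_ids: Sequence[str], values: np.ndarray, path: str | Path) -> None:
    """Square matrix (IBS, K2P, kinship) as TSV with id header/index."""
    pd.DataFrame(values, index=list(sample_ids), columns=list(sample_ids)) \
        .to_csv(path, sep="\t")
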