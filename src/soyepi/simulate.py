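"""Synthetic genotype/phenotype generator.

The generator emulates the statistical structure of a large inbred cultivar
collection: two weakly diverged subgroups (improved-cultivar-like "IC" and
landrace-like "LR"), Balding-Nichols allele-frequency divergence at a target
Fst, extreme excess homozygosity from habitual selfing, local linkage
disequilibrium decaying exponentially with physical distance, and a
days-to-flowering phenotype built from subgroup means, planted additive QTL
and planted multilocus (non-additive) interaction effects.

Genotypes are produced by a first-order Gaussian copula along each
chromosome: one latent autoregressive path per haplotype, thresholded at the
subgroup allele frequency.  Inbreeding is realized by duplicating one
haplotype path with probability F per individual, which matches the
method-of-moments inbreeding coefficient in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from soyepi import io as sio
from soyepi.datatypes import GeneAnnotation, GenotypeMatrix, MarkerInfo, PhenotypeVector

_NUCS = np.array(list("ACGT"))
_COMPLEMENTARY = {"A": "G", "G": "A", "C": "T", "T": "C"}  # transition partner


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic panel.

    Defaults are the desk-scale stand-in for the real collection: two
    subgroups at Fst 0.0581, inbreeding F 0.971, subgroup trait means 42.16
    (IC-like) and 45.86 (LR-like) days.
    """

    n_ic: int = 200
    n_lr: int = 200
    n_markers: int = 2_000
    n_chromosomes: int = 4
    chromosome_length: int = 5_000_000
    target_fst: float = 0.0581
    target_inbreeding_f: float = 0.971
    ld_decay_scale: float = 100_000.0
    maf_floor: float = 0.05
    phenotype_mean_ic: float = 42.16
    phenotype_mean_lr: float = 45.86
    residual_sd: float = 5.0
    #: list of (marker index, additive effect in days per alt dosage)
    additive_qtl: list = field(default_factory=list)
    #: list of (marker index tuple, effect table of shape (3,)*k in days)
    interaction_groups: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fst < 1.0):
            raise ValueError("target_fst must lie in [0, 1)")
        if not (0.0 <= self.target_inbreeding_f <= 1.0):
            raise ValueError("target_inbreeding_f must lie in [0, 1]")
        if self.n_markers < 2:
            raise ValueError("need at least 2 markers")
        if not (0.0 < self.maf_floor < 0.5):
            raise ValueError("maf_floor must lie in (0, 0.5)")
        for idx, effect in self.additive_qtl:
            if not (0 <= idx < self.n_markers) or not np.isfinite(effect):
                raise ValueError(f"invalid additive QTL ({idx}, {effect})")
        for idxs, table in self.interaction_groups:
            table = np.asarray(table, dtype=float)
            if table.shape != (3,) * len(idxs):
                raise ValueError("interaction table must have shape (3,)*k")
            if not np.all(np.isfinite(table)):
                raise ValueError("interaction effects must be finite")
            for idx in idxs:
                if not (0 <= idx < self.n_markers):
                    raise ValueError(f"interaction marker index {idx} out of range")


def xor_interaction_table(effect: float) -> np.ndarray:
    """Default two-locus pure epistatic pattern: ``effect`` days whenever
    exactly one of the two markers carries an alternate allele (dominant
    coding), zero otherwise.  The pattern has no additive marginal signal at
    balanced frequencies."""
    a = np.arange(3)[:, None] > 0
    b = np.arange(3)[None, :] > 0
    return np.where(a ^ b, float(effect), 0.0)


def _marker_layout(spec: SimulationSpec, rng: np.random.Generator):
    """Distribute markers over chromosomes with sorted distinct positions."""
    per = np.full(spec.n_chromosomes, spec.n_markers // spec.n_chromosomes)
    per[: spec.n_markers % spec.n_chromosomes] += 1
    chroms, positions = [], []
    for c, k in enumerate(per, start=1):
        pos = np.sort(rng.choice(spec.chromosome_length, size=k, replace=False)) + 1
        chroms.extend([f"Chr{c:02d}"] * k)
        positions.extend(pos.tolist())
    return np.array(chroms), np.array(positions, dtype=np.int64)


def simulate_genotypes(spec: SimulationSpec) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw the genotype matrix; returns (genotypes, subgroup labels).

    Labels are "IC"/"LR" strings aligned to the sample order.
    """
    rng = np.random.default_rng(spec.seed)
    chroms, positions = _marker_layout(spec, rng)
    p = spec.n_markers

    # ancestral allele frequencies from a truncated spectrum
    p0 = rng.uniform(spec.maf_floor, 1.0 - spec.maf_floor, size=p)

    # Balding-Nichols subgroup frequencies
    theta = spec.target_fst
    if theta > 0:
        scale = (1.0 - theta) / theta
        freqs = np.vstack(
            [rng.beta(p0 * scale, (1.0 - p0) * scale) for _ in range(2)]
        )
    else:
        freqs = np.vstack([p0, p0])
    freqs = np.clip(freqs, 1e-4, 1.0 - 1e-4)

    # adjacent-marker latent correlation, reset at chromosome boundaries
    rho = np.zeros(p)
    same_chrom = np.concatenate([[False], chroms[1:] == chroms[:-1]])
    gaps = np.diff(positions).astype(float)
    if spec.ld_decay_scale > 0:
        rho[1:][same_chrom[1:]] = np.exp(-gaps[same_chrom[1:]] / spec.ld_decay_scale)

    def draw_group(n: int, group_freqs: np.ndarray) -> np.ndarray:
        thresholds = norm.ppf(group_freqs)  # allele is alt when z < threshold
        z1 = np.empty((n, p))
        z2 = np.empty((n, p))
        eps = rng.standard_normal((2, n, p))
        for j in range(p):
            if rho[j] == 0.0:
                z1[:, j] = eps[0, :, j]
                z2[:, j] = eps[1, :, j]
            else:
                r, s = rho[j], np.sqrt(1.0 - rho[j] ** 2)
                z1[:, j] = r * z1[:, j - 1] + s * eps[0, :, j]
                z2[:, j] = r * z2[:, j - 1] + s * eps[1, :, j]
        # excess homozygosity: per locus, the second allele copies the first
        # with probability F.  (A per-individual copy would concentrate all
        # heterozygosity in a few outbred samples and induce identity
        # disequilibrium between unlinked loci; per-locus mixing gives the
        # same method-of-moments F without cross-locus dependence.)
        copied = rng.random((n, p)) < spec.target_inbreeding_f
        z2 = np.where(copied, z1, z2)
        return (z1 < thresholds).astype(np.int8) + (z2 < thresholds).astype(np.int8)

    dos_ic = draw_group(spec.n_ic, freqs[0])
    dos_lr = draw_group(spec.n_lr, freqs[1])
    dosages = np.vstack([dos_ic, dos_lr])

    refs = _NUCS[rng.integers(0, 4, size=p)]
    # half transitions, half transversions (soybean array SNPs are a mix)
    transition = rng.random(p) < 0.5
    alts = np.array(
        [
            _COMPLEMENTARY[r] if t else ("C" if r in "AG" else "A")
            for r, t in zip(refs, transition)
        ]
    )

    order = np.lexsort((positions, chroms))
    markers = [
        MarkerInfo(
            marker_id=f"AX-{i + 1:06d}",
            chromosome=chroms[j],
            position=int(positions[j]),
            ref_allele=str(refs[j]),
            alt_allele=str(alts[j]),
        )
        for i, j in enumerate(order)
    ]
    sample_ids = [f"IC{i + 1:04d}" for i in range(spec.n_ic)] + [
        f"LR{i + 1:04d}" for i in range(spec.n_lr)
    ]
    labels = np.array(["IC"] * spec.n_ic + ["LR"] * spec.n_lr)
    genotypes = GenotypeMatrix(
        sample_ids=sample_ids, markers=markers, dosages=dosages[:, order]
    )
    return genotypes, labels


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    spec: SimulationSpec,
    labels: np.ndarray,
) -> tuple[PhenotypeVector, dict]:
    """Build the quantitative trait and a truth record of planted effects.

    value = subgroup mean + sum(additive effect * dosage)
          + sum(interaction cell effect) + Gaussian(0, residual_sd)
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n = genotypes.n_samples
    means = np.where(labels == "IC", spec.phenotype_mean_ic, spec.phenotype_mean_lr)
    values = means.astype(float).copy()

    for idx, effect in spec.additive_qtl:
        values += effect * genotypes.dosages[:, idx]

    interactions_truth = []
    for idxs, table in spec.interaction_groups:
        table = np.asarray(table, dtype=float)
        cells = tuple(genotypes.dosages[:, i] for i in idxs)
        values += table[cells]
        interactions_truth.append(
            {
                "marker_indices": [int(i) for i in idxs],
                "marker_ids": [genotypes.markers[i].marker_id for i in idxs],
                "effect_table": table.tolist(),
            }
        )

    if spec.residual_sd > 0:
        values += rng.normal(0.0, spec.residual_sd, size=n)

    truth = {
        "seed": spec.seed,
        "phenotype_mean_ic": spec.phenotype_mean_ic,
        "phenotype_mean_lr": spec.phenotype_mean_lr,
        "residual_sd": spec.residual_sd,
        "additive_qtl": [
            {
                "marker_index": int(i),
                "marker_id": genotypes.markers[i].marker_id,
                "effect": float(e),
            }
            for i, e in spec.additive_qtl
        ],
        "interaction_groups": interactions_truth,
        "labels": labels.tolist(),
    }
    return PhenotypeVector(list(genotypes.sample_ids), values), truth


def tile_genes(spec: SimulationSpec, gene_size: int = 10_000) -> list[GeneAnnotation]:
    """Contiguous non-overlapping gene tiles covering every chromosome, so
    each marker falls in exactly one gene."""
    genes = []
    for c in range(1, spec.n_chromosomes + 1):
        chrom = f"Chr{c:02d}"
        for i, start in enumerate(range(1, spec.chromosome_length + 1, gene_size)):
            end = min(start + gene_size - 1, spec.chromosome_length)
            genes.append(GeneAnnotation(f"Gene.{chrom}.{i + 1:04d}", chrom, start, end))
    return genes


def make_fixture_bundle(spec: SimulationSpec, out_dir: str | Path,
                        n_related_genes: int = 40) -> dict:
    """Write a complete, loadable input bundle to ``out_dir``.

    Files: genotypes.vcf, phenotypes.tsv, genes.bed, homology.tsv (synthetic
    BLAST tabular naming a subset of genes as trait-related, including some
    rows that fail the identity/length filters), truth.json.  Same seed,
    same bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genotypes, labels = simulate_genotypes(spec)
    phenotypes, truth = simulate_phenotype(genotypes, spec, labels)
    genes = tile_genes(spec)

    sio.write_genotypes(genotypes, out / "genotypes.vcf")
    sio.write_phenotypes(phenotypes, out / "phenotypes.tsv")
    sio.write_gene_annotation_bed(genes, out / "genes.bed")

    # trait-related gene subset: genes holding planted loci first, then a
    # deterministic spread of fillers
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    by_key = {}
    for g in genes:
        by_key.setdefault(g.chromosome, []).append(g)
    planted = set()
    for rec in truth["interaction_groups"]:
        for i in rec["marker_indices"]:
            m = genotypes.markers[i]
            for g in by_key[m.chromosome]:
                if g.start <= m.position <= g.end:
                    planted.add(g.gene_id)
    others = [g.gene_id for g in genes if g.gene_id not in planted]
    extra = rng.choice(len(others), size=min(n_related_genes, len(others)),
                       replace=False)
    related = sorted(planted) + sorted(others[i] for i in extra)

    with open(out / "homology.tsv", "w") as fh:
        for k, gene_id in enumerate(related):
            ident = float(np.round(81.0 + 18.0 * rng.random(), 2))
            length = int(rng.integers(71, 500))
            fh.write(
                f"AT_DTF_{k + 1:04d}\t{gene_id}\t{ident}\t{length}\t"
                f"5\t0\t1\t{length}\t1\t{length}\t1e-30\t200.0\n"
            )
        # rows that must be removed by the >80% / >70 bp filters
        fh.write("AT_DTF_FAIL1\tGene.Chr01.0001\t79.5\t200\t5\t0\t1\t200\t1\t200\t1e-10\t80.0\n")
        fh.write("AT_DTF_FAIL2\tGene.Chr01.0002\t95.0\t70\t5\t0\t1\t70\t1\t70\t1e-10\t80.0\n")

    truth_out = dict(truth)
    truth_out["related_genes"] = related
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_out, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "genotypes": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "genes": out / "genes.bed",
        "homology": out / "homology.tsv",
        "truth": out / "truth.json",
    }
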