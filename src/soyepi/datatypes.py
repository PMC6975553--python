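"""Core in-memory containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

VALID_ALLELES = frozenset("ACGT")
#: transition pairs (purine<->purine, pyrimidine<->pyrimidine)
_TRANSITIONS = (frozenset(("A", "G")), frozenset(("C", "T")))


@dataclass(frozen=True)
class MarkerInfo:
    """A single biallelic SNP marker on the array."""

    marker_id: str
    chromosome: str
    position: int  # 1-based bp
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.marker_id}: position must be >= 1")
        if self.ref_allele not in VALID_ALLELES or self.alt_allele not in VALID_ALLELES:
            raise ValueError(f"{self.marker_id}: alleles must be one of A,C,G,T")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.marker_id}: ref and alt alleles identical")

    @property
    def is_transition(self) -> bool:
        """True if ref<->alt is a transition (A<->G or C<->T)."""
        return frozenset((self.ref_allele, self.alt_allele)) in _TRANSITIONS


@dataclass
class GenotypeMatrix:
    """Samples x markers alternate-allele dosage matrix.

    Dosages are integers in {0, 1, 2} (count of the alternate allele in a
    diploid call); missing data must be resolved at load time.  Markers are
    kept sorted by (chromosome, position) so that repeated loads of the same
    file are bit-identical.
    """

    sample_ids: list[str]
    markers: list[MarkerInfo]
    dosages: np.ndarray  # shape (n_samples, n_markers), int8

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        n, p = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage rows != number of samples")
        if p != len(self.markers):
            raise ValueError("dosage columns != number of markers")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != p:
            raise ValueError("duplicate marker ids")
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be 0, 1 or 2 after loading")
        keys = [(m.chromosome, m.position) for m in self.markers]
        if keys != sorted(keys):
            order = np.lexsort(
                (
                    [m.position for m in self.markers],
                    [m.chromosome for m in self.markers],
                )
            )
            self.markers = [self.markers[i] for i in order]
            self.dosages = self.dosages[:, order]

    # -- basic geometry -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position for m in self.markers], dtype=np.int64)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([m.chromosome for m in self.markers])

    # -- allele statistics ----------------------------------------------

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    # -- subsetting ------------------------------------------------------

    def subset_markers(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            markers=[self.markers[i] for i in index],
            dosages=self.dosages[:, index].copy(),
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing[:5]}")
        idx = np.array([pos[s] for s in wanted], dtype=int)
        return GenotypeMatrix(
            sample_ids=wanted,
            markers=list(self.markers),
            dosages=self.dosages[idx, :].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.markers == other.markers
            and np.array_equal(self.dosages, other.dosages)
        )


@dataclass
class PhenotypeVector:
    """Per-sample quantitative trait values (days to flowering)."""

    sample_ids: list[str]
    values: np.ndarray  # float64, days

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sample_ids) != len(self.values):
            raise ValueError("sample ids and values differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in phenotype")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite phenotype values")
        if np.any(self.values <= 0):
            raise ValueError("days-to-flowering values must be positive")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def align_to(self, genotypes: GenotypeMatrix) -> "PhenotypeVector":
        """Reorder to the genotype matrix's sample order.

        Phenotyped samples must be a subset of the genotyped ones; samples
        without a phenotype are dropped from the result.
        """
        have = set(genotypes.sample_ids)
        extra = [s for s in self.sample_ids if s not in have]
        if extra:
            raise KeyError(f"phenotyped samples missing genotypes: {extra[:5]}")
        lookup = dict(zip(self.sample_ids, self.values))
        ids = [s for s in genotypes.sample_ids if s in lookup]
        return PhenotypeVector(ids, np.array([lookup[s] for s in ids]))


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval; internal convention is 1-based closed."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1")

    def contains(self, chromosome: str, position: int) -> bool:
        return self.chromosome == chromosome and self.start <= position <= self.end


@dataclass(frozen=True)
class HomologyHit:
    """One row of a 12-column BLAST tabular homology search."""

    query_gene: str
    subject_gene: str
    percent_identity: float
    alignment_length: int
    e_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent identity outside [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment length must be >= 1")
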