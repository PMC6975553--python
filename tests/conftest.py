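import numpy as np
import pytest

from soyepi.datatypes import GenotypeMatrix, MarkerInfo, PhenotypeVector


def make_genotypes(
    dosages,
    chromosomes=None,
    positions=None,
    refs=None,
    alts=None,
    spacing=1_000,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw dosage array with sensible
    defaults for the marker metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, p = dosages.shape
    chromosomes = chromosomes or ["Chr01"] * p
    positions = positions or [100 + spacing * j for j in range(p)]
    refs = refs or ["A"] * p
    alts = alts or ["G"] * p
    markers = [
        MarkerInfo(f"mk{j:04d}", chromosomes[j], positions[j], refs[j], alts[j])
        for j in range(p)
    ]
    return GenotypeMatrix(
        sample_ids=[f"s{i:04d}" for i in range(n)],
        markers=markers,
        dosages=dosages,
    )


def make_phenotypes(genotypes: GenotypeMatrix, values) -> PhenotypeVector:
    return PhenotypeVector(list(genotypes.sample_ids), np.asarray(values, float))


@pytest.fixture(scope="session")
def structured_panel():
    """Default-condition synthetic panel shared across tests (two subgroups
    at target Fst, high inbreeding)."""
    from soyepi.simulate import SimulationSpec, simulate_genotypes, simulate_phenotype

    spec = SimulationSpec(seed=1)
    genotypes, labels = simulate_genotypes(spec)
    phenotypes, truth = simulate_phenotype(genotypes, spec, labels)
    return genotypes, phenotypes, labels, spec
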