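import pytest

from mcmtrace.locus import (GenomeModel, OriginCatalog, OriginEntry,
                            RepeatArrayAnnotation, default_genome_model)
from mcmtrace.simulate import (GenotypeParams, SimulationSpec,
                               simulate_chec_timecourse)


@pytest.fixture(scope="session")
def model150():
    return default_genome_model(150)


@pytest.fixture(scope="session")
def mini_model():
    """Tiny model (91 kb unique + 2x9.1 kb collapsed array, 10 physical
    copies) for brute-force and closed-form checks."""
    rdna = RepeatArrayAnnotation(chrom="chrR", collapsed_start=0,
                                 physical_copies=10)
    catalog = OriginCatalog((
        OriginEntry("oriE1", "chrU", 20_000, "early"),
        OriginEntry("oriE2", "chrU", 40_000, "early"),
        OriginEntry("oriL1", "chrU", 60_000, "late"),
        OriginEntry("oriL2", "chrU", 80_000, "late"),
        OriginEntry("rARS", "chrR", rdna.mcm_nondisplaced, "rdna"),
    ))
    return GenomeModel(chromosomes=(("chrU", 91_000), ("chrR", 18_200)),
                       rdna=rdna, origins=catalog)


@pytest.fixture(scope="session")
def wt_chec(model150):
    spec = SimulationSpec(model=model150,
                          genotype=GenotypeParams.for_genotype("wt"),
                          n_fragments=200_000, seed=11)
    return spec, simulate_chec_timecourse(spec)


@pytest.fixture(scope="session")
def sir2_chec(model150):
    spec = SimulationSpec(model=model150,
                          genotype=GenotypeParams.for_genotype("sir2"),
                          n_fragments=200_000, seed=12)
    return spec, simulate_chec_timecourse(spec)
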