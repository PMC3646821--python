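import pytest

from pedexome.core import Affection, GenomicInterval, Individual, Pedigree, Sex
from pedexome.simulate import SimulationConfig

ORIGINAL_INTERVAL = GenomicInterval("chr7", 126_287_140, 129_964_025)
REFINED_INTERVAL = GenomicInterval("chr7", 126_287_140, 128_845_555)
CAUSAL_POS = 128_597_310


@pytest.fixture
def small_config() -> SimulationConfig:
    """Scaled-down cohort: same structure, ~20x fewer sites, 5 generations."""
    return SimulationConfig(
        seed=17,
        n_generations=5,
        n_common_sites=2_000,
        n_rare_sites=1_500,
    )


@pytest.fixture
def trio() -> Pedigree:
    ped = Pedigree(family_id="TRIO")
    ped.add(Individual("F1", sex=Sex.MALE, affected=Affection.AFFECTED))
    ped.add(Individual("M1", sex=Sex.FEMALE, affected=Affection.UNAFFECTED))
    ped.add(
        Individual(
            "C1", father_id="F1", mother_id="M1", sex=Sex.FEMALE,
            affected=Affection.AFFECTED,
        )
    )
    return ped
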