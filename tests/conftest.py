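import pytest

from pahscan.experiments import cascade_truth_fixture
from pahscan.synthetic import (
    CohortConfig,
    PedigreeSpec,
    PlantedDeletion,
    PlantedGene,
    DeletionModel,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort exercising every feature: planted gene, pedigrees,
    planted deletion, X genes, population structure."""
    cfg = CohortConfig(
        n_cases=60,
        n_controls=300,
        n_genes=30,
        n_panel_snps=2000,
        n_reference_per_pop=30,
        planted_genes=(PlantedGene("CAUSAL1", 0.25, 0.002),),
        pedigrees=(PedigreeSpec("trio", 1), PedigreeSpec("sib_pair", 2)),
        deletion_model=DeletionModel(planted=(PlantedDeletion("DELGENE", 0.1, 0.0),)),
        seed=41,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def cascade_fixture():
    """Labelled 20-variant fixture covering every filter-rule boundary."""
    return cascade_truth_fixture()
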