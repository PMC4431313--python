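import pytest

from netpharm import SimulationSpec


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """A scaled-down simulated study that keeps every planted feature
    (hubs spanning all three strata, dominant pathway, mimic/reverser)
    but runs in well under a second."""
    return SimulationSpec(
        n_molecules=20,
        n_targets=60,
        n_pathways=12,
        n_diseases=40,
        n_symptoms=20,
        hit_fraction=0.02,
        hub_spec=((0, 35), (1, 20), (2, 8)),
        mean_pathways_per_target=3.0,
        mean_diseases_per_pathway=2.5,
        mean_symptoms_per_disease=5.0,
        n_zheng=30,
        n_perturbagens=6,
        n_instances=2,
        n_tags=60,
        seed=11,
    )
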