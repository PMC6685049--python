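import numpy as np
import pytest

from mitotails import (
    PeptideObservation,
    ProteinAnnotation,
    Stage,
    default_design,
)
from mitotails.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def toy_protein():
    # 30 residues, Met start; TP [1,10], propeptide [11,18]
    return ProteinAnnotation(
        accession="TOY1",
        sequence="MAGHKLRSTWAVDEFGHIKLNPQRSTVWYA",
        has_initiator_met=True,
        transit_peptide=(1, 10),
        chain=(11, 30),
        propeptides=((11, 18),),
        in_reference_set=True,
    )


@pytest.fixture(scope="session")
def design7():
    return default_design(7)


def make_observation(sequence, replicate, light=None, heavy=None, stage=Stage.POSTsel, **kw):
    return PeptideObservation(
        sequence=sequence,
        replicate_id=replicate,
        stage=stage,
        area_light=light,
        area_heavy=heavy,
        **kw,
    )


@pytest.fixture(scope="session")
def small_experiment():
    """One seeded synthetic experiment reused across tests."""
    config = SimulationConfig(n_proteins=120, seed=11)
    return simulate_study(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
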