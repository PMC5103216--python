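import pytest

from gpr139pharm import ConformerPolicy, generate_conformers
from gpr139pharm.chem import reference_compound, reference_compounds
from gpr139pharm.hypothesis import GPR139_MODEL_SEED, gpr139_model


@pytest.fixture(scope="session")
def references():
    return {m.id: m for m in reference_compounds()}


@pytest.fixture(scope="session")
def model():
    """The packaged GPR139 AAADHRR model (built once per session)."""
    return gpr139_model()


@pytest.fixture(scope="session")
def ensemble_1a():
    """Reference agonist 1a with the pinned model-build conformer ensemble."""
    return generate_conformers(
        reference_compound("1a"), ConformerPolicy(seed=GPR139_MODEL_SEED)
    )


@pytest.fixture(scope="session")
def ensemble_dl96():
    return generate_conformers(
        reference_compound("DL96"), ConformerPolicy(seed=GPR139_MODEL_SEED)
    )
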