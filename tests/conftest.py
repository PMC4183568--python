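import numpy as np
import pytest

from trflpsim.digest import GenotypeRecord
from trflpsim.enzymes import AluI, HinfI
from trflpsim.model import TRFLPBiasModel
from trflpsim.simulate import BiasConfig, StudyConfig, generate_study_dataset


@pytest.fixture(scope="session")
def enzymes():
    return {"AluI": AluI, "HinfI": HinfI}


@pytest.fixture
def toy_record():
    # AluI site at 4 (cut coord 6); HinfI site at 12 (GATTC, cut coord 13)
    return GenotypeRecord(id="toy", sequence="CCCCAGCTCCCCGATTCCCCC")


@pytest.fixture(scope="session")
def zero_bias_results():
    """Full study pipeline under bias-free conditions (identity check)."""
    config = StudyConfig(seed=11, bias=BiasConfig.zero(), pipetting_cv=0.0)
    dataset = generate_study_dataset(config)
    model = TRFLPBiasModel.from_study(dataset)
    return dataset, model, model.fit(n_perm=99, seed=0)


@pytest.fixture(scope="session")
def calibrated_dataset():
    """One full study simulation under the calibrated bias regime."""
    return generate_study_dataset(StudyConfig(seed=7))


def brute_force_sites(sequence: str, pattern_sets) -> list[int]:
    """Independent position-by-position IUPAC scan."""
    r = len(pattern_sets)
    return [
        i
        for i in range(len(sequence) - r + 1)
        if all(sequence[i + j] in pattern_sets[j] for j in range(r))
    ]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
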