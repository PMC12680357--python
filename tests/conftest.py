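import numpy as np
import pytest
import trimesh

from cranioplan.anatomy import apply_osteotomy, build_skull, sample_population
from cranioplan.mesh import TriangleMesh
from cranioplan.springs import SpringSpec, SurgicalConfig


def icosphere(radius: float = 50.0, subdivisions: int = 3) -> TriangleMesh:
    tm = trimesh.creation.icosphere(subdivisions, radius)
    return TriangleMesh(np.array(tm.vertices), np.array(tm.faces))


@pytest.fixture(scope="session")
def patient():
    return sample_population(1, 42)[0]


@pytest.fixture(scope="session")
def skull(patient):
    return build_skull(patient)


@pytest.fixture(scope="session")
def mid_config():
    return SurgicalConfig(A=0.24, AP=0.55, LAT=0.18,
                          anterior_spring=SpringSpec(1.0, model_name="model-2"),
                          posterior_spring=SpringSpec(1.0, model_name="model-2"))


@pytest.fixture(scope="session")
def cut_skull(skull, mid_config):
    return apply_osteotomy(skull, mid_config)


@pytest.fixture(scope="session")
def trained_corpus():
    """An 8-patient corpus with a fitted fixed-hyperparameter SVR surrogate.

    Shared by the prediction-pipeline tests; big enough that the surrogate
    is meaningfully trained, small enough to build in under a minute.
    """
    from cranioplan.pipeline import run_corpus, train_surrogate

    corpus = run_corpus(n_patients=8, master_seed=3)
    model, report, split = train_surrogate(
        corpus, kind="svm", tune=False,
        hyperparams={"kernel": "rbf", "C": 1.85, "epsilon": 0.0, "gamma": "scale"},
        seed=1)
    return corpus, model, report, split
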