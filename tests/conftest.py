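import pytest

from orientbayes import EstimatorSpec, ExperimentDesign

#: Pooled-data maximum-likelihood noise parameters used as standard
#: operating points in the tests (sigma in degrees for EP, Weber fraction
#: for VP).
MLE_LAMBDA = {"map_ep": 3.6, "map_vp": 0.27, "bls_ep": 3.75, "bls_vp": 0.23}


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def specs(design):
    return {m: EstimatorSpec.from_model(m, lam, design)
            for m, lam in MLE_LAMBDA.items()}
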