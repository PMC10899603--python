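import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_msa():
    """MSA with the ten stabilizing-site signals planted (seed fixed)."""
    from indikit.synthetic_data import gen_msa

    aln, truth = gen_msa(seed=1)
    return aln, truth


@pytest.fixture(scope="session")
def synthetic_model():
    """Coordinate model with one planted disulfide pair and two B hotspots."""
    from indikit.synthetic_data import gen_structure

    model, truth = gen_structure(seed=2, n_residues=400,
                                 planted_ss_pairs=[(30, 120)],
                                 b_hotspots=[(251, 261), (310, 336)])
    return model, truth
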