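import pytest

from dmdgp.model import GeometryParams, build_instance
from dmdgp.synthetic import sample_conformation


@pytest.fixture(scope="session")
def params_planar():
    """Exact trans peptide planes: in-plane atoms are degenerate bits."""
    return GeometryParams(omega_jitter=0.0)


@pytest.fixture(scope="session")
def params_jitter():
    """Non-planar peptides (PDB-like): every non-repeat bit is free."""
    return GeometryParams(omega_jitter=5.0)


@pytest.fixture
def planted(params_jitter):
    """Factory: planted (conformation, instance) pairs."""
    def make(n_residues=3, seed=0, policy=None, params=None):
        p = params or params_jitter
        conf = sample_conformation(n_residues, p, seed=seed)
        if policy is None:
            inst = build_instance(conf)
        else:
            inst = build_instance(conf, policy=policy)
        return conf, inst
    return make
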