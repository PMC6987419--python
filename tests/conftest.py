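import numpy as np
import pytest

from peprdc import synthetic as syn


@pytest.fixture
def helical_peptide():
    """20-residue all-Ala α-helix built at ideal geometry."""
    return syn.build_peptide("A" * 20, [(-57.0, -47.0)] * 20)


@pytest.fixture
def mixed_peptide():
    """Peptide with methylene/methine side chains for RDC simulations."""
    seq = "ACDEFHIKLMNQRSTVWYE" * 3
    return syn.build_peptide(seq, [(-57.0, -47.0)] * len(seq))


@pytest.fixture
def two_medium_rdcs(mixed_peptide):
    """Backbone RDCs in two media, σ = 1 Hz noise (study-like layout)."""
    from peprdc import RDCSet

    t1 = syn.random_tensor(21, da=10.0, rhombicity=0.3)
    t2 = syn.random_tensor(22, da=8.0, rhombicity=0.5)
    r1 = syn.simulate_rdcs(mixed_peptide, t1,
                           syn.backbone_rdc_records(mixed_peptide, "pf1"),
                           noise_sd=1.0, seed=31)
    r2 = syn.simulate_rdcs(mixed_peptide, t2,
                           syn.backbone_rdc_records(mixed_peptide, "peg"),
                           noise_sd=1.0, seed=32)
    return RDCSet(list(r1) + list(r2)), (t1, t2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
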