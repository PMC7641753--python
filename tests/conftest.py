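import numpy as np
import pytest

from poc import sequences as sq
from poc import synthetic

# The study's local target window: 5'-UUCGAUC | CACAG | AAUUCGCACCA-3'.
# Local position 1 corresponds to study residue 54, so CACAG spans 61-65.
LOCAL_TARGET = "UUCGAUCCACAGAAUUCGCACCA"
NUMBERING_OFFSET = 53


@pytest.fixture(scope="session")
def designs():
    """The packaged 14-conjugate library, keyed by name."""
    return {d.name: d for d in sq.packaged_conjugate_table()}


@pytest.fixture(scope="session")
def local_target():
    return sq.NucleotideSequence.from_str(LOCAL_TARGET, "RNA")


@pytest.fixture(scope="session")
def bc5_complex(designs, local_target):
    return sq.hybridize(designs["BC5"], local_target, numbering_offset=NUMBERING_OFFSET)


@pytest.fixture(scope="session")
def bc2_complex(designs, local_target):
    return sq.hybridize(designs["BC2"], local_target, numbering_offset=NUMBERING_OFFSET)


@pytest.fixture(scope="session")
def planted_ensemble():
    """100-frame synthetic ensemble: 30 in-line frames, 12 productive."""
    spec = synthetic.EnsembleSpec(
        sites=(63,),
        n_frames=100,
        planted_inline=((63, 30),),
        planted_productive=((63, 12),),
        seed=42,
    )
    ens, truth = synthetic.simulate_ensemble(spec)
    return spec, ens, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
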