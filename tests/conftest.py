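import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from linemeth import LocusReference, ReadMethylationMatrix
from linemeth.synthetic import consensus_scaffold


@pytest.fixture(scope="session")
def small_locus() -> LocusReference:
    """A 12-CpG scaffold-derived locus with an identity consensus map."""
    seq, positions = consensus_scaffold(n_cpg=12)
    return LocusReference(
        locus_id="L1TEST",
        sequence=seq,
        cpg_positions=positions,
        consensus_cpg_index=tuple(range(len(positions))),
        consensus_bp_position=positions,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(17)


def make_matrix(calls, locus_id="L", sample_id="S") -> ReadMethylationMatrix:
    return ReadMethylationMatrix(
        locus_id=locus_id, sample_id=sample_id, calls=np.asarray(calls, dtype=np.int8)
    )
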