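import numpy as np
import pytest

import ddgkit as dk
from ddgkit.dataset import DDGDataset, MutationKey, MutationRecord
from ddgkit.synthetic import make_helix_structure, make_profile_fixtures

HELIX_SEQ = "MKTAYIAKQRLWSEHFGDVN"


@pytest.fixture(scope="session")
def helix_structure():
    return dk.read_pdb(make_helix_structure(HELIX_SEQ), source="S000")


@pytest.fixture(scope="session")
def helix_pssm():
    return dk.parse_pssm_ascii(make_profile_fixtures(HELIX_SEQ, seed=3).pssm_text)


@pytest.fixture()
def small_dataset():
    recs = [
        MutationRecord(MutationKey("S000", "A", 6, "I", "A"), 7.0, 25.0, 1.2),
        MutationRecord(MutationKey("S000", "A", 10, "R", "E"), 7.0, 25.0, -0.4),
        MutationRecord(MutationKey("S000", "A", 15, "H", "G"), 5.5, 30.0, 0.0),
    ]
    return DDGDataset(records=recs, provenance=["fixture"])


def make_record(pdb="S000", chain="A", pos=6, wt="I", mut="A",
                ph=7.0, temp=25.0, ddg=1.0, origin="direct", pair_id=None):
    return MutationRecord(
        MutationKey(pdb, chain, pos, wt, mut), ph, temp, ddg, origin, pair_id
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.RandomState(12345)
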