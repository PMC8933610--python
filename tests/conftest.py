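import numpy as np
import pandas as pd
import pytest

import setscape as ss

GENEPOP_2DIGIT = """Two-population toy
loc1
POP
A_ind1 , 0101
A_ind2 , 0102
POP
B_ind1 , 0202
B_ind2 , 0202
"""

GENEPOP_3DIGIT = """Two-population toy (3-digit)
loc1
POP
A_ind1 , 001001
A_ind2 , 001002
POP
B_ind1 , 002002
B_ind2 , 002002
"""


@pytest.fixture
def genepop_2digit(tmp_path):
    p = tmp_path / "toy2.gen"
    p.write_text(GENEPOP_2DIGIT)
    return p


@pytest.fixture
def genepop_3digit(tmp_path):
    p = tmp_path / "toy3.gen"
    p.write_text(GENEPOP_3DIGIT)
    return p


def make_freq_table(freq, n, pops=None, loci=None):
    freq = np.asarray(freq, float)
    pops = pops or [f"pop{i+1}" for i in range(freq.shape[0])]
    loci = loci or [f"L{j+1}" for j in range(freq.shape[1])]
    n = np.broadcast_to(np.asarray(n, int), freq.shape)
    return ss.AlleleFrequencyTable(
        freq=pd.DataFrame(freq, index=pops, columns=loci),
        n_alleles=pd.DataFrame(n, index=pops, columns=loci),
    )


@pytest.fixture(scope="session")
def neutral_sim():
    """One scaled neutral (drift-only) colonization run, shared across tests."""
    return ss.simulate(ss.scaled_scenario(seed=11, with_selection=False))


@pytest.fixture(scope="session")
def selected_sim():
    """One scaled run with E1 selection on demes 3-5."""
    return ss.simulate(ss.scaled_scenario(seed=12))


@pytest.fixture(scope="session")
def neutral_tree(neutral_sim):
    return ss.fit_tree(ss.drift_covariance(neutral_sim.freqs), root="pop1")
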