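import numpy as np
import pytest

import regushift as rs


@pytest.fixture
def micro_m():
    """Single-gene, three-point intensity matrix with a sign flip."""
    return np.array([[5.0, -5.0, 5.0]])


@pytest.fixture
def pair_network():
    """One regulator controlling one target."""
    return rs.RegulatoryNetwork([rs.Edge("p", "c")])


def write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")
    return path


@pytest.fixture
def tsv_writer():
    return write_tsv
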