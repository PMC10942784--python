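import numpy as np
import pytest

import sjkit


@pytest.fixture(scope="session")
def sim_small():
    """A small seeded study with planted switches and DE genes."""
    config = sjkit.SimConfig(seed=11, n_genes=60, n_switch=8, n_de=8)
    return sjkit.simulate_study(config)


@pytest.fixture(scope="session")
def gls():
    """GAC/KGA-structured fixture gene with a planted GAC-to-KGA switch."""
    model, matrix, design = sjkit.gls_like_fixture(seed=5)
    return model, matrix, design


@pytest.fixture()
def three_exon_gene():
    """Cassette toy gene: exons e1, e2, e3; t1 includes e2, t2 skips it."""
    exons = [(100, 200), (300, 400), (500, 600)]
    return sjkit.GeneModel(
        "TOY", "chr1", "+", (100, 600),
        {"TOY.t1": list(exons), "TOY.t2": [exons[0], exons[2]]},
    )


def make_matrix(junction_counts, design):
    """Build a JunctionCountMatrix from {sample: {junction: count}} dicts."""
    records = {
        d.sample_id: [
            sjkit.SJRecord(j, unique_reads=c)
            for j, c in sorted(junction_counts[d.sample_id].items())
        ]
        for d in design
    }
    return sjkit.build_matrix(records, design)
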