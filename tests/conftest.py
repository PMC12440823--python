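"""Shared fixtures: all synthetic, generated at test time."""

import pandas as pd
import pytest

from flipms import io, simulate
from flipms.diffstats import median_normalize


@pytest.fixture(scope="session")
def proteome():
    return simulate.make_proteome(20, (50, 200), seed=1)


@pytest.fixture(scope="session")
def annotations(proteome):
    return simulate.digest_in_silico(proteome, pk_sites_per_protein=2, seed=2)


@pytest.fixture(scope="session")
def truth(proteome, annotations):
    return simulate.default_truth(
        proteome, annotations, n_markers=5, log2fc=1.0, seed=3
    )


@pytest.fixture(scope="session")
def experiment(truth, proteome, annotations):
    """Filtered, per-fraction median-normalised (lip, control) tables."""
    lip, ctrl = simulate.simulate_flip_experiment(truth, proteome, annotations)
    records = pd.concat([lip, ctrl], ignore_index=True)
    records = io.detection_filter(records)
    records = median_normalize(records, scope="per_group")
    return (
        records[records["sample_type"] == "lip"],
        records[records["sample_type"] == "tryptic_control"],
    )


@pytest.fixture(scope="session")
def toy_dimer():
    structure, planted = simulate.simulate_dimer_structure(40, 10, seed=5)
    return structure, planted
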