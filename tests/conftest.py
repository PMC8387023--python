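import numpy as np
import pandas as pd
import pytest

import replirate as rr
from replirate.data import pawm36_fasta_path, assay_primers_path


@pytest.fixture(scope="session")
def template():
    return rr.read_fasta(pawm36_fasta_path())


@pytest.fixture(scope="session")
def primer_pairs():
    return rr.read_primer_table(assay_primers_path())


@pytest.fixture(scope="session")
def assay_map(template, primer_pairs):
    return rr.map_assay(template, primer_pairs)


def make_plate(
    fractions: np.ndarray,
    sites=(200, 500, 1000, 1500, 2000),
    timepoints=(2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0),
    cv=0.0,
    loading_cv=0.0,
    seed=0,
) -> pd.DataFrame:
    """Plate from explicit true fractions (shape sites x timepoints)."""
    curves = rr.SiteFractionCurves(tuple(sites), tuple(timepoints), fractions)
    noise = rr.QpcrNoiseModel(cv=cv, loading_cv=loading_cv)
    return rr.simulate_qpcr_readout(curves, noise, seed=seed)


@pytest.fixture()
def step_fractions():
    """Fractions of a deterministic motor at 100 bp/min (step arrival)."""
    sites = np.array([200, 500, 1000, 1500, 2000])
    tps = np.array([2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0])
    return (tps[None, :] >= sites[:, None] / 100.0).astype(float)
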