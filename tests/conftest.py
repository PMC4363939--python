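import numpy as np
import pandas as pd
import pytest

from plsig.preprocess import PROBE_COLUMNS
from plsig.synthetic import StudyDesign, generate_study


def probe(probe_id, gene, reps, p):
    reps = list(reps)
    return (probe_id, gene, reps[0], reps[1], reps[2],
            float(np.mean(reps)), p)


@pytest.fixture
def hand_probe_table():
    """10 probes: 4 replicate-inconsistent, 2 duplicate pairs among the
    consistent rest -> a master list of exactly 4 genes."""
    rows = [
        # consistent, duplicated gene GA (pair 1)
        probe("P01", "GA", (1.4, 1.6, 1.8), 0.010),
        probe("P02", "GA", (1.3, 1.5, 1.7), 0.040),
        # consistent, duplicated gene GB (pair 2, down-regulated)
        probe("P03", "GB", (-1.2, -1.5, -2.0), 0.030),
        probe("P04", "GB", (-1.1, -1.4, -1.9), 0.005),
        # consistent singletons
        probe("P05", "GC", (2.0, 2.2, 2.4), 0.020),
        probe("P06", "GD", (-1.6, -1.3, -1.2), 0.015),
        # inconsistent: mixed signs or classes
        probe("P07", "GE", (1.2, -1.5, 2.0), 0.010),
        probe("P08", "GF", (1.4, 0.5, 1.6), 0.010),
        probe("P09", "GG", (-1.2, 0.0, -1.4), 0.010),
        probe("P10", "GH", (0.2, 0.5, 0.4), 0.010),  # all insignificant
    ]
    return pd.DataFrame(rows, columns=PROBE_COLUMNS)


@pytest.fixture(scope="session")
def planted_study():
    """Moderate planted-signal study shared across tests (seed fixed)."""
    design = StudyDesign(n_genes=120, n_signature=12, noise_sd=0.1, seed=7)
    tables, phenotypes, truth = generate_study(design)
    return design, tables, phenotypes, truth
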