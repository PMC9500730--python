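"""Shared fixtures: synthetic libraries and simulated SWATH run pairs.

Heavy simulations are session-scoped.  The 20-seed batch keeps only the
lightweight objects (ground truth, identifications) per seed, not the runs
themselves, so memory stays flat.
"""

from __future__ import annotations

import numpy as np
import pytest

from swath_annotator import FiltrationParams, annotate_run
from swath_annotator.synthdata import (make_ground_truth,
                                       make_synthetic_library, simulate_run)

N_SEEDS = 20


@pytest.fixture(scope="session")
def default_params() -> FiltrationParams:
    return FiltrationParams()


@pytest.fixture(scope="session")
def library_seed7():
    """50-compound synthetic library (raw spectra + curated entries)."""
    return make_synthetic_library(50, seed=7)


@pytest.fixture(scope="session")
def sim_pair(library_seed7):
    """One full simulated run pair (seed 7, 10 spiked compounds)."""
    _, entries = library_seed7
    truth = make_ground_truth(entries, n_spike=10, seed=7)
    sample, blank = simulate_run(truth)
    return {"entries": entries, "truth": truth, "sample": sample, "blank": blank}


@pytest.fixture(scope="session")
def identifications_seed7(sim_pair, default_params):
    return annotate_run(sim_pair["sample"], sim_pair["blank"],
                        sim_pair["entries"], default_params)


@pytest.fixture(scope="session")
def multi_seed_batch(default_params):
    """Per-seed end-to-end results over 20 seeds (study conditions).

    Each element: spiked compound ids, library compound ids, and the final
    identifications (runs are discarded after annotation).
    """
    batch = []
    for seed in range(1, N_SEEDS + 1):
        _, entries = make_synthetic_library(50, seed=seed)
        truth = make_ground_truth(entries, n_spike=10, seed=seed)
        sample, blank = simulate_run(truth)
        idents = annotate_run(sample, blank, entries, default_params)
        batch.append({
            "seed": seed,
            "spiked": set(truth.spiked_ids),
            "library_ids": {e.compound_id for e in entries},
            "identifications": idents,
        })
    return batch


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
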