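"""Shared fixtures: simulated datasets reused across test modules.

All datasets are generated at session start from fixed seeds; nothing
is stored on disk except through tmp_path-scoped writes inside tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from axiomcurate import (
    CurationLedger,
    SimulationConfig,
    clean_config,
    simulate,
)


@pytest.fixture(scope="session")
def defect_sim():
    """Standard study fixture: 5000 SNPs, 56 samples + 1 duplicate,
    2% injections per problematic class, 0.2% genotyping error."""
    return simulate(SimulationConfig(n_duplicates=1, seed=11))


@pytest.fixture(scope="session")
def clean_sim():
    """Defect-free, error-free dataset (the clean-data null)."""
    return simulate(clean_config(seed=1))


@pytest.fixture(scope="session")
def relationship_sim():
    """Clean SNPs with a planted duplicate, pedigree, 0.2% call errors."""
    return simulate(
        clean_config(
            n_duplicates=1,
            genotyping_error_rate=0.002,
            no_call_rate=0.005,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def ploidy_sim():
    """Diploid/triploid mix at the hardest stated noise (mode sd 0.15)."""
    return simulate(clean_config(frac_triploid=0.3, cluster_sd=0.15, seed=3))


@pytest.fixture()
def registered_ledger(defect_sim):
    dataset, _ = defect_sim
    ledger = CurationLedger()
    ledger.register_dataset(dataset.probeset_ids, dataset.sample_ids)
    return ledger


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
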