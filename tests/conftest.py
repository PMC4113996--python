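from __future__ import annotations

import random

import pytest

from gnnkit import SimulationConfig, run_synthetic

#: Synthetic study cutoffs for the full-size (L=300) conditions.
STRICT_CUTOFF = 1e-50
RELAXED_CUTOFF = 1e-5
GNN_CUTOFF = 1e-20

#: Laxer cutoffs matched to the short (L=120) desk-scale fixtures, where
#: within-family e-values land around 1e-40.
SMALL_SSN_CUTOFF = 1e-12
SMALL_GNN_CUTOFF = 1e-12


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(length))


@pytest.fixture(scope="session")
def small_run():
    """Desk-scale end-to-end run with the exact internal aligner."""
    cfg = SimulationConfig(
        n_families=3, members_per_family=4, length=120,
        n_partner_families=2, n_scatter_families=3, scatter_prob=0.15,
        seed=11,
    )
    return run_synthetic(
        cfg, ssn_cutoff=SMALL_SSN_CUTOFF, gnn_cutoff=SMALL_GNN_CUTOFF,
        backend="internal",
    )


@pytest.fixture(scope="session")
def adjacent_run():
    """Two query families with members placed adjacently on one replicon:
    the substrate of the query-in-query-neighborhood semantics."""
    cfg = SimulationConfig(
        n_families=2, members_per_family=3, length=120,
        n_partner_families=0, n_scatter_families=0, scatter_prob=0.0,
        adjacent_pair=(0, 1), seed=5,
    )
    return run_synthetic(
        cfg, ssn_cutoff=SMALL_SSN_CUTOFF, gnn_cutoff=SMALL_GNN_CUTOFF,
        backend="internal",
    )


@pytest.fixture(scope="session")
def ten_runs():
    """Ten full-condition pipeline runs (independent seeds), blastp backend."""
    runs = []
    for seed in range(1, 11):
        cfg = SimulationConfig(seed=seed)
        runs.append(
            run_synthetic(
                cfg, ssn_cutoff=STRICT_CUTOFF, gnn_cutoff=GNN_CUTOFF,
                backend="blast",
            )
        )
    return runs
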