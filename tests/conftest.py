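"""Shared fixtures: simulated studies at study scale and unit scale."""

from __future__ import annotations

import numpy as np
import pytest

from phosrewire import diffreg, simulate
from phosrewire.datamodel import PhosphoPeptideRecord, ReplicateDesign


@pytest.fixture(scope="session")
def default_study():
    """Full-scale synthetic study (8,000 sites) at a fixed seed."""
    return simulate.simulate_study(simulate.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_calls(default_study):
    return diffreg.run_diffreg(default_study.phospho, default_study.design)


@pytest.fixture(scope="session")
def null_study():
    """Same scale with no planted signal anywhere."""
    cfg = simulate.SimConfig(seed=11, frac_regulated=0.0,
                             frac_regulated_proteins=0.0,
                             active_kinases=0, active_tfs=0)
    phospho, proteins, design, truth = \
        simulate.simulate_phospho_experiment(cfg)
    return phospho, proteins, design, truth


@pytest.fixture(scope="session")
def small_study():
    """Fast small study for plumbing tests."""
    cfg = simulate.SimConfig(seed=5, n_sites=400, n_proteins=150,
                             n_kinases=10, active_kinases=2,
                             substrates_per_kinase=6, n_tfs=8,
                             active_tfs=2, targets_per_tf=10,
                             community_sizes=(20, 20, 20), p_within=0.4)
    return simulate.simulate_study(cfg)


def make_records(log2_matrix, design: ReplicateDesign | None = None,
                 loc_prob: float = 0.99):
    """Build phospho records whose *oriented* log2 ratios equal the given
    matrix rows (raw ratios are back-computed through the design signs)."""
    design = design or ReplicateDesign()
    signs = design.orientation_signs
    records = []
    for i, row in enumerate(np.asarray(log2_matrix, dtype=float)):
        ratios = tuple(
            None if np.isnan(v) else float(2.0 ** (signs[j] * v))
            for j, v in enumerate(row))
        records.append(PhosphoPeptideRecord(
            protein_id=f"P{i:03d}", gene=f"G{i:03d}", position=10,
            residue="S", multiplicity=1, loc_prob=loc_prob, ratios=ratios))
    return records
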