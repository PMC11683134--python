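"""Shared fixtures: synthetic populations and pipeline helpers.

Populations are generated once per session where reuse is safe; all seeds
are fixed so the suite is deterministic.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cytomito as cm


def mode_of(table: cm.EventTable, expected_ploidy: str = "2n") -> cm.PeakSet:
    """Run the log2 -> density -> mode-detection chain on one table."""
    t = table if table.is_transformed else cm.log2_transform(table)
    profile = cm.estimate_density(t.events["fluor_log2"].to_numpy())
    return cm.find_peak_modes(profile, expected_arrest_ploidy=expected_ploidy)


def pipeline_shift_2n(rho_plus: cm.EventTable, rho_zero: cm.EventTable) -> float:
    """2n-peak mode contrast (rho+ minus rho0) via the full detection path."""
    return mode_of(rho_plus).mode_2n - mode_of(rho_zero).mode_2n


@pytest.fixture(scope="session")
def g2m_specs():
    """Matched 2n-only rho+ / rho0 specs at the default 30.8 copies, 5% noise."""
    common = dict(
        ploidy_fractions={"G1": 0.0, "S": 0.0, "G2M": 1.0},
        measurement_cv=0.05,
    )
    plus = cm.PopulationSpec(mito_status="rho_plus", seed=11, **common)
    zero = cm.PopulationSpec(mito_status="rho_zero", seed=12, **common)
    return plus, zero


@pytest.fixture(scope="session")
def g2m_pair(g2m_specs):
    plus, zero = g2m_specs
    return cm.generate_population(plus, "rho_plus"), cm.generate_population(zero, "rho_zero")


@pytest.fixture(scope="session")
def arrest_base_spec():
    """Clean stated world for arrest diagnostics: exact copies, FSC ~ size."""
    return cm.PopulationSpec(
        ploidy_fractions={"G1": 0.0, "S": 0.0, "G2M": 1.0},
        copies_cv=0.0,
        fsc_noise_sd=0.02,
        measurement_cv=0.05,
        seed=5,
    )


@pytest.fixture(scope="session")
def arrested_coupled(arrest_base_spec):
    """G2/M-arrested population with size-coupled (regulated) accumulation."""
    pair = cm.generate_arrest_pair(
        cm.ArrestSpec(base=arrest_base_spec, arrest_ploidy="2n",
                      accumulation_fold=3.3, growth_factor=2.5)
    )
    return pair["arrested"]


@pytest.fixture(scope="session")
def arrested_walk(arrest_base_spec):
    """G2/M-arrested population with stochastic (unregulated) accumulation."""
    pair = cm.generate_arrest_pair(
        cm.ArrestSpec(base=arrest_base_spec, arrest_ploidy="2n",
                      accumulation_fold=3.3, growth_factor=2.5,
                      accumulation_mode="stochastic_walk", walk_dispersion=0.15)
    )
    return pair["arrested"]


def gated_right_of_2n(table, width=1.0):
    """Gate a raw table right of its detected 2n mode; returns (gated, gate)."""
    t = cm.log2_transform(table)
    pk = mode_of(t)
    gated = cm.gate_right_of_2n(t, pk, width)
    gate = cm.Gate2nRight(pk.mode_2n, pk.mode_2n + min(width, 1.0))
    return gated, gate


def make_event_table(fluor, fsc, sample_id="test") -> cm.EventTable:
    return cm.EventTable(
        sample_id=sample_id,
        events=pd.DataFrame(
            {"fluor_linear": np.asarray(fluor, float), "fsc_linear": np.asarray(fsc, float)}
        ),
    )
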