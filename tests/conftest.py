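"""Shared fixtures: synthetic samples, gated replicates, role-named tables."""

from __future__ import annotations

import numpy as np
import pytest

from sputumflow.channels import ChannelMap, channel_map
from sputumflow.fcs import EventTable
from sputumflow.gating import GateConfig, run_gating
from sputumflow.synthetic import generate_sample
from sputumflow.transforms import logicle_table

#: populations counted as planted-live for recall statements
LIVE_POPS = ("leukocyte_bulk", "tcpp_bright", "fvs_intermediate",
             "inflammatory_linmid", "macrophage")


def table_from_roles(columns: dict, scales: dict | None = None) -> EventTable:
    """Build an EventTable whose channel names equal the role names."""
    names = list(columns)
    events = np.column_stack([np.asarray(columns[n], dtype=float) for n in names])
    t = EventTable(events=events, channel_names=names,
                   channel_map=ChannelMap.from_dict({n: n for n in names}))
    for name, scale in (scales or {}).items():
        t.scale[name] = scale
    return t


def gate_sample(sample, seed: int = 1, tube: str = "blood"):
    """Logicle-transform an assay tube (generator truth spillover is left
    in place; it does not affect the gating channels) and run the cascade."""
    cmap = channel_map("lsrii", tube=tube)
    t = logicle_table(sample.tubes[tube], cmap.fluor_roles())
    return t, run_gating({"beads": sample.tubes["beads"], tube: t},
                         GateConfig(seed=seed), assay=tube)


@pytest.fixture(scope="session")
def blood_map():
    return channel_map("lsrii", tube="blood")


@pytest.fixture(scope="session")
def healthy_sample():
    """One default non-cancer sample, desk scale."""
    return generate_sample("non-cancer", n_events=30_000, seed=7)


@pytest.fixture(scope="session")
def gated_healthy(healthy_sample):
    return gate_sample(healthy_sample)


@pytest.fixture(scope="session")
def gated_replicates():
    """Twenty seeded cancer-profile samples with their gating results.

    Shared across the nesting, conservation, recall and target-recovery
    checks so the expensive generation+gating work runs once.
    """
    out = []
    for seed in range(20):
        sample = generate_sample("cancer", n_events=30_000, seed=100 + seed)
        tube, result = gate_sample(sample, seed=1)
        out.append((sample, tube, result))
    return out
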