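"""Shared fixtures: one full-size pipeline run and one small genome.

The full default synthetic genome (64 planted genes) drives the
truth-recovery checks; it is expensive (~1 min) and therefore session
scoped.  The small genome exercises the same code paths at a fraction of
the cost for unit-level assertions.
"""

from __future__ import annotations

import pytest

from orfish.reporting import PipelineConfig, run_pipeline
from orfish.simulate import SimulationConfig, generate_repertoire


def small_config(seed: int = 7) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_contigs=16,
        contig_length_mean=6000,
        n_or_templates=4,
        complete_single_exon=8,
        complete_multi_exon=2,
        pseudogene_frameshift=1,
        pseudogene_stop=1,
        edge=2,
        fragment=1,
        decoy_gpcr=2,
        near_identical_groups=1,
        near_identical_group_size=2,
    )


@pytest.fixture(scope="session")
def small_repertoire():
    return generate_repertoire(small_config())


@pytest.fixture(scope="session")
def small_pipeline():
    return run_pipeline(PipelineConfig(simulation=small_config()))


@pytest.fixture(scope="session")
def default_pipeline():
    """Full pipeline on the default study conditions (64 planted genes)."""
    return run_pipeline(PipelineConfig(simulation=SimulationConfig(seed=1)))
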