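"""Shared fixtures: small synthetic study objects, generated at test time."""

from __future__ import annotations

import pytest

from srnapipe import simdata


def small_sim_config(seed: int = 3, n_reads: int = 2000) -> simdata.SimConfig:
    return simdata.SimConfig(
        seed=seed,
        n_reads_per_library=n_reads,
        n_known_mirnas=10,
        n_novel_hairpins=3,
        n_ncrnas=12,
        n_transcripts=8,
        n_target_sites=4,
    )


@pytest.fixture(scope="session")
def small_config() -> simdata.SimConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def small_bundle(small_config) -> simdata.ReferenceBundle:
    return simdata.generate_reference(small_config)


@pytest.fixture(scope="session")
def small_library(small_config, small_bundle):
    """One cleaned control library of the small study: (tags, ledger, truth)."""
    from srnapipe import preprocess

    records, truth = simdata.generate_library(small_bundle, small_config, "control")
    tags, ledger = preprocess.clean_reads(
        records, small_config.adapter_5p, small_config.adapter_3p, library="control")
    return tags, ledger, truth
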