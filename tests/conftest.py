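"""Shared fixtures: simulated study bundles reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from edscan.calling import call_editing
from edscan.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_bundle():
    """The default study conditions (12 case / 10 control, depth 50, seed 1)."""
    return simulate_all(SimulationConfig(), 1)


@pytest.fixture(scope="session")
def default_matrix(default_bundle):
    return call_editing(default_bundle.counts, default_bundle.genome)


def network_study_config() -> SimulationConfig:
    """One group-driven hub block of 20 events plus 80 background events."""
    return SimulationConfig(n_edit=100, n_differential=20, n_hub=20,
                            n_het_snp=0, n_hom_snp=0, n_decoy=0, n_null=0)


def clinical_study_config(**hormone_overrides) -> SimulationConfig:
    """Small 22-sample cohort of 20 hub events for replicated clinical runs."""
    cfg = SimulationConfig(
        contig_length=8_000, exon_length=1_500, intron_length=500,
        n_homopolymers=4, n_simple_repeats=2, n_alu=2,
        n_edit=20, n_differential=20, n_hub=20,
        n_het_snp=0, n_hom_snp=0, n_decoy=0, n_null=0,
        whitelist_fraction=0.0, snp_blacklist_fraction=0.0)
    if hormone_overrides:
        hm = dict(cfg.hormone_model)
        hm.update(hormone_overrides)
        cfg.hormone_model = hm
    return cfg


@pytest.fixture(scope="session")
def network_bundle():
    bundle = simulate_all(network_study_config(), 1)
    matrix = call_editing(bundle.counts, bundle.genome)
    return bundle, matrix


def hub_site_keys(truth) -> set[tuple[str, int]]:
    t = truth.table
    return {(r.contig, int(r.pos)) for r in t[t.is_hub].itertuples()}


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
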