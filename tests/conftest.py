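"""Shared fixtures: hand-built micro-panels and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from ldchase.panel import AncestryComposition, ReferencePanel
from ldchase.simulate import SyntheticPanelConfig, synthetic_panel


def make_panel(
    haplotypes: np.ndarray,
    positions=None,
    populations=None,
    chrom: str = "chr1",
) -> ReferencePanel:
    """Build a ReferencePanel from a 0/1 matrix with defaulted metadata."""
    haplotypes = np.asarray(haplotypes, dtype=np.uint8)
    n_hap, n_sites = haplotypes.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if populations is None:
        populations = ["P1"] * n_hap
    return ReferencePanel(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.array(["A"] * n_sites),
        alt=np.array(["G"] * n_sites),
        haplotypes=haplotypes,
        populations=np.array(populations, dtype=object),
    )


@pytest.fixture
def ld_panel() -> ReferencePanel:
    """4 haplotypes, 2 sites in perfect LD, both allele frequencies 0.5."""
    return make_panel(np.array([[1, 1], [1, 1], [0, 0], [0, 0]]))


@pytest.fixture
def equilibrium_panel() -> ReferencePanel:
    """4 haplotypes, 2 sites in linkage equilibrium, frequencies 0.5."""
    return make_panel(np.array([[1, 1], [1, 0], [0, 1], [0, 0]]))


@pytest.fixture
def two_pop_panel() -> ReferencePanel:
    """Two populations with different allele frequencies at one site."""
    return make_panel(
        np.array([[1], [1], [1], [0], [1], [0], [0], [0], [0], [0]]),
        populations=["EUR"] * 4 + ["EAS"] * 6,
    )


@pytest.fixture(scope="session")
def coalescent_panel() -> ReferencePanel:
    """A session-wide 200-haplotype coalescent panel on a 2 Mbp chromosome."""
    return synthetic_panel(
        SyntheticPanelConfig(n_haplotypes=200, chrom_length=2_000_000, seed=11)
    )


@pytest.fixture(scope="session")
def benchmark_panel() -> ReferencePanel:
    """The 500-haplotype panel used by the simulation-recovery tests."""
    return synthetic_panel(
        SyntheticPanelConfig(n_haplotypes=500, chrom_length=6_000_000, seed=1)
    )


@pytest.fixture
def single_pop() -> AncestryComposition:
    return AncestryComposition.single("P1")
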