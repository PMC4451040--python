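import numpy as np
import pytest

from cocult import (
    build_kmer_index,
    generate_coculture,
    generate_marker_scenario,
    screen_reads,
    select_markers,
)
from cocult.synthetic import CocultureParams, MarkerScenarioParams


@pytest.fixture(scope="session")
def default_coculture():
    """The default co-culture scenario (shared; treat as read-only)."""
    return generate_coculture()


@pytest.fixture(scope="session")
def default_screen(default_coculture):
    """Kmer screen of every default-scenario read against the rRNA refs."""
    index = build_kmer_index(default_coculture.rrna_refs, 21)
    return screen_reads(default_coculture.all_reads_flat(), index, min_hits=5)


@pytest.fixture(scope="session")
def default_marker_scenario():
    return generate_marker_scenario()


@pytest.fixture(scope="session")
def default_selection(default_marker_scenario):
    ms = default_marker_scenario
    return select_markers(ms.presence, ms.gene_tree_objects())


def small_coculture_params(seed: int) -> CocultureParams:
    """A fast, scaled-down co-culture that keeps the planted structure:
    clear coverage separation and disjoint GC windows."""
    return CocultureParams(
        predator_len=30_000,
        host_len=18_000,
        plasmid_lens=(4_000, 3_000),
        n_predator_contigs=6,
        n_host_contigs=8,
        predator_cov=250.0,
        host_cov=30.0,
        n_marker_tags=20,
        rrna_read_counts={
            ("Vampirovibrio_chlorellavorus", "16S"): 12,
            ("Chlorella_vulgaris_chloroplast", "chloroplast-16S"): 4,
            ("Chlorella_vulgaris_mitochondrion", "mitochondrial-rRNA"): 2,
        },
        seed=seed,
    )


def small_marker_params(seed: int, **overrides) -> MarkerScenarioParams:
    """A fast, scaled-down marker scenario with the same planted logic."""
    kwargs = dict(
        n_trusted_genomes=20,
        genomes_per_species=2,
        n_families_A=30,
        n_families_B=20,
        n_redundant_pairs=5,
        n_candidates=40,
        n_divergent=10,
        n_congruent_multicopy=5,
        block_len=60,
        seed=seed,
    )
    kwargs.update(overrides)
    return MarkerScenarioParams(**kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
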