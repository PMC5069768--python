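"""Shared fixtures: one small planted world, aligned once per session."""

import pytest

from panlink import genefamilies as gf
from panlink.worldgen import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """Default scaled-down 13-strain world with the planted 11-gene cluster."""
    return generate_world(WorldConfig.small(seed=11))


@pytest.fixture(scope="session")
def small_world_hits(small_world):
    return gf.all_pairwise_hits(small_world.proteomes)


@pytest.fixture(scope="session")
def small_world_barcodes(small_world, small_world_hits):
    barcodes, groups = gf.bbh_orthologs(small_world.proteomes, small_world_hits)
    return barcodes, groups


@pytest.fixture(scope="session")
def tiny_world():
    """Very small world (4 strains) for exhaustive-alignment style checks."""
    config = WorldConfig(
        n_strains=4,
        clade_split=((0, 1), (2, 3)),
        clonal_pairs=(),
        n_core_families=6,
        n_accessory_families=8,
        n_singletons_per_strain=2,
        genes_per_contig=12,
        planted_clusters=(),
        features_per_strain=40,
        blank_features=5,
        n_halogenated_features=6,
        seed=7,
    )
    return generate_world(config)
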