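import pytest

from metasecretome.simulate import (
    CommunityConfig,
    PhylumSpec,
    default_phyla,
    generate_community,
)


@pytest.fixture(scope="session")
def tiny_community():
    """Two phyla x 5 MAGs x 20 ORFs, redundancy 3: small enough to cluster."""
    phyla = (
        PhylumSpec("Bacteroidetes_like", n_mags=5, secretion_fraction=0.30,
                   cazyme_profile={"GH2": 2.0, "GH13": 1.0},
                   cazyme_secretion_fraction=0.2, cog_rates={"G": 2.0, "M": 1.0}),
        PhylumSpec("Firmicutes_like", n_mags=5, secretion_fraction=0.10,
                   cazyme_profile={"GH1": 2.0, "GH18": 0.5},
                   cazyme_secretion_fraction=0.05, cog_rates={"G": 1.0, "M": 1.0}),
    )
    cfg = CommunityConfig(seed=11, phyla=phyla, orfs_per_mag=20, cluster_redundancy=3.0)
    return generate_community(cfg)


@pytest.fixture(scope="session")
def default_community_nosequences():
    """Full-size default community (15,000 ORFs) without sequence strings."""
    return generate_community(CommunityConfig(seed=5, with_sequences=False))


@pytest.fixture(scope="session")
def default_phyla_specs():
    return default_phyla()
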