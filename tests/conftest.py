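import pytest

from hypoxiscan.simulate import default_species_tree, simulate_gene_family


@pytest.fixture(scope="session")
def species_tree():
    return default_species_tree()


@pytest.fixture(scope="session")
def families_with_duplications(species_tree):
    """Moderate duplication-loss families (dup 0.1, loss 0.05)."""
    return [
        simulate_gene_family(species_tree, 0.1, 0.05, seed=seed)
        for seed in range(60)
    ]


@pytest.fixture(scope="session")
def loss_only_families(species_tree):
    """Families with losses but no duplications: all relations are 1:1."""
    return [
        simulate_gene_family(species_tree, 0.0, 0.15, seed=seed)
        for seed in range(60)
    ]
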