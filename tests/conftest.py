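import pytest

from opsinphylo import io, simulate


@pytest.fixture
def quartet_tree():
    tree = io.read_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
    return simulate.name_nodes(tree)


@pytest.fixture
def six_taxon_tree():
    tree = io.read_newick(
        "((A:0.08,B:0.08):0.04,((C:0.05,D:0.05):0.04,(E:0.06,F:0.06):0.03):0.03);"
    )
    return simulate.name_nodes(tree)


@pytest.fixture
def small_alignment(six_taxon_tree):
    spec = simulate.SimulationSpec(
        tree=six_taxon_tree, kappa=2.0, omega=0.3, n_codons=150, seed=11
    )
    aln, _ = simulate.simulate_codon_alignment(spec)
    return aln


@pytest.fixture
def preset_tree():
    return simulate.preset_tree("pteropodid-like")
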