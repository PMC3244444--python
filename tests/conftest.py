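"""Shared fixtures: small trees, simulated alignments, frequency vectors.

Everything is generated programmatically and deterministically; heavier
simulated datasets are session-scoped so multiple tests share one fit.
"""

import numpy as np
import pytest

from protsel import codon_model as cm
from protsel import synthetic_data as sd
from protsel.seqio import CODONS, CodonAlignment
from protsel.synthetic_data import _f3x4_freqs
from protsel.trees import Phylogeny


@pytest.fixture(scope="session")
def freqs_uniform():
    return np.full(61, 1 / 61)


@pytest.fixture(scope="session")
def freqs_skewed():
    return _f3x4_freqs()


@pytest.fixture(scope="session")
def quartet_tree():
    return Phylogeny.from_newick("((A:0.2,B:0.3):0.1,(C:0.15,D:0.25):0.1);")


@pytest.fixture(scope="session")
def triplet_tree():
    return Phylogeny.from_newick("((A:0.1,B:0.2):0.15,C:0.3);")


@pytest.fixture(scope="session")
def six_taxon_tree():
    return Phylogeny.from_newick(
        "(((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2):0.2,(E:0.5,F:0.5):0.2);"
    )


@pytest.fixture(scope="session")
def toy_alignment(triplet_tree):
    """3 taxa x 5 codons, random sense codons (not tree-generated)."""
    rng = np.random.default_rng(0)
    seqs = [
        "".join(CODONS[i] for i in rng.integers(0, 61, 5)) for _ in range(3)
    ]
    return CodonAlignment(["A", "B", "C"], seqs)


@pytest.fixture(scope="session")
def m0_sim(quartet_tree, freqs_skewed):
    """An M0 (omega=0.5, kappa=2) simulation at Lc=2000 with its spec."""
    spec = cm.CodonModelSpec(2.0, freqs_skewed, 0.5, "F3X4")
    aln, truth = sd.simulate_codon_alignment(quartet_tree, spec, 2000, seed=17)
    return aln, truth, spec


@pytest.fixture(scope="session")
def m2a_sim():
    """M2a world on the deep site tree: 5% of sites at omega=3."""
    tree = sd.site_tree()
    mix = cm.SiteMixtureSpec(
        "M2a", classes=[(0.55, 0.1), (0.40, 1.0), (0.05, 3.0)]
    )
    spec = cm.CodonModelSpec(2.0, _f3x4_freqs(), mix, "F3X4")
    aln, truth = sd.simulate_codon_alignment(tree, spec, 500, seed=11)
    return tree, aln, truth, spec


@pytest.fixture(scope="session")
def m2a_fit(m2a_sim):
    tree, aln, truth, spec = m2a_sim
    r = cm.fit(
        aln, tree, "M2a", optimize_branch_lengths=False, n_starts=2, seed=0
    )
    return tree, aln, truth, r
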