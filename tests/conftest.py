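import numpy as np
import pytest

from rhodosplice.synthetic_cohort import CohortParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-gene, six-species cohort with the default study conditions."""
    return simulate_cohort(CohortParams(seed=7, n_genes=60))


@pytest.fixture(scope="session")
def cohort_no_indel():
    """Substitution-only cohort: proteins stay colinear, alignments gapless."""
    return simulate_cohort(CohortParams(seed=13, n_genes=50, indel_rate=0.0))


@pytest.fixture(scope="session")
def static_cohort():
    """All evolutionary rates zero: every species is a copy of the ancestor."""
    return simulate_cohort(CohortParams(
        seed=3, n_genes=25, intron_gain_rate=0.0, intron_loss_rate=0.0,
        gene_loss_rate=0.0, substitution_rate=0.0, indel_rate=0.0))


def random_bifurcating_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random rooted bifurcating tree over leaves L0..L{n-1} by random merges."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a}:1,{b}:1)")
    return nodes[0] + "root;"
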