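"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by brute force or via a
third-party implementation, independent of the package's own algorithms:
exhaustive enumeration over all ancestral labelings for parsimony,
all-substring pairing checks for hairpins, and Biopython's codon table for
translation.
"""

import random

import numpy as np
import pytest

from acromito.fixture import study_fixture
from acromito.parsimony import read_tree


@pytest.fixture(scope="session")
def fixture_data():
    return study_fixture()


@pytest.fixture(scope="session")
def fixture_records(fixture_data):
    return fixture_data[0]


@pytest.fixture(scope="session")
def fixture_matrix(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def fixture_tree(fixture_data):
    return fixture_data[2]


# ---------------------------------------------------------------------------
# exhaustive parsimony oracle (vectorized enumeration over all labelings)


def exhaustive_parsimony(tree, tip_states, states, root_state=None,
                         derived_state=None):
    """Brute-force parsimony over every ancestral labeling.

    Enumerates all k^(internal nodes) labelings, computes each labeling's
    change count by summing mismatched edges, and returns
    ``(min_cost, min_gains, max_gains)`` where the gain statistics (edges
    entering `derived_state`) are taken over the cost-minimal labelings
    only (None when no derived_state given).  `root_state` is a tie-break
    preference mirroring outgroup polarization: when some globally optimal
    labeling carries that root state only such labelings are considered,
    otherwise all optimal labelings are.
    """
    t = read_tree(tree)
    internals = [n for n in t.preorder_node_iter() if not n.is_leaf()]
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    n_int = len(internals)
    pos = {id(n): i for i, n in enumerate(internals)}
    if n_int:
        grids = np.meshgrid(*[np.arange(k)] * n_int, indexing="ij")
        labs = np.stack(grids, -1).reshape(-1, n_int)
    else:
        labs = np.zeros((1, 0), int)

    cost = np.zeros(len(labs))
    gains = np.zeros(len(labs))
    d_idx = idx[derived_state] if derived_state is not None else None
    for node in t.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        pcol = labs[:, pos[id(parent)]]
        if node.is_leaf():
            s = tip_states[node.taxon.label]
            if s == "?":
                continue
            ccol = np.full(len(labs), idx[s])
        else:
            ccol = labs[:, pos[id(node)]]
        cost += pcol != ccol
        if d_idx is not None:
            gains += (pcol != d_idx) & (ccol == d_idx)

    best = cost.min()
    optimal = cost == best
    if root_state is not None and n_int:
        rooted = optimal & (labs[:, pos[id(t.seed_node)]] == idx[root_state])
        if rooted.any():
            optimal = rooted
    if d_idx is None:
        return int(best), None, None
    return int(best), int(gains[optimal].min()), int(gains[optimal].max())


# ---------------------------------------------------------------------------
# brute-force hairpin oracle (all-substring pairing check)

_ORACLE_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
                 ("G", "T"), ("T", "G")}


def brute_hairpin_present(seq, min_stem, loop_range=(3, 20)):
    """Does any perfect stem-loop of stem >= min_stem exist?  Checks every
    (start, stem, loop) triple directly."""
    seq = seq.upper()
    n = len(seq)
    for start in range(n):
        for loop in range(loop_range[0], loop_range[1] + 1):
            end = start + 2 * min_stem + loop
            if end > n:
                continue
            if all((seq[start + k], seq[end - 1 - k]) in _ORACLE_PAIRS
                   for k in range(min_stem)):
                return True
    return False


# ---------------------------------------------------------------------------
# misc helpers


def hamming(a, b):
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def random_signed_order(rng: random.Random):
    """A random signed permutation over the canonical symbol set."""
    from acromito.genome import GeneOrder, canonical_vertebrate_order
    elems = list(canonical_vertebrate_order().elements)
    head, rest = elems[0], elems[1:]
    rng.shuffle(rest)
    rest = [(n, rng.choice("+-")) for n, _ in rest]
    return GeneOrder(elements=tuple([head] + rest), anchor="F")
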