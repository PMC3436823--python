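"""Shared fixtures: small trees, models and simulated datasets."""

import itertools

import numpy as np
import pytest

import coevonet as cn
from coevonet.simulate import random_tree

BALANCED4 = "((A:1,B:1):1,(C:1,D:1):1);"
TREE6 = "(((A:0.3,B:0.7):0.2,(C:0.5,D:0.1):0.4):0.3,(E:0.6,F:0.2):0.5);"
TREE8 = (
    "(((A:0.4,B:0.3):0.2,(C:0.5,D:0.2):0.3):0.2,"
    "((E:0.3,F:0.4):0.3,(G:0.2,H:0.5):0.2):0.3);"
)


@pytest.fixture(scope="session")
def tree4():
    return cn.read_newick(BALANCED4)


@pytest.fixture(scope="session")
def tree6():
    return cn.read_newick(TREE6)


@pytest.fixture(scope="session")
def tree8():
    return cn.read_newick(TREE8)


@pytest.fixture(scope="session")
def tree32():
    return random_tree(32, np.random.default_rng(5), mean_length=0.35)


@pytest.fixture(scope="session")
def model_k1():
    return cn.GainLossModel(gain=1.0, loss=1.0, rho=1.0, n_categories=1)


@pytest.fixture(scope="session")
def model_skew():
    return cn.GainLossModel(gain=1.3, loss=0.7, rho=1.2, n_categories=1)


@pytest.fixture(scope="session")
def model_k4():
    return cn.GainLossModel(
        gain=1.0, loss=1.0, alpha_gain=0.8, alpha_loss=1.5, rho=1.0, n_categories=4
    )


def brute_force_loglik(row, tree, model):
    """Likelihood by exhaustive enumeration over internal-node states."""
    total = 0.0
    rates = model.category_rates()
    leaves = list(tree.leaves)
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    eff = model.rho * tree.lengths
    for g, l in rates:
        P = [None] + [cn.transition_matrix(g, l, eff[v]) for v in range(1, tree.n_nodes)]
        pi = np.array([l / (g + l), g / (g + l)])
        cat = 0.0
        for assign in itertools.product([0, 1], repeat=len(internal)):
            st = dict(zip(internal, assign))
            for i, v in enumerate(leaves):
                st[v] = int(row[i])
            p = pi[st[0]]
            for v in range(1, tree.n_nodes):
                p *= P[v][st[tree.parent[v]], st[v]]
            cat += p
        total += cat / model.n_categories
    return np.log(total)


def set_partitions(items):
    """All partitions of a list (restricted-growth strings)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part
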