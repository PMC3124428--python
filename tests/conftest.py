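import itertools

import numpy as np
import pytest

import phyloinform as pf
from phyloinform.io_phylo import state_set


@pytest.fixture
def make_tree(tmp_path):
    """Factory: write a Newick string and parse it as an UltrametricTree."""
    counter = itertools.count()

    def _make(newick: str, tolerance: float = 1e-4):
        p = tmp_path / f"tree{next(counter)}.nwk"
        p.write_text(newick + ("\n" if not newick.endswith("\n") else ""))
        return pf.read_tree(p, tolerance=tolerance)

    return _make


@pytest.fixture
def jc():
    return pf.make_model("jc69")


@pytest.fixture
def two_taxon_tree(make_tree):
    return make_tree("(A:0.1,B:0.1);")


@pytest.fixture
def four_taxon_tree(make_tree):
    return make_tree("((A:0.3,B:0.3):0.7,(C:0.6,D:0.6):0.4);")


def brute_force_loglik(utree, model, column, lam):
    """Independent oracle: sum the column likelihood over every assignment
    of states to internal nodes (feasible for small trees)."""
    nodes = list(utree.tree.preorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    P = {}
    for n in nodes:
        if n.parent_node is not None:
            P[id(n)] = model.transition_matrix(lam * n.edge.length)
    total = 0.0
    root = utree.tree.seed_node
    for assign in itertools.product(range(model.n_states), repeat=len(internals)):
        st = {id(n): s for n, s in zip(internals, assign)}
        p = model.pi[st[id(root)]]
        for n in nodes:
            if n.parent_node is None:
                continue
            ps = st[id(n.parent_node)]
            if n.is_leaf():
                allowed = state_set(column[n.taxon.label], model.alphabet)
                p *= sum(P[id(n)][ps, s] for s in allowed)
            else:
                p *= P[id(n)][ps, st[id(n)]]
        total += p
    return np.log(total) if total > 0 else -np.inf
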