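import numpy as np
import pytest

from cladecons import SubstitutionModel, parse_newick


@pytest.fixture(scope="session")
def jc():
    return SubstitutionModel.jc69()


@pytest.fixture(scope="session")
def hky():
    return SubstitutionModel.hky85(3.0, [0.3, 0.2, 0.2, 0.3])


@pytest.fixture(scope="session")
def tree4():
    return parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")


@pytest.fixture(scope="session")
def tree6():
    # six-leaf ingroup-style tree, total length ~2 substitutions/site
    return parse_newick(
        "(((s1:0.2,s2:0.2):0.15,(s3:0.2,s4:0.2):0.15):0.1,(s5:0.25,s6:0.25):0.15);"
    )


@pytest.fixture(scope="session")
def clade_tree():
    # 4 ingroup species b1-b4 plus three successively deeper outgroups
    return parse_newick(
        "((((b1:0.12,b2:0.12):0.1,(b3:0.12,b4:0.12):0.1):0.25,og1:0.45):0.15,"
        "(og2:0.3,og3:0.3):0.2);"
    )


def brute_force_column_likelihood(tree, model, column):
    """Exhaustive sum over internal-node state assignments (oracle)."""
    import itertools

    from cladecons.alignment import _CODE

    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf[i]]
    pmats = [model.transition_matrix(t) for t in tree.lengths]
    leaf_states = {}
    missing = set()
    for li in tree.leaf_indices:
        ch = column.get(tree.names[li], "N")
        if ch in "ACGT":
            leaf_states[li] = _CODE[ch]
        else:
            missing.add(li)
    total = 0.0
    free = internal + sorted(missing)
    for assign in itertools.product(range(4), repeat=len(free)):
        st = dict(zip(free, assign))
        st.update(leaf_states)
        p = model.pi[st[tree.root]]
        for v in range(tree.n_nodes - 1):
            p *= pmats[v][st[tree.parent[v]], st[v]]
        total += p
    return np.log(total) if total > 0 else -np.inf
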