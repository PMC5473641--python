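"""Felsenstein pruning likelihoods and maximum-likelihood model fitting.

All likelihood computation runs on column *patterns*: the distinct columns
of an alignment with their multiplicities, so repeated columns are costed
once.  Gaps and N are missing data and are marginalised; a species present
in the tree but absent from the alignment contributes a flat partial
likelihood (fully missing row).

Branch-length and model fitting use bounded quasi-Newton optimisation on
log-parameters from deterministic starts, so fits are reproducible without
any seed.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment import GAP, MultipleAlignment, encode
from .models import SubstitutionModel
from .tree import PhyloTree

__all__ = [
    "compress_patterns",
    "site_log_likelihoods",
    "column_log_likelihood",
    "fit_neutral_model",
    "fit_branch_lengths",
    "fit_branch_scales",
    "fit_scale_groups",
]

# partial likelihood row for each observed code A,C,G,T,-,N
_LEAF_PARTIAL = np.vstack([np.eye(4), np.ones((2, 4))])

_MIN_LENGTH, _MAX_LENGTH = 1e-9, 20.0
_CLAMP = 1e-8


def compress_patterns(matrix: np.ndarray):
    """Unique columns of a (species x column) matrix.

    Returns (patterns, counts, inverse): ``patterns`` has shape
    (n_patterns, n_species); ``matrix[:, j] == patterns[inverse[j]].T``.
    """
    patterns, inverse, counts = np.unique(
        matrix.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns, counts.astype(float), inverse


def leaf_row_map(tree: PhyloTree, species: Sequence[str]) -> np.ndarray:
    """Map tree node id -> alignment row index (-1 = missing species)."""
    rows = {sp: i for i, sp in enumerate(species)}
    out = np.full(tree.n_nodes, -1, dtype=np.int64)
    for li in tree.leaf_indices:
        out[li] = rows.get(tree.names[li], -1)
    return out


def site_log_likelihoods(
    tree: PhyloTree,
    model: SubstitutionModel,
    patterns: np.ndarray,
    row_of_node: np.ndarray,
    lengths: np.ndarray | None = None,
    scale: float = 1.0,
) -> np.ndarray:
    """Log-likelihood of each column pattern under the pruning algorithm.

    ``scale`` multiplies every branch length.  Returns shape (n_patterns,);
    impossible patterns give ``-inf``, fully missing patterns give 0.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if lengths is None:
        lengths = tree.lengths
    pmats = model.transition_matrices(np.asarray(lengths, float) * scale)
    P = patterns.shape[0]
    logscale = np.zeros(P)
    partials: list[np.ndarray | None] = [None] * tree.n_nodes
    for v in tree.postorder():
        if tree.is_leaf[v]:
            r = row_of_node[v]
            if r < 0:
                partials[v] = np.ones((P, 4))
            else:
                partials[v] = _LEAF_PARTIAL[patterns[:, r]]
        else:
            acc = np.ones((P, 4))
            for c in tree.children[v]:
                acc *= partials[c] @ pmats[c].T
                partials[c] = None
            m = acc.max(axis=1)
            nz = m > 0
            acc[nz] /= m[nz, None]
            with np.errstate(divide="ignore"):
                logscale += np.where(nz, np.log(np.where(nz, m, 1.0)), -np.inf)
            partials[v] = acc
    like = partials[tree.root] @ model.pi
    with np.errstate(divide="ignore"):
        out = np.where(like > 0, np.log(np.where(like > 0, like, 1.0)), -np.inf) + logscale
    # a fully missing column has probability exactly 1
    observed = np.zeros(P, dtype=bool)
    for v in tree.leaf_indices:
        r = row_of_node[v]
        if r >= 0:
            observed |= patterns[:, r] < 4
    out[~observed] = 0.0
    return out


def site_loglik_and_gradient(
    tree: PhyloTree,
    model: SubstitutionModel,
    patterns: np.ndarray,
    row_of_node: np.ndarray,
    lengths: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pattern log-likelihoods and d(logL)/d(branch length) per edge.

    One upward (pruning) and one downward (outside) pass; uses
    dP(t)/dt = Q P(t).  Unscaled partials — adequate for the small trees
    this package targets (the bounded optimiser keeps every length
    positive, so no pattern has zero probability).
    """
    lengths = np.asarray(lengths, float)
    pmats = model.transition_matrices(np.maximum(lengths, 1e-12))
    q = model.Q
    qp = np.einsum("ij,njk->nik", q, pmats)
    P = patterns.shape[0]
    up: list[np.ndarray | None] = [None] * tree.n_nodes
    msgs: list[np.ndarray | None] = [None] * tree.n_nodes  # U_child @ P_child.T
    for v in tree.postorder():
        if tree.is_leaf[v]:
            r = row_of_node[v]
            up[v] = np.ones((P, 4)) if r < 0 else _LEAF_PARTIAL[patterns[:, r]]
        else:
            acc = np.ones((P, 4))
            for c in tree.children[v]:
                msgs[c] = up[c] @ pmats[c].T
                acc *= msgs[c]
            up[v] = acc
    like = up[tree.root] @ model.pi
    grad = np.zeros((P, tree.n_nodes - 1))
    above: list[np.ndarray | None] = [None] * tree.n_nodes
    above[tree.root] = np.broadcast_to(model.pi, (P, 4))
    for v in range(tree.n_nodes - 1, -1, -1):  # preorder
        if tree.is_leaf[v]:
            continue
        for c in tree.children[v]:
            sib = above[v].copy()
            for s in tree.children[v]:
                if s != c:
                    sib *= msgs[s]
            grad[:, c] = np.einsum("pi,ij,pj->p", sib, qp[c], up[c]) / like
            above[c] = sib @ pmats[c]
    with np.errstate(divide="ignore"):
        return np.log(like), grad


def column_log_likelihood(
    tree: PhyloTree,
    model: SubstitutionModel,
    scale: float,
    column: dict[str, str],
) -> float:
    """Log-probability of one alignment column (species -> character).

    Species of the tree absent from ``column`` are missing data; gaps and N
    are marginalised.  A column missing at every leaf returns 0.
    """
    unknown = set(column) - set(tree.leaf_names)
    if unknown:
        raise ValueError(f"column species not in tree: {sorted(unknown)}")
    if not column:
        return 0.0
    species = list(column)
    pattern = np.concatenate([encode(column[sp]) for sp in species])[None, :]
    row_of_node = leaf_row_map(tree, species)
    return float(
        site_log_likelihoods(tree, model, pattern.reshape(1, -1), row_of_node, scale=scale)[0]
    )


def alignment_log_likelihood(
    aln: MultipleAlignment, tree: PhyloTree, model: SubstitutionModel, scale: float = 1.0
) -> float:
    patterns, counts, _ = compress_patterns(aln.matrix)
    rows = leaf_row_map(tree, aln.species)
    return float(counts @ site_log_likelihoods(tree, model, patterns, rows, scale=scale))


# --------------------------------------------------------------------- #
# fitting


def _empirical_pi(matrix: np.ndarray) -> np.ndarray:
    counts = np.bincount(matrix[matrix < GAP].ravel(), minlength=4).astype(float)
    counts += 1.0  # flat pseudocount keeps frequencies strictly positive
    return counts / counts.sum()


def _optimize(fun, x0_list, bounds):
    best = None
    for x0 in x0_list:
        res = minimize(
            fun, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_neutral_model(
    aln: MultipleAlignment,
    topology: PhyloTree,
    family: str = "HKY85",
) -> tuple[SubstitutionModel, PhyloTree]:
    """ML fit of a neutral substitution model and branch lengths.

    Fits branch lengths on the fixed topology jointly with the family's
    exchangeability parameters; equilibrium frequencies are the observed
    base frequencies (fixed at 1/4 for JC69).  Intended to be run on
    putatively neutral columns such as fourfold-degenerate sites.
    """
    patterns, counts, _ = compress_patterns(aln.matrix)
    rows = leaf_row_map(topology, aln.species)
    n_edges = topology.n_nodes - 1
    pi = np.full(4, 0.25) if family == "JC69" else _empirical_pi(aln.matrix)

    variable = np.array(
        [len(set(p[p < GAP]) ) > 1 for p in patterns]
    )
    if not np.any(variable & (counts > 0)):
        warnings.warn("no variable columns: branch lengths collapse to zero")

    n_extra = {"JC69": 0, "HKY85": 1, "GTR": 5}[family]

    def build(theta):
        if family == "JC69":
            return SubstitutionModel.jc69()
        if family == "HKY85":
            return SubstitutionModel.hky85(np.exp(theta[0]), pi)
        rates = np.ones(6)
        rates[:5] = np.exp(theta[:5])
        return SubstitutionModel.gtr(rates, pi)

    def negll(x):
        lengths = np.append(np.exp(x[:n_edges]), 0.0)
        model = build(x[n_edges:])
        return -float(counts @ site_log_likelihoods(topology, model, patterns, rows, lengths))

    bounds = [(np.log(_MIN_LENGTH), np.log(_MAX_LENGTH))] * n_edges + [
        (np.log(1e-3), np.log(1e3))
    ] * n_extra
    starts = []
    for b0 in (0.1, 0.3):
        starts.append(np.concatenate([np.full(n_edges, np.log(b0)), np.zeros(n_extra)]))
    res = _optimize(negll, starts, bounds)
    lengths = np.append(np.exp(res.x[:n_edges]), 0.0)
    lengths[lengths < _CLAMP] = 0.0
    model = build(res.x[n_edges:])
    return model, topology.copy(lengths=lengths)


def fit_branch_lengths(
    patterns: np.ndarray,
    counts: np.ndarray,
    tree: PhyloTree,
    model: SubstitutionModel,
    row_of_node: np.ndarray,
    init: np.ndarray | None = None,
    free_edges: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """ML branch lengths on a fixed topology and model.

    Returns (lengths, log-likelihood).  ``init`` warm-starts the optimiser
    (used by bootstrap replicates).  When ``free_edges`` (edge/child-node
    indices) is given, only those branch lengths are optimised and the
    rest stay at ``init`` — e.g. holding outgroup branches at their
    neutral lengths, which also pins down the otherwise unidentifiable
    split of length across the root.
    """
    n_edges = tree.n_nodes - 1
    if init is None:
        init = np.full(n_edges, 0.1)
    init = np.asarray(init, float)[:n_edges]
    if free_edges is None:
        free_edges = np.arange(n_edges)
    # no variable columns: the ML is exactly at zero length on free edges
    informative = np.array(
        [len(np.unique(p[p < GAP])) > 1 for p in patterns]
    )
    if not np.any(informative & (counts > 0)):
        lengths = np.append(init, 0.0)
        lengths[np.asarray(free_edges, dtype=np.int64)] = 0.0
        ll = float(counts @ site_log_likelihoods(tree, model, patterns, row_of_node, lengths))
        return lengths, ll
    free_edges = np.asarray(free_edges, dtype=np.int64)
    x0 = np.log(np.clip(init[free_edges], _MIN_LENGTH, _MAX_LENGTH))
    template = np.append(init, 0.0)

    def negll_grad(x):
        lengths = template.copy()
        t = np.exp(x)
        lengths[free_edges] = t
        llp, gradp = site_loglik_and_gradient(tree, model, patterns, row_of_node, lengths)
        g = counts @ gradp[:, free_edges]
        return -float(counts @ llp), -(g * t)

    res = minimize(
        negll_grad, x0, jac=True, method="L-BFGS-B",
        bounds=[(np.log(_MIN_LENGTH), np.log(_MAX_LENGTH))] * len(free_edges),
        options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-6},
    )
    lengths = template.copy()
    lengths[free_edges] = np.exp(res.x)
    lengths[lengths < _CLAMP] = 0.0
    return lengths, -float(res.fun)


def fit_branch_scales(
    element: MultipleAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    min_columns: int = 20,
) -> PhyloTree:
    """Element-specific ML branch lengths on the fixed neutral topology.

    Species in the tree that are absent from the element alignment are
    treated as missing data.  Warns when the element is shorter than
    ``min_columns``.
    """
    if element.n_columns < min_columns:
        warnings.warn(
            f"element has {element.n_columns} columns (<{min_columns}); "
            "branch-length estimates will be noisy"
        )
    patterns, counts, _ = compress_patterns(element.matrix)
    rows = leaf_row_map(tree, element.species)
    lengths, _ = fit_branch_lengths(
        patterns, counts, tree, model, rows, init=np.maximum(tree.lengths[:-1], 1e-4)
    )
    return tree.copy(lengths=lengths)


def fit_scale_groups(
    patterns: np.ndarray,
    counts: np.ndarray,
    tree: PhyloTree,
    model: SubstitutionModel,
    row_of_node: np.ndarray,
    edge_group: np.ndarray,
    n_groups: int,
) -> tuple[np.ndarray, float]:
    """ML scale factor per edge group, multiplying the fixed neutral lengths.

    ``edge_group[v]`` assigns the edge above node ``v`` to a group.  Used by
    the subtree-rate likelihood-ratio test (one shared scale under H0, an
    ingroup and an outgroup scale under H1).
    """
    base = tree.lengths.copy()

    def negll_vec(scales):
        lengths = base * scales[edge_group]
        return -float(counts @ site_log_likelihoods(tree, model, patterns, row_of_node, lengths))

    if n_groups == 1:
        res = minimize_scalar(
            lambda s: negll_vec(np.array([np.exp(s)])),
            bounds=(np.log(1e-6), np.log(1e3)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        return np.array([np.exp(res.x)]), -float(res.fun)

    def negll(x):
        return negll_vec(np.exp(x))

    res = minimize(
        negll, np.zeros(n_groups), method="L-BFGS-B",
        bounds=[(np.log(1e-6), np.log(1e3))] * n_groups,
        options={"maxiter": 200, "ftol": 1e-13, "gtol": 1e-7},
    )
    return np.exp(res.x), -float(res.fun)
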