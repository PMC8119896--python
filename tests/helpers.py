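"""Independent oracles used by the test suite.

Everything here is deliberately written without reusing the package's
likelihood code: transition probabilities come straight from the Poisson
closed form, and column likelihoods are computed by exhaustive summation
over internal-node state assignments (vectorized over the assignment grid),
so they can serve as a brute-force check of the pruning implementation.
"""

from __future__ import annotations

import numpy as np

N = 20


def poisson_transition(t: float) -> np.ndarray:
    """P[a, b] under the equal-rates amino-acid model (independent copy)."""
    e = np.exp(-N * t / (N - 1))
    return np.full((N, N), (1.0 - e) / N) + np.eye(N) * e


def brute_force_likelihood(tree, leaf_states: dict[str, int | None], rate: float) -> float:
    """Column likelihood by exhaustive enumeration over hidden states.

    ``leaf_states`` maps taxon label to an amino-acid code 0..19, or None
    for a missing observation (gap/unknown), which is summed over like an
    internal node.  Uniform root frequencies.
    """
    internal = [n for n in range(tree.n_nodes) if not tree.is_leaf(n)]
    missing_leaves = [
        n for n, lab in tree.leaf_labels.items() if leaf_states[lab] is None
    ]
    free = internal + missing_leaves
    grid = np.indices((N,) * len(free)).reshape(len(free), -1)  # (n_free, N**n_free)
    state_of: dict[int, np.ndarray] = {}
    for i, node in enumerate(free):
        state_of[node] = grid[i]
    for node, lab in tree.leaf_labels.items():
        if leaf_states[lab] is not None:
            state_of[node] = np.full(grid.shape[1], leaf_states[lab], dtype=np.int64)
    factors = np.full(grid.shape[1], 1.0 / N)  # root frequency
    for node in range(tree.n_nodes):
        if node == tree.root:
            continue
        p_mat = poisson_transition(float(tree.branch_lengths[node]) * rate)
        factors = factors * p_mat[state_of[int(tree.parent[node])], state_of[node]]
    return float(factors.sum())


def invariant_column_probability(tree, rate: float) -> float:
    """P(all leaves share the same amino acid) at a given site rate.

    Computed as sum over target residues a of the likelihood of the
    constant-a column, via an independent bottom-up recursion (conditional
    probabilities that every leaf below a node equals a).
    """
    total = 0.0
    for a in range(N):
        cond: dict[int, np.ndarray] = {}
        for node in tree.postorder:
            node = int(node)
            if tree.is_leaf(node):
                vec = np.zeros(N)
                vec[a] = 1.0
            else:
                vec = np.ones(N)
                for child in tree.children[node]:
                    p_mat = poisson_transition(float(tree.branch_lengths[child]) * rate)
                    vec = vec * (p_mat @ cond[child])
            cond[node] = vec
        total += float(cond[tree.root].mean())  # uniform root frequencies
    return total


def rank_then_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as Pearson correlation of average ranks (oracle route)."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
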