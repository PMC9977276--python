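"""Shared fixtures and independent oracles.

The brute-force likelihood/posterior oracle enumerates every assignment of
states to internal nodes explicitly (feasible up to ~5 leaves) and is kept
deliberately independent of the pruning engine it checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from ancseq.alignment import ProteinAlignment
from ancseq.alphabet import AMINO_ACIDS, MISSING_CODE, N_STATES
from ancseq.substitution import SubstitutionModel, get_model
from ancseq.synthetic import simulate_tree
from ancseq.tree import PhyloTree


# ------------------------------------------------------------------ oracle
def brute_force_likelihood_and_posteriors(
    tree: PhyloTree, model: SubstitutionModel, alignment: ProteinAlignment
) -> tuple[float, dict[int, np.ndarray]]:
    """Exhaustive sum over all internal-node state assignments.

    Returns the total log-likelihood (gamma mixture, equal weights) and the
    marginal posterior matrix (L x 20) for every internal node.
    """
    internal = tree.internal_ids
    order = {sid: j for j, sid in enumerate(alignment.ids)}
    pos = {nid: i for i, nid in enumerate(internal)}
    n_int = len(internal)
    # all assignments: (20^n_int, n_int)
    grids = np.meshgrid(*[np.arange(N_STATES)] * n_int, indexing="ij")
    assign = np.stack([g.ravel() for g in grids], axis=1)

    L = alignment.length
    K = model.n_categories
    rates = model.gamma_rates.rates
    total_log = 0.0
    posts = {nid: np.zeros((L, N_STATES)) for nid in internal}
    for s in range(L):
        site_lik_k = np.zeros(K)
        site_post_k = {nid: np.zeros((K, N_STATES)) for nid in internal}
        for k in range(K):
            P = {
                c: model.transition_matrix(float(tree.lengths[c]), rates[k])
                for c in range(tree.n_nodes - 1)
            }
            w = model.frequencies[assign[:, pos[tree.root]]].copy()
            for c in range(tree.n_nodes - 1):
                p = int(tree.parent[c])
                pa = assign[:, pos[p]]
                if tree.is_leaf(c):
                    obs = alignment.codes[order[tree.labels[c]], s]
                    if obs == MISSING_CODE:
                        w *= 1.0  # sum over child states of a stochastic row
                    else:
                        w *= P[c][pa, obs]
                else:
                    w *= P[c][pa, assign[:, pos[c]]]
            site_lik_k[k] = w.sum()
            for nid in internal:
                site_post_k[nid][k] = np.bincount(
                    assign[:, pos[nid]], weights=w, minlength=N_STATES
                )
        site_lik = site_lik_k.mean()
        total_log += np.log(site_lik)
        for nid in internal:
            posts[nid][s] = site_post_k[nid].sum(axis=0) / K / site_lik
    return float(total_log), posts


def random_instance(
    seed: int,
    n_leaves: int,
    n_sites: int,
    n_categories: int,
    max_branch: float = 2.0,
    gap_fraction: float = 0.1,
) -> tuple[PhyloTree, SubstitutionModel, ProteinAlignment]:
    """Random small tree, LG+G model, and random leaf alignment (with gaps)."""
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_leaves, 1.0, seed)
    lengths = rng.uniform(0.0, max_branch, size=tree.n_nodes)
    lengths[tree.root] = 0.0
    tree = PhyloTree(tree.parent, lengths, tree.labels)
    model = get_model(
        "LG",
        gamma_shape=float(rng.uniform(0.3, 2.0)),
        n_categories=n_categories,
    )
    chars = list(AMINO_ACIDS)
    rows = []
    for _ in range(n_leaves):
        row = [
            "-" if rng.random() < gap_fraction else chars[int(rng.integers(20))]
            for _ in range(n_sites)
        ]
        rows.append("".join(row))
    aln = ProteinAlignment([tree.labels[k] for k in tree.leaf_ids], rows)
    return tree, model, aln


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def lg_model():
    return get_model("LG", gamma_shape=1.0, n_categories=4)


@pytest.fixture(scope="session")
def poisson_model():
    return get_model("POISSON", gamma_shape=None)


@pytest.fixture(scope="session")
def small_simulation(lg_model):
    """16-taxon LG+G simulation with recorded truth, reused across tests."""
    from ancseq.synthetic import simulate_evolution

    tree = simulate_tree(16, 0.8, seed=42)
    truth = simulate_evolution(tree, lg_model, 300, seed=43)
    return truth
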