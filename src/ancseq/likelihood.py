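"""Felsenstein pruning likelihood under a discrete-gamma rate mixture.

The engine computes, for every node and rate category, the conditional
("inside") likelihoods of the data below the node and — on demand — the
complementary "outside" quantities needed for marginal ancestral posteriors.
Identical site patterns are compressed and weighted; underflow is controlled
by per-node max-rescaling with the log scalers accumulated into the
returned log-likelihood.  Gaps ('-') and unknowns ('X') enter as all-ones
partial vectors, the standard missing-data treatment.

Branch lengths are fixed throughout (the tree is an input, not a free
parameter); only the gamma shape can be fitted, by bounded 1-D maximum
likelihood (:func:`estimate_alpha`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import ProteinAlignment
from .alphabet import MISSING_CODE, N_STATES
from .substitution import SubstitutionModel
from .tree import PhyloTree

__all__ = ["PruningEngine", "SiteLikelihoods", "total_log_likelihood", "estimate_alpha", "AlphaFit"]


@dataclass
class SiteLikelihoods:
    """Per-site, per-category log-likelihoods (uncompressed, length L)."""

    log_total: float
    site_log_likelihood: np.ndarray  # (L,) mixture log-likelihood per site
    category_log_likelihood: np.ndarray  # (K, L)
    category_weights: np.ndarray  # (K, L) empirical-Bayes posterior of category


class PruningEngine:
    """Likelihood and posterior machinery bound to one (tree, model, alignment)."""

    def __init__(
        self, tree: PhyloTree, model: SubstitutionModel, alignment: ProteinAlignment
    ) -> None:
        tree_leaves = set(tree.leaf_labels)
        aln_ids = set(alignment.ids)
        if tree_leaves != aln_ids:
            only_t = sorted(tree_leaves - aln_ids)[:5]
            only_a = sorted(aln_ids - tree_leaves)[:5]
            raise ValueError(
                f"tree/alignment label mismatch (tree-only: {only_t}, "
                f"alignment-only: {only_a})"
            )
        self.tree = tree
        self.model = model
        self.alignment = alignment
        self.K = model.n_categories

        # site-pattern compression: unique columns with multiplicities
        cols = alignment.codes.T  # (L, n_seq)
        patterns, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (npat, n_seq)
        self.pattern_of_site = inverse.ravel()
        self.pattern_weights = counts.astype(float)
        self.n_patterns = patterns.shape[0]

        order = {sid: j for j, sid in enumerate(alignment.ids)}
        self._leaf_col = {
            k: order[tree.labels[k]] for k in tree.leaf_ids
        }  # node id -> column in pattern rows

        # per-node, per-category transition matrices (branch above the node)
        self.P = np.zeros((tree.n_nodes, self.K, N_STATES, N_STATES))
        for k in range(tree.n_nodes - 1):
            self.P[k] = self.model.category_transition_matrices(float(tree.lengths[k]))

        self._down = None  # lazy caches
        self._down_scaler = None
        self._up = None

    # ------------------------------------------------------------ down pass
    def _leaf_partial(self, node: int) -> np.ndarray:
        """Indicator partials for one leaf, shape (npat, 20)."""
        states = self.patterns[:, self._leaf_col[node]]
        out = np.zeros((self.n_patterns, N_STATES))
        obs = states != MISSING_CODE
        out[np.arange(self.n_patterns)[obs], states[obs]] = 1.0
        out[~obs] = 1.0
        return out

    def down_pass(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Inside likelihoods per node: arrays (K, npat, 20) plus log scalers
        (K, npat) accumulated from the node's subtree."""
        if self._down is not None:
            return self._down, self._down_scaler
        n = self.tree.n_nodes
        down: list[np.ndarray | None] = [None] * n
        scaler: list[np.ndarray | None] = [None] * n
        for k in range(n):  # post-order by construction
            if self.tree.is_leaf(k):
                leaf = self._leaf_partial(k)
                down[k] = np.broadcast_to(leaf, (self.K, self.n_patterns, N_STATES)).copy()
                scaler[k] = np.zeros((self.K, self.n_patterns))
            else:
                part = np.ones((self.K, self.n_patterns, N_STATES))
                sc = np.zeros((self.K, self.n_patterns))
                for c in self.tree.children[k]:
                    part *= self._message_up(c, down[c])
                    sc += scaler[c]
                m = part.max(axis=2)
                safe = np.where(m > 0, m, 1.0)
                part /= safe[:, :, None]
                with np.errstate(divide="ignore"):
                    sc += np.where(m > 0, np.log(safe), -np.inf)
                down[k] = part
                scaler[k] = sc
        self._down = down
        self._down_scaler = scaler
        return down, scaler

    def _message_up(self, child: int, child_partial: np.ndarray) -> np.ndarray:
        """M[k, p, a] = sum_b P_child[k, a, b] * child_partial[k, p, b]."""
        return np.einsum("kab,kpb->kpa", self.P[child], child_partial, optimize=True)

    # --------------------------------------------------------- likelihoods
    def category_log_likelihood_patterns(self) -> np.ndarray:
        """log L_k per (K, npat) at the root, scalers folded in."""
        down, scaler = self.down_pass()
        root = self.tree.root
        pi = self.model.frequencies
        lik = down[root] @ pi  # (K, npat)
        with np.errstate(divide="ignore"):
            return np.log(lik) + scaler[root]

    def site_likelihoods(self) -> SiteLikelihoods:
        cat_pat = self.category_log_likelihood_patterns()  # (K, npat)
        logw = -np.log(self.K)
        site_pat = logsumexp(cat_pat + logw, axis=0)  # (npat,)
        total = float(self.pattern_weights @ site_pat)
        with np.errstate(invalid="ignore"):
            weights_pat = np.exp(cat_pat + logw - site_pat[None, :])
        weights_pat = np.nan_to_num(weights_pat, nan=1.0 / self.K)
        idx = self.pattern_of_site
        return SiteLikelihoods(
            log_total=total,
            site_log_likelihood=site_pat[idx],
            category_log_likelihood=cat_pat[:, idx],
            category_weights=weights_pat[:, idx],
        )

    def log_likelihood(self) -> float:
        return self.site_likelihoods().log_total

    # ------------------------------------------------------------- up pass
    def up_pass(self) -> list[np.ndarray]:
        """Outside arrays O[node] of shape (K, npat, 20): the (rescaled)
        likelihood of all data *not* below the node, joint with the root
        prior, as a function of the node's state.  Scale factors cancel in
        posteriors and are not tracked."""
        if self._up is not None:
            return self._up
        down, _ = self.down_pass()
        n = self.tree.n_nodes
        up: list[np.ndarray | None] = [None] * n
        pi = self.model.frequencies
        up[self.tree.root] = np.broadcast_to(
            pi, (self.K, self.n_patterns, N_STATES)
        ).copy()
        for v in range(n - 1, -1, -1):  # pre-order (reverse post-order)
            kids = self.tree.children[v]
            if not kids:
                continue
            msgs = [self._message_up(c, down[c]) for c in kids]
            # prefix/suffix products so each child sees its siblings only
            m = len(kids)
            prefix = [None] * (m + 1)
            prefix[0] = up[v]
            for i in range(m):
                prefix[i + 1] = prefix[i] * msgs[i]
            suffix = np.ones_like(up[v])
            for i in range(m - 1, -1, -1):
                outer = prefix[i] * suffix  # (K, npat, 20) at parent states
                c = kids[i]
                o = np.einsum("kba,kpb->kpa", self.P[c], outer, optimize=True)
                mx = o.max(axis=2)
                o /= np.where(mx > 0, mx, 1.0)[:, :, None]
                up[c] = o
                suffix = suffix * msgs[i]
        self._up = up
        return up

    def node_posteriors_patterns(self, node: int) -> np.ndarray:
        """Marginal posterior over states at *node*, per pattern (npat, 20),
        integrated over rate categories with empirical-Bayes weights."""
        if self.tree.is_leaf(node):
            states = self.patterns[:, self._leaf_col[node]]
            post = np.zeros((self.n_patterns, N_STATES))
            obs = states != MISSING_CODE
            post[np.arange(self.n_patterns)[obs], states[obs]] = 1.0
            post[~obs] = 1.0 / N_STATES
            return post
        down, _ = self.down_pass()
        up = self.up_pass()
        joint = down[node] * up[node]  # (K, npat, 20), arbitrary scale per (k,p)
        norm = joint.sum(axis=2, keepdims=True)
        post_k = joint / np.where(norm > 0, norm, 1.0)
        cat_pat = self.category_log_likelihood_patterns()
        logw = cat_pat - logsumexp(cat_pat, axis=0, keepdims=True)
        w = np.exp(logw)  # (K, npat)
        return np.einsum("kp,kpa->pa", w, post_k, optimize=True)

    def expand_to_sites(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern array (npat, ...) back to site order (L, ...)."""
        return per_pattern[self.pattern_of_site]


def total_log_likelihood(
    tree: PhyloTree, model: SubstitutionModel, alignment: ProteinAlignment
) -> tuple[float, SiteLikelihoods]:
    """Mixture log-likelihood of the alignment on the fixed tree.

    Returns the total and the per-site per-category breakdown (the latter
    also carries the empirical-Bayes category weights used for posterior
    mean site rates).
    """
    engine = PruningEngine(tree, model, alignment)
    sl = engine.site_likelihoods()
    return sl.log_total, sl


@dataclass
class AlphaFit:
    """Result of 1-D maximum-likelihood estimation of the gamma shape."""

    alpha: float
    log_likelihood: float
    at_bound: bool
    bounds: tuple[float, float]
    n_evaluations: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        flag = " (AT BOUND)" if self.at_bound else ""
        return f"<AlphaFit alpha={self.alpha:.4f} logL={self.log_likelihood:.3f}{flag}>"


def estimate_alpha(
    tree: PhyloTree,
    model: SubstitutionModel,
    alignment: ProteinAlignment,
    bounds: tuple[float, float] = (0.05, 50.0),
    xatol: float = 1e-4,
) -> AlphaFit:
    """Fit the gamma shape alpha on a fixed tree by bounded 1-D optimization.

    All other model components (exchangeabilities, frequencies, K, branch
    lengths) are held fixed.  A fit landing on a bound is returned flagged
    (with a warning): typically an alignment without rate signal drives
    alpha to the upper bound.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError(f"bounds must satisfy 0 < lo < hi, got {bounds}")
    n_eval = 0

    def neg_loglik(alpha: float) -> float:
        nonlocal n_eval
        n_eval += 1
        m = model.with_gamma(float(alpha))
        return -PruningEngine(tree, m, alignment).log_likelihood()

    res = minimize_scalar(
        neg_loglik, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    alpha_hat = float(res.x)
    at_bound = (alpha_hat - lo) < 10 * xatol or (hi - alpha_hat) < 10 * xatol * hi
    if at_bound:
        warnings.warn(
            f"alpha estimate {alpha_hat:.4g} lies at the search bound {bounds}",
            stacklevel=2,
        )
    return AlphaFit(
        alpha=alpha_hat,
        log_likelihood=-float(res.fun),
        at_bound=at_bound,
        bounds=(lo, hi),
        n_evaluations=n_eval,
    )
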