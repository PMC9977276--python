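"""Empirical-Bayes marginal ancestral sequence reconstruction.

For each internal node and alignment site the posterior distribution over
the 20 amino acids is computed by combining inside (subtree) and outside
(rest-of-tree plus root prior) likelihoods, integrating over the discrete
gamma rate categories with per-site empirical-Bayes weights
``w_k(s) ∝ (1/K) L_k(s)``.  The reconstruction reported is marginal: each
site is summarized independently; no joint ancestral path is inferred.

Ancestral gap presence is decided separately by Fitch small parsimony on
the binary gap/residue character (ambiguities resolved toward residue),
and the mask is applied after residue reconstruction — the likelihood
machinery itself always treats gaps as missing data.

Everything here is deterministic; no random numbers are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import ProteinAlignment
from .alphabet import AMINO_ACIDS, MISSING_CODE, N_STATES
from .likelihood import AlphaFit, PruningEngine, estimate_alpha
from .substitution import SubstitutionModel, empirical_frequencies
from .tree import PhyloTree

__all__ = [
    "AncestralReconstruction",
    "marginal_posteriors",
    "extract_map_ancestor",
    "infer_gap_mask",
    "infer_gap_masks_all",
    "AncestralReconstructionModel",
    "AncestralReconstructionResults",
]

# state indices in alphabetical order of the one-letter code (tie-breaking)
_ALPHA_ORDER = np.argsort(list(AMINO_ACIDS), kind="stable")


@dataclass
class AncestralReconstruction:
    """Per-site posterior summary of one ancestral node.

    ``map_sequence`` carries the most-probable residue at every site, with
    '-' at gap-masked sites; ``mean_pp`` averages the per-site MAP posterior
    over non-gap sites only.
    """

    node_id: int
    posteriors: np.ndarray  # (L, 20)
    map_sequence: str
    site_pp: np.ndarray  # (L,)
    mean_pp: float
    gap_mask: np.ndarray  # (L,) bool
    tie_mask: np.ndarray  # (L,) bool, exact posterior ties at the max

    @property
    def length(self) -> int:
        return len(self.map_sequence)

    @property
    def ungapped_sequence(self) -> str:
        return self.map_sequence.replace("-", "")

    @property
    def n_tied_sites(self) -> int:
        return int(self.tie_mask.sum())

    def to_frame(self) -> pd.DataFrame:
        """Posterior table: site (1-based), 20 residue columns, MAP, pp, gap."""
        df = pd.DataFrame(self.posteriors, columns=list(AMINO_ACIDS))
        df.insert(0, "site", np.arange(1, self.length + 1))
        df["map_residue"] = list(self.map_sequence)
        df["pp"] = self.site_pp
        df["gap"] = self.gap_mask
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def marginal_posteriors(
    tree: PhyloTree,
    model: SubstitutionModel,
    alignment: ProteinAlignment,
    node_id: int,
) -> np.ndarray:
    """L x 20 marginal posterior state probabilities at one node.

    Querying a leaf returns its degenerate distribution (delta on the
    observed residue; uniform over the 20 states at '-'/'X').
    """
    engine = PruningEngine(tree, model, alignment)
    return engine.expand_to_sites(engine.node_posteriors_patterns(node_id))


def extract_map_ancestor(
    posteriors: np.ndarray,
    gap_mask: np.ndarray | None = None,
    node_id: int = -1,
) -> AncestralReconstruction:
    """Most-probable-residue ancestor from a posterior matrix.

    Exact ties at the maximum are broken alphabetically by one-letter code
    and flagged per site.  Gap-masked sites emit '-' and are excluded from
    ``mean_pp``.
    """
    post = np.asarray(posteriors, dtype=float)
    if post.ndim != 2 or post.shape[1] != N_STATES:
        raise ValueError(f"posterior matrix must be L x 20, got {post.shape}")
    row_sums = post.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(row_sums - 1.0)))
        raise ValueError(f"posterior row {bad} sums to {row_sums[bad]!r}")
    L = post.shape[0]
    if gap_mask is None:
        gap_mask = np.zeros(L, dtype=bool)
    gap_mask = np.asarray(gap_mask, dtype=bool)
    if gap_mask.shape != (L,):
        raise ValueError("gap mask length mismatch")

    alph = post[:, _ALPHA_ORDER]  # argmax picks the alphabetically first max
    j = np.argmax(alph, axis=1)
    states = _ALPHA_ORDER[j]
    site_pp = post[np.arange(L), states]
    tie_mask = (post == site_pp[:, None]).sum(axis=1) > 1
    residues = np.array(list(AMINO_ACIDS))[states]
    residues[gap_mask] = "-"
    non_gap = ~gap_mask
    mean_pp = float(site_pp[non_gap].mean()) if non_gap.any() else float("nan")
    return AncestralReconstruction(
        node_id=node_id,
        posteriors=post,
        map_sequence="".join(residues),
        site_pp=site_pp,
        mean_pp=mean_pp,
        gap_mask=gap_mask,
        tie_mask=tie_mask,
    )


def infer_gap_masks_all(tree: PhyloTree, alignment: ProteinAlignment) -> np.ndarray:
    """Fitch small-parsimony gap/residue states for every node.

    Returns a boolean (n_nodes, L) array, True where the node is inferred
    gapped.  State sets are bitmasks (1 = residue, 2 = gap); ambiguities at
    the root and in the top-down resolution resolve toward residue.
    """
    order = {sid: j for j, sid in enumerate(alignment.ids)}
    n, L = tree.n_nodes, alignment.length
    sets = np.zeros((n, L), dtype=np.uint8)
    for k in tree.leaf_ids:
        gapped = alignment.codes[order[tree.labels[k]]] == MISSING_CODE
        is_gap_char = np.frombuffer(
            alignment.rows[order[tree.labels[k]]].encode(), dtype=np.uint8
        ) == ord("-")
        # 'X' is an unknown residue, not a gap
        sets[k] = np.where(gapped & is_gap_char, 2, 1)
    for k in tree.internal_ids:  # post-order
        inter = np.full(L, 3, dtype=np.uint8)
        union = np.zeros(L, dtype=np.uint8)
        for c in tree.children[k]:
            inter &= sets[c]
            union |= sets[c]
        sets[k] = np.where(inter != 0, inter, union)
    # top-down resolution
    final = np.zeros((n, L), dtype=np.uint8)
    root = tree.root
    final[root] = np.where(sets[root] == 2, 2, 1)  # ambiguous -> residue
    for v in range(n - 1, -1, -1):  # pre-order
        for c in tree.children[v]:
            inherits = (sets[c] & final[v]) != 0
            own = np.where(sets[c] == 2, 2, 1)  # ambiguous -> residue
            final[c] = np.where(inherits, final[v], own)
    return final == 2


def infer_gap_mask(tree: PhyloTree, alignment: ProteinAlignment, node_id: int) -> np.ndarray:
    """Length-L boolean gap mask at one node (see :func:`infer_gap_masks_all`)."""
    return infer_gap_masks_all(tree, alignment)[node_id]


# --------------------------------------------------------------------------
# Model / Results interface
# --------------------------------------------------------------------------


class AncestralReconstructionModel:
    """Marginal ASR on a fixed rooted tree.

    Parameters
    ----------
    alignment
        The leaf alignment (ids must match the tree's leaf labels).
    tree
        Rooted phylogeny with branch lengths in substitutions/site.
    substitution_model
        A :class:`SubstitutionModel`; when ``use_empirical_frequencies`` is
        true its frequencies are replaced by alignment counts ("+F").
    use_empirical_frequencies
        Apply "+F" frequencies counted from the alignment (default True).
    pseudocount
        Pseudocount for "+F" counting (default 0.5, so rare residues never
        produce an invalid zero frequency).

    Examples
    --------
    >>> model = AncestralReconstructionModel(aln, tree, get_model("LG"))
    >>> res = model.fit()                      # fits the gamma shape
    >>> anc = res.reconstruct(res.tree.root)   # AncestralReconstruction
    """

    def __init__(
        self,
        alignment: ProteinAlignment,
        tree: PhyloTree,
        substitution_model: SubstitutionModel,
        use_empirical_frequencies: bool = True,
        pseudocount: float = 0.5,
    ) -> None:
        self.alignment = alignment
        self.tree = tree
        if use_empirical_frequencies:
            pi = empirical_frequencies(alignment, pseudocount=pseudocount)
            substitution_model = substitution_model.with_frequencies(pi)
        self.substitution_model = substitution_model

    def loglike(self, alpha: float | None = None) -> float:
        m = (
            self.substitution_model
            if alpha is None
            else self.substitution_model.with_gamma(alpha)
        )
        return PruningEngine(self.tree, m, self.alignment).log_likelihood()

    def fit(
        self,
        fit_alpha: bool = True,
        alpha_bounds: tuple[float, float] = (0.05, 50.0),
    ) -> "AncestralReconstructionResults":
        """Fit the gamma shape (optional) and prepare posterior machinery."""
        alpha_fit: AlphaFit | None = None
        model = self.substitution_model
        if fit_alpha and model.gamma_shape is not None:
            alpha_fit = estimate_alpha(self.tree, model, self.alignment, bounds=alpha_bounds)
            model = model.with_gamma(alpha_fit.alpha)
        engine = PruningEngine(self.tree, model, self.alignment)
        return AncestralReconstructionResults(self, model, engine, alpha_fit)


class AncestralReconstructionResults:
    """Fitted ASR: per-node posteriors, MAP ancestors, diagnostics."""

    def __init__(
        self,
        model: AncestralReconstructionModel,
        substitution_model: SubstitutionModel,
        engine: PruningEngine,
        alpha_fit: AlphaFit | None,
    ) -> None:
        self.model = model
        self.substitution_model = substitution_model
        self.engine = engine
        self.alpha_fit = alpha_fit
        self.tree = model.tree
        self.alignment = model.alignment
        self._site_lik = engine.site_likelihoods()
        self._gap_masks: np.ndarray | None = None

    @property
    def alpha(self) -> float | None:
        return self.substitution_model.gamma_shape

    @property
    def log_likelihood(self) -> float:
        return self._site_lik.log_total

    @property
    def site_rates(self) -> np.ndarray:
        """Posterior-mean relative rate per site (empirical Bayes)."""
        w = self._site_lik.category_weights  # (K, L)
        return w.T @ self.substitution_model.gamma_rates.rates

    def posteriors(self, node_id: int) -> np.ndarray:
        return self.engine.expand_to_sites(self.engine.node_posteriors_patterns(node_id))

    def gap_mask(self, node_id: int) -> np.ndarray:
        if self._gap_masks is None:
            self._gap_masks = infer_gap_masks_all(self.tree, self.alignment)
        return self._gap_masks[node_id]

    def reconstruct(self, node_id: int) -> AncestralReconstruction:
        """MAP ancestor with posterior summaries and parsimony gap mask."""
        return extract_map_ancestor(
            self.posteriors(node_id), self.gap_mask(node_id), node_id=node_id
        )

    def summary(self, node_ids: list[int] | None = None) -> pd.DataFrame:
        """Per-node table: descendant count, mean PP, tied sites, gaps."""
        if node_ids is None:
            node_ids = self.tree.internal_ids
        rows = []
        for nid in node_ids:
            rec = self.reconstruct(nid)
            rows.append(
                {
                    "node": nid,
                    "n_descendants": len(self.tree.leaf_set(nid)),
                    "mean_pp": rec.mean_pp,
                    "n_tied_sites": rec.n_tied_sites,
                    "n_gap_sites": int(rec.gap_mask.sum()),
                }
            )
        return pd.DataFrame(rows)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        a = f", alpha={self.alpha:.3f}" if self.alpha else ""
        return (
            f"<AncestralReconstructionResults logL={self.log_likelihood:.2f}{a}, "
            f"{self.tree.n_leaves} leaves>"
        )
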