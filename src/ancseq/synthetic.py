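"""Ground-truth generators for validating the reconstruction pipeline.

The real study inputs (hundreds of nitrogenase and outgroup protein
sequences with their maximum-likelihood tree) live in an external
repository, so validation here rests on synthetic data with recorded
truth: Yule trees, alignments evolved under the same reversible
gamma-mixture model the inference uses (with every internal-node sequence
and per-site rate category kept), replicate logistic growth curves with
Gaussian noise, and paired reference/ancestor codon-design cases.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .alignment import ProteinAlignment
from .alphabet import AMINO_ACIDS, MISSING_CODE, N_STATES, decode
from .phenotype import GrowthCurveData, logistic
from .resurrection import CodonUsageTable
from .substitution import SubstitutionModel
from .tree import PhyloTree

__all__ = [
    "simulate_tree",
    "SimulationTruth",
    "simulate_evolution",
    "simulate_growth_curves",
    "simulate_codon_case",
    "CodonCase",
]


def simulate_tree(n_taxa: int, depth: float, seed: int) -> PhyloTree:
    """Yule (pure-birth) rooted binary tree, rescaled so the mean
    root-to-tip path length equals *depth* substitutions/site."""
    if n_taxa < 2:
        raise ValueError(f"need >= 2 taxa, got {n_taxa}")
    if not depth > 0:
        raise ValueError(f"depth must be positive, got {depth}")
    rng = random.Random(int(seed))
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_taxa)])
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=taxa,
        rng=rng,
    )
    tree = PhyloTree.from_dendropy(dtree)
    mean_depth = float(np.mean([tree.depth(k) for k in tree.leaf_ids]))
    if mean_depth <= 0:
        # degenerate star-ish draw: fall back to uniform unit branches
        tree = PhyloTree(tree.parent, np.ones(tree.n_nodes), tree.labels)
        mean_depth = float(np.mean([tree.depth(k) for k in tree.leaf_ids]))
    return tree.scaled(depth / mean_depth)


@dataclass
class SimulationTruth:
    """Full record of one sequence-evolution simulation.

    ``states`` holds the true sequence (integer codes) at *every* node,
    including internals; ``site_categories`` the gamma category drawn once
    per site and shared across the whole tree; the leaf rows of ``states``
    (with gap blocks applied) equal the emitted alignment.
    """

    tree: PhyloTree
    model: SubstitutionModel
    alignment: ProteinAlignment
    states: np.ndarray  # (n_nodes, L) integer codes
    site_categories: np.ndarray  # (L,) in [0, K)
    seed: int

    def true_sequence(self, node_id: int) -> str:
        return decode(self.states[node_id])

    def truth_frame(self) -> pd.DataFrame:
        """Tidy truth table: node, site (1-based), state, category."""
        n, L = self.states.shape
        node = np.repeat(np.arange(n), L)
        site = np.tile(np.arange(1, L + 1), n)
        return pd.DataFrame(
            {
                "node": node,
                "site": site,
                "state": [decode(np.array([s]))[0] if s != MISSING_CODE else "-"
                          for s in self.states.ravel()],
                "category": np.tile(self.site_categories, n),
            }
        )


def _sample_rows(P: np.ndarray, parent_states: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Sample child states: row parent_states[i] of P, inverse-CDF with u[i]."""
    cdf = np.cumsum(P[parent_states], axis=1)
    cdf[:, -1] = 1.0
    return (u[:, None] > cdf).sum(axis=1)


def simulate_evolution(
    tree: PhyloTree,
    model: SubstitutionModel,
    L: int,
    seed: int,
    gap_block_rate: float | None = None,
) -> SimulationTruth:
    """Evolve an alignment of length *L* down the tree under the model.

    The root sequence is drawn from the equilibrium frequencies; each site
    draws one gamma category which is fixed across the whole tree; descent
    samples from the per-branch, per-category transition matrices.  With
    ``gap_block_rate`` set, contiguous gap blocks are painted onto random
    leaf clades (Poisson(gap_block_rate) blocks, geometric lengths) to
    exercise gap masking; gaps affect only the emitted alignment, never the
    recorded true states.
    """
    rng = np.random.default_rng(int(seed))
    K = model.n_categories
    cats = rng.integers(0, K, size=L)
    states = np.zeros((tree.n_nodes, L), dtype=np.int64)
    states[tree.root] = rng.choice(N_STATES, size=L, p=model.frequencies)
    for v in range(tree.n_nodes - 1, -1, -1):  # pre-order
        for c in tree.children[v]:
            P = model.category_transition_matrices(float(tree.lengths[c]))
            child = np.empty(L, dtype=np.int64)
            u = rng.random(L)
            for k in range(K):
                mask = cats == k
                if mask.any():
                    child[mask] = _sample_rows(P[k], states[v][mask], u[mask])
            states[c] = child

    leaf_codes = {k: states[k].copy() for k in tree.leaf_ids}
    if gap_block_rate:
        n_blocks = rng.poisson(gap_block_rate)
        internal = [k for k in tree.internal_ids if k != tree.root]
        for _ in range(int(n_blocks)):
            clade = int(rng.choice(internal)) if internal else tree.root
            members = tree.leaf_set(clade)
            start = int(rng.integers(0, L))
            length = 1 + int(rng.geometric(0.1))
            stop = min(L, start + length)
            for k in tree.leaf_ids:
                if tree.labels[k] in members:
                    leaf_codes[k][start:stop] = MISSING_CODE
    ids = [tree.labels[k] for k in tree.leaf_ids]
    rows = [decode(leaf_codes[k]) for k in tree.leaf_ids]
    alignment = ProteinAlignment(ids, rows)
    return SimulationTruth(tree, model, alignment, states, cats, int(seed))


def simulate_growth_curves(
    strain_params: dict[str, tuple[float, float, float]],
    noise_sd: float,
    n_replicates: int,
    seed: int,
    times: np.ndarray | None = None,
    param_jitter: float = 0.0,
) -> list[GrowthCurveData]:
    """Replicate logistic OD600 series with iid Gaussian noise.

    ``strain_params`` maps strain name to (K, r, N0); observations are
    truncated at zero.  ``param_jitter`` optionally multiplies each
    replicate's parameters by lognormal noise of that sd.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be nonnegative")
    rng = np.random.default_rng(int(seed))
    if times is None:
        times = np.arange(0.0, 49.0, 1.0)  # hourly over 48 h
    times = np.asarray(times, dtype=float)
    curves = []
    for strain in sorted(strain_params):
        K, r, N0 = strain_params[strain]
        if not (K > N0 > 0 and r > 0):
            raise ValueError(f"invalid logistic parameters for {strain!r}")
        for rep in range(1, n_replicates + 1):
            Kr, rr, N0r = K, r, N0
            if param_jitter > 0:
                Kr, rr, N0r = (
                    v * float(np.exp(rng.normal(0.0, param_jitter)))
                    for v in (K, r, N0)
                )
            y = logistic(times, Kr, rr, N0r) + rng.normal(0.0, noise_sd, size=times.size)
            curves.append(GrowthCurveData(strain, rep, times, np.maximum(y, 0.0)))
    return curves


@dataclass
class CodonCase:
    """Paired reference/ancestor design case with known differing sites."""

    reference_protein: str
    reference_cds: str
    ancestral_protein: str
    differing_sites: list[int]  # 0-based positions where the two differ
    seed: int


def simulate_codon_case(
    protein_length: int,
    divergence_fraction: float,
    usage: CodonUsageTable,
    seed: int,
) -> CodonCase:
    """Reference CDS drawn codon-by-codon from usage; ancestor differing at
    exactly ``round(fraction * length)`` uniformly chosen positions."""
    if not 0.0 <= divergence_fraction <= 1.0:
        raise ValueError("divergence fraction must lie in [0, 1]")
    rng = np.random.default_rng(int(seed))
    aas = list(AMINO_ACIDS)
    ref_protein = "".join(rng.choice(aas, size=protein_length))
    ref_cds = "".join(usage.sample_codon(aa, rng) for aa in ref_protein)
    n_diff = round(divergence_fraction * protein_length)
    sites = sorted(rng.choice(protein_length, size=n_diff, replace=False).tolist())
    anc = list(ref_protein)
    for s in sites:
        choices = [a for a in aas if a != anc[s]]
        anc[s] = choices[int(rng.integers(len(choices)))]
    return CodonCase(
        reference_protein=ref_protein,
        reference_cds=ref_cds,
        ancestral_protein="".join(anc),
        differing_sites=sites,
        seed=int(seed),
    )
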