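# ancseq

Marginal ancestral protein reconstruction, resurrection-ready gene design,
and diazotrophic phenotype quantification.

`ancseq` implements the computational side of an ancestral-enzyme
"resurrection" study, built around nitrogenase (NifHDK) but generic over
any protein family: given a fixed rooted phylogeny with branch lengths and
a protein alignment, it reconstructs ancestral sequences at internal nodes,
designs synthesizable genes for those ancestors that stay maximally close
to a wild-type coding sequence, grades per-site conservation from
evolutionary rates, and quantifies the organism-level measurements
(growth curves, acetylene-reduction assays, H₂/N₂ efficiency ratios) used
to compare resurrected strains against wild type.

It is aimed at molecular-evolution and synthetic-biology practitioners who
already have an alignment and tree (from MAFFT/RAxML/IQ-TREE or similar)
and need the downstream reconstruction-to-design-to-phenotype pipeline in
one auditable, seedable place.

## The model

Sequence evolution is the standard reversible amino-acid CTMC with
among-site rate variation (LG+G+F by default):

- rate matrix `Q_ij = S_ij π_j` (i≠j) from symmetric exchangeabilities `S`
  (bundled LG values) and equilibrium frequencies `π` counted from the
  alignment ("+F"), normalized so `−Σ_i π_i Q_ii = 1` (branch lengths in
  expected substitutions/site);
- discrete-gamma rate heterogeneity: K equal-weight categories with rates
  equal to the conditional means of a unit-mean gamma(α, α) distribution
  ("+G"); α is fitted on the fixed tree by bounded 1-D maximum likelihood;
- likelihoods by Felsenstein pruning with site-pattern compression and
  per-node rescaling; gaps and `X` enter as missing data.

Ancestral states are **marginal, empirical-Bayes** posteriors: at node *v*
and site *s*,

    P(state = a | data) = Σ_k w_k(s) · P_k(a | data),    w_k(s) ∝ L_k(s)/K,

computed from inside/outside messages, with the MAP residue taken per site
(alphabetical tie-break, ties flagged) and ancestral gap presence decided
separately by Fitch parsimony on the gap/residue character. Gene design
follows the semi-randomized codon strategy: sites where ancestor and wild
type agree copy the wild-type codon verbatim; differing or inserted sites
draw a synonymous codon weighted by host codon usage, so nucleotide
identity to the wild-type gene is maximal subject to encoding the ancestor.
Growth curves are fitted to the logistic model `N(t) = K/(1+((K−N0)/N0)e^{−rt})`
(doubling time `ln2/r`, midpoint `t_mid`); assay groups are compared by
one-way ANOVA with post-hoc Tukey HSD.

## Worked example

Simulate a 16-taxon study with known ancestral truth, then reconstruct the
root ancestor:

```bash
ancseq simulate --n-taxa 16 --depth 0.6 --sites 200 --seed 11 --outdir demo
ancseq asr --alignment demo/alignment.fasta --tree demo/tree.nwk \
           --out demo/root_posteriors.tsv
# node 30: mean PP 0.8414 over 200 non-gap sites (alpha=0.9395, logL=-3422.62)
```

or from Python:

```python
import numpy as np
from ancseq import AncestralReconstructionModel, get_model
from ancseq.synthetic import simulate_tree, simulate_evolution

model = get_model("LG", gamma_shape=1.0)
tree = simulate_tree(16, 0.6, seed=11)
truth = simulate_evolution(tree, model, 200, seed=12)

res = AncestralReconstructionModel(truth.alignment, tree, model).fit()
rec = res.reconstruct(tree.root)
print(res.alpha, res.log_likelihood)   # 0.9395 -3422.62
print(rec.mean_pp)                     # 0.8414
true_seq = truth.true_sequence(tree.root)
print(np.mean([a == b for a, b in zip(rec.map_sequence, true_seq)]))  # 0.855
```

The fitted shape (0.94) recovers the generating α = 1; the root ancestor is
called with mean posterior probability 0.84 and, because the truth is
recorded, we can see that 85.5% of MAP residues are exactly right — and
that the per-site posteriors are honest about the rest (see the calibration
test). On shallower trees both numbers rise toward 1.

The full pipeline (`ancseq run --config config.yaml`) chains outgroup
rooting, α fitting, per-node reconstruction, identity matrices,
substitution maps in wild-type numbering (`I355V`-style labels),
conservation calls (grade > 7 on the 1–9 rate-percentile scale), and
seeded codon-optimized gene FASTAs, with a JSON report carrying input
checksums and every seed.

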