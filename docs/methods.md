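# Methods

This note documents the models, algorithms, defaults, and design choices
behind `ancseq`, in the order data flows through the package.

## Substitution model

Evolution is modeled as a reversible continuous-time Markov chain on the
20 amino acids. The instantaneous rate matrix is assembled as
`Q_ij = S_ij π_j` (i ≠ j) from a symmetric exchangeability matrix `S` and
equilibrium frequencies `π`, with the diagonal closing rows to zero and a
global rescaling enforcing `−Σ_i π_i Q_ii = 1`, so branch lengths are in
expected substitutions per site at stationarity. Two named matrices ship
with the package: `LG` (the published Le–Gascuel matrix, bundled in PAML
`.dat` layout under `src/ancseq/data/lg.dat` with provenance in its
header) and `POISSON` (all-equal exchangeabilities, mainly for closed-form
tests). User matrices in PAML lower-triangle format are accepted.

"+F" frequencies are counted from the alignment with gaps/`X` excluded.
A zero observed frequency would break the reversibility scaling, so the
default pseudocount-free counting *rejects* alignments missing a residue;
the model constructor used by the reconstruction pipeline defaults to a
pseudocount of 0.5, which keeps rare residues strictly positive without
noticeably distorting abundant ones.

Transition matrices `P(t) = exp(Qrt)` are computed through the symmetric
similarity transform `B = D^{1/2} Q D^{−1/2}` (`D = diag(π)`): `B` is
symmetric for a reversible `Q`, so one `eigh` eigendecomposition serves
every branch length and rate category, which is both numerically stable
and cheap to reuse. Entries are clipped to [0, 1] to absorb ±1e−16
round-off; detailed balance holds to ~1e−14 in practice.

### Discrete-gamma rates

Among-site rate variation uses the K-category discrete approximation of a
unit-mean gamma(α, α) distribution with equal category weights. Category
rates are the **conditional means** within the K quantile intervals
(computed from the regularized incomplete gamma with shape α+1), not the
medians: mean-of-category preserves the unit mean exactly, which the code
additionally renormalizes to absorb floating-point drift. Default K = 4,
the convention of the standard reconstruction tools; K is configurable.
As K → ∞ the discrete second moment converges to the continuous 1 + 1/α
(checked at K = 1024 within 1%).

α is fitted on the fixed tree by bounded scalar maximum likelihood
(default bounds [0.05, 50], bracketing tolerance 1e−4). Branch lengths are
**never** re-optimized: the tree is an input, matching the usual practice
of reconstructing on a tree estimated elsewhere. A fit landing on a bound
is flagged and warned about rather than silently returned; note that
degenerate all-invariant alignments legitimately drive α to the *lower*
bound, since near-zero rates fit unvarying data best.

## Likelihood engine

Felsenstein pruning over the rooted tree, vectorized across site patterns
and rate categories. Identical site patterns are compressed and weighted
(bit-identical in exact arithmetic to the uncompressed sum, and tested as
exactly 2× on a duplicated alignment). Underflow is controlled by
per-node max-rescaling with accumulated log scalers — a portable precision
contract that does not rely on extended-precision floats. Gaps and `X`
contribute all-ones partial vectors (standard missing-data treatment).
Multifurcations are accepted as hard polytomies; zero-length branches give
identity transitions; negative branch lengths are rejected unless
explicitly clamped (`clamp_negative`), because silent clamping hides
malformed input.

Trees carry stable post-order integer ids (children before parents, root
last), reassigned after any structural change. Node equivalence across
differently produced trees is established by descendant leaf sets — the
`mrca`/`resolve_node` selectors accept a leaf-label set for exactly this
reason — never by comparing raw ids, which are tool-internal in every
phylogenetics package.

Outgroup rooting treats the input root as arbitrary (pulley principle),
finds the single edge separating the outgroup leaf set from the rest, and
bisects it; when the old root was a degree-2 vertex on that edge, its two
incident edges are merged before the midpoint is measured. Re-rooting a
reversible-model tree anywhere leaves the log-likelihood unchanged to
< 1e−8, which the tests assert directly.

## Marginal ancestral reconstruction

Posteriors at a node are empirical-Bayes marginals under the rate
mixture: per category, inside ("data below") and outside ("data elsewhere
plus root prior") messages are combined and normalized per site; the
mixture over categories uses per-site weights proportional to the
per-category site likelihood. This matches the brute-force definition —
the test suite enumerates all internal-state assignments on trees of ≤ 5
leaves and requires agreement to 1e−8 per posterior entry — and is
invariant to re-rooting except at the moved root itself. Querying a leaf
returns the degenerate distribution (delta on the observed residue;
uniform for missing characters) rather than an error.

The reported ancestor takes the most probable residue per site. Exact
posterior ties are broken alphabetically by one-letter code and flagged
per site. Only marginal reconstruction is implemented; joint paths and
posterior sampling ("altAll"-style alternates) are out of scope.

Ancestral **gap** placement is decided outside the probabilistic core:
Fitch small parsimony on the binary gap/residue character per column,
with set ambiguity during the top-down pass resolved toward residue. The
mask is applied after residue reconstruction; masked sites emit `-` and
are excluded from the node's mean posterior probability (the summary
statistic reported per ancestor). Excluding gap sites from the mean is a
documented choice — including near-certain gap columns would inflate it.

## Conservation grading

Per-site rates are the empirical-Bayes posterior means of the gamma
category rates, `Σ_k w_k(s) r_k`. Sites are ranked (slowest first, stable
ties) and cut into nine equal-percentile bins; grade 9 is the slowest
ninth and sites with grade > 7 are called conserved. This is a relative,
rate-percentile grading in the spirit of the familiar 1–9 conservation
scales; it is *not* claimed to reproduce any specific server's Bayesian
grading, whose exact rate-estimation flavor is not recoverable. Fewer
than nine sites triggers a warning (grades are then coarse).

## Gene design

The codon optimizer walks the aligned ancestor/reference pair column by
column: identical residues copy the reference codon verbatim; differing
residues, and ancestral residues opposite a reference gap, draw a codon
for the ancestral residue weighted by host codon usage; ancestral gaps
opposite reference residues emit nothing. A trailing stop codon on the
reference CDS is carried over. Usage weights (counts, frequencies, or
per-thousand; DNA or RNA codons) are renormalized **within each synonymous
family** on load — the only normalization under which a weighted draw is
guaranteed to encode the intended residue. The reference CDS is verified
codon-by-codon against the reference protein before any design, and the
output is a pure function of (inputs, seed); every designed gene records
its seed and per-codon provenance (`copied`/`sampled`/`inserted`). An
optional user-supplied nucleotide cassette (e.g. an N-terminal Strep-II
tag) can be prepended; choosing the cassette's codons is the user's
responsibility. Restriction-site scrubbing, GC targeting and RNA-structure
awareness are out of scope.

Substitution maps are reported in reference numbering (1-based over
non-gap reference columns, `I355V`-style labels); columns where exactly
one side is gapped are listed separately as insertions/deletions rather
than substitutions, which preserves translation fidelity bookkeeping when
ancestors carry indels relative to the reference.

## Phenotype quantification

Growth curves fit the three-parameter logistic
`N(t) = K/(1+((K−N0)/N0)e^{−rt})` by nonlinear least squares (positivity
bounds; initialization from the max OD, first positive OD, and the
log-OD slope over the 20–80% rise). Derived quantities: doubling time
`ln2/r` and midpoint `t_mid = ln((K−N0)/N0)/r`. There is no explicit lag
parameter — "lag" differences surface as midpoint shifts, so a strain
with a delayed takeoff reports a larger `t_mid` at equal `r`. Fits that
fail to converge or end with K ≤ N0 are returned flagged with the
optimizer's message, never silently.

Assay rates are ordinary-least-squares slopes of product vs time (free
intercept) divided by total protein, with the slope's standard error
propagated. Group comparison is classical one-way ANOVA; post-hoc
pairwise p-values use the studentized-range distribution (SciPy's
numerically integrated implementation) with the Tukey–Kramer standard
error under unequal replicate counts. The post-hoc stage can be skipped
(`pairwise=False`) when only the omnibus F test is needed, since the
studentized-range integration dominates the cost. Degenerate inputs are
explicit: all-identical data reports F = 0, p = 1 (flagged); zero
within-group variance with unequal means reports the p → 0 limit
(flagged). The H₂/N₂ efficiency ratio is reported with its mechanistic
floor of 1 as an annotation: measured ratios below 1 are flagged as
physically suspect, not rejected. An `from_ammonia` flag converts NH₃
quantities to N₂ (÷2).

## Synthetic data

The generators stand in for the study-scale external dataset (hundreds of
ingroup and outgroup sequences) and provide recorded ground truth:

- **Trees**: Yule topologies (dendropy's birth–death simulator, seeded),
  rescaled so the mean root-to-tip path equals the requested depth.
- **Alignments**: root drawn from π; one gamma category per site, fixed
  across the whole tree (the exact "+G" site-rate interpretation the
  likelihood assumes); descent by sampling per-branch, per-category
  transition rows. Every internal node's sequence and every site's
  category are recorded. Optional gap blocks are painted on random leaf
  clades (Poisson block count, geometric lengths) — block-wise rather
  than iid per cell, so the Fitch gap machinery is exercised on
  indel-like structure. No realistic indel length model or horizontal
  transfer is simulated, so passing tests demonstrate statistical
  correctness of the machinery, not robustness to alignment error or
  model misspecification in real data.
- **Growth curves**: logistic trajectories plus iid Gaussian noise
  truncated at zero, five replicates per strain by default, optional
  lognormal parameter jitter.
- **Codon cases**: reference CDS drawn codon-by-codon from a usage table;
  ancestor differing at exactly `round(fraction·length)` uniform
  positions (the ~90% identity regime of real ancestor/wild-type pairs is
  `fraction = 0.10`).

Every generator is a pure function of its parameters and seed.

## Validation scales and the acceptance script

The statistical validation suite uses problem sizes chosen to give the
relevant estimators room to concentrate while staying desk-scale: oracle
equivalence on ≤ 5-leaf trees (where exhaustive enumeration over internal
states is exact and fast); posterior calibration on a 16-taxon,
2000-site simulation binned by site PP; depth–confidence monotonicity
across root-to-tip depths 0.1/0.5/1.0 with 20 replicates; α recovery on
32 taxa × 500 sites judged against the profile-likelihood 95% interval;
10 000-replicate null simulations for the ANOVA type-I error.
`scripts/acceptance.py` replays the whole pipeline at a 72-taxon,
300-site scale — a deliberate stand-in for the study-scale input, chosen
so every stage (rooting, α fit, reconstruction, design, phenotype fits)
runs end-to-end in seconds — and writes only quantities it has just
computed.

## Known limitations

- The tree and its branch lengths are trusted inputs; no topology search,
  support values, or branch-length re-estimation.
- Marginal-only reconstruction; no joint paths or sampled ancestors.
- Gap ancestry is parsimony-based, not probabilistic; sites gapped in all
  leaves of a clade are masked by construction, and alternative gap
  histories are not scored.
- Conservation grades are relative percentiles within the analyzed
  alignment: they shift with taxon and site sampling, and the grade-> 7
  "conserved" call should be read accordingly.
- The logistic growth model has no lag or death phase; strongly diauxic
  or declining curves will fit poorly (and are flagged via residual sd
  and convergence status rather than modeled).
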