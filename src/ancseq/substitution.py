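"""Amino-acid substitution models: rate matrices, transition probabilities,
and discrete-gamma rate heterogeneity.

The model class implemented here is the standard reversible CTMC used in
protein phylogenetics: a symmetric exchangeability matrix ``S`` combined
with equilibrium frequencies ``pi`` gives the instantaneous rate matrix

    Q[i, j] = S[i, j] * pi[j]      (i != j)

with the diagonal set so rows sum to zero and the whole matrix rescaled so
that the expected number of substitutions per unit branch length at
stationarity is one (``-sum_i pi_i Q_ii = 1``).  Among-site rate variation
is the usual K-category discrete approximation of a unit-mean gamma
distribution with shape ``alpha`` ("+G"), and "+F" frequencies are counted
from the alignment.

Transition matrices ``P(t) = expm(Q t)`` are computed through the symmetric
similarity transform ``B = D^{1/2} Q D^{-1/2}`` (``D = diag(pi)``): ``B`` is
symmetric for a reversible ``Q``, so a single eigendecomposition serves
every branch length and rate category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import special
from scipy.stats import gamma as gamma_dist

from .alphabet import AMINO_ACIDS, MISSING_CODE, N_STATES

__all__ = [
    "SubstitutionModel",
    "GammaRates",
    "build_rate_matrix",
    "transition_matrix",
    "discretize_gamma",
    "empirical_frequencies",
    "load_paml_matrix",
    "get_model",
    "lg_exchangeabilities",
    "poisson_exchangeabilities",
]


def build_rate_matrix(exchangeabilities: np.ndarray, frequencies: np.ndarray) -> np.ndarray:
    """Construct the mean-rate-normalized reversible rate matrix Q.

    Parameters
    ----------
    exchangeabilities
        Symmetric nonnegative 20x20 matrix (diagonal ignored/zero).
    frequencies
        Length-20 strictly positive probability vector.

    Returns
    -------
    Q such that ``Q[i, j] = c * S[i, j] * pi[j]`` off-diagonal, zero row
    sums, and ``-sum_i pi_i Q_ii == 1``.
    """
    S = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(frequencies, dtype=float)
    if S.shape != (N_STATES, N_STATES):
        raise ValueError(f"exchangeability matrix must be 20x20, got {S.shape}")
    asym = np.abs(S - S.T)
    if asym.max() > 1e-12:
        i, j = np.unravel_index(int(np.argmax(asym)), S.shape)
        raise ValueError(
            f"exchangeabilities not symmetric: S[{i},{j}]={S[i, j]!r} "
            f"vs S[{j},{i}]={S[j, i]!r}"
        )
    if np.any(S < 0):
        i, j = np.unravel_index(int(np.argmin(S)), S.shape)
        raise ValueError(f"negative exchangeability S[{i},{j}]={S[i, j]!r}")
    _check_frequencies(pi)

    Q = S * pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(pi @ np.diag(Q))
    if mu <= 0:
        raise ValueError("degenerate rate matrix: zero total rate")
    return Q / mu


def _check_frequencies(pi: np.ndarray) -> None:
    if pi.shape != (N_STATES,):
        raise ValueError(f"frequency vector must have length 20, got {pi.shape}")
    if np.any(pi <= 0):
        bad = int(np.argmin(pi))
        raise ValueError(
            f"frequency for {AMINO_ACIDS[bad]!r} is {pi[bad]!r}; all must be "
            "strictly positive (consider a pseudocount)"
        )
    if abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError(f"frequencies sum to {pi.sum()!r}, expected 1")


@dataclass(frozen=True)
class GammaRates:
    """Discrete-gamma rate categories (equal weights, unit weighted mean)."""

    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "weights", w)
        if r.shape != w.shape or r.ndim != 1:
            raise ValueError("rates and weights must be 1-D and equally long")
        if np.any(r <= 0):
            raise ValueError("category rates must be positive")
        if np.any(np.diff(r) < 0):
            raise ValueError("category rates must be nondecreasing")
        if abs(float(w @ r) - 1.0) > 1e-12:
            raise ValueError("weighted mean rate must equal 1")

    def __len__(self) -> int:
        return self.rates.size


def discretize_gamma(alpha: float, n_categories: int) -> GammaRates:
    """Mean-of-category discretization of the unit-mean gamma distribution.

    The gamma(alpha, rate=alpha) density is cut at its K-quantiles and each
    category's rate is the conditional mean within its quantile interval,
    which keeps the weighted mean at exactly one (a final renormalization
    absorbs floating-point drift).
    """
    if n_categories < 1:
        raise ValueError(f"need at least one category, got {n_categories}")
    if not alpha > 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    K = int(n_categories)
    if K == 1:
        return GammaRates(np.ones(1), np.ones(1))
    edges = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    cut = np.concatenate(([0.0], alpha * edges, [np.inf]))
    # E[X; a<X<b] for X~gamma(alpha, rate alpha) via the regularized lower
    # incomplete gamma with shape alpha+1 (mean of gamma(alpha, alpha) is 1).
    upper = special.gammainc(alpha + 1.0, cut[1:])
    lower = special.gammainc(alpha + 1.0, cut[:-1])
    rates = K * (upper - lower)
    weights = np.full(K, 1.0 / K)
    rates = rates / float(weights @ rates)
    return GammaRates(np.sort(rates), weights)


def empirical_frequencies(alignment, pseudocount: float = 0.0) -> np.ndarray:
    """Observed residue frequencies ("+F"), gaps and X excluded.

    With the default ``pseudocount=0`` an alignment missing any residue is
    rejected, because a zero equilibrium frequency breaks the reversibility
    scaling; pass ``pseudocount=0.5`` (or any positive value) to regularize.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    codes = alignment.codes
    counts = np.bincount(codes[codes != MISSING_CODE].ravel(), minlength=N_STATES)
    counts = counts[:N_STATES].astype(float)
    if counts.sum() == 0:
        raise ValueError("alignment has no non-gap characters")
    counts += pseudocount
    if np.any(counts == 0):
        missing = [AMINO_ACIDS[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(
            f"residues {missing} unobserved; zero frequencies are invalid — "
            "pass pseudocount=0.5 to regularize"
        )
    return counts / counts.sum()


class SubstitutionModel:
    """Reversible amino-acid substitution model with discrete-gamma rates.

    Parameters
    ----------
    exchangeabilities
        Symmetric 20x20 nonnegative matrix (arbitrary scale).
    frequencies
        Equilibrium probabilities pi (length 20, strictly positive).
    gamma_shape
        Shape alpha of the unit-mean gamma rate distribution; ``None``
        disables rate heterogeneity (single unit-rate category).
    n_categories
        Number K of discrete gamma categories (ignored when gamma_shape is
        None).
    """

    def __init__(
        self,
        exchangeabilities: np.ndarray,
        frequencies: np.ndarray,
        gamma_shape: float | None = 1.0,
        n_categories: int = 4,
        name: str = "custom",
    ) -> None:
        self.exchangeabilities = np.asarray(exchangeabilities, dtype=float)
        self.frequencies = np.asarray(frequencies, dtype=float)
        self.name = name
        self.Q = build_rate_matrix(self.exchangeabilities, self.frequencies)
        if gamma_shape is None:
            self.gamma_shape = None
            self.n_categories = 1
            self.gamma_rates = GammaRates(np.ones(1), np.ones(1))
        else:
            if not gamma_shape > 0:
                raise ValueError(f"gamma shape must be positive, got {gamma_shape}")
            self.gamma_shape = float(gamma_shape)
            self.n_categories = int(n_categories)
            self.gamma_rates = discretize_gamma(self.gamma_shape, self.n_categories)
        # Symmetric eigendecomposition reused by every transition matrix.
        sqrt_pi = np.sqrt(self.frequencies)
        B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        B = 0.5 * (B + B.T)
        self._eigenvalues, self._eigenvectors = np.linalg.eigh(B)
        self._left = self._eigenvectors.T * sqrt_pi[None, :]
        self._right = self._eigenvectors / sqrt_pi[:, None]

    def with_gamma(self, gamma_shape: float, n_categories: int | None = None) -> "SubstitutionModel":
        """Copy of this model with a different gamma shape (same Q)."""
        return SubstitutionModel(
            self.exchangeabilities,
            self.frequencies,
            gamma_shape=gamma_shape,
            n_categories=n_categories or self.n_categories,
            name=self.name,
        )

    def with_frequencies(self, frequencies: np.ndarray) -> "SubstitutionModel":
        gs = self.gamma_shape
        return SubstitutionModel(
            self.exchangeabilities,
            frequencies,
            gamma_shape=gs,
            n_categories=self.n_categories,
            name=self.name + "+F",
        )

    def transition_matrix(self, branch_length: float, rate: float = 1.0) -> np.ndarray:
        """P = expm(Q * rate * branch_length); rows sum to 1."""
        if branch_length < 0:
            raise ValueError(f"negative branch length {branch_length}")
        if rate <= 0:
            raise ValueError(f"rate must be positive, got {rate}")
        t = branch_length * rate
        P = (self._right * np.exp(self._eigenvalues * t)[None, :]) @ self._left
        np.clip(P, 0.0, 1.0, out=P)
        return P

    def category_transition_matrices(self, branch_length: float) -> np.ndarray:
        """Stack of per-category transition matrices, shape (K, 20, 20)."""
        return np.stack(
            [self.transition_matrix(branch_length, r) for r in self.gamma_rates.rates]
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g = f"+G(alpha={self.gamma_shape}, K={self.n_categories})" if self.gamma_shape else ""
        return f"<SubstitutionModel {self.name}{g}>"


def transition_matrix(Q: np.ndarray, branch_length: float, rate: float = 1.0) -> np.ndarray:
    """Module-level transition-probability helper for an arbitrary Q.

    Uses ``scipy.linalg.expm``; the model method above is preferred when many
    branch lengths share one Q.
    """
    from scipy.linalg import expm

    if branch_length < 0:
        raise ValueError(f"negative branch length {branch_length}")
    P = expm(np.asarray(Q, dtype=float) * (branch_length * rate))
    np.clip(P, 0.0, 1.0, out=P)
    return P


def load_paml_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-style ``.dat`` file: 19 lower-triangle exchangeability
    rows followed by a row of 20 frequencies.  '#' lines are comments."""
    values: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            values.extend(float(tok) for tok in line.split())
    n_tri = N_STATES * (N_STATES - 1) // 2
    if len(values) < n_tri + N_STATES:
        raise ValueError(
            f"{path}: expected at least {n_tri + N_STATES} numbers, got {len(values)}"
        )
    S = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = values[k]
            k += 1
    pi = np.array(values[k : k + N_STATES])
    pi = pi / pi.sum()
    return S, pi


def lg_exchangeabilities() -> tuple[np.ndarray, np.ndarray]:
    """Bundled LG exchangeabilities and default LG frequencies."""
    with resources.as_file(resources.files("ancseq.data") / "lg.dat") as p:
        return load_paml_matrix(p)


def poisson_exchangeabilities() -> tuple[np.ndarray, np.ndarray]:
    """All-equal exchangeabilities with uniform frequencies (20-state Poisson)."""
    S = np.ones((N_STATES, N_STATES)) - np.eye(N_STATES)
    return S, np.full(N_STATES, 1.0 / N_STATES)


def get_model(
    name: str = "LG",
    frequencies: np.ndarray | None = None,
    gamma_shape: float | None = 1.0,
    n_categories: int = 4,
    matrix_file: str | Path | None = None,
) -> SubstitutionModel:
    """Build a named model ("LG", "POISSON") or one from a PAML matrix file.

    ``frequencies`` overrides the file's frequency row (the "+F" case).
    """
    if matrix_file is not None:
        S, pi = load_paml_matrix(matrix_file)
        name = Path(matrix_file).stem
    elif name.upper() == "LG":
        S, pi = lg_exchangeabilities()
    elif name.upper() == "POISSON":
        S, pi = poisson_exchangeabilities()
    else:
        raise ValueError(f"unknown model {name!r}; use 'LG', 'POISSON' or a matrix file")
    if frequencies is not None:
        pi = np.asarray(frequencies, dtype=float)
    return SubstitutionModel(S, pi, gamma_shape=gamma_shape, n_categories=n_categories, name=name)
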