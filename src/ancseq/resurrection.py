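"""Design layer for ancestral-protein resurrection.

Covers the computational steps between a reconstructed ancestor and a
synthesizable gene: pairwise identity matrices, mapping of ancestral
substitutions into reference (wild-type) residue numbering, rate-based
site conservation grading, and the semi-randomized codon-optimization
strategy that maximizes nucleotide identity of the designed gene to the
wild-type coding sequence — identical residues keep the wild-type codon
verbatim, substituted or inserted residues draw a synonymous codon at
random weighted by host codon usage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .alignment import ProteinAlignment
from .alphabet import AMINO_ACIDS, MISSING_CODE
from .asr import AncestralReconstruction
from .likelihood import total_log_likelihood
from .substitution import SubstitutionModel
from .tree import PhyloTree

__all__ = [
    "pairwise_identity",
    "identity_matrix",
    "SubstitutionMap",
    "SubstitutionEntry",
    "map_substitutions",
    "ConservationProfile",
    "conservation_grades",
    "CodonUsageTable",
    "OptimizedGene",
    "codon_optimize",
    "translate_cds",
    "STREP_II_TAG",
]

STREP_II_TAG = "ASWSHPQFEK"  # N-terminal affinity/immunodetection tag

_CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
_STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
_SENSE_CODONS: tuple[str, ...] = tuple(sorted(_CODON_TO_AA))
_AA_TO_CODONS: dict[str, list[str]] = {}
for _c, _a in _CODON_TO_AA.items():
    _AA_TO_CODONS.setdefault(_a, []).append(_c)
for _a in _AA_TO_CODONS:
    _AA_TO_CODONS[_a].sort()


# --------------------------------------------------------------- identity
def pairwise_identity(alignment: ProteinAlignment, id_a: str, id_b: str) -> float:
    """Percent identity over columns where both sequences carry a residue.

    Returns NaN when the two sequences share no mutually ungapped column.
    """
    a = alignment.row_codes(id_a)
    b = alignment.row_codes(id_b)
    both = (a != MISSING_CODE) & (b != MISSING_CODE)
    n = int(both.sum())
    if n == 0:
        return float("nan")
    return float((a[both] == b[both]).sum()) / n * 100.0


def identity_matrix(alignment: ProteinAlignment) -> pd.DataFrame:
    """Symmetric all-pairs percent-identity matrix (diagonal 100)."""
    ids = alignment.ids
    n = len(ids)
    M = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pairwise_identity(alignment, ids[i], ids[j])
    return pd.DataFrame(M, index=ids, columns=ids)


# ---------------------------------------------------------- substitutions
@dataclass(frozen=True)
class SubstitutionEntry:
    reference_position: int  # 1-based in reference (non-gap) numbering
    reference_residue: str
    ancestral_residue: str
    alignment_column: int  # 1-based
    conservation_grade: int | None = None

    @property
    def label(self) -> str:
        """Wild-type-numbered label, e.g. 'I355V'."""
        return f"{self.reference_residue}{self.reference_position}{self.ancestral_residue}"


@dataclass
class SubstitutionMap:
    """Ancestral substitutions relative to a reference sequence.

    ``insertions`` are alignment columns where the ancestor has a residue
    over a reference gap; ``deletions`` the converse.  Coordinates are
    1-based throughout.
    """

    reference_id: str
    entries: list[SubstitutionEntry]
    insertions: list[int]  # alignment columns (1-based)
    deletions: list[int]

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": e.label,
                    "reference_position": e.reference_position,
                    "reference_residue": e.reference_residue,
                    "ancestral_residue": e.ancestral_residue,
                    "alignment_column": e.alignment_column,
                    "conservation_grade": e.conservation_grade,
                }
                for e in self.entries
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def map_substitutions(
    ancestor: AncestralReconstruction | str,
    reference_id: str,
    alignment: ProteinAlignment,
    grades: np.ndarray | None = None,
) -> SubstitutionMap:
    """Ancestral substitutions in reference numbering.

    The ancestor must live in the same column space as the alignment.
    Reference numbering counts non-gap reference columns from 1; columns
    where exactly one side is gapped are reported as insertions/deletions,
    not substitutions.  Optional per-column conservation ``grades`` are
    attached to each entry.
    """
    anc_seq = ancestor.map_sequence if isinstance(ancestor, AncestralReconstruction) else ancestor
    ref_seq = alignment.row(reference_id)
    if len(anc_seq) != alignment.length:
        raise ValueError(
            f"ancestor length {len(anc_seq)} != alignment length {alignment.length}"
        )
    entries: list[SubstitutionEntry] = []
    insertions: list[int] = []
    deletions: list[int] = []
    ref_pos = 0
    for col0, (r, a) in enumerate(zip(ref_seq, anc_seq)):
        ref_gap = r == "-"
        anc_gap = a == "-"
        if not ref_gap:
            ref_pos += 1
        if ref_gap and anc_gap:
            continue
        if ref_gap and not anc_gap:
            insertions.append(col0 + 1)
        elif anc_gap and not ref_gap:
            deletions.append(col0 + 1)
        elif r != a:
            entries.append(
                SubstitutionEntry(
                    reference_position=ref_pos,
                    reference_residue=r,
                    ancestral_residue=a,
                    alignment_column=col0 + 1,
                    conservation_grade=(
                        int(grades[col0]) if grades is not None else None
                    ),
                )
            )
    return SubstitutionMap(reference_id, entries, insertions, deletions)


# ------------------------------------------------------------ conservation
@dataclass
class ConservationProfile:
    """Rate-based site conservation on the 1-9 grade scale (9 = most conserved).

    Grades come from ranking the empirical-Bayes posterior-mean site rates
    and cutting into nine equal-percentile bins; sites with grade > 7 are
    called conserved.  This is a rate-percentile grading in the spirit of
    the familiar 1-9 conservation scales, not a reimplementation of any
    particular server's Bayesian grading.
    """

    site_rates: np.ndarray  # (L,)
    grades: np.ndarray  # (L,) ints 1..9
    conserved_threshold: int = 7

    @property
    def conserved(self) -> np.ndarray:
        """Boolean per site: grade strictly above the threshold."""
        return self.grades > self.conserved_threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": np.arange(1, self.site_rates.size + 1),
                "rate": self.site_rates,
                "grade": self.grades,
                "conserved": self.conserved,
            }
        )


def conservation_grades(
    tree: PhyloTree, model: SubstitutionModel, alignment: ProteinAlignment
) -> ConservationProfile:
    """Grade sites 1-9 by posterior-mean evolutionary rate (9 = slowest).

    The per-site rate is the empirical-Bayes mixture mean of the gamma
    category rates; grades are equal-percentile rate bins so each grade
    holds ~L/9 sites.  Exactly tied rates are split by site order (stable),
    which keeps the partition even without creating rate/grade inversions.
    """
    import warnings

    _, site_lik = total_log_likelihood(tree, model, alignment)
    rates = site_lik.category_weights.T @ model.gamma_rates.rates
    L = rates.size
    if L < 9:
        warnings.warn(f"only {L} sites; conservation grades are coarse", stacklevel=2)
    order = np.argsort(rates, kind="stable")  # slowest first
    rank = np.empty(L, dtype=np.int64)
    rank[order] = np.arange(L)
    grades = 9 - np.minimum(8, (9 * rank) // max(L, 1)).astype(int)
    return ConservationProfile(site_rates=rates, grades=grades)


# ------------------------------------------------------------- codon usage
class CodonUsageTable:
    """Host codon-usage weights with per-amino-acid normalized sampling.

    Accepts counts, frequencies, or per-thousand values for the 61 sense
    codons; weights are renormalized within each amino acid's synonymous
    family on load (relative synonymous codon usage), which is what
    guarantees a usage-weighted draw still encodes the intended residue.
    """

    def __init__(self, weights: dict[str, float]) -> None:
        clean: dict[str, float] = {}
        for codon, w in weights.items():
            c = codon.upper().replace("U", "T")
            if c in _STOP_CODONS:
                continue
            if c not in _CODON_TO_AA:
                raise ValueError(f"unknown codon {codon!r}")
            if w < 0:
                raise ValueError(f"negative weight for codon {codon!r}")
            clean[c] = clean.get(c, 0.0) + float(w)
        self.weights = {c: clean.get(c, 0.0) for c in _SENSE_CODONS}
        self._per_aa: dict[str, tuple[list[str], np.ndarray]] = {}
        for aa, codons in _AA_TO_CODONS.items():
            w = np.array([self.weights[c] for c in codons])
            total = w.sum()
            if total <= 0:
                raise ValueError(f"amino acid {aa!r} has no positive-weight codon")
            self._per_aa[aa] = (codons, w / total)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonUsageTable":
        """Read a two-column table (codon, weight); '#' lines ignored."""
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, names=["codon", "weight"])
        return cls(dict(zip(df["codon"].astype(str), df["weight"].astype(float))))

    @classmethod
    def uniform(cls) -> "CodonUsageTable":
        return cls({c: 1.0 for c in _SENSE_CODONS})

    def synonymous_weights(self, amino_acid: str) -> tuple[list[str], np.ndarray]:
        """Sorted synonymous codons and their normalized weights."""
        aa = amino_acid.upper()
        if aa not in self._per_aa:
            raise KeyError(f"not a standard amino acid: {amino_acid!r}")
        return self._per_aa[aa]

    def sample_codon(self, amino_acid: str, rng: np.random.Generator) -> str:
        codons, w = self.synonymous_weights(amino_acid)
        return codons[int(rng.choice(len(codons), p=w))]


def translate_cds(cds: str) -> str:
    """Translate a coding sequence (standard code); trailing stop dropped."""
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in _STOP_CODONS:
            if i != len(cds) - 3:
                raise ValueError(f"internal stop codon {codon} at nucleotide {i + 1}")
            break
        if codon not in _CODON_TO_AA:
            raise ValueError(f"unknown codon {codon!r} at nucleotide {i + 1}")
        aas.append(_CODON_TO_AA[codon])
    return "".join(aas)


# ---------------------------------------------------------- gene design
@dataclass
class OptimizedGene:
    """Designed coding sequence with per-codon provenance.

    Provenance tags: ``copied`` (wild-type codon kept verbatim),
    ``sampled`` (usage-weighted draw at a substituted site),
    ``inserted`` (usage-weighted draw at an ancestral insertion).
    """

    nucleotide_sequence: str
    provenance: list[str]
    seed: int
    stop_codon: str | None = None

    @property
    def translation(self) -> str:
        return translate_cds(self.nucleotide_sequence)

    @property
    def full_sequence(self) -> str:
        return self.nucleotide_sequence + (self.stop_codon or "")

    def identity_to(self, cds: str) -> float:
        """Percent nucleotide identity over the aligned length to *cds*."""
        n = min(len(self.nucleotide_sequence), len(cds))
        a = self.nucleotide_sequence[:n]
        b = cds[:n].upper()
        return sum(x == y for x, y in zip(a, b)) / n * 100.0

    def provenance_frame(self) -> pd.DataFrame:
        codons = [
            self.nucleotide_sequence[i : i + 3]
            for i in range(0, len(self.nucleotide_sequence), 3)
        ]
        return pd.DataFrame(
            {
                "codon_index": np.arange(1, len(codons) + 1),
                "codon": codons,
                "amino_acid": list(self.translation),
                "provenance": self.provenance,
            }
        )


def codon_optimize(
    ancestral_protein_aligned: str,
    reference_protein_aligned: str,
    reference_cds: str,
    usage: CodonUsageTable,
    seed: int,
    tag_cassette: str | None = None,
) -> OptimizedGene:
    """Semi-randomized back-translation maximizing identity to the wild type.

    Walking the aligned ancestor/reference column pair: identical residues
    copy the wild-type codon verbatim; differing residues and ancestral
    insertions draw a codon for the ancestral residue at random, weighted
    by host codon usage; ancestral deletions emit nothing.  A trailing stop
    codon on the reference CDS is carried over.  The output is a pure
    function of the inputs and the seed.

    ``tag_cassette`` optionally prepends a user-supplied nucleotide cassette
    (e.g. encoding an N-terminal Strep-II tag); its length must be a
    multiple of three.
    """
    anc = ancestral_protein_aligned.upper()
    ref = reference_protein_aligned.upper()
    if len(anc) != len(ref):
        raise ValueError(
            f"aligned proteins differ in length: {len(anc)} vs {len(ref)}"
        )
    cds = reference_cds.upper().replace("U", "T")
    stop: str | None = None
    if len(cds) % 3 != 0:
        raise ValueError(f"reference CDS length {len(cds)} not divisible by 3")
    if cds[-3:] in _STOP_CODONS:
        stop = cds[-3:]
        cds = cds[:-3]
    ref_ungapped = ref.replace("-", "")
    if len(cds) != 3 * len(ref_ungapped):
        raise ValueError(
            f"reference CDS encodes {len(cds) // 3} residues but the reference "
            f"protein has {len(ref_ungapped)}"
        )
    for i, aa in enumerate(ref_ungapped):
        codon = cds[3 * i : 3 * i + 3]
        if _CODON_TO_AA.get(codon) != aa:
            raise ValueError(
                f"reference CDS codon {i + 1} ({codon}) does not encode "
                f"reference residue {aa!r}"
            )

    rng = np.random.default_rng(seed)
    out: list[str] = []
    prov: list[str] = []
    ref_i = 0  # codon index into the ungapped reference
    for a, r in zip(anc, ref):
        ref_codon = cds[3 * ref_i : 3 * ref_i + 3] if r != "-" else None
        if r != "-":
            ref_i += 1
        if a == "-":
            continue  # deletion relative to reference, or mutual gap
        if r == "-":
            out.append(usage.sample_codon(a, rng))
            prov.append("inserted")
        elif a == r:
            out.append(ref_codon)
            prov.append("copied")
        else:
            out.append(usage.sample_codon(a, rng))
            prov.append("sampled")
    nt = "".join(out)
    if tag_cassette:
        tag = tag_cassette.upper().replace("U", "T")
        if len(tag) % 3 != 0:
            raise ValueError("tag cassette length must be a multiple of 3")
        nt = tag + nt
        prov = ["tag"] * (len(tag) // 3) + prov
    return OptimizedGene(nucleotide_sequence=nt, provenance=prov, seed=seed, stop_codon=stop)
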