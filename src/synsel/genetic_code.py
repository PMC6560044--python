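"""Standard genetic code services: translation, synonymy and site degeneracy.

Everything downstream — conservation counting at wobble and fourfold degenerate
sites, codon-usage profiles, synonymous-only sequence evolution — reduces to
three questions about the standard nuclear genetic code:

* what amino acid does a codon encode (`translate`),
* which codons are synonymous with each other (`synonymous_codons`),
* at a given codon position, how many of the four nucleotides leave the amino
  acid unchanged (`degeneracy`)?

The code table is a single internal constant (the standard code, DNA alphabet);
all study species are vertebrates or flies and only nuclear genes are analysed,
so alternative codes are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Data import CodonTable as _CodonTable

__all__ = [
    "BASES",
    "CODON_TO_AA",
    "SENSE_CODONS",
    "STOP_CODONS",
    "AMINO_ACIDS",
    "GeneticCodeError",
    "InternalStopError",
    "DegeneracyClass",
    "translate",
    "degeneracy",
    "is_fourfold",
    "synonymous_codons",
    "validate_cds",
]

BASES: tuple[str, ...] = ("A", "C", "G", "T")

_STANDARD = _CodonTable.unambiguous_dna_by_id[1]

#: Mapping of the 61 sense codons to one-letter amino-acid codes.
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: The three stop codons of the standard code.
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: The 61 sense codons.
SENSE_CODONS: frozenset[str] = frozenset(CODON_TO_AA)

#: The 20 amino acids (one-letter codes).
AMINO_ACIDS: frozenset[str] = frozenset(CODON_TO_AA.values())


class GeneticCodeError(ValueError):
    """Invalid codon, amino acid, or CDS at the genetic-code layer."""


class InternalStopError(GeneticCodeError):
    """A stop codon occurs before the final codon of a CDS."""


def validate_cds(cds: str) -> str:
    """Uppercase and validate a CDS string.

    Raises :class:`GeneticCodeError` if the sequence is empty, its length is
    not a multiple of 3, or it contains characters outside ``ACGT``.
    Ambiguity codes are rejected here by design: upstream readers are expected
    to drop whole records containing them.
    """
    seq = cds.upper()
    if not seq:
        raise GeneticCodeError("empty CDS")
    if len(seq) % 3 != 0:
        raise GeneticCodeError(f"CDS length {len(seq)} is not a multiple of 3")
    bad = set(seq) - set(BASES)
    if bad:
        raise GeneticCodeError(f"non-ACGT characters in CDS: {sorted(bad)}")
    return seq


def translate(cds: str) -> str:
    """Translate a CDS under the standard code.

    A trailing stop codon is dropped from the product (but the caller keeps
    the codon itself for bookkeeping purposes); an internal stop raises
    :class:`InternalStopError`.
    """
    seq = validate_cds(cds)
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    protein = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if i != len(codons) - 1:
                raise InternalStopError(
                    f"internal stop codon {codon} at codon index {i}"
                )
            break
        protein.append(CODON_TO_AA[codon])
    return "".join(protein)


@dataclass(frozen=True)
class DegeneracyClass:
    """Degeneracy of one codon position.

    ``fold`` counts the nucleotides (including the observed one) that leave
    the encoded amino acid unchanged when substituted at ``position``; a
    position with ``fold == 4`` is a fourfold degenerate site — every possible
    substitution there is synonymous.
    """

    codon: str
    position: int
    fold: int
    is_fourfold: bool


@lru_cache(maxsize=None)
def degeneracy(codon: str, position: int) -> DegeneracyClass:
    """Degeneracy class of ``codon`` at ``position`` (1-based, in {1,2,3})."""
    codon = codon.upper()
    if codon not in SENSE_CODONS:
        raise GeneticCodeError(f"not a sense codon: {codon!r}")
    if position not in (1, 2, 3):
        raise GeneticCodeError(f"codon position must be 1, 2 or 3, got {position}")
    aa = CODON_TO_AA[codon]
    i = position - 1
    fold = sum(
        1
        for b in BASES
        if CODON_TO_AA.get(codon[:i] + b + codon[i + 1 :]) == aa
    )
    return DegeneracyClass(codon=codon, position=position, fold=fold,
                           is_fourfold=(fold == 4))


def is_fourfold(codon: str) -> bool:
    """True if the codon's third position is fourfold degenerate."""
    return degeneracy(codon, 3).is_fourfold


@lru_cache(maxsize=None)
def synonymous_codons(amino_acid: str) -> frozenset[str]:
    """The set of sense codons encoding ``amino_acid`` (one-letter code)."""
    aa = amino_acid.upper()
    if aa not in AMINO_ACIDS:
        raise GeneticCodeError(f"unknown amino-acid code: {amino_acid!r}")
    return frozenset(c for c, a in CODON_TO_AA.items() if a == aa)
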