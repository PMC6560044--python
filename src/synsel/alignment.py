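"""Pairwise global alignment, codon-aware multiple alignment, and the
gap-excluded identity score.

The identity score used throughout the package is

    identity = 1 - M / N

where M is the number of mismatching positions and N the number of alignment
columns at which *neither* sequence carries a gap. Columns with a gap in
either row contribute to neither M nor N, so insertions and deletions cannot
deflate the score — the property that makes the measure usable on highly
indel-variable sequences such as 3'UTRs.

Pairwise alignment is global (Needleman–Wunsch) with affine gap costs: a gap
run of length L costs ``gap_open + (L - 1) * gap_extend``. Nucleotide scoring
defaults to match +2 / mismatch -1 / open -5 / extend -1; proteins use
BLOSUM62 with open -11 / extend -1. Tie-breaking among co-optimal alignments
is deterministic (the aligner's fixed traceback order), so identical inputs
always yield identical alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genetic_code import GeneticCodeError, STOP_CODONS, translate

__all__ = [
    "AlignmentError",
    "UndefinedIdentityError",
    "NUCLEOTIDE_SCORING",
    "PROTEIN_GAP_SCORES",
    "PairwiseAlignment",
    "CodonAlignment",
    "global_align",
    "identity_gap_excluded",
    "alignment_coverage",
    "codon_align",
    "utr3_similarity",
]


class AlignmentError(ValueError):
    """Invalid input to an alignment operation."""


class UndefinedIdentityError(AlignmentError):
    """No gap-free column exists; 1 - M/N is undefined (N == 0)."""


#: Default nucleotide scoring: (match, mismatch, gap_open, gap_extend).
NUCLEOTIDE_SCORING: dict[str, float] = {
    "match": 2.0,
    "mismatch": -1.0,
    "gap_open": -5.0,
    "gap_extend": -1.0,
}

#: Default affine gap costs for protein alignment (with BLOSUM62).
PROTEIN_GAP_SCORES: dict[str, float] = {"gap_open": -11.0, "gap_extend": -1.0}


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment.

    ``aligned_a`` and ``aligned_b`` are equal-length strings over the
    sequence alphabet plus ``'-'``; removing gaps recovers the inputs and no
    column is a gap in both rows.
    """

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("aligned rows differ in length")

    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.aligned_a, self.aligned_b)


from functools import lru_cache


@lru_cache(maxsize=32)
def _cached_aligner(key: tuple, protein: bool) -> Align.PairwiseAligner:
    return _make_aligner(dict(key), protein)


def _make_aligner(scoring: dict[str, float] | None, protein: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if protein:
        gaps = dict(PROTEIN_GAP_SCORES)
        if scoring:
            gaps.update({k: v for k, v in scoring.items() if k in gaps})
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = gaps["gap_open"]
        aligner.extend_gap_score = gaps["gap_extend"]
    else:
        params = dict(NUCLEOTIDE_SCORING)
        if scoring:
            params.update(scoring)
        aligner.match_score = params["match"]
        aligner.mismatch_score = params["mismatch"]
        aligner.open_gap_score = params["gap_open"]
        aligner.extend_gap_score = params["gap_extend"]
    return aligner


def global_align(
    seq_a: str,
    seq_b: str,
    scoring: dict[str, float] | None = None,
    *,
    protein: bool = False,
    id_a: str = "a",
    id_b: str = "b",
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences under affine-gap scoring.

    Parameters
    ----------
    seq_a, seq_b
        Nonempty sequences (case-insensitive; uppercased on entry).
    scoring
        Optional overrides for ``match``/``mismatch``/``gap_open``/``gap_extend``
        (nucleotide mode) or ``gap_open``/``gap_extend`` (protein mode).
    protein
        Use BLOSUM62 instead of match/mismatch scoring.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    key = tuple(sorted((scoring or {}).items()))
    aligner = _cached_aligner(key, protein)
    result = aligner.align(a, b)
    best = result[0]  # deterministic first traceback
    return PairwiseAlignment(
        id_a=id_a, id_b=id_b,
        aligned_a=str(best[0]), aligned_b=str(best[1]),
        score=float(best.score),
    )


def identity_gap_excluded(aln: PairwiseAlignment) -> float:
    """Gap-excluded identity, ``1 - M/N``.

    M counts mismatching gap-free columns, N all gap-free columns. Raises
    :class:`UndefinedIdentityError` when no gap-free column exists rather
    than silently returning 0.
    """
    n = m = 0
    for ca, cb in aln.columns():
        if ca == "-" or cb == "-":
            continue
        n += 1
        if ca != cb:
            m += 1
    if n == 0:
        raise UndefinedIdentityError(
            f"no gap-free column between {aln.id_a} and {aln.id_b}"
        )
    return 1.0 - m / n


def alignment_coverage(aln: PairwiseAlignment) -> float:
    """Fraction of the shorter sequence covered by gap-free columns."""
    n = sum(1 for ca, cb in aln.columns() if ca != "-" and cb != "-")
    shorter = min(
        len(aln.aligned_a.replace("-", "")), len(aln.aligned_b.replace("-", ""))
    )
    return n / shorter if shorter else 0.0


def utr3_similarity(
    utr_a: str, utr_b: str, scoring: dict[str, float] | None = None
) -> float:
    """Gap-excluded identity of two 3'UTRs after global alignment.

    Indels (common in UTRs) appear as gap columns and are excluded from the
    score, so length variation does not deflate the similarity.
    """
    return identity_gap_excluded(global_align(utr_a, utr_b, scoring))


@dataclass(frozen=True)
class CodonAlignment:
    """A codon-structured multiple alignment of CDSs.

    All rows have equal length divisible by 3, gaps occur only as whole
    codon triplets, and ungapping a row recovers the input CDS (minus a
    terminal stop codon when the inputs disagree about having one).
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise AlignmentError("a codon alignment needs at least two rows")
        length = len(self.rows[0])
        if any(len(r) != length for r in self.rows):
            raise AlignmentError("rows differ in length")
        if length % 3 != 0:
            raise AlignmentError("alignment length not divisible by 3")
        for r in self.rows:
            for j in range(0, length, 3):
                codon = r[j : j + 3]
                if "-" in codon and codon != "---":
                    raise AlignmentError("gap not aligned to a whole codon")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon_column(self, k: int) -> tuple[str, ...]:
        """The k-th codon (triplet) of every row, gaps included."""
        return tuple(r[3 * k : 3 * k + 3] for r in self.rows)


def _strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def _expand_protein_gaps(cds: str, aligned_protein: str) -> str:
    """Back-translate a gapped protein row to a codon-gapped CDS row."""
    out = []
    pos = 0
    for ch in aligned_protein:
        if ch == "-":
            out.append("---")
        else:
            out.append(cds[pos : pos + 3])
            pos += 3
    if pos != len(cds):
        raise AlignmentError("protein row does not cover the CDS")
    return "".join(out)


def codon_align(cds_set: Sequence[tuple[str, str]]) -> CodonAlignment:
    """Codon-aware multiple alignment of CDSs.

    ``cds_set`` is a sequence of ``(id, cds)`` pairs. When all CDSs encode
    the identical protein and have equal length — the typical case for
    duplicate genes with an invariant product — the alignment is the inputs
    stacked verbatim, gap-free. Otherwise proteins are globally aligned
    (pairwise to the first sequence, insertions merged by reference
    position) and gaps are back-translated into whole-codon triplets.

    Terminal stop codons are kept as a final column when every input has
    one; if the inputs disagree, stops are stripped before aligning.
    """
    if len(cds_set) < 2:
        raise AlignmentError("codon_align needs at least two CDSs")
    ids = [str(i) for i, _ in cds_set]
    raw = [c.upper() for _, c in cds_set]
    proteins = [translate(c) for c in raw]  # validates; raises on internal stop

    has_stop = [len(c) >= 3 and c[-3:] in STOP_CODONS for c in raw]
    if all(has_stop) or not any(has_stop):
        seqs = list(raw)
    else:
        seqs = [_strip_terminal_stop(c) for c in raw]

    if len(set(proteins)) == 1 and len({len(s) for s in seqs}) == 1:
        return CodonAlignment(ids=tuple(ids), rows=tuple(seqs))

    # Sense portions only (stop has no residue to guide it in mixed cases).
    sense = [_strip_terminal_stop(c) for c in raw]
    ref_protein = proteins[0]

    # Align every other protein to the reference; record, per reference
    # position k (0..len(ref)), the residues each sequence inserts before it.
    n = len(cds_set)
    inserts: list[dict[int, str]] = [dict() for _ in range(n)]
    ref_cols: list[list[str | None]] = [[None] * len(ref_protein) for _ in range(n)]
    ref_cols[0] = list(ref_protein)
    for i in range(1, n):
        aln = global_align(ref_protein, proteins[i], protein=True)
        k = 0  # reference position
        pending = []
        for ca, cb in aln.columns():
            if ca == "-":
                pending.append(cb)
                continue
            if pending:
                inserts[i][k] = "".join(pending)
                pending = []
            ref_cols[i][k] = None if cb == "-" else cb
            k += 1
        if pending:
            inserts[i][k] = "".join(pending)

    ins_len = {
        k: max(len(ins.get(k, "")) for ins in inserts)
        for k in range(len(ref_protein) + 1)
    }

    aligned_proteins = []
    for i in range(n):
        row = []
        for k in range(len(ref_protein) + 1):
            block = inserts[i].get(k, "")
            row.append(block.ljust(ins_len[k], "-"))
            if k < len(ref_protein):
                row.append(ref_cols[i][k] or "-")
        aligned_proteins.append("".join(row))

    rows = [
        _expand_protein_gaps(sense[i], aligned_proteins[i]) for i in range(n)
    ]
    if all(has_stop):
        rows = [rows[i] + raw[i][-3:] for i in range(n)]
    return CodonAlignment(ids=tuple(ids), rows=tuple(rows))
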