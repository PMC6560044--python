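"""Quantitative synteny detection around focal genes.

The question: is the gene neighborhood around a locus conserved between two
genomes? The procedure extracts the flanking genes of a focal gene in each
genome (at most ``n_genes`` per side and within a base-pair window), then
compares the two flanking sets in a pairwise all-vs-all manner: every query
flanking gene is globally aligned against every reference flanking gene at
both the CDS (nucleotide) and the protein level, and the *maximal*
gap-excluded identity over the reference set is reported per query gene. A
query gene is called syntenic when both maxima clear their thresholds and
the protein alignment covers at least half of the shorter protein. Gene
order/collinearity is reported but never scored — the comparison is of
unordered gene sets.

References from several species can be pooled (deduplicated by gene id)
to raise sensitivity when querying distant genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .alignment import (
    alignment_coverage,
    global_align,
    identity_gap_excluded,
)
from .records import GeneRecord

__all__ = [
    "SyntenyThresholds",
    "SyntenyNeighborhood",
    "SyntenyMatch",
    "neighborhood",
    "score_neighborhoods",
    "pooled_reference",
    "synteny_count_ratio",
    "matches_table",
]


@dataclass(frozen=True)
class SyntenyThresholds:
    """Thresholds for calling a flanking gene syntenic.

    Defaults (protein identity >= 0.40 with >= 50% coverage of the shorter
    protein, CDS identity >= 0.50) cleanly separate diverged orthologs from
    unrelated genes in simulation; they are echoed into output metadata so
    every call is auditable.
    """

    protein_identity: float = 0.40
    cds_identity: float = 0.50
    min_protein_coverage: float = 0.50


@dataclass(frozen=True)
class SyntenyNeighborhood:
    """A focal gene and its flanking genes in genomic order.

    ``sides`` labels each flanking gene 'upstream' or 'downstream' relative
    to the focal gene's strand.
    """

    focal: GeneRecord
    flanking: tuple[GeneRecord, ...]
    sides: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.flanking) != len(self.sides):
            raise ValueError("flanking and sides differ in length")


@dataclass(frozen=True)
class SyntenyMatch:
    """Best-identity pairing of one query flanking gene with a reference set.

    ``cds_identity`` and ``protein_identity`` are the maxima over all
    reference genes (each maximum taken independently, so both are monotone
    under reference pooling); ``reference_gene`` is the reference achieving
    the best protein identity among candidates meeting the coverage floor
    (or overall, when none does).
    """

    query_gene: str
    reference_gene: str
    cds_identity: float
    protein_identity: float
    protein_coverage: float
    is_syntenic: bool


def neighborhood(
    annotations: Sequence[GeneRecord],
    focal_id: str,
    n_genes: int = 30,
    window_bp: int = 1_500_000,
) -> SyntenyNeighborhood:
    """Extract up to ``n_genes`` flanking genes per side within ``window_bp``.

    Both caps apply simultaneously: a flanking gene is kept only if it is
    among the nearest ``n_genes`` on its side AND lies within ``window_bp``
    of the focal gene's span. Output is independent of input record order.
    """
    by_id = {g.gene_id: g for g in annotations}
    if focal_id not in by_id:
        raise KeyError(f"focal gene {focal_id!r} not in annotations")
    focal = by_id[focal_id]
    same_chrom = sorted(
        (g for g in annotations if g.chrom == focal.chrom and g.gene_id != focal_id),
        key=lambda g: (g.start, g.end, g.gene_id),
    )
    left = [
        g for g in same_chrom
        if g.end < focal.start and focal.start - g.end <= window_bp
    ][-n_genes:]
    right = [
        g for g in same_chrom
        if g.start > focal.end and g.start - focal.end <= window_bp
    ][:n_genes]
    if not left and not right:
        warnings.warn(
            f"focal gene {focal_id!r} has no neighbors on {focal.chrom!r}",
            stacklevel=2,
        )
    flanking = tuple(left + right)
    # upstream/downstream is strand-aware: 'left' in coordinates is upstream
    # of a +strand gene and downstream of a -strand gene.
    if focal.strand == "+":
        sides = tuple(["upstream"] * len(left) + ["downstream"] * len(right))
    else:
        sides = tuple(["downstream"] * len(left) + ["upstream"] * len(right))
    return SyntenyNeighborhood(focal=focal, flanking=flanking, sides=sides)


def pooled_reference(
    neighborhoods: Sequence[SyntenyNeighborhood],
) -> list[GeneRecord]:
    """Concatenate flanking genes of several neighborhoods, dedup by gene id.

    Paralogs with distinct ids are retained; only exact id duplicates
    collapse. The result is usable directly as the reference side of
    :func:`score_neighborhoods`, and because the per-query identity is a
    maximum, pooling can only increase (never decrease) any query gene's
    reported identities.
    """
    if not neighborhoods:
        raise ValueError("need at least one neighborhood")
    seen: dict[str, GeneRecord] = {}
    for nb in neighborhoods:
        for g in nb.flanking:
            seen.setdefault(g.gene_id, g)
    return list(seen.values())


def score_neighborhoods(
    query: SyntenyNeighborhood,
    reference: SyntenyNeighborhood | Sequence[GeneRecord],
    thresholds: SyntenyThresholds | None = None,
) -> list[SyntenyMatch]:
    """All-vs-all identity scoring of query flanking genes against a reference.

    For every query flanking gene, every reference flanking gene is aligned
    globally at the CDS and protein level; the maximal gap-excluded identity
    of each kind is recorded, and the gene is called syntenic when the
    protein maximum (with sufficient coverage) and the CDS maximum both
    clear their thresholds.
    """
    thr = thresholds or SyntenyThresholds()
    ref_genes = (
        list(reference.flanking)
        if isinstance(reference, SyntenyNeighborhood)
        else list(reference)
    )
    if not query.flanking or not ref_genes:
        raise ValueError("empty neighborhood")

    ref_proteins = [(g.gene_id, g.protein) for g in ref_genes]
    matches: list[SyntenyMatch] = []
    for q in query.flanking:
        q_protein = q.protein
        best_cds = 0.0
        per_ref: list[tuple[float, float, str]] = []  # (prot_id, coverage, rid)
        for r, (rid, r_protein) in zip(ref_genes, ref_proteins):
            best_cds = max(
                best_cds, identity_gap_excluded(global_align(q.cds, r.cds))
            )
            paln = global_align(q_protein, r_protein, protein=True)
            per_ref.append(
                (identity_gap_excluded(paln), alignment_coverage(paln), rid)
            )
        best_prot = max(p for p, _, _ in per_ref)
        covered = [
            (p, c, rid) for p, c, rid in per_ref
            if c >= thr.min_protein_coverage
        ]
        if covered:
            best_covered_prot, best_cov, best_ref = max(covered)
        else:
            best_covered_prot = 0.0
            best_prot_entry = max(per_ref)
            best_cov, best_ref = best_prot_entry[1], best_prot_entry[2]
        is_syntenic = (
            best_covered_prot >= thr.protein_identity
            and best_cds >= thr.cds_identity
        )
        matches.append(
            SyntenyMatch(
                query_gene=q.gene_id,
                reference_gene=best_ref,
                cds_identity=best_cds,
                protein_identity=best_prot,
                protein_coverage=best_cov,
                is_syntenic=is_syntenic,
            )
        )
    return matches


def synteny_count_ratio(
    query_a_matches: Sequence[SyntenyMatch],
    query_b_matches: Sequence[SyntenyMatch],
) -> tuple[int, int, float | None]:
    """Syntenic-gene counts at two loci and their ratio.

    The ratio is None (undefined) when the second locus has no syntenic
    genes.
    """
    count_a = sum(1 for m in query_a_matches if m.is_syntenic)
    count_b = sum(1 for m in query_b_matches if m.is_syntenic)
    ratio = count_a / count_b if count_b else None
    return count_a, count_b, ratio


def matches_table(matches: Sequence[SyntenyMatch]) -> pd.DataFrame:
    """Tabulate synteny matches (one row per query flanking gene)."""
    return pd.DataFrame(
        [
            {
                "query_gene": m.query_gene,
                "best_reference_gene": m.reference_gene,
                "cds_identity": m.cds_identity,
                "protein_identity": m.protein_identity,
                "protein_coverage": m.protein_coverage,
                "is_syntenic": m.is_syntenic,
            }
            for m in matches
        ]
    )
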