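"""Nucleotide-level selection analysis for genes with an invariant protein.

When duplicate genes encode exactly the same protein, dN/dS-style tests are
powerless (dN is undefined), but selection can still be read off the
*synonymous* sites directly:

* the **nucleotide substitution score** — observed substitutions divided by
  CDS length — is a raw genetic distance between orthologous CDSs;
* **absolutely conserved** wobble and fourfold degenerate sites (third codon
  positions where substitutions would be synonymous, hence invisible to
  protein-level selection) quantify purifying selection on codon identity:
  a fourfold site conserved across a whole clade is conserved *despite*
  every substitution there being neutral at the protein level;
* the ratio of such conservation frequencies between two paralogs
  (``freq_ratio``) measures which copy is under stronger synonymous-site
  selection;
* **GC3**, the G+C fraction at third positions, is a composition summary
  that tracks codon-usage regime.

Group comparisons of score distributions use the Mann–Whitney rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import CodonAlignment, codon_align
from .genetic_code import STOP_CODONS, degeneracy, translate, validate_cds

__all__ = [
    "DistanceMatrix",
    "SiteClassification",
    "ConservationReport",
    "RankSumResult",
    "substitution_score",
    "distance_matrix",
    "classify_sites",
    "conserved_report",
    "freq_ratio",
    "gc3",
    "rank_sum_test",
]

SiteClass = Literal["third_position", "wobble", "fourfold"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise nucleotide substitution scores."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long(self, group: str = "") -> pd.DataFrame:
        """Long-format upper-triangle table (id_a, id_b, group, score)."""
        records = []
        for i, a in enumerate(self.ids):
            for j in range(i + 1, len(self.ids)):
                records.append((a, self.ids[j], group, self.values[i, j]))
        return pd.DataFrame(records, columns=["id_a", "id_b", "group", "score"])

    def offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


@dataclass(frozen=True)
class SiteClassification:
    """Per-column site classes of a codon alignment.

    Arrays are indexed by alignment column. ``valid`` is False for columns
    whose codon contains a gap in any row or is a stop codon in any row;
    such columns are excluded from all conservation counts. ``is_wobble``
    marks third positions where the codon of *every* row tolerates at least
    one synonymous substitution (fold >= 2); ``is_fourfold`` marks third
    positions fourfold degenerate in every row.
    """

    codon_position: np.ndarray  # int, 1/2/3
    valid: np.ndarray  # bool
    is_wobble: np.ndarray  # bool
    is_fourfold: np.ndarray  # bool

    def mask(self, site_class: SiteClass) -> np.ndarray:
        if site_class == "third_position":
            return self.valid & (self.codon_position == 3)
        if site_class == "wobble":
            return self.valid & self.is_wobble
        if site_class == "fourfold":
            return self.valid & self.is_fourfold
        raise ValueError(f"unknown site class: {site_class!r}")


@dataclass(frozen=True)
class ConservationReport:
    """Absolutely conserved site counts for one group and site class."""

    group_name: str
    site_class: str
    conserved_count: int
    total_sites: int

    @property
    def frequency(self) -> float | None:
        """Fraction of sites absolutely conserved; None when total is 0."""
        if self.total_sites == 0:
            return None
        return self.conserved_count / self.total_sites


@dataclass(frozen=True)
class RankSumResult:
    """Mann–Whitney U test result."""

    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str


def substitution_score(
    cds_a: str,
    cds_b: str,
    denominator: Literal["gap_free", "min_length", "mean_length"] = "gap_free",
) -> float:
    """Observed substitutions per site between two CDSs.

    The CDSs are codon-aligned first; the score is the number of
    mismatching gap-free columns divided by the number of gap-free columns.
    For equal-length CDSs encoding the same protein (the focal case) the
    denominator is simply the CDS length; under indels the alternative
    normalisations by the shorter or the mean CDS length are available.
    """
    aln = codon_align([("a", cds_a), ("b", cds_b)])
    ra, rb = aln.rows
    n = m = 0
    for ca, cb in zip(ra, rb):
        if ca == "-" or cb == "-":
            continue
        n += 1
        if ca != cb:
            m += 1
    if n == 0:
        raise ValueError("no gap-free columns between the CDSs")
    if denominator == "min_length":
        n = min(len(cds_a), len(cds_b))
    elif denominator == "mean_length":
        n = (len(cds_a) + len(cds_b)) / 2.0
    elif denominator != "gap_free":
        raise ValueError(f"unknown denominator: {denominator!r}")
    return m / n


def distance_matrix(genes: Sequence[tuple[str, str]]) -> DistanceMatrix:
    """All pairwise substitution scores for ``(id, cds)`` pairs."""
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    ids = tuple(str(i) for i, _ in genes)
    n = len(genes)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = substitution_score(genes[i][1], genes[j][1])
            values[i, j] = values[j, i] = s
    return DistanceMatrix(ids=ids, values=values)


def classify_sites(aln: CodonAlignment) -> SiteClassification:
    """Classify every column of a codon alignment.

    A third-position column is fourfold iff the containing codon is fourfold
    degenerate at position 3 in EVERY row — "any possible substitution is
    synonymous" must hold in all organisms counted. Codon columns containing
    a gap or a stop codon in any row are marked invalid.
    """
    length = aln.length
    codon_position = np.tile([1, 2, 3], length // 3)
    valid = np.ones(length, dtype=bool)
    is_wobble = np.zeros(length, dtype=bool)
    is_fourfold = np.zeros(length, dtype=bool)
    for k in range(aln.n_codons):
        codons = aln.codon_column(k)
        cols = slice(3 * k, 3 * k + 3)
        if any("-" in c for c in codons) or any(c in STOP_CODONS for c in codons):
            valid[cols] = False
            continue
        folds = [degeneracy(c, 3).fold for c in codons]
        third = 3 * k + 2
        is_wobble[third] = min(folds) >= 2
        is_fourfold[third] = min(folds) == 4
    return SiteClassification(
        codon_position=codon_position,
        valid=valid,
        is_wobble=is_wobble,
        is_fourfold=is_fourfold,
    )


def conserved_report(
    aln: CodonAlignment,
    site_class: SiteClass,
    group_name: str = "",
    classification: SiteClassification | None = None,
) -> ConservationReport:
    """Count absolutely conserved sites of one class.

    A site is absolutely conserved when every row of the alignment carries
    the identical nucleotide at that column. A report with ``total_sites``
    of zero carries an undefined (None) frequency rather than a silent 0.
    """
    cls = classification if classification is not None else classify_sites(aln)
    mask = cls.mask(site_class)
    total = int(mask.sum())
    if total == 0:
        warnings.warn(
            f"no sites of class {site_class!r} in alignment for {group_name!r}",
            stacklevel=2,
        )
        return ConservationReport(group_name, site_class, 0, 0)
    cols = np.flatnonzero(mask)
    conserved = sum(
        1 for j in cols if len({row[j] for row in aln.rows}) == 1
    )
    return ConservationReport(group_name, site_class, conserved, total)


def freq_ratio(report_a: ConservationReport, report_b: ConservationReport) -> float:
    """Ratio of absolutely-conserved-site frequencies between two reports.

    The conventional reading is report_a = the more constrained paralog
    (e.g. H3F3A) and report_b = the other (H3F3B); a ratio above 1 means
    stronger synonymous-site conservation in A.
    """
    fa, fb = report_a.frequency, report_b.frequency
    if fa is None or fb is None:
        raise ValueError("frequency undefined (zero total sites)")
    if fb == 0:
        raise ZeroDivisionError("report_b has zero conserved frequency")
    return fa / fb


def gc3(cds: str) -> float:
    """G+C fraction at third codon positions (terminal stop excluded)."""
    seq = validate_cds(cds)
    translate(seq)  # validates: internal stops rejected
    if seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
    if not seq:
        raise ValueError("CDS contains only a stop codon")
    thirds = seq[2::3]
    return sum(1 for b in thirds if b in "GC") / len(thirds)


def rank_sum_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: Literal["two-sided", "less", "greater"] = "two-sided",
) -> RankSumResult:
    """Mann–Whitney U test of two score distributions.

    The exact null distribution is used when the smaller group has at most
    8 observations and there are no ties; otherwise the tie-corrected
    normal approximation (with continuity correction) is applied. When all
    values are identical across both groups the test is degenerate and
    p = 1 is returned with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; rank-sum test is degenerate",
                      stacklevel=2)
        return RankSumResult(
            u_statistic=a.size * b.size / 2.0, p_value=1.0,
            n_a=a.size, n_b=b.size, method="degenerate",
        )
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return RankSumResult(
        u_statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
        n_a=a.size, n_b=b.size, method=method,
    )


def conservation_table(reports: Sequence[tuple[ConservationReport, ConservationReport]]) -> pd.DataFrame:
    """Tabulate paired (paralog A, paralog B) reports with their ratio.

    One row per (group, site class): conserved and total counts and
    frequencies for both paralogs, plus the A/B frequency ratio.
    """
    rows = []
    for ra, rb in reports:
        ratio = None
        if ra.frequency is not None and rb.frequency not in (None, 0):
            ratio = ra.frequency / rb.frequency
        rows.append({
            "group": ra.group_name,
            "site_class": ra.site_class,
            "conserved_a": ra.conserved_count,
            "total_a": ra.total_sites,
            "freq_a": ra.frequency,
            "conserved_b": rb.conserved_count,
            "total_b": rb.total_sites,
            "freq_b": rb.frequency,
            "freq_ratio_a_over_b": ratio,
        })
    return pd.DataFrame(rows)
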