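"""Codon-usage metrics, profiles, and transcriptional-program benchmarking.

Two codon-usage metrics are supported:

* ``aa_specific`` — amino-acid-specific codon frequencies: each codon's count
  divided by the count of its amino acid, i.e. the conditional probability
  that a codon is used given its amino acid appears in the protein. This
  corrects for amino-acid composition; codons of amino acids absent from a
  gene are *undefined* (a conditional probability with no conditioning
  events), not zero.
* ``raw_frequency`` — codon occurrences divided by the total codon count of
  the gene.

Profiles are built per gene, per gene set (pooled counts), or genome-wide
(from a Kazusa-style codon usage table). Pearson correlation between
profiles is the similarity measure; a gene's codon usage is benchmarked
against transcriptional-program profiles (e.g. proliferation- vs
differentiation-induced gene sets) by correlating it with each pooled
profile and placing it within the distribution of the programs' own member
genes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import (
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    synonymous_codons,
    translate,
    validate_cds,
)

__all__ = [
    "Metric",
    "CodonUsageProfile",
    "CorrelationResult",
    "ProgramBenchmark",
    "codon_counts",
    "raw_frequencies",
    "aa_specific_frequencies",
    "group_profile",
    "profile_correlation",
    "benchmark_gene",
]

Metric = Literal["aa_specific", "raw_frequency"]

#: Amino acids with a single codon; their aa_specific frequency is the
#: constant 1 and is excluded from aa_specific correlations by default.
SINGLE_CODON_AAS = frozenset(
    aa for aa in set(CODON_TO_AA.values()) if len(synonymous_codons(aa)) == 1
)
_DEGENERATE_CODONS = frozenset(
    c for c in SENSE_CODONS if CODON_TO_AA[c] not in SINGLE_CODON_AAS
)

#: Stable codon ordering used for vectors and tables.
CODON_ORDER: tuple[str, ...] = tuple(sorted(SENSE_CODONS))


def codon_counts(cds: str) -> Counter[str]:
    """Sense-codon occurrence counts of a CDS (terminal stop excluded)."""
    seq = validate_cds(cds)
    translate(seq)  # rejects internal stops
    if seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
    return Counter(seq[i : i + 3] for i in range(0, len(seq), 3))


@dataclass(frozen=True)
class CodonUsageProfile:
    """Per-codon usage vector under one metric, with raw counts retained.

    ``frequencies`` maps codons to values; under ``aa_specific`` codons of
    absent amino acids are simply missing (undefined), under
    ``raw_frequency`` every sense codon is present and the values sum to 1.
    """

    metric: Metric
    counts: Mapping[str, int]
    frequencies: Mapping[str, float]
    source: str = ""

    def defined_codons(self) -> frozenset[str]:
        return frozenset(self.frequencies)

    def vector(self, codons: Sequence[str]) -> np.ndarray:
        return np.array([self.frequencies[c] for c in codons])

    def to_series(self) -> pd.Series:
        return pd.Series(
            {c: self.frequencies.get(c, np.nan) for c in CODON_ORDER},
            name=self.source,
        )


def _check_counts(counts: Mapping[str, int]) -> dict[str, int]:
    clean = {c: int(n) for c, n in counts.items() if n}
    if not clean:
        raise ValueError("empty codon counts")
    bad = set(clean) - SENSE_CODONS
    if bad:
        raise ValueError(f"non-sense codons in counts: {sorted(bad)}")
    return clean


def raw_frequencies(counts: Mapping[str, int], source: str = "") -> CodonUsageProfile:
    """Codon frequencies: counts divided by the gene's total codon count."""
    clean = _check_counts(counts)
    total = sum(clean.values())
    freqs = {c: clean.get(c, 0) / total for c in SENSE_CODONS}
    return CodonUsageProfile("raw_frequency", clean, freqs, source)


def aa_specific_frequencies(counts: Mapping[str, int], source: str = "") -> CodonUsageProfile:
    """Amino-acid-specific codon frequencies.

    Each codon count is divided by the total count of its amino acid.
    Codons of amino acids that never occur are left undefined.
    """
    clean = _check_counts(counts)
    aa_totals: Counter[str] = Counter()
    for codon, n in clean.items():
        aa_totals[CODON_TO_AA[codon]] += n
    freqs = {
        c: clean.get(c, 0) / aa_totals[CODON_TO_AA[c]]
        for c in SENSE_CODONS
        if CODON_TO_AA[c] in aa_totals
    }
    return CodonUsageProfile("aa_specific", clean, freqs, source)


def profile_from_counts(
    counts: Mapping[str, int], metric: Metric, source: str = ""
) -> CodonUsageProfile:
    if metric == "aa_specific":
        return aa_specific_frequencies(counts, source)
    if metric == "raw_frequency":
        return raw_frequencies(counts, source)
    raise ValueError(f"unknown metric: {metric!r}")


def group_profile(
    genes: Sequence[Mapping[str, int]], metric: Metric, source: str = ""
) -> CodonUsageProfile:
    """Pooled-count profile of a gene set.

    Counts are summed across genes before normalisation (a pooled profile,
    not a mean of per-gene profiles), so long genes weigh proportionally to
    their codon count.
    """
    if not genes:
        raise ValueError("empty gene set")
    pooled: Counter[str] = Counter()
    for g in genes:
        pooled.update(g)
    return profile_from_counts(pooled, metric, source)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two codon-usage profiles."""

    r: float
    n_codons: int
    profile_a: str = ""
    profile_b: str = ""


def default_codon_filter(metric: Metric) -> frozenset[str]:
    """Codons retained in correlation vectors by default.

    Under ``aa_specific`` the single-codon amino acids (Met, Trp) are
    excluded: their frequency is the constant 1 in every gene and would
    inflate r. Under ``raw_frequency`` all 61 sense codons are retained.
    """
    if metric == "aa_specific":
        return _DEGENERATE_CODONS
    return SENSE_CODONS


def profile_correlation(
    p_a: CodonUsageProfile,
    p_b: CodonUsageProfile,
    codon_filter: frozenset[str] | None = None,
) -> CorrelationResult:
    """Pearson correlation over the shared, defined codon dimensions.

    Codons undefined in either profile (absent amino acids under
    ``aa_specific``) are dropped pairwise rather than imputed as zero.
    Requires at least 3 shared dimensions and nonzero variance in both
    vectors.
    """
    if p_a.metric != p_b.metric:
        raise ValueError(
            f"metric mismatch: {p_a.metric!r} vs {p_b.metric!r}"
        )
    keep = codon_filter if codon_filter is not None else default_codon_filter(p_a.metric)
    shared = sorted(p_a.defined_codons() & p_b.defined_codons() & keep)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared codon dimensions")
    va, vb = p_a.vector(shared), p_b.vector(shared)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("zero variance in a profile vector")
    r, _ = stats.pearsonr(va, vb)
    return CorrelationResult(
        r=float(r), n_codons=len(shared),
        profile_a=p_a.source, profile_b=p_b.source,
    )


@dataclass(frozen=True)
class ProgramBenchmark:
    """Benchmark of one gene's codon usage against program profiles.

    ``r_by_program`` holds the gene's correlation with each program's pooled
    profile; ``benchmark_own``/``benchmark_opposite`` the distributions of
    each program's member genes correlated with their own (leave-one-out)
    and the opposite group profile; ``percentile_by_program`` the focal
    gene's rank percentile within each own-group benchmark distribution.
    """

    gene_id: str
    r_by_program: dict[str, float]
    r_genomewide: float | None
    assignment: str | None
    ambiguous: bool
    percentile_by_program: dict[str, float]
    benchmark_own: dict[str, list[float]] = field(default_factory=dict)
    benchmark_opposite: dict[str, list[float]] = field(default_factory=dict)


def _percentile_of(value: float, distribution: Sequence[float]) -> float:
    if not distribution:
        return math.nan
    return 100.0 * float(np.mean([d <= value for d in distribution]))


def benchmark_gene(
    gene_counts: Mapping[str, int],
    program_gene_counts: Mapping[str, Sequence[Mapping[str, int]]],
    genomewide_profile: CodonUsageProfile | None = None,
    *,
    metric: Metric = "aa_specific",
    codon_filter: frozenset[str] | None = None,
    gene_id: str = "focal",
    member_of: str | None = None,
    leave_one_out: bool = True,
    compute_benchmarks: bool = True,
) -> ProgramBenchmark:
    """Assign a gene to the transcriptional program its codon usage matches.

    Parameters
    ----------
    gene_counts
        Codon counts of the focal gene.
    program_gene_counts
        Program name -> list of member-gene codon counts (e.g.
        ``{"proliferation": [...], "differentiation": [...]}``).
    genomewide_profile
        Optional genome-wide profile to correlate against as well.
    member_of
        Name of the program the focal gene belongs to, if any; with
        ``leave_one_out`` its own counts are removed from that program's
        pooled profile to avoid self-correlation bias.

    The assignment is the program whose pooled profile correlates best with
    the focal gene; if the top correlations are indistinguishable the
    result is flagged ambiguous. Benchmark distributions correlate every
    program member with its own (leave-one-out) and the opposite group
    profile, and the focal gene's percentile within each own-group
    distribution is reported.
    """
    if len(program_gene_counts) < 2:
        raise ValueError("need at least two program gene sets")
    programs = list(program_gene_counts)

    totals: dict[str, Counter[str]] = {}
    for name in programs:
        pooled: Counter[str] = Counter()
        for g in program_gene_counts[name]:
            pooled.update(g)
        if not pooled:
            raise ValueError(f"program {name!r} has no codon counts")
        totals[name] = pooled

    def pooled_profile(name: str, exclude: Mapping[str, int] | None = None) -> CodonUsageProfile:
        counts = totals[name]
        if exclude is not None and leave_one_out:
            counts = counts - Counter(exclude)
            if not counts:
                raise ValueError(f"program {name!r} empty after leave-one-out")
        return profile_from_counts(counts, metric, source=name)

    focal = profile_from_counts(gene_counts, metric, source=gene_id)
    r_by_program: dict[str, float] = {}
    for name in programs:
        prof = pooled_profile(name, exclude=gene_counts if member_of == name else None)
        r_by_program[name] = profile_correlation(focal, prof, codon_filter).r

    r_gw = None
    if genomewide_profile is not None:
        r_gw = profile_correlation(focal, genomewide_profile, codon_filter).r

    benchmark_own: dict[str, list[float]] = {}
    benchmark_opposite: dict[str, list[float]] = {}
    if compute_benchmarks:
        full = {name: pooled_profile(name) for name in programs}
        for name in programs:
            others = [p for p in programs if p != name]
            own: list[float] = []
            opp: list[float] = []
            for member in program_gene_counts[name]:
                mprof = profile_from_counts(member, metric, source="member")
                own.append(
                    profile_correlation(
                        mprof, pooled_profile(name, exclude=member), codon_filter
                    ).r
                )
                for other in others:
                    opp.append(
                        profile_correlation(mprof, full[other], codon_filter).r
                    )
            benchmark_own[name] = own
            benchmark_opposite[name] = opp

    best = max(r_by_program.values())
    top = [name for name, r in r_by_program.items() if math.isclose(r, best)]
    ambiguous = len(top) > 1
    assignment = None if ambiguous else top[0]

    percentile = {
        name: _percentile_of(r_by_program[name], benchmark_own.get(name, []))
        for name in programs
    }
    return ProgramBenchmark(
        gene_id=gene_id,
        r_by_program=r_by_program,
        r_genomewide=r_gw,
        assignment=assignment,
        ambiguous=ambiguous,
        percentile_by_program=percentile,
        benchmark_own=benchmark_own,
        benchmark_opposite=benchmark_opposite,
    )
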