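"""Codon-usage metrics, profiles, correlations and program benchmarking."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synsel.codon_usage import (
    CodonUsageProfile,
    aa_specific_frequencies,
    benchmark_gene,
    codon_counts,
    default_codon_filter,
    group_profile,
    profile_correlation,
    profile_from_counts,
    raw_frequencies,
)
from synsel.genetic_code import CODON_TO_AA, SENSE_CODONS, synonymous_codons


class TestCodonCounts:
    def test_hand_count(self):
        assert codon_counts("ATGGCTGCCGCT") == {"ATG": 1, "GCT": 2, "GCC": 1}

    def test_single_codon(self):
        assert codon_counts("ATG") == {"ATG": 1}

    def test_terminal_stop_dropped(self):
        assert codon_counts("ATGTAA") == {"ATG": 1}

    def test_internal_stop_rejected(self):
        with pytest.raises(Exception):
            codon_counts("ATGTAAGCT")


class TestRawFrequencies:
    def test_hand_arithmetic(self):
        prof = raw_frequencies({"ATG": 1, "GCT": 2, "GCC": 1})
        assert prof.frequencies["GCT"] == pytest.approx(0.5)
        assert prof.frequencies["ATG"] == pytest.approx(0.25)
        assert sum(prof.frequencies.values()) == pytest.approx(1.0)

    def test_single_codon_gene(self):
        prof = raw_frequencies({"ATG": 3})
        assert prof.frequencies["ATG"] == 1.0

    def test_pooling_equals_concatenation(self):
        a, b = codon_counts("ATGGCTGCC"), codon_counts("GCTAAAAAG")
        pooled = group_profile([a, b], "raw_frequency")
        concat = raw_frequencies(codon_counts("ATGGCTGCC" + "GCTAAAAAG"))
        for c in SENSE_CODONS:
            assert pooled.frequencies[c] == pytest.approx(concat.frequencies[c])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            raw_frequencies({})


class TestAaSpecificFrequencies:
    def test_hand_arithmetic(self):
        prof = aa_specific_frequencies({"ATG": 1, "GCT": 2, "GCC": 1})
        assert prof.frequencies["GCT"] == pytest.approx(2 / 3)
        assert prof.frequencies["GCC"] == pytest.approx(1 / 3)
        assert prof.frequencies["GCA"] == 0.0
        assert prof.frequencies["GCG"] == 0.0
        assert prof.frequencies["ATG"] == 1.0

    def test_absent_amino_acid_is_undefined_not_zero(self):
        prof = aa_specific_frequencies({"ATG": 1, "GCT": 1})
        assert "AAA" not in prof.frequencies
        assert "AAG" not in prof.frequencies

    def test_sums_to_one_per_present_amino_acid(self, rng):
        from synsel.synthetic import sample_protein, sample_gene
        cds = sample_gene(sample_protein(rng, 120), None, 0.0, rng)
        prof = aa_specific_frequencies(codon_counts(cds))
        present = {CODON_TO_AA[c] for c in prof.frequencies}
        for aa in present:
            total = sum(
                prof.frequencies[c]
                for c in synonymous_codons(aa)
                if c in prof.frequencies
            )
            assert total == pytest.approx(1.0)
        assert all(0 <= v <= 1 for v in prof.frequencies.values())


_counts = st.dictionaries(
    st.sampled_from(sorted(SENSE_CODONS)),
    st.integers(min_value=1, max_value=500),
    min_size=1,
    max_size=30,
)


@settings(derandomize=True, max_examples=80, deadline=None)
@given(_counts)
def test_normalisation_identities_hold_for_arbitrary_counts(counts):
    """Raw frequencies sum to 1 overall; aa-specific frequencies sum to 1
    within every present amino acid and lie in [0, 1]."""
    raw = raw_frequencies(counts)
    assert sum(raw.frequencies.values()) == pytest.approx(1.0)
    aa_prof = aa_specific_frequencies(counts)
    present = {CODON_TO_AA[c] for c in counts}
    assert {CODON_TO_AA[c] for c in aa_prof.frequencies} == present
    for aa in present:
        total = sum(
            v for c, v in aa_prof.frequencies.items() if CODON_TO_AA[c] == aa
        )
        assert total == pytest.approx(1.0)
    assert all(0.0 <= v <= 1.0 for v in aa_prof.frequencies.values())


class TestGroupProfile:
    def test_single_gene_equals_gene_profile(self):
        counts = codon_counts("ATGGCTGCCAAA")
        single = group_profile([counts], "aa_specific")
        direct = aa_specific_frequencies(counts)
        assert single.frequencies == direct.frequencies

    def test_duplicate_gene_leaves_profile_unchanged(self):
        counts = codon_counts("ATGGCTGCCAAA")
        once = group_profile([counts], "aa_specific")
        twice = group_profile([counts, counts], "aa_specific")
        for c, v in once.frequencies.items():
            assert twice.frequencies[c] == pytest.approx(v)

    def test_disjoint_amino_acids_union(self):
        a = {"GCT": 2}   # Ala only
        b = {"AAA": 3}   # Lys only
        prof = group_profile([a, b], "aa_specific")
        assert prof.frequencies["GCT"] == 1.0
        assert prof.frequencies["AAA"] == 1.0
        assert "TTT" not in prof.frequencies


class TestProfileCorrelation:
    def test_self_correlation_is_one(self, rng):
        from synsel.synthetic import sample_protein, sample_gene
        cds = sample_gene(sample_protein(rng, 100), None, 0.0, rng)
        prof = aa_specific_frequencies(codon_counts(cds))
        assert profile_correlation(prof, prof).r == pytest.approx(1.0)

    def test_anti_profile_on_twofold_families_is_minus_one(self):
        """1-p on the twofold amino acids correlates at exactly -1."""
        twofold = [
            aa for aa in {CODON_TO_AA[c] for c in SENSE_CODONS}
            if len(synonymous_codons(aa)) == 2
        ]
        rng = np.random.default_rng(0)
        freqs, anti = {}, {}
        counts = {}
        for aa in twofold:
            c1, c2 = sorted(synonymous_codons(aa))
            p = float(rng.uniform(0.05, 0.95))
            freqs[c1], freqs[c2] = p, 1 - p
            anti[c1], anti[c2] = 1 - p, p
            counts[c1] = counts[c2] = 1
        pa = CodonUsageProfile("aa_specific", counts, freqs, "p")
        pb = CodonUsageProfile("aa_specific", counts, anti, "1-p")
        res = profile_correlation(pa, pb)
        assert res.r == pytest.approx(-1.0)

    def test_symmetric_and_order_invariant(self, rng):
        from synsel.synthetic import sample_protein, sample_gene
        c1 = sample_gene(sample_protein(rng, 100), None, 0.0, rng)
        c2 = sample_gene(sample_protein(rng, 100), None, 0.0, rng)
        pa = aa_specific_frequencies(codon_counts(c1))
        pb = aa_specific_frequencies(codon_counts(c2))
        assert profile_correlation(pa, pb).r == pytest.approx(
            profile_correlation(pb, pa).r
        )

    def test_metric_mismatch_rejected(self):
        counts = codon_counts("ATGGCTGCCAAA")
        with pytest.raises(ValueError):
            profile_correlation(
                aa_specific_frequencies(counts), raw_frequencies(counts)
            )

    def test_default_filter_excludes_single_codon_aas_for_aa_specific(self):
        keep = default_codon_filter("aa_specific")
        assert "ATG" not in keep
        assert "TGG" not in keep
        assert len(default_codon_filter("raw_frequency")) == 61

    def test_generating_profile_recovered(self):
        """Genes sampled from profile P correlate higher with P than with
        an independent random profile, for 100+ codon genes."""
        from synsel.synthetic import (
            random_profile, sample_protein, sample_gene, _rng,
        )
        p = random_profile(_rng(5, "p"), 0.5, "P")
        d = random_profile(_rng(5, "d"), 0.5, "D")
        wins = 0
        n = 50
        for k in range(n):
            rng = _rng(5, "gene", k)
            g = sample_gene(sample_protein(rng, 120), p, 1.0, rng)
            prof = aa_specific_frequencies(codon_counts(g))
            if profile_correlation(prof, p).r > profile_correlation(prof, d).r:
                wins += 1
        assert wins >= 0.95 * n


class TestBenchmarkGene:
    def _programs(self, seed=11, n=12, length=90):
        from synsel.synthetic import (
            random_profile, sample_protein, sample_gene, _rng,
        )
        profiles = {
            name: random_profile(_rng(seed, name), 0.5, name)
            for name in ("prolif", "diff")
        }
        counts = {}
        for name, prof in profiles.items():
            counts[name] = [
                codon_counts(
                    sample_gene(
                        sample_protein(_rng(seed, name, k), length),
                        prof, 1.0, _rng(seed, name, k, "c"),
                    )
                )
                for k in range(n)
            ]
        return profiles, counts

    def test_gene_matching_group_counts_correlates_at_one(self):
        _, counts = self._programs()
        pooled = Counter()
        for c in counts["prolif"]:
            pooled.update(c)
        res = benchmark_gene(pooled, counts, leave_one_out=False,
                             compute_benchmarks=False)
        assert res.r_by_program["prolif"] == pytest.approx(1.0)
        assert res.assignment == "prolif"

    def test_sampled_gene_assigned_to_generating_program(self):
        from synsel.synthetic import sample_protein, sample_gene, _rng
        profiles, counts = self._programs()
        rng = _rng(12, "focal")
        g = codon_counts(
            sample_gene(sample_protein(rng, 90), profiles["diff"], 1.0, rng)
        )
        res = benchmark_gene(g, counts)
        assert res.assignment == "diff"
        assert res.percentile_by_program["diff"] >= 0.0

    def test_identical_program_profiles_flagged_ambiguous(self):
        counts = codon_counts("ATGGCTGCCAAAAAGTTTTTC")
        programs = {"x": [counts], "y": [counts]}
        res = benchmark_gene(counts, programs, leave_one_out=False,
                             compute_benchmarks=False)
        assert res.ambiguous
        assert res.assignment is None
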