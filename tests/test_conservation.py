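"""Conservation statistics: hand-count oracles, degeneracy cross-checks,
rank-sum exactness, and cross-module consistency."""

import itertools
import warnings

import numpy as np
import pytest

from synsel.alignment import codon_align, global_align, identity_gap_excluded
from synsel.conservation import (
    ConservationReport,
    classify_sites,
    conserved_report,
    distance_matrix,
    freq_ratio,
    gc3,
    rank_sum_test,
    substitution_score,
)
from synsel.genetic_code import degeneracy


class TestSubstitutionScore:
    @pytest.mark.parametrize(
        "a,b,score",
        [
            ("ATGGCT", "ATGGCC", 1 / 6),
            ("ATGGCT", "ATGGCT", 0.0),
            ("ATGGCT", "ATGGCA", 1 / 6),
            ("ATGGCT", "ATGGCG", 1 / 6),
        ],
    )
    def test_hand_counts(self, a, b, score):
        assert substitution_score(a, b) == pytest.approx(score)

    def test_planted_substitution_count(self, rng):
        """k planted synonymous changes in a CDS of length L score k/L."""
        from synsel.synthetic import sample_protein, sample_gene
        protein = sample_protein(rng, 60)
        cds = sample_gene(protein, None, 0.0, rng)
        # plant 4 third-position substitutions at fourfold codons
        seq = list(cds)
        planted = 0
        for i in range(len(cds) // 3):
            codon = cds[3 * i : 3 * i + 3]
            if degeneracy(codon, 3).is_fourfold and planted < 4:
                seq[3 * i + 2] = next(
                    b for b in "ACGT" if b != codon[2]
                )
                planted += 1
        assert planted == 4
        assert substitution_score(cds, "".join(seq)) == pytest.approx(
            4 / len(cds)
        )

    def test_alternative_denominators(self):
        # one codon insertion: gap-free columns = 6, no mismatches
        assert substitution_score("ATGGCT", "ATGGGAGCT") == 0.0
        assert substitution_score(
            "ATGGCT", "ATGGGAGCT", denominator="min_length"
        ) == 0.0
        with pytest.raises(ValueError):
            substitution_score("ATGGCT", "ATGGCC", denominator="bogus")

    def test_consistent_with_gap_excluded_identity(self, rng):
        from synsel.synthetic import sample_protein, sample_gene, evolve_synonymous
        protein = sample_protein(rng, 50)
        a = sample_gene(protein, None, 0.0, rng)
        b, _ = evolve_synonymous(a, 0.3, rng=rng)
        ident = identity_gap_excluded(global_align(a, b))
        assert substitution_score(a, b) == pytest.approx(1.0 - ident)


class TestDistanceMatrix:
    def test_identical_cdss_give_zero_matrix(self):
        dm = distance_matrix([("a", "ATGGCT"), ("b", "ATGGCT"), ("c", "ATGGCT")])
        assert np.all(dm.values == 0)

    def test_symmetry_and_diagonal(self):
        dm = distance_matrix([("a", "ATGGCT"), ("b", "ATGGCC"), ("c", "ATGGCA")])
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        assert dm.values[0, 1] == pytest.approx(1 / 6)

    def test_rate_ordering_of_simulated_paralogs(self):
        """Orthologs evolved 5x faster show larger median distances."""
        from synsel.synthetic import SimulationConfig, simulate_family
        slower, faster = [], []
        for seed in range(20):
            fams, _ = simulate_family(SimulationConfig(seed=seed, n_tips=6))
            slower.append(np.median(distance_matrix(fams["A"]).offdiagonal()))
            faster.append(np.median(distance_matrix(fams["B"]).offdiagonal()))
        assert np.median(slower) < np.median(faster)


class TestClassifySites:
    def test_fourfold_requires_all_rows(self):
        # GCT/GCC/GCA: all Ala -> fourfold third column
        aln = codon_align([("a", "GCT"), ("b", "GCC"), ("c", "GCA")])
        cls = classify_sites(aln)
        assert cls.is_fourfold[2]
        assert cls.is_wobble[2]

    def test_twofold_codon_is_wobble_not_fourfold(self):
        aln = codon_align([("a", "AAT"), ("b", "AAC")])
        cls = classify_sites(aln)
        assert cls.is_wobble[2]
        assert not cls.is_fourfold[2]

    def test_single_codon_amino_acid_not_wobble(self):
        aln = codon_align([("a", "ATG"), ("b", "ATG")])
        cls = classify_sites(aln)
        assert not cls.is_wobble[2]
        assert not cls.is_fourfold[2]

    def test_mixed_fold_column_takes_minimum(self):
        # CTT (Leu, fourfold at pos3) with TTA (Leu, twofold at pos3)
        aln = codon_align([("a", "CTT"), ("b", "TTA")])
        cls = classify_sites(aln)
        assert cls.is_wobble[2]
        assert not cls.is_fourfold[2]

    def test_agrees_with_bruteforce_degeneracy_per_column(self, rng):
        from synsel.synthetic import sample_protein, sample_gene
        protein = sample_protein(rng, 40)
        genes = [
            (f"g{i}", sample_gene(protein, None, 0.0, rng)) for i in range(4)
        ]
        aln = codon_align(genes)
        cls = classify_sites(aln)
        for k in range(aln.n_codons):
            folds = [degeneracy(c, 3).fold for c in aln.codon_column(k)]
            assert cls.is_fourfold[3 * k + 2] == (min(folds) == 4)
            assert cls.is_wobble[3 * k + 2] == (min(folds) >= 2)

    def test_stop_codon_columns_excluded(self):
        aln = codon_align([("a", "ATGGCTTAA"), ("b", "ATGGCCTAA")])
        cls = classify_sites(aln)
        assert not cls.valid[6:].any()
        assert cls.valid[:6].all()


class TestConservedReport:
    def test_hand_counted_fourfold_example(self):
        # codons: GCT|GCA, GCT|GCC, GCT|GCG -> two fourfold columns (3,6);
        # column 3 conserved (T,T,T), column 6 not (A,C,G)
        aln = codon_align(
            [("a", "GCTGCA"), ("b", "GCTGCC"), ("c", "GCTGCG")]
        )
        rep = conserved_report(aln, "fourfold", "demo")
        assert (rep.conserved_count, rep.total_sites) == (1, 2)
        assert rep.frequency == pytest.approx(0.5)

    def test_identical_rows_fully_conserved(self):
        aln = codon_align([("a", "GCTGCA"), ("b", "GCTGCA")])
        rep = conserved_report(aln, "third_position")
        assert rep.frequency == 1.0

    def test_zero_total_flagged_not_silent_zero(self):
        aln = codon_align([("a", "ATGTGG"), ("b", "ATGTGG")])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            rep = conserved_report(aln, "fourfold")
        assert rep.total_sites == 0
        assert rep.frequency is None
        assert caught

    def test_invariant_under_row_reordering(self, rng):
        from synsel.synthetic import sample_protein, sample_gene, evolve_synonymous
        protein = sample_protein(rng, 50)
        anc = sample_gene(protein, None, 0.0, rng)
        genes = []
        for i in range(5):
            cds, _ = evolve_synonymous(anc, 0.2, rng=rng)
            genes.append((f"g{i}", cds))
        rep = conserved_report(codon_align(genes), "fourfold")
        shuffled = [genes[i] for i in rng.permutation(len(genes))]
        renamed = [(f"x{i}", cds) for i, (_, cds) in enumerate(shuffled)]
        rep2 = conserved_report(codon_align(renamed), "fourfold")
        assert (rep.conserved_count, rep.total_sites) == (
            rep2.conserved_count, rep2.total_sites
        )

    def test_monotone_decreasing_in_substitution_rate(self):
        from synsel.synthetic import SimulationConfig, simulate_family
        freqs = []
        for bl in (0.01, 0.05, 0.25):
            vals = []
            for seed in range(10):
                fams, _ = simulate_family(
                    SimulationConfig(seed=seed, branch_length=bl,
                                     paralog_rates={"A": 1.0})
                )
                rep = conserved_report(codon_align(fams["A"]), "third_position")
                vals.append(rep.frequency)
            freqs.append(np.mean(vals))
        assert freqs[0] > freqs[1] > freqs[2]


class TestFreqRatio:
    def test_simple_ratios(self):
        ra = ConservationReport("g", "fourfold", 5, 10)
        rb = ConservationReport("g", "fourfold", 1, 4)
        assert freq_ratio(ra, rb) == pytest.approx(2.0)
        assert freq_ratio(ra, ra) == 1.0

    def test_zero_denominator_raises(self):
        ra = ConservationReport("g", "fourfold", 5, 10)
        rb = ConservationReport("g", "fourfold", 0, 4)
        with pytest.raises(ZeroDivisionError):
            freq_ratio(ra, rb)

    def test_undefined_frequency_raises(self):
        ra = ConservationReport("g", "fourfold", 0, 0)
        rb = ConservationReport("g", "fourfold", 1, 4)
        with pytest.raises(ValueError):
            freq_ratio(ra, rb)


class TestGC3:
    @pytest.mark.parametrize(
        "cds,value",
        [("ATGGCT", 0.5), ("ATGGCC", 1.0), ("ATGGCA", 0.5),
         ("ATGGCCTAA", 1.0)],  # terminal stop excluded
    )
    def test_hand_counts(self, cds, value):
        assert gc3(cds) == pytest.approx(value)


class TestRankSum:
    def test_exact_separated_groups(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_multisets_near_one(self):
        res = rank_sum_test([1.5, 2.5, 3.5], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value > 0.5

    def test_degenerate_all_equal_warns_p_one(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = rank_sum_test([1, 1], [1, 1, 1])
        assert res.p_value == 1.0
        assert caught

    def test_matches_exact_permutation_oracle(self, rng):
        """U and p equal brute-force permutation for small tie-free groups."""
        for n_a, n_b in [(3, 3), (4, 5), (6, 6), (7, 7), (2, 7)]:
            for _ in range(3):
                pooled = rng.choice(10_000, size=n_a + n_b, replace=False)
                a, b = pooled[:n_a].tolist(), pooled[n_a:].tolist()
                res = rank_sum_test(a, b)
                u_obs, p_oracle = _exact_two_sided(a, b)
                assert res.u_statistic == u_obs
                assert res.p_value == pytest.approx(p_oracle)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


def _u_statistic(a, b):
    return sum((x > y) + 0.5 * (x == y) for x in a for y in b)


def _exact_two_sided(a, b):
    """Brute-force two-sided Mann-Whitney p over all group assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)
    u_obs = _u_statistic(a, b)
    mean_u = n_a * len(b) / 2.0
    dev_obs = abs(u_obs - mean_u)
    total = hits = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        if abs(_u_statistic(ga, gb) - mean_u) >= dev_obs - 1e-12:
            hits += 1
    return u_obs, hits / total
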