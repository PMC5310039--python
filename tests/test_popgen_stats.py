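import itertools
import math

import numpy as np
import pytest

from sigmapop.core_io import AlignmentError, SequenceAlignment
from sigmapop.popgen_stats import (
    beta_pvalue_D,
    coalescent_pvalue_D,
    diversity_stats,
    filter_columns,
    mean_pairwise_differences,
    nucleotide_diversity,
    segregating_sites,
    simulate_null_D,
    synonymous_restriction,
    tajima_constants,
    tajima_D_bounds,
    tajimas_D,
)
from sigmapop.synthetic_data import SimulationConfig, simulate_coalescent


def oracle_tajima_D(seqs):
    """Constant-by-constant independent recomputation of Tajima's D.

    Deliberately naive: explicit python loops over pairs and columns,
    constants written out term by term.
    """
    n = len(seqs)
    L = len(seqs[0])
    S = 0
    for col in range(L):
        if len({s[col] for s in seqs}) > 1:
            S += 1
    if S == 0:
        return None
    total = 0
    npairs = 0
    for i, j in itertools.combinations(range(n), 2):
        total += sum(1 for c in range(L) if seqs[i][c] != seqs[j][c])
        npairs += 1
    kbar = total / npairs
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (kbar - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestFilterColumns:
    def test_identity_without_gaps(self, make_alignment):
        aln = make_alignment(["ACGT", "ACGA"])
        filtered, cmap = filter_columns(aln)
        assert filtered is aln and cmap == (0, 1, 2, 3)

    def test_drops_n_column(self, make_alignment):
        aln = make_alignment(["ACGTACGTAC", "ACGTNCGTAC"])
        filtered, cmap = filter_columns(aln)
        assert filtered.L == 9
        assert 4 not in cmap

    def test_column_map_strictly_increasing(self, random_alignment):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            aln = random_alignment(6, 50, seed=seed)
            seqs = [list(s) for s in aln.seqs]
            for _ in range(8):
                seqs[rng.integers(6)][rng.integers(50)] = "-N"[rng.integers(2)]
            dirty = SequenceAlignment(aln.ids, tuple("".join(s) for s in seqs))
            _, cmap = filter_columns(dirty)
            assert all(a < b for a, b in zip(cmap, cmap[1:]))

    def test_all_columns_removed_is_error(self, make_alignment):
        aln = make_alignment(["N-", "-N"])
        with pytest.raises(AlignmentError):
            filter_columns(aln)


class TestSegregatingSites:
    @pytest.mark.parametrize(
        "seqs, expected",
        [
            (["ACGTACGTAC", "ACGTACGTAT"], (1, 1)),
            (["AAAA"] * 3, (0, 0)),
            # columns {AAAAG} and {AACAA}: two segregating, both singleton sites
            (["AA", "AA", "AC", "AA", "GA"], (2, 2)),
        ],
    )
    def test_examples(self, make_alignment, seqs, expected):
        assert segregating_sites(make_alignment(seqs)) == expected

    def test_multiallelic_singleton_rule(self, make_alignment):
        # minor alleles C and G each once -> singleton site;
        # second column has a doubleton -> not a singleton site
        aln = make_alignment(["AA", "AC", "CC", "GC", "AA"])
        S, singles = segregating_sites(aln)
        assert (S, singles) == (2, 1)


class TestDiversity:
    def test_two_sequences_one_diff(self, make_alignment):
        aln = make_alignment(["ACGTACGTAC", "ACGTACGTAT"])
        assert nucleotide_diversity(aln) == pytest.approx(0.1)

    def test_identical(self, make_alignment):
        assert nucleotide_diversity(make_alignment(["ACGT"] * 4)) == 0.0

    def test_matches_brute_force_pairs(self, random_alignment):
        aln = random_alignment(4, 40, seed=9, p_variant=0.3)
        brute = np.mean(
            [
                sum(a != b for a, b in zip(aln.seqs[i], aln.seqs[j]))
                for i, j in itertools.combinations(range(4), 2)
            ]
        )
        assert mean_pairwise_differences(aln) == pytest.approx(brute)

    def test_needs_two_sequences(self, make_alignment):
        with pytest.raises(AlignmentError):
            nucleotide_diversity(make_alignment(["ACGT"]))

    def test_invariant_under_permutations(self, random_alignment):
        aln = random_alignment(8, 60, seed=11, p_variant=0.2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(8)
        aln2 = aln.select_samples([aln.ids[i] for i in perm])
        cols = rng.permutation(60)
        aln3 = aln.select_columns(cols)
        assert nucleotide_diversity(aln) == pytest.approx(nucleotide_diversity(aln2))
        assert segregating_sites(aln) == segregating_sites(aln3)


class TestTajimasD:
    def test_matches_independent_oracle(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            cfg = SimulationConfig(
                n=int(rng.integers(4, 13)),
                L=int(rng.integers(20, 61)),
                theta=2.0,
                seed=seed + 1000,
            )
            aln = simulate_coalescent(cfg).alignment
            expected = oracle_tajima_D(aln.seqs)
            got = tajimas_D(aln)
            if expected is None:
                assert got is None
                continue
            assert got == pytest.approx(expected, rel=1e-12)
            hits += 1
        assert hits >= 20

    def test_sign_identity(self, random_alignment):
        # sign(D) = sign(pi*L - S/a1) on every input
        for seed in range(10):
            aln = random_alignment(8, 80, seed=seed, p_variant=0.15)
            stats = diversity_stats(aln)
            if stats.S == 0:
                continue
            d = tajimas_D(aln)
            lhs = stats.kbar - stats.S / stats.constants["a1"]
            assert np.sign(d) == np.sign(lhs) or d == 0

    def test_theta_w_consistency(self, random_alignment):
        aln = random_alignment(10, 100, seed=3, p_variant=0.1)
        stats = diversity_stats(aln)
        assert stats.theta_w * stats.L_used == pytest.approx(
            stats.S / stats.constants["a1"]
        )

    def test_no_polymorphism_not_applicable(self, make_alignment):
        assert tajimas_D(make_alignment(["ACGT"] * 5)) is None

    def test_constants_match_published_values_small_n(self):
        c = tajima_constants(4)
        assert c["a1"] == pytest.approx(1 + 1 / 2 + 1 / 3)
        assert c["b1"] == pytest.approx(5 / 9)


class TestCoalescentNull:
    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(1)
        null = simulate_null_D(30, 12, 3000, rng)
        assert abs(null.mean()) < 0.15

    def test_median_gives_p_near_one(self):
        rng = np.random.default_rng(2)
        null = simulate_null_D(20, 10, 2000, rng)
        med = float(np.median(null))
        p = coalescent_pvalue_D(med, 20, 10, reps=2000, seed=3)
        assert p > 0.7

    def test_star_data_significant(self):
        # all-singleton data: D at its minimum for n=50, S=40
        n, S = 50, 40
        kbar = 2 * S / n  # every mutation a singleton
        from sigmapop.popgen_stats import tajimas_D_from_counts

        d = tajimas_D_from_counts(n, S, kbar)
        assert d < -2
        p = coalescent_pvalue_D(d, n, S, reps=10_000, seed=4)
        assert p < 0.01

    def test_requires_min_reps(self):
        with pytest.raises(ValueError):
            coalescent_pvalue_D(0.0, 10, 5, reps=50)


class TestBetaPvalue:
    def test_p_maximal_at_zero(self):
        assert beta_pvalue_D(0.0, 50) > 0.9

    def test_monotone_decreasing_in_abs_d(self):
        ps = [beta_pvalue_D(d, 50) for d in (0.0, -0.5, -1.0, -1.5, -2.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_bounds_bracket_zero(self):
        lo, hi = tajima_D_bounds(20)
        assert lo < 0 < hi

    def test_outside_range_clamped_with_warning(self):
        lo, _ = tajima_D_bounds(10)
        with pytest.warns(UserWarning, match="clamped"):
            p = beta_pvalue_D(lo - 1.0, 10)
        assert 0.0 <= p <= 1.0

    def test_agrees_with_coalescent_null_moderately(self):
        # the two significance routes should roughly agree for moderate data
        n, S, d = 50, 15, -1.5
        p_beta = beta_pvalue_D(d, n)
        p_coal = coalescent_pvalue_D(d, n, S, reps=4000, seed=5)
        assert abs(p_beta - p_coal) < 0.05


class TestSynonymous:
    def _aln(self, codon_rows):
        return SequenceAlignment(
            tuple(f"s{i}" for i in range(len(codon_rows))),
            tuple(codon_rows),
        )

    def test_third_position_gly_synonymous(self):
        aln = self._aln(["GGAGGA", "GGAGGA", "GGGGGA", "GGAGGA"])
        res = synonymous_restriction(aln)
        assert res.synonymous_columns == (2,)
        assert res.S_syn == 1

    def test_first_position_met_leu_nonsynonymous(self):
        aln = self._aln(["ATGGGA", "ATGGGA", "TTGGGA", "ATGGGA"])
        res = synonymous_restriction(aln)
        assert res.synonymous_columns == ()
        assert res.S_syn == 0

    def test_site_count_matches_nei_gojobori_oracle(self):
        # brute-force oracle: enumerate all 9 one-step changes per codon
        from Bio.Seq import Seq

        rows = ["GGATTCAAACTGATGCGA", "GGATTTAAACTGATGCGA",
                "GGATTCAAACTAATGCGA", "GGCTTCAAACTGATGCGA"]
        aln = self._aln(rows)
        res = synonymous_restriction(aln)

        def codon_s(codon):
            aa = str(Seq(codon).translate())
            if aa == "*":
                return None
            s = 0.0
            for pos in range(3):
                for b in "ACGT":
                    if b == codon[pos]:
                        continue
                    mut = codon[:pos] + b + codon[pos + 1:]
                    if str(Seq(mut).translate()) == aa:
                        s += 1 / 3
            return s

        per_seq = []
        for row in rows:
            tot = 0.0
            for k in range(0, len(row), 3):
                s = codon_s(row[k:k + 3])
                if s is not None:
                    tot += s
            per_seq.append(tot)
        assert res.synonymous_site_count == pytest.approx(np.mean(per_seq))

    def test_frame_offset_respected(self):
        # same data shifted by one junk column
        aln = self._aln(["CGGAGGA", "CGGAGGA", "CGGGGGA", "CGGAGGA"])
        res = synonymous_restriction(aln, frame=1)
        assert res.synonymous_columns == (3,)


class TestWattersonExpectation:
    def test_mean_s_matches_theta_a1(self):
        theta, n = 5.0, 10
        a1 = tajima_constants(n)["a1"]
        Ss = []
        for seed in range(400):
            cfg = SimulationConfig(n=n, L=500, theta=theta, seed=seed)
            Ss.append(segregating_sites(simulate_coalescent(cfg).alignment)[0])
        # E[S] = theta*a1 with finite-sites losses being negligible at L=500
        assert np.mean(Ss) == pytest.approx(theta * a1, rel=0.08)


@pytest.mark.parametrize("n", [5, 20, 87])
def test_null_D_matches_msprime_distribution(n):
    """Cross-check the fixed-S null against an independent simulator.

    msprime genealogies with S mutations placed by branch length should
    give the same D distribution as the internal coalescent.
    """
    msprime = pytest.importorskip("msprime")
    from sigmapop.popgen_stats import tajimas_D_from_counts

    S = 12
    rng = np.random.default_rng(42)
    ours = simulate_null_D(n, S, 1500, rng)

    ext = []
    for ts in msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=0.5, num_replicates=1500, random_seed=7
    ):
        tree = ts.first()
        nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
        lens = np.array([tree.branch_length(u) for u in nodes])
        counts = np.array([tree.num_samples(u) for u in nodes])
        rng2 = np.random.default_rng(int(tree.total_branch_length * 1e6) % 2**31)
        picks = rng2.choice(len(nodes), size=S, p=lens / lens.sum())
        kbar = sum(counts[p] * (n - counts[p]) for p in picks) * 2 / (n * (n - 1))
        ext.append(tajimas_D_from_counts(n, S, kbar))

    # D is discrete for small n, so compare binned counts by a two-sample
    # chi-squared homogeneity test rather than KS (which breaks on ties)
    from scipy.stats import chi2_contingency

    edges = np.quantile(np.concatenate([ours, ext]), np.linspace(0, 1, 9)[1:-1])
    c1 = np.bincount(np.digitize(ours, edges), minlength=len(edges) + 1)
    c2 = np.bincount(np.digitize(ext, edges), minlength=len(edges) + 1)
    keep = (c1 + c2) > 0
    _, pvalue, _, _ = chi2_contingency(np.stack([c1[keep], c2[keep]]))
    assert pvalue > 0.01
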