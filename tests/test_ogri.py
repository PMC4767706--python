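import itertools

import numpy as np
import pytest

from genotax.io import GenomeRecord, RelatednessMatrix, ValidationError
from genotax.ogri import (SubjectIndex, anib_matrix, anib_oneway, best_hit,
                          distance_to_similarity, fragment_genome,
                          reverse_complement, similarity_to_distance,
                          tetra_correlation, tetra_profile, TetraProfile)
from genotax.synthetic import mutate_nucleotide


def smith_waterman(a: str, b: str, match=2.0, mismatch=-3.0,
                   gap_open=-5.0, gap_extend=-2.0):
    """Quadratic affine-gap Smith-Waterman oracle (independent of Biopython)."""
    n, m = len(a), len(b)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a
    F = np.full((n + 1, m + 1), neg)  # gap in b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            sub = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFragmentation:
    def test_floor_division_and_remainder_rule(self):
        g = GenomeRecord("g", [("c", random_seq(2540, 0))])
        assert len(fragment_genome(g, 1020)) == 2
        short = GenomeRecord("s", [("c", random_seq(900, 1))])
        assert fragment_genome(short, 1020) == []

    def test_total_count_is_sum_of_per_contig_floors(self):
        lengths = [1020, 5100, 999, 2039, 3061]
        g = GenomeRecord("g", [(f"c{i}", random_seq(n, i)) for i, n in enumerate(lengths)])
        assert len(fragment_genome(g, 1020)) == sum(n // 1020 for n in lengths)

    def test_mostly_ambiguous_fragments_discarded(self):
        seq = "N" * 1020 + random_seq(1020, 2)
        g = GenomeRecord("g", [("c", seq)])
        assert len(fragment_genome(g, 1020)) == 1


class TestBestHit:
    def test_exact_containment_gives_perfect_hit(self):
        subject = GenomeRecord("s", [("c", random_seq(3000, 3))])
        frag = subject.sequences[0][1][500:1520]
        hit = best_hit(frag, SubjectIndex(subject))
        assert hit.identity == pytest.approx(100.0)
        assert hit.alignable_fraction == pytest.approx(1.0)

    def test_reverse_strand_found(self):
        subject = GenomeRecord("s", [("c", random_seq(3000, 4))])
        frag = reverse_complement(subject.sequences[0][1][100:1120])
        hit = best_hit(frag, SubjectIndex(subject))
        assert hit.identity == pytest.approx(100.0)

    def test_no_shared_seed_word_gives_none(self):
        subject = GenomeRecord("s", [("c", "A" * 2000)])
        assert best_hit("C" * 1020, SubjectIndex(subject)) is None

    @pytest.mark.parametrize("seed,rate", [(5, 0.02), (6, 0.1), (7, 0.25)])
    def test_score_matches_quadratic_dp_oracle(self, seed, rate):
        rng = np.random.default_rng(seed)
        base = rng.integers(0, 4, size=160)
        frag = "".join("ACGT"[b] for b in base)
        mutated = "".join("ACGT"[b] for b in mutate_nucleotide(base, rate, rng))
        subject = GenomeRecord("s", [("c", random_seq(200, seed) + mutated
                                      + random_seq(200, seed + 50))])
        hit = best_hit(frag, SubjectIndex(subject))
        oracle = smith_waterman(frag, subject.sequences[0][1])
        assert hit is not None
        assert hit.score == pytest.approx(oracle)


class TestAnib:
    def test_self_comparison_is_exactly_100(self):
        g = GenomeRecord("g", [("c", random_seq(4000, 8))])
        assert anib_oneway(g, g) == pytest.approx(100.0)

    def test_uniform_substitution_rate_sets_identity(self):
        rng = np.random.default_rng(9)
        base = rng.integers(0, 4, size=8160)
        a = GenomeRecord("a", [("c", "".join("ACGT"[b] for b in base))])
        mut = mutate_nucleotide(base, 0.02, rng)
        b = GenomeRecord("b", [("c", "".join("ACGT"[x] for x in mut))])
        ani = anib_oneway(a, b)
        assert ani == pytest.approx(98.0, abs=0.3)

    def test_monotone_in_substitution_rate(self):
        rng = np.random.default_rng(10)
        base = rng.integers(0, 4, size=6120)
        a = GenomeRecord("a", [("c", "".join("ACGT"[b] for b in base))])
        anis = []
        for rate in (0.01, 0.05, 0.12):
            mut = mutate_nucleotide(base, rate, np.random.default_rng(100 + int(rate * 1000)))
            b = GenomeRecord("b", [("c", "".join("ACGT"[x] for x in mut))])
            anis.append(anib_oneway(a, b))
        assert anis[0] > anis[1] > anis[2]

    def test_matrix_cells_agree_with_oneway_and_diag_100(self):
        rng = np.random.default_rng(11)
        base = rng.integers(0, 4, size=3060)
        genomes = [GenomeRecord(f"g{i}",
                                [("c", "".join("ACGT"[x] for x in
                                               mutate_nucleotide(base, 0.01 * i, rng)))])
                   for i in range(3)]
        m = anib_matrix(genomes)
        assert m.kind == "ANIb"
        np.testing.assert_allclose(np.diag(m.values), 100.0)
        for i, j in itertools.permutations(range(3), 2):
            direct = anib_oneway(genomes[i], genomes[j])
            assert m.values[i, j] == pytest.approx(direct)

    def test_empty_query_rejected(self):
        a = GenomeRecord("a", [("c", random_seq(500, 12))])   # < fragment length
        b = GenomeRecord("b", [("c", random_seq(2000, 13))])
        with pytest.raises(ValidationError):
            anib_oneway(a, b)


class TestTetra:
    def test_profile_matches_brute_force_on_toy(self):
        seq = "ACGTACGGTACCGTAAATTTCCGGATCGATCGGCTAGCTAAGGCCTTAAGCGTACGTACG"
        g = GenomeRecord("t", [("c", seq)])
        prof = tetra_profile(g)
        # independent recount: windows of both strands
        from collections import Counter
        both = [seq, reverse_complement(seq)]
        c4 = Counter(s[i:i + 4] for s in both for i in range(len(s) - 3))
        c3 = Counter(s[i:i + 3] for s in both for i in range(len(s) - 2))
        c2 = Counter(s[i:i + 2] for s in both for i in range(len(s) - 1))
        for idx, word in enumerate("".join(w) for w in
                                   itertools.product("ACGT", repeat=4)):
            nbc = c2[word[1:3]]
            if nbc == 0:
                assert prof.z[idx] == 0.0
                continue
            e = c3[word[:3]] * c3[word[1:]] / nbc
            var = e * (nbc - c3[word[:3]]) * (nbc - c3[word[1:]]) / nbc ** 2
            if var <= 0:
                assert prof.z[idx] == 0.0
            else:
                assert prof.z[idx] == pytest.approx((c4[word] - e) / np.sqrt(var))

    def test_strand_pooling_makes_profile_revcomp_invariant(self, nucleotide_record):
        g = nucleotide_record
        rc = GenomeRecord("rc", [("c", reverse_complement(g.sequences[0][1]))])
        np.testing.assert_allclose(tetra_profile(g).z, tetra_profile(rc).z)

    def test_correlation_self_one_negation_minus_one_and_pearson_oracle(self, nucleotide_record):
        prof = tetra_profile(nucleotide_record)
        assert tetra_correlation(prof, prof) == pytest.approx(1.0)
        neg = TetraProfile("neg", -prof.z)
        assert tetra_correlation(prof, neg) == pytest.approx(-1.0)
        rng = np.random.default_rng(14)
        other = TetraProfile("o", rng.normal(size=256))
        r = tetra_correlation(prof, other)
        x, y = prof.z - prof.z.mean(), other.z - other.z.mean()
        assert r == pytest.approx(float(x @ y / np.sqrt((x @ x) * (y @ y))))

    def test_permutation_applied_to_both_vectors_preserves_correlation(self, nucleotide_record):
        rng = np.random.default_rng(15)
        a = tetra_profile(nucleotide_record)
        b = TetraProfile("b", rng.normal(size=256))
        perm = rng.permutation(256)
        r1 = tetra_correlation(a, b)
        r2 = tetra_correlation(TetraProfile("ap", a.z[perm]), TetraProfile("bp", b.z[perm]))
        assert r1 == pytest.approx(r2)


class TestScaleConversion:
    def test_methods_formula_and_round_trip(self):
        vals = np.array([[100.0, 95.7], [95.7, 100.0]])
        m = RelatednessMatrix(["a", "b"], vals, kind="ANIb")
        d = similarity_to_distance(m)
        assert d.loc("a", "b") == pytest.approx(4.3)
        assert d.loc("a", "a") == 0.0
        back = distance_to_similarity(d)
        np.testing.assert_allclose(back.values, vals)

    def test_tetra_matrices_not_convertible(self):
        m = RelatednessMatrix(["a", "b"], np.array([[1.0, 0.9], [0.9, 1.0]]),
                              kind="TETRA")
        with pytest.raises(ValidationError):
            similarity_to_distance(m)
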