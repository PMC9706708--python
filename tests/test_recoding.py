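"""Recoding schemes: builtins, application, random generation, similarity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phylorecode as pr
from phylorecode.core import AMINO_ACIDS
from phylorecode.recoding import RecodingScheme


class TestBuiltins:
    def test_dayhoff6_bin_sizes(self):
        d6 = pr.builtin_scheme("dayhoff6")
        assert sorted(len(m) for _, m in d6.bins) == [1, 3, 3, 4, 4, 5]

    def test_dayhoff6_cysteine_singleton(self):
        d6 = pr.builtin_scheme("dayhoff6")
        singles = [m for _, m in d6.bins if len(m) == 1]
        assert singles == [frozenset("C")]

    @pytest.mark.parametrize("name", ["dayhoff6", "sr6", "kgb6"])
    def test_builtins_partition_20_amino_acids(self, name):
        sch = pr.builtin_scheme(name)
        members = sorted(aa for _, m in sch.bins for aa in m)
        assert members == sorted(AMINO_ACIDS)

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            pr.builtin_scheme("dayhoff4")


class TestApplyRecoding:
    def test_table_lookup(self, aa_alphabet):
        aln = pr.Alignment(["x"], np.array([list("CATS")]), aa_alphabet)
        rec = pr.apply_recoding(aln, pr.builtin_scheme("dayhoff6"))
        assert rec.sequence("x") == "FAAA"

    def test_missing_unchanged(self, aa_alphabet):
        aln = pr.Alignment(["x"], np.array([list("--?A")]), aa_alphabet)
        rec = pr.apply_recoding(aln, pr.builtin_scheme("dayhoff6"))
        assert rec.sequence("x") == "--?A"

    def test_requires_amino_acid_alignment(self):
        aln = pr.Alignment(["x"], np.array([list("AB")]), pr.recoded_alphabet(6))
        with pytest.raises(ValueError):
            pr.apply_recoding(aln, pr.builtin_scheme("dayhoff6"))

    def test_recoding_merges_column_states(self, aa_alphabet):
        # A and G share a Dayhoff bin: variable column becomes constant
        aln = pr.Alignment(["x", "y"], np.array([list("A"), list("G")]),
                           aa_alphabet)
        rec = pr.apply_recoding(aln, pr.builtin_scheme("dayhoff6"))
        assert pr.div_stat(aln) == 2.0
        assert pr.div_stat(rec) == 1.0

    def test_state_merging_is_monotone(self, sim_alignment):
        rec = pr.apply_recoding(sim_alignment, pr.builtin_scheme("dayhoff6"))
        src = sim_alignment.indices()
        out = rec.indices()
        for col in range(sim_alignment.n_sites):
            n_src = len(set(src[:, col]) - {-1})
            n_rec = len(set(out[:, col]) - {-1})
            assert n_rec <= n_src


class TestRandomScheme:
    def test_partition_invariants(self):
        sch = pr.random_scheme((5, 4, 4, 3, 3, 1), 3)
        assert sorted(len(m) for _, m in sch.bins) == [1, 3, 3, 4, 4, 5]
        assert sorted(aa for _, m in sch.bins for aa in m) == sorted(AMINO_ACIDS)

    def test_seed_determinism(self):
        a = pr.random_scheme(rng_seed=11)
        b = pr.random_scheme(rng_seed=11)
        assert a.partition_key() == b.partition_key()
        assert a.partition_key() != pr.random_scheme(rng_seed=12).partition_key()

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            pr.random_scheme((5, 5, 5), 0)

    def test_singleton_exchangeable_over_amino_acids(self):
        # each amino acid hits the singleton bin with frequency ~1/20
        rng = np.random.default_rng(0)
        n = 10_000
        counts = {aa: 0 for aa in AMINO_ACIDS}
        for _ in range(n):
            sch = pr.random_scheme((5, 4, 4, 3, 3, 1), rng)
            aa = next(iter(next(m for _, m in sch.bins if len(m) == 1)))
            counts[aa] += 1
        p = 1 / 20
        se = np.sqrt(p * (1 - p) / n)
        for aa, c in counts.items():
            assert abs(c / n - p) < 3 * se + 1e-9, aa


class TestSimilarity:
    def test_identity_is_100(self):
        d6 = pr.builtin_scheme("dayhoff6")
        assert pr.similarity(d6, d6) == 100.0

    def test_two_displaced_amino_acids_give_90(self):
        d6 = pr.builtin_scheme("dayhoff6")
        swapped = RecodingScheme.from_bins(
            "swap", ["DGPST", "AENQ", "HKR", "ILMV", "FWY", "C"])
        assert pr.similarity(d6, swapped) == 90.0

    def test_symmetric_and_quantized(self):
        d6 = pr.builtin_scheme("dayhoff6")
        rng = np.random.default_rng(4)
        for _ in range(50):
            sch = pr.random_scheme(rng_seed=rng)
            s = pr.similarity(d6, sch)
            assert s == pr.similarity(sch, d6)
            assert s % 5 == 0 and 0 <= s <= 100

    def test_mismatched_bin_sizes_rejected(self):
        with pytest.raises(ValueError):
            pr.similarity(pr.builtin_scheme("dayhoff6"), pr.builtin_scheme("sr6"))

    def test_matches_brute_force_on_toy_universe(self):
        # 6-symbol universe, bins {3,2,1}: compare against exhaustive
        # maximization over size-respecting bin correspondences
        from phylorecode.recoding import similarity as sim_fn

        def brute(a, b):
            per_size_a, per_size_b = {}, {}
            for _, m in a.bins:
                per_size_a.setdefault(len(m), []).append(m)
            for _, m in b.bins:
                per_size_b.setdefault(len(m), []).append(m)
            total = 0
            for size, ba in per_size_a.items():
                bb = per_size_b[size]
                best = 0
                for perm in itertools.permutations(range(len(bb))):
                    best = max(best, sum(len(ba[i] & bb[perm[i]])
                                         for i in range(len(ba))))
                total += best
            return total

        # embed the toy universe in the amino-acid world by keeping the
        # remaining 14 amino acids in fixed singleton-free filler bins
        filler = ["HKRMFP", "WYVDEN", "QI"]
        rng = np.random.default_rng(9)
        letters = list("ACGLST")
        for _ in range(30):
            rng.shuffle(letters)
            a = RecodingScheme.from_bins(
                "a", ["".join(letters[:3]), "".join(letters[3:5]), letters[5]]
                + filler)
            rng.shuffle(letters)
            b = RecodingScheme.from_bins(
                "b", ["".join(letters[:3]), "".join(letters[3:5]), letters[5]]
                + filler)
            assert sim_fn(a, b) == 100.0 * brute(a, b) / 20.0


class TestFindSchemes:
    def test_zero_similarity_is_feasible(self):
        d6 = pr.builtin_scheme("dayhoff6")
        found = pr.find_schemes_at_similarity(0.0, d6, 3, rng_seed=1,
                                              max_draws=200_000)
        assert len(found) == 3
        for sch in found:
            assert pr.similarity(sch, d6) == 0.0

    def test_ninety_percent_schemes_verify(self):
        d6 = pr.builtin_scheme("dayhoff6")
        found = pr.find_schemes_at_similarity(90.0, d6, 5, rng_seed=2)
        assert len(found) == 5
        for sch in found:
            assert pr.similarity(sch, d6) == 90.0

    def test_full_similarity_multiplicity_rejected(self):
        with pytest.raises(ValueError):
            pr.find_schemes_at_similarity(100.0, pr.builtin_scheme("dayhoff6"), 2)

    def test_target_must_be_multiple_of_five(self):
        with pytest.raises(ValueError):
            pr.find_schemes_at_similarity(42.0, pr.builtin_scheme("dayhoff6"), 1)


class TestSchemeIO:
    def test_singleton_line(self, tmp_path):
        path = tmp_path / "sch.txt"
        path.write_text("A: AGPST\nB: DENQ\nC: HKR\nD: ILMV\nE: FWY\nF: C\n")
        sch = pr.read_scheme(path)
        assert frozenset("C") in {m for _, m in sch.bins}
        assert sch.partition_key() == pr.builtin_scheme("dayhoff6").partition_key()

    def test_round_trip(self, tmp_path):
        sch = pr.random_scheme(rng_seed=5)
        path = tmp_path / "rt.txt"
        pr.write_scheme(sch, path)
        back = pr.read_scheme(path)
        assert back.partition_key() == sch.partition_key()

    def test_incomplete_scheme_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("A: AGPST\nB: DENQ\n")
        with pytest.raises(ValueError):
            pr.read_scheme(path)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_random_scheme_always_valid_partition(seed):
    sch = pr.random_scheme((5, 4, 4, 3, 3, 1), seed)
    sizes = sorted(len(m) for _, m in sch.bins)
    assert sizes == [1, 3, 3, 4, 4, 5]
    assert sorted(aa for _, m in sch.bins for aa in m) == sorted(AMINO_ACIDS)
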