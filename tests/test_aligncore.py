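import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endotrawl.aligncore import (
    FRAMES,
    LocalHit,
    ScoringScheme,
    alignment_score,
    build_kmer_index,
    reverse_complement,
    seeded_map,
    seeded_ungapped_hit,
    smith_waterman,
    translate_six_frames,
    translated_best_hit,
)
from endotrawl.errors import InputError, ParameterError
from endotrawl.simdata import SimSpec, generate_symbiont_genome, make_marker_catalog, simulate_reads

from conftest import random_dna, random_protein
from oracles import gotoh_local_score, matrix_substitution, nt_substitution, translate_naive


class TestScoringScheme:
    def test_defaults(self, nt_scheme, protein_scheme):
        assert nt_scheme.match == 2 and nt_scheme.mismatch == -3
        assert nt_scheme.gap_open == 5 and nt_scheme.gap_extend == 2
        assert protein_scheme.gap_open == 11 and protein_scheme.gap_extend == 1

    def test_invalid_schemes(self):
        with pytest.raises(ParameterError):
            ScoringScheme(mode="nucleotide", match=-1)
        with pytest.raises(ParameterError):
            ScoringScheme(mode="nucleotide", gap_open=1, gap_extend=2)
        with pytest.raises(ParameterError):
            ScoringScheme(mode="bogus")


class TestSmithWaterman:
    def test_exact_match(self, nt_scheme):
        hit = smith_waterman("ACGT", "ACGT", nt_scheme)
        assert hit.score == 8.0
        assert hit.identity == 1.0
        assert hit.query_interval == (0, 4) and hit.ref_interval == (0, 4)

    def test_no_positive_cell(self, nt_scheme):
        hit = smith_waterman("AAAA", "CCCC", nt_scheme)
        assert hit.score == 0.0 and hit.is_empty

    def test_alphabet_mismatch(self, nt_scheme):
        with pytest.raises(InputError):
            smith_waterman("ACGU", "ACGT", nt_scheme)
        with pytest.raises(InputError):
            smith_waterman("", "ACGT", nt_scheme)

    def test_matches_dp_oracle_nt(self, nt_scheme):
        rng = np.random.default_rng(0)
        sub = nt_substitution()
        for _ in range(60):
            a = random_dna(rng, int(rng.integers(5, 61)))
            b = random_dna(rng, int(rng.integers(5, 61)))
            expected = gotoh_local_score(a, b, sub, 5, 2)
            assert smith_waterman(a, b, nt_scheme).score == expected

    def test_matches_dp_oracle_protein(self, protein_scheme):
        from Bio.Align import substitution_matrices

        rng = np.random.default_rng(1)
        sub = matrix_substitution(substitution_matrices.load("BLOSUM62"))
        for _ in range(30):
            a = random_protein(rng, int(rng.integers(5, 40)), start_m=False)
            b = random_protein(rng, int(rng.integers(5, 40)), start_m=False)
            expected = gotoh_local_score(a, b, sub, 11, 1)
            assert smith_waterman(a, b, protein_scheme).score == expected

    def test_symmetry(self, nt_scheme):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = random_dna(rng, 40), random_dna(rng, 40)
            assert smith_waterman(a, b, nt_scheme).score == smith_waterman(b, a, nt_scheme).score

    def test_self_is_maximal(self, nt_scheme):
        rng = np.random.default_rng(3)
        a = random_dna(rng, 50)
        self_score = smith_waterman(a, a, nt_scheme).score
        assert self_score == nt_scheme.self_score(a)
        for _ in range(30):
            b = random_dna(rng, 50)
            assert smith_waterman(a, b, nt_scheme).score <= self_score

    def test_monotone_degradation(self, nt_scheme):
        """Mean score is non-increasing as substitutions are added."""
        rng = np.random.default_rng(4)
        levels = [0, 3, 8, 15]
        sums = {lev: 0.0 for lev in levels}
        for _ in range(200):
            ref = random_dna(rng, 60)
            base = list(ref)
            positions = rng.permutation(60)
            for lev in levels:
                mutated = base[:]
                for p in positions[:lev]:
                    mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
                sums[lev] += smith_waterman("".join(mutated), ref, nt_scheme).score
        means = [sums[lev] / 200 for lev in levels]
        assert all(x > y for x, y in zip(means, means[1:]))

    def test_outfmt6_row(self, nt_scheme):
        hit = smith_waterman("ACGTACGT", "ACGTACGT", nt_scheme, "q1", "r1")
        fields = hit.as_outfmt6().split("\t")
        assert fields[0] == "q1" and fields[1] == "r1"
        assert fields[6:10] == ["1", "8", "1", "8"]  # 1-based inclusive
        assert float(fields[11]) == hit.score


class TestTranslation:
    def test_forward_frame(self):
        assert translate_six_frames("ATGGCC")[1] == "MA"

    def test_reverse_frame(self):
        assert translate_six_frames("ATG")[-1] == "H"

    def test_too_short(self):
        with pytest.raises(InputError):
            translate_six_frames("AT")

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_frame_lengths(self, seed):
        rng = np.random.default_rng(seed)
        nt = random_dna(rng, 100)
        frames = translate_six_frames(nt)
        assert set(frames) == set(FRAMES)
        for frame in FRAMES:
            offset = abs(frame) - 1
            assert len(frames[frame]) == (100 - offset) // 3

    def test_matches_naive_translation(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            nt = random_dna(rng, int(rng.integers(3, 120)))
            frames = translate_six_frames(nt)
            for frame in FRAMES:
                assert frames[frame] == translate_naive(nt, frame)


class TestTranslatedBestHit:
    def test_exact_reverse_translation(self, protein_scheme):
        rng = np.random.default_rng(8)
        from endotrawl.simdata import reverse_translate

        marker = random_protein(rng, 80, start_m=False)
        fragment = marker[10:60]
        read = reverse_translate(fragment, rng)[:-3]  # drop appended stop
        hit = translated_best_hit(read, marker, protein_scheme)
        assert hit.identity == 1.0
        assert hit.aligned_columns == 50
        assert hit.strand_or_frame == 1

    def test_matches_frame_oracle(self, protein_scheme):
        from Bio.Align import substitution_matrices

        rng = np.random.default_rng(9)
        sub = matrix_substitution(substitution_matrices.load("BLOSUM62"))
        for _ in range(15):
            read = random_dna(rng, 45)
            marker = random_protein(rng, 40, start_m=False)
            expected = max(
                gotoh_local_score(translate_naive(read, f), marker, sub, 11, 1)
                for f in FRAMES
                if translate_naive(read, f)
            )
            assert translated_best_hit(read, marker, protein_scheme).score == expected

    def test_short_read_rejected(self, protein_scheme):
        with pytest.raises(InputError):
            translated_best_hit("AT", "MKV", protein_scheme)

    def test_requires_protein_scheme(self, nt_scheme):
        with pytest.raises(ParameterError):
            translated_best_hit("ATGGCC", "MA", nt_scheme)


class TestSeededMap:
    def test_error_free_reads_map_to_origin(self, nt_scheme):
        catalog = make_marker_catalog(n_completeness=3, seed=21)
        spec = SimSpec(seed=21, genome_length=8000, marker_catalog=catalog)
        genome, _ = generate_symbiont_genome(spec)
        reads, truth = simulate_reads(
            {"g": genome}, {"g": 1.0}, read_length=120, error_rate=0.0,
            total_reads=200, seed=22,
        )
        hits = seeded_map([(r.id, r.seq) for r in reads], genome, circular=True)
        for read in reads:
            hit = hits[read.id]
            assert hit is not None
            origin = truth.read_origins[read.id][1]
            assert hit.ref_interval[0] % 8000 == origin
            assert hit.identity == 1.0
            assert hit.strand_or_frame == "+"

    def test_no_shared_kmer_no_hit(self, nt_scheme):
        genome = "A" * 500
        hits = seeded_map([("r1", "C" * 50)], genome)
        assert hits["r1"] is None

    def test_reported_score_bounded_by_full_dp(self, nt_scheme):
        rng = np.random.default_rng(23)
        genome = random_dna(rng, 2000)
        for i in range(100):
            if rng.random() < 0.5:
                start = int(rng.integers(0, 1900))
                read = genome[start : start + 80]
            else:
                read = random_dna(rng, 80)
            hits = seeded_map([("r", read)], genome)
            hit = hits["r"]
            if hit is not None:
                full_fwd = smith_waterman(read, genome, nt_scheme).score
                full_rev = smith_waterman(reverse_complement(read), genome, nt_scheme).score
                assert hit.score <= max(full_fwd, full_rev)

    def test_k_larger_than_read(self):
        with pytest.raises(ParameterError):
            seeded_map([("r", "ACGTACGTAC")], "ACGT" * 100, k=50)

    def test_k_too_small(self):
        with pytest.raises(ParameterError):
            seeded_map([("r", "ACGTACGTAC")], "ACGT" * 100, k=4)

    def test_reverse_strand_read(self, nt_scheme):
        rng = np.random.default_rng(24)
        genome = random_dna(rng, 1000)
        read = reverse_complement(genome[200:320])
        hit = seeded_map([("r", read)], genome)["r"]
        assert hit is not None
        assert hit.strand_or_frame == "-"
        assert hit.ref_interval == (200, 320)


class TestSeededUngappedHit:
    def test_exact_substring(self, nt_scheme):
        rng = np.random.default_rng(25)
        ref = random_dna(rng, 5000)
        query = ref[1000:3000]
        hit = seeded_ungapped_hit(query, ref, nt_scheme)
        assert hit is not None
        assert hit.identity == 1.0
        assert hit.ref_interval == (1000, 3000)
        assert hit.aligned_columns == 2000

    def test_score_bounded_by_full_dp(self, nt_scheme):
        rng = np.random.default_rng(26)
        for _ in range(20):
            ref = random_dna(rng, 300)
            query = random_dna(rng, 100)
            hit = seeded_ungapped_hit(query, ref, nt_scheme, k=8, query_stride=1)
            if hit is not None:
                full = max(
                    smith_waterman(query, ref, nt_scheme).score,
                    smith_waterman(reverse_complement(query), ref, nt_scheme).score,
                )
                assert hit.score <= full

    def test_reverse_strand(self, nt_scheme):
        rng = np.random.default_rng(27)
        ref = random_dna(rng, 4000)
        query = reverse_complement(ref[500:1500])
        hit = seeded_ungapped_hit(query, ref, nt_scheme)
        assert hit is not None and hit.strand_or_frame == "-"
        assert hit.ref_interval == (500, 1500)


def test_kmer_index_positions():
    index = build_kmer_index("ACGTACGT", 4)
    assert index["ACGT"] == [0, 4]
    assert index["CGTA"] == [1]
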