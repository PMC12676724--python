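"""Local alignment engine (nucleotide and translated-protein).

Provides affine-gap Smith-Waterman scores and hits consumed by the marker
prescreen, contig recruitment, rRNA detection, read mapping and species
assignment stages.  The dynamic programming itself is delegated to
``Bio.Align.PairwiseAligner`` (C implementation of the Gotoh recurrences);
the surrounding code normalizes its output into :class:`LocalHit` records
with 0-based half-open coordinates.
"""

from __future__ import annotations

import functools
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .errors import ComputationError, InputError, ParameterError

DNA_ALPHABET = frozenset("ACGT")
# 20 standard residues plus the stop symbol; BLOSUM62 is diagonal-dominant on
# this sub-alphabet (X is not, and is therefore excluded).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Bacterial/archaeal code: codon -> amino acid map identical to the standard
# code for elongation; start-codon differences are handled by the ORF caller.
_CODON_TABLE_ID = 11
_table = CodonTable.unambiguous_dna_by_id[_CODON_TABLE_ID]
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment parameters for one of the two search spaces.

    ``gap_open``/``gap_extend`` are nonnegative penalties; a gap of length L
    costs ``gap_open + L * gap_extend`` (BLAST convention).
    """

    mode: str  # "nucleotide" | "protein"
    match: float = 2.0
    mismatch: float = -3.0
    matrix_name: str = "BLOSUM62"
    gap_open: float = 5.0
    gap_extend: float = 2.0

    def __post_init__(self):
        if self.mode not in ("nucleotide", "protein"):
            raise ParameterError(f"unknown scheme mode {self.mode!r}")
        if self.mode == "nucleotide" and not (self.match > 0 > self.mismatch):
            raise ParameterError("nucleotide scheme requires match > 0 > mismatch")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ParameterError("require gap_open >= gap_extend >= 0")
        if self.mode == "protein":
            _check_diagonal_dominance(self.matrix_name)

    @classmethod
    def nucleotide(cls) -> "ScoringScheme":
        return cls(mode="nucleotide", match=2, mismatch=-3, gap_open=5, gap_extend=2)

    @classmethod
    def protein(cls) -> "ScoringScheme":
        return cls(mode="protein", matrix_name="BLOSUM62", gap_open=11, gap_extend=1)

    @property
    def alphabet(self) -> frozenset:
        return DNA_ALPHABET if self.mode == "nucleotide" else PROTEIN_ALPHABET

    def self_score(self, seq: str) -> float:
        """Score of the trivial full-length self alignment.

        With a diagonal-dominant matrix and positive diagonal this equals the
        optimal local self-alignment score, and is much cheaper than running
        the aligner.
        """
        if self.mode == "nucleotide":
            return self.match * len(seq)
        matrix = _load_matrix(self.matrix_name)
        return float(sum(matrix[c, c] for c in seq))


@functools.lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@functools.lru_cache(maxsize=8)
def _check_diagonal_dominance(name: str) -> None:
    matrix = _load_matrix(name)
    for x in sorted(PROTEIN_ALPHABET):
        row_max = max(matrix[x, y] for y in sorted(PROTEIN_ALPHABET))
        if matrix[x, x] != row_max or matrix[x, x] <= 0:
            raise ParameterError(
                f"matrix {name}: diagonal entry for {x!r} is not a positive row maximum"
            )


@functools.lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if scheme.mode == "nucleotide":
        aligner.match_score = scheme.match
        aligner.mismatch_score = scheme.mismatch
    else:
        aligner.substitution_matrix = _load_matrix(scheme.matrix_name)
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


@dataclass
class LocalHit:
    """A scored local alignment; intervals are 0-based half-open."""

    query_id: str = "query"
    ref_id: str = "ref"
    query_interval: tuple[int, int] = (0, 0)
    ref_interval: tuple[int, int] = (0, 0)
    strand_or_frame: object = "+"
    score: float = 0.0
    identity: float = 0.0
    aligned_columns: int = 0

    @property
    def is_empty(self) -> bool:
        return self.aligned_columns == 0

    def as_outfmt6(self) -> str:
        """BLAST outfmt-6-like row (1-based inclusive coordinates)."""
        qs, qe = self.query_interval
        rs, re = self.ref_interval
        mism = round((1.0 - self.identity) * self.aligned_columns)
        return "\t".join(
            str(x)
            for x in (
                self.query_id,
                self.ref_id,
                f"{self.identity * 100:.2f}",
                self.aligned_columns,
                mism,
                0,
                qs + 1,
                qe,
                rs + 1,
                re,
                "NA",
                f"{self.score:g}",
            )
        )


def _validate(seq: str, scheme: ScoringScheme, what: str) -> None:
    if not seq:
        raise InputError(f"empty {what} sequence")
    bad = set(seq) - scheme.alphabet
    if bad:
        raise InputError(
            f"{what} sequence contains characters {sorted(bad)} outside the "
            f"{scheme.mode} alphabet"
        )


def smith_waterman(
    query: str,
    ref: str,
    scheme: ScoringScheme,
    query_id: str = "query",
    ref_id: str = "ref",
) -> LocalHit:
    """Maximum-score affine-gap local alignment of ``query`` against ``ref``.

    Returns a zero-score :class:`LocalHit` with empty intervals when no
    positive-scoring cell exists.
    """
    _validate(query, scheme, "query")
    _validate(ref, scheme, "ref")
    aligner = _aligner(scheme)
    score = aligner.score(ref, query)
    if score <= 0:
        return LocalHit(query_id=query_id, ref_id=ref_id)
    alignment = aligner.align(ref, query)[0]
    ref_blocks, query_blocks = alignment.aligned
    rs, re = int(ref_blocks[0][0]), int(ref_blocks[-1][1])
    qs, qe = int(query_blocks[0][0]), int(query_blocks[-1][1])
    aligned_len = int(sum(b[1] - b[0] for b in ref_blocks))
    columns = (qe - qs) + (re - rs) - aligned_len
    identities = int(alignment.counts().identities)
    return LocalHit(
        query_id=query_id,
        ref_id=ref_id,
        query_interval=(qs, qe),
        ref_interval=(rs, re),
        strand_or_frame="+",
        score=float(score),
        identity=identities / columns,
        aligned_columns=columns,
    )


def alignment_score(query: str, ref: str, scheme: ScoringScheme) -> float:
    """Score-only fast path of :func:`smith_waterman`."""
    _validate(query, scheme, "query")
    _validate(ref, scheme, "ref")
    score = _aligner(scheme).score(ref, query)
    return max(0.0, float(score))


FRAMES = (1, 2, 3, -1, -2, -3)


def translate_frame(nt: str, frame: int) -> str:
    seq = nt if frame > 0 else reverse_complement(nt)
    offset = abs(frame) - 1
    sub = seq[offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    return "".join(CODON_TO_AA[sub[i : i + 3]] for i in range(0, len(sub), 3))


def translate_six_frames(nt: str) -> dict[int, str]:
    """All six reading-frame translations; stops rendered '*'."""
    if len(nt) < 3:
        raise InputError("sequence shorter than one codon")
    bad = set(nt) - DNA_ALPHABET
    if bad:
        raise InputError(f"non-ACGT characters {sorted(bad)} in nucleotide sequence")
    return {frame: translate_frame(nt, frame) for frame in FRAMES}


def translated_best_hit(
    read_nt: str,
    marker_protein: str,
    scheme: ScoringScheme,
    query_id: str = "query",
    ref_id: str = "marker",
) -> LocalHit:
    """Best hit of any six-frame translation of a read against a marker.

    Ties are broken by the lowest frame in the order +1,+2,+3,-1,-2,-3.
    """
    if scheme.mode != "protein":
        raise ParameterError("translated_best_hit requires a protein scheme")
    frames = translate_six_frames(read_nt)
    best: LocalHit | None = None
    for frame in FRAMES:
        protein = frames[frame]
        if not protein:
            continue
        hit = smith_waterman(protein, marker_protein, scheme, query_id, ref_id)
        hit.strand_or_frame = frame
        if best is None or hit.score > best.score:
            best = hit
    if best is None:
        return LocalHit(query_id=query_id, ref_id=ref_id, strand_or_frame=1)
    return best


# ---------------------------------------------------------------------------
# Seeded search
# ---------------------------------------------------------------------------


def build_kmer_index(seq: str, k: int, stride: int = 1) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for pos in range(0, len(seq) - k + 1, stride):
        index[seq[pos : pos + k]].append(pos)
    return index


def _seed_diagonals(read: str, index: dict[str, list[int]], k: int, stride: int):
    votes: dict[int, int] = defaultdict(int)
    for offset in range(0, len(read) - k + 1, stride):
        for pos in index.get(read[offset : offset + k], ()):
            votes[pos - offset] += 1
    return votes


def seeded_map(
    reads,
    genome,
    k: int = 15,
    scheme: ScoringScheme | None = None,
    circular: bool = False,
    seed_stride: int = 4,
) -> dict[str, LocalHit | None]:
    """Map reads onto a genome (or dict of contigs) by exact k-mer seeding.

    Each read reports its best windowed Smith-Waterman hit or ``None``.  For a
    circular genome, seeds are looked up on the doubled sequence; reported
    ``ref_interval`` starts are normalized into ``[0, length)`` and intervals
    may extend past ``length`` to indicate an origin-spanning hit.  A reported
    score never exceeds the full-DP score for the same pair, because the
    windowed alignment is itself a valid local alignment.
    """
    scheme = scheme or ScoringScheme.nucleotide()
    if isinstance(genome, str):
        refs = {"ref": genome}
    else:
        refs = dict(genome)
    if k < 8:
        raise ParameterError("seed length k must be >= 8")
    indexes = {}
    lengths = {}
    for ref_id, seq in refs.items():
        lengths[ref_id] = len(seq)
        search_seq = seq + seq if circular else seq
        indexes[ref_id] = (build_kmer_index(search_seq, k), search_seq)

    results: dict[str, LocalHit | None] = {}
    pad = int(2 * scheme.gap_open)
    for read_id, read in reads:
        if k > len(read):
            raise ParameterError(f"seed length {k} exceeds read length for {read_id}")
        best: LocalHit | None = None
        for strand, oriented in (("+", read), ("-", reverse_complement(read))):
            for ref_id, (index, search_seq) in indexes.items():
                votes = _seed_diagonals(oriented, index, k, seed_stride)
                if not votes:
                    continue
                diag = max(votes, key=lambda d: (votes[d], -d))
                ws = max(0, diag - pad)
                we = min(len(search_seq), diag + len(oriented) + pad)
                hit = smith_waterman(
                    oriented, search_seq[ws:we], scheme, read_id, ref_id
                )
                if hit.is_empty:
                    continue
                rs, re = hit.ref_interval
                rs, re = rs + ws, re + ws
                if circular:
                    length = lengths[ref_id]
                    shift = (rs // length) * length
                    rs, re = rs - shift, re - shift
                hit.ref_interval = (rs, re)
                hit.strand_or_frame = strand
                if best is None or hit.score > best.score:
                    best = hit
        results[read_id] = best
    return results


def seeded_ungapped_hit(
    query: str,
    ref: str,
    scheme: ScoringScheme | None = None,
    k: int = 15,
    query_stride: int = 8,
    index: dict[str, list[int]] | None = None,
    query_id: str = "query",
    ref_id: str = "ref",
    n_diagonals: int = 5,
    both_strands: bool = True,
) -> LocalHit | None:
    """Best ungapped local segment shared by two long nucleotide sequences.

    Exact k-mer seeds vote for diagonals; on each of the top diagonals the
    maximal-scoring ungapped segment is found by a Kadane scan under the
    scheme's match/mismatch scores.  Suited to substitution-only divergence
    (no indel handling); the result is a valid local alignment, so its score
    is a lower bound on the full DP score.
    """
    scheme = scheme or ScoringScheme.nucleotide()
    if scheme.mode != "nucleotide":
        raise ParameterError("seeded_ungapped_hit operates on nucleotide sequences")
    if index is None:
        index = build_kmer_index(ref, k)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    best: LocalHit | None = None
    orientations = [("+", query)]
    if both_strands:
        orientations.append(("-", reverse_complement(query)))
    for strand, oriented in orientations:
        votes = _seed_diagonals(oriented, index, k, query_stride)
        if not votes:
            continue
        q_arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
        top = sorted(votes, key=lambda d: -votes[d])[:n_diagonals]
        for diag in top:
            qs = max(0, -diag)
            qe = min(len(oriented), len(ref) - diag)
            if qe <= qs:
                continue
            matches = q_arr[qs:qe] == ref_arr[qs + diag : qe + diag]
            scores = np.where(matches, scheme.match, scheme.mismatch)
            seg_start, seg_end, seg_score = _max_subarray(scores)
            if seg_score <= 0:
                continue
            a, b = qs + seg_start, qs + seg_end
            n_match = int(matches[seg_start:seg_end].sum())
            hit = LocalHit(
                query_id=query_id,
                ref_id=ref_id,
                query_interval=(a, b),
                ref_interval=(a + diag, b + diag),
                strand_or_frame=strand,
                score=float(seg_score),
                identity=n_match / (b - a),
                aligned_columns=b - a,
            )
            if strand == "-":
                # report in forward coordinates of the query
                qa, qb = hit.query_interval
                hit.query_interval = (len(query) - qb, len(query) - qa)
            if best is None or hit.score > best.score:
                best = hit
    return best


def _max_subarray(scores: np.ndarray) -> tuple[int, int, float]:
    """Kadane maximal-scoring contiguous segment: (start, end, score)."""
    best_score = 0.0
    best_start = best_end = 0
    run_score = 0.0
    run_start = 0
    for i, s in enumerate(scores.tolist()):
        if run_score <= 0:
            run_score = s
            run_start = i
        else:
            run_score += s
        if run_score > best_score:
            best_score = run_score
            best_start, best_end = run_start, i + 1
    return best_start, best_end, float(best_score)


def write_hits_tsv(hits, path) -> None:
    """Write hits as 12-column BLAST-outfmt-6-like TSV (1-based inclusive)."""
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(hit.as_outfmt6() + "\n")
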