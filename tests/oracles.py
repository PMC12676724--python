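"""Independent brute-force oracles used to validate the package.

These are intentionally naive reimplementations (full-matrix dynamic
programming, exhaustive enumeration) kept separate from the package code
paths they check.
"""

from __future__ import annotations

import itertools

NEG = float("-inf")


def gotoh_local_score(a: str, b: str, substitution, gap_open: float, gap_extend: float) -> float:
    """Full-matrix affine-gap local alignment score.

    ``substitution(x, y)`` returns the pair score; a gap of length L costs
    ``gap_open + L * gap_extend``.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + substitution(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def nt_substitution(match: float = 2.0, mismatch: float = -3.0):
    return lambda x, y: match if x == y else mismatch


def matrix_substitution(matrix):
    return lambda x, y: float(matrix[x, y])


_CODONS = {}


def _codon_table():
    if not _CODONS:
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[11]
        _CODONS.update(table.forward_table)
        for stop in table.stop_codons:
            _CODONS[stop] = "*"
    return _CODONS


def translate_naive(nt: str, frame: int) -> str:
    """Six-frame translation by direct codon lookup (frame in +-1..3)."""
    table = _codon_table()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    seq = nt if frame > 0 else "".join(comp[c] for c in reversed(nt))
    offset = abs(frame) - 1
    out = []
    for i in range(offset, len(seq) - 2, 3):
        out.append(table[seq[i : i + 3]])
    return "".join(out)


def brute_force_lis(values: list[int]) -> int:
    """Longest strictly increasing subsequence by exhaustive enumeration."""
    best = 0
    n = len(values)
    for mask in range(1 << n):
        picked = [values[i] for i in range(n) if mask >> i & 1]
        if all(x < y for x, y in zip(picked, picked[1:])):
            best = max(best, len(picked))
    return best


def brute_force_n50(lengths: list[int]) -> int:
    """Largest L such that contigs >= L sum to >= half the total."""
    total = sum(lengths)
    best = 0
    for L in sorted(set(lengths)):
        if sum(x for x in lengths if x >= L) >= total / 2:
            best = max(best, L)
    return best


def brute_force_coverage(intervals, length: int, circular: bool = False):
    """(depth array, mean depth, breadth) by per-position counting."""
    depth = [0] * length
    for start, end in intervals:
        for pos in range(start, end):
            depth[pos % length if circular else pos] += 1
    covered = sum(1 for d in depth if d > 0)
    return depth, sum(depth) / length, covered / length
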