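"""Reference-guided recovery of symbiont bins from contigs.

Contigs longer than the size cutoff that align convincingly to a reference
genome are recruited into a bin; a terminal-repeat check stands in for
assembly-graph circularity, and a gene-order (synteny) audit flags contigs
that look like binning errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .aligncore import (
    LocalHit,
    ScoringScheme,
    build_kmer_index,
    seeded_ungapped_hit,
)
from .errors import AuditError, InputError, ParameterError
from .prescreen import score_ratio


@dataclass(frozen=True)
class RecruitConfig:
    min_contig_len: int = 3000  # exclusive: strictly longer contigs qualify
    min_hit_columns: int = 1000
    min_identity: float = 0.80
    circular_overlap_min: int = 50

    def __post_init__(self):
        if min(self.min_contig_len, self.min_hit_columns, self.circular_overlap_min) <= 0:
            raise ParameterError("all recruit thresholds must be positive")
        if not (0.0 < self.min_identity <= 1.0):
            raise ParameterError("min_identity must be in (0, 1]")


def recruit_contigs(
    contigs: dict[str, str],
    references: dict[str, str],
    config: RecruitConfig | None = None,
    scheme: ScoringScheme | None = None,
    k: int = 15,
) -> dict[str, list[tuple[str, LocalHit]]]:
    """Assign qualifying contigs to their best-scoring reference.

    A contig is retained iff it is strictly longer than ``min_contig_len``
    and its best reference hit spans at least ``min_hit_columns`` aligned
    columns at ``min_identity`` or better.  Each contig goes to at most one
    reference (highest score; ties to the lexicographically smallest id).
    """
    config = config or RecruitConfig()
    scheme = scheme or ScoringScheme.nucleotide()
    if not references:
        raise InputError("at least one reference genome is required")
    indexes = {rid: build_kmer_index(seq, k) for rid, seq in references.items()}
    result: dict[str, list[tuple[str, LocalHit]]] = {rid: [] for rid in references}
    for contig_id in sorted(contigs):
        seq = contigs[contig_id]
        if len(seq) <= config.min_contig_len:
            continue
        best: tuple[float, str, LocalHit] | None = None
        for rid in sorted(references):
            hit = seeded_ungapped_hit(
                seq,
                references[rid],
                scheme,
                k=k,
                index=indexes[rid],
                query_id=contig_id,
                ref_id=rid,
            )
            if hit is None:
                continue
            if best is None or hit.score > best[0]:
                best = (hit.score, rid, hit)
        if best is None:
            continue
        _, rid, hit = best
        if hit.aligned_columns >= config.min_hit_columns and hit.identity >= config.min_identity:
            result[rid].append((contig_id, hit))
    return result


@dataclass
class Bin:
    """A recruited set of contigs with its assembly statistics."""

    bin_id: str
    contigs: dict[str, str]
    best_reference: str
    circular: bool = False
    circular_overlap: int = 0

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def largest_contig(self) -> int:
        return max(len(s) for s in self.contigs.values())

    @property
    def n50(self) -> int:
        lengths = sorted((len(s) for s in self.contigs.values()), reverse=True)
        half = self.total_length / 2
        acc = 0
        for length in lengths:
            acc += length
            if acc >= half:
                return length
        return lengths[-1]

    def stats(self) -> dict:
        return {
            "bin_id": self.bin_id,
            "best_reference": self.best_reference,
            "n_contigs": self.n_contigs,
            "total_length": self.total_length,
            "largest_contig": self.largest_contig,
            "N50": self.n50,
            "circular": self.circular,
            "circular_overlap": self.circular_overlap,
        }


def build_bin(contigs: dict[str, str], reference_id: str, bin_id: str | None = None) -> Bin:
    if not contigs:
        raise InputError("cannot build a bin from zero contigs")
    return Bin(bin_id or f"bin_{reference_id}", dict(contigs), reference_id)


def detect_circularity(bin_: Bin, config: RecruitConfig | None = None) -> tuple[bool, int, str | None]:
    """Terminal-exact-repeat circularity proxy.

    A single-contig bin is circular iff its prefix of length >=
    ``circular_overlap_min`` equals its suffix of the same length.  Returns
    ``(flag, longest overlap, trimmed sequence or None)`` and updates the bin.
    """
    config = config or RecruitConfig()
    if bin_.n_contigs != 1:
        return False, 0, None
    seq = next(iter(bin_.contigs.values()))
    overlap = _longest_border(seq, len(seq) // 2, config.circular_overlap_min)
    if overlap:
        bin_.circular = True
        bin_.circular_overlap = overlap
        return True, overlap, seq[:-overlap]
    return False, 0, None


def _z_array(seq: str) -> list[int]:
    """Z[i] = length of the longest common prefix of seq and seq[i:]."""
    n = len(seq)
    z = [0] * n
    z[0] = n
    left = right = 0
    for i in range(1, n):
        if i < right:
            z[i] = min(right - i, z[i - left])
        while i + z[i] < n and seq[z[i]] == seq[i + z[i]]:
            z[i] += 1
        if i + z[i] > right:
            left, right = i, i + z[i]
    return z


def _longest_border(seq: str, cap: int, minimum: int) -> int:
    """Longest p in [minimum, cap] with seq[:p] == seq[-p:], else 0."""
    n = len(seq)
    if n == 0 or minimum > cap:
        return 0
    z = _z_array(seq)
    for p in range(cap, minimum - 1, -1):
        if z[n - p] == p:
            return p
    return 0


@dataclass
class SyntenyAudit:
    """Collinearity of bin genes against the reference gene order."""

    anchors: list[tuple[str, str]]  # (bin gene id, reference gene id)
    collinear_fraction: float
    flagged_contigs: list[str]


def _best_hits(queries, subjects, scheme, bsr_min):
    """query gene id -> (subject gene id, ratio) for ratios >= bsr_min."""
    best = {}
    for qid, qseq in queries.items():
        top = None
        for sid in sorted(subjects):
            _, _, ratio = score_ratio(qseq, subjects[sid], scheme)
            if top is None or ratio > top[1]:
                top = (sid, ratio)
        if top is not None and top[1] >= bsr_min:
            best[qid] = top
    return best


def _longest_chain(values: list[int]) -> tuple[int, set[int]]:
    """Length and member indexes of a longest strictly increasing subsequence."""
    n = len(values)
    if n == 0:
        return 0, set()
    lengths = [1] * n
    parents = [-1] * n
    for i in range(n):
        for j in range(i):
            if values[j] < values[i] and lengths[j] + 1 > lengths[i]:
                lengths[i] = lengths[j] + 1
                parents[i] = j
    best_end = max(range(n), key=lambda i: lengths[i])
    members = set()
    i = best_end
    while i != -1:
        members.add(i)
        i = parents[i]
    return lengths[best_end], members


def audit_synteny(
    bin_genes: list[tuple[str, str, str]],
    reference_genes: list[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    bsr_min: float = 0.4,
) -> SyntenyAudit:
    """Best-reciprocal-hit anchoring plus longest collinear chain.

    ``bin_genes`` is an ordered list of ``(contig_id, gene_id, protein)``;
    ``reference_genes`` an ordered list of ``(gene_id, protein)``.  The
    collinear fraction is the longest order-preserving anchor chain (computed
    for both orientations) over the total number of anchors; contigs with no
    anchor on the chain are flagged.
    """
    scheme = scheme or ScoringScheme.protein()
    if not bin_genes or not reference_genes:
        raise AuditError("synteny audit requires genes on both sides")
    bin_prot = {gid: prot for _, gid, prot in bin_genes}
    ref_prot = dict(reference_genes)
    fwd = _best_hits(bin_prot, ref_prot, scheme, bsr_min)
    rev = _best_hits(ref_prot, bin_prot, scheme, bsr_min)
    ref_order = {gid: i for i, (gid, _) in enumerate(reference_genes)}
    anchors = []  # (bin order index, ref order index, bin gene id, ref gene id, contig)
    for order, (contig_id, gid, _prot) in enumerate(bin_genes):
        if gid not in fwd:
            continue
        rid = fwd[gid][0]
        if rev.get(rid, (None,))[0] == gid:
            anchors.append((order, ref_order[rid], gid, rid, contig_id))
    if not anchors:
        return SyntenyAudit([], 0.0, sorted({c for c, _, _ in bin_genes}))
    ref_indexes = [a[1] for a in anchors]
    n_fwd, members_fwd = _longest_chain(ref_indexes)
    n_rev, members_rev = _longest_chain([-v for v in ref_indexes])
    members = members_fwd if n_fwd >= n_rev else members_rev
    chain_len = max(n_fwd, n_rev)
    on_chain_contigs = {anchors[i][4] for i in members}
    all_contigs = {c for c, _, _ in bin_genes}
    flagged = sorted(all_contigs - on_chain_contigs)
    return SyntenyAudit(
        anchors=[(a[2], a[3]) for a in anchors],
        collinear_fraction=chain_len / len(anchors),
        flagged_contigs=flagged,
    )
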