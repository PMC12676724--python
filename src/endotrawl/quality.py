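"""Bin quality assessment: ORF calling, marker-set completeness and
contamination, rRNA presence, quality-tier classification and 16S identity
species assignment.

Completeness uses a custom marker set sized for tiny genomes; a marker found
in one or more copies counts as present, and the multi-copy fraction of the
set is reported as contamination.  Tier thresholds follow the community
MAG-quality standard: high needs >90% completeness, <5% contamination, all
three rRNAs and at least 18 tRNAs; medium needs >=50% and <10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .aligncore import (
    CODON_TO_AA,
    ScoringScheme,
    reverse_complement,
    seeded_ungapped_hit,
    smith_waterman,
)
from .errors import ConfigurationError, InputError
from .prescreen import score_ratio

START_CODONS = ("ATG", "GTG", "TTG")
RRNA_GENES = ("5S", "16S", "23S")


@dataclass
class OrfRecord:
    orf_id: str
    contig_id: str
    start: int  # includes the start codon
    end: int  # half-open, includes the stop codon
    strand: str
    protein: str


def _scan_frames(seq: str, limit: int, min_aa: int):
    """Maximal ORFs on the forward strand of ``seq`` starting before ``limit``."""
    for frame in range(3):
        start = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            aa = CODON_TO_AA[codon]
            if aa == "*":
                if start is not None and (pos - start) // 3 >= min_aa:
                    yield start, pos + 3
                start = None
            elif start is None and codon in START_CODONS and pos < limit:
                start = pos


def find_orfs(
    sequences: dict[str, str] | str,
    min_aa: int = 30,
    circular: bool = False,
) -> list[OrfRecord]:
    """All maximal start-to-stop ORFs of at least ``min_aa`` residues.

    Scans six frames; circular sequences are scanned across the origin on the
    doubled sequence.  Coordinates are forward-strand 0-based half-open and
    include both the start and the stop codon; the initiator codon is
    reported as M.
    """
    if isinstance(sequences, str):
        sequences = {"seq": sequences}
    orfs: list[OrfRecord] = []
    for contig_id in sorted(sequences):
        seq = sequences[contig_id]
        length = len(seq)
        scan = seq + seq if circular else seq
        limit = length if circular else len(scan)
        seen = set()
        for strand in "+-":
            oriented = scan if strand == "+" else reverse_complement(scan)
            for s, e in _scan_frames(oriented, len(oriented), min_aa):
                if strand == "-":
                    s, e = len(oriented) - e, len(oriented) - s
                if e - s > length:
                    continue
                if circular:
                    if s >= length:
                        s, e = s - length, e - length
                    if s >= length:
                        continue
                key = (strand, s, e)
                if key in seen:
                    continue
                seen.add(key)
                sub = (
                    scan[s:e]
                    if strand == "+"
                    else reverse_complement((seq + seq)[s:e] if circular else seq[s:e])
                )
                protein = "M" + "".join(
                    CODON_TO_AA[sub[i : i + 3]] for i in range(3, len(sub) - 3, 3)
                )
                orfs.append(
                    OrfRecord(
                        f"{contig_id}_orf{len(orfs) + 1:05d}",
                        contig_id,
                        s,
                        e,
                        strand,
                        protein,
                    )
                )
    return orfs


@dataclass
class MarkerSet:
    """Ordered set of single-copy marker proteins."""

    markers: list[tuple[str, str]]

    def __post_init__(self):
        ids = [m for m, _ in self.markers]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("marker ids must be unique")
        if not ids:
            raise ConfigurationError("marker set is empty")

    @property
    def size(self) -> int:
        return len(self.markers)

    @property
    def ids(self) -> list[str]:
        return [m for m, _ in self.markers]


def score_markers(
    proteins: list[tuple[str, str]],
    marker_set: MarkerSet,
    scheme: ScoringScheme | None = None,
    bsr_min: float = 0.4,
) -> dict[str, int]:
    """Per-marker hit counts over a bin's protein complement.

    A protein counts for marker ``m`` iff ``m`` is its best-scoring marker
    and the score ratio reaches ``bsr_min``.
    """
    scheme = scheme or ScoringScheme.protein()
    counts = {mid: 0 for mid in marker_set.ids}
    for _pid, protein in proteins:
        best = None
        for mid, mseq in marker_set.markers:
            _, _, ratio = score_ratio(protein, mseq, scheme)
            if best is None or ratio > best[1]:
                best = (mid, ratio)
        if best is not None and best[1] >= bsr_min:
            counts[best[0]] += 1
    return counts


def _round_percent(numerator: int, denominator: int, places: int = 2) -> float:
    quantum = Decimal(1).scaleb(-places)
    value = (Decimal(100) * numerator / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass
class QualityReport:
    bin_id: str
    found_single: list[str]
    found_multi: list[str]
    missing: list[str]
    completeness: float  # percent, 2 decimals, half away from zero
    contamination: float  # percent, 2 decimals
    rrna_5s: bool
    rrna_16s: bool
    rrna_23s: bool
    trna_count: int
    tier: str
    bin_stats: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def completeness_report(
    counts: dict[str, int],
    marker_set: MarkerSet,
    rrna_flags: dict[str, bool] | None = None,
    trna_count: int = 0,
    bin_stats: dict | None = None,
    bin_id: str = "bin",
) -> QualityReport:
    """Completeness/contamination percentages and the quality tier."""
    missing_keys = set(marker_set.ids) - set(counts)
    if missing_keys:
        raise InputError(f"counts lack markers: {sorted(missing_keys)[:5]} ...")
    rrna_flags = rrna_flags or {}
    single = [m for m in marker_set.ids if counts[m] == 1]
    multi = [m for m in marker_set.ids if counts[m] >= 2]
    missing = [m for m in marker_set.ids if counts[m] == 0]
    n = marker_set.size
    present = len(single) + len(multi)
    completeness_raw = 100.0 * present / n
    contamination_raw = 100.0 * len(multi) / n
    rrna_all = all(rrna_flags.get(g, False) for g in RRNA_GENES)
    if (
        completeness_raw > 90.0
        and contamination_raw < 5.0
        and rrna_all
        and trna_count >= 18
    ):
        tier = "high"
    elif completeness_raw >= 50.0 and contamination_raw < 10.0:
        tier = "medium"
    else:
        tier = "low"
    return QualityReport(
        bin_id=bin_id,
        found_single=single,
        found_multi=multi,
        missing=missing,
        completeness=_round_percent(present, n),
        contamination=_round_percent(len(multi), n),
        rrna_5s=rrna_flags.get("5S", False),
        rrna_16s=rrna_flags.get("16S", False),
        rrna_23s=rrna_flags.get("23S", False),
        trna_count=trna_count,
        tier=tier,
        bin_stats=bin_stats or {},
    )


def detect_rrna(
    bin_contigs: dict[str, str],
    rrna_refs: dict[str, str],
    scheme: ScoringScheme | None = None,
    min_identity: float = 0.80,
    min_cov: float = 0.80,
) -> dict[str, bool]:
    """Presence flags for the 5S/16S/23S genes in a bin."""
    scheme = scheme or ScoringScheme.nucleotide()
    for gene in RRNA_GENES:
        if gene not in rrna_refs:
            raise ConfigurationError(f"rRNA reference set lacks {gene}")
    flags = {}
    for gene in RRNA_GENES:
        ref = rrna_refs[gene]
        found = False
        for contig_id in sorted(bin_contigs):
            hit = seeded_ungapped_hit(
                ref, bin_contigs[contig_id], scheme, k=15, query_stride=1
            )
            if (
                hit is not None
                and hit.identity >= min_identity
                and hit.aligned_columns >= min_cov * len(ref)
            ):
                found = True
                break
        flags[gene] = found
    return flags


def assign_species(
    query_16s: str,
    reference_db: list[tuple[str, str, str]],
    scheme: ScoringScheme | None = None,
    min_identity: float = 0.987,
) -> tuple[str, str, float]:
    """Taxonomy of the best-scoring reference iff identity is strictly above
    the cutoff; otherwise ``("unclassified", ...)``.

    ``reference_db`` holds ``(ref_id, sequence, taxonomy)`` rows.  Returns
    ``(taxonomy, ref_id, identity)``.
    """
    if not query_16s:
        raise InputError("empty query sequence")
    if not reference_db:
        raise ConfigurationError("empty 16S reference database")
    scheme = scheme or ScoringScheme.nucleotide()
    best = None
    for ref_id, seq, taxonomy in reference_db:
        hit = smith_waterman(query_16s, seq, scheme, "query", ref_id)
        key = (hit.score, hit.identity, _neg_lex(ref_id))
        if best is None or key > best[0]:
            best = (key, ref_id, taxonomy, hit.identity)
    _, ref_id, taxonomy, identity = best
    if identity > min_identity:
        return taxonomy, ref_id, identity
    return "unclassified", ref_id, identity


class _neg_lex(str):
    """Orders strings in reverse, so max() prefers the lexicographically
    smallest id on full ties."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
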