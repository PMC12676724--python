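"""Sequential marker-gene triage of read sets via the BLAST Score Ratio.

A dataset is first screened for the ATP/ADP translocase marker (``tlcA``);
only datasets whose estimated marker coverage clears the gate are then
screened for the nitrous oxide reductase marker (``nosZ``).  Both marker
coverages must exceed the gate (default, strictly above 5-fold) for a pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .aligncore import (
    FRAMES,
    ScoringScheme,
    alignment_score,
    translate_six_frames,
)
from .errors import ComputationError, ConfigurationError, InputError

STAGE1_MARKER = "tlcA"
STAGE2_MARKER = "nosZ"
DEFAULT_BSR_MIN = 0.4
DEFAULT_COVERAGE_MIN = 5.0


@dataclass
class BsrRecord:
    """One read's score ratio against one marker."""

    query_id: str
    marker_id: str
    raw_score: float
    self_score: float
    bsr: float


def score_ratio(query: str, subject: str, scheme: ScoringScheme) -> tuple[float, float, float]:
    """(raw, self, ratio) for two sequences already in the scheme's space.

    With a diagonal-dominant scheme the ratio lies in [0, 1]; the self score
    is the query's full-length self-alignment score.
    """
    self_score = scheme.self_score(query)
    if self_score <= 0:
        raise ComputationError("degenerate query: non-positive self score")
    raw = alignment_score(query, subject, scheme)
    return raw, self_score, raw / self_score


def bsr(
    read: str,
    marker: str,
    scheme: ScoringScheme,
    read_id: str = "read",
    marker_id: str = "marker",
) -> BsrRecord:
    """BLAST Score Ratio of a read against a marker.

    Protein mode translates the read in six frames and takes the best
    per-frame ratio (each frame normalized by its own self score), so a read
    that is an exact reverse-translation of a marker fragment scores exactly
    1.0.  Nucleotide mode compares the read directly.
    """
    if not read or not marker:
        raise InputError("read and marker must be non-empty")
    if scheme.mode == "protein":
        best = None
        frames = translate_six_frames(read)
        for frame in FRAMES:
            protein = frames[frame]
            if not protein:
                continue
            raw, self_score, ratio = score_ratio(protein, marker, scheme)
            if best is None or ratio > best[2]:
                best = (raw, self_score, ratio)
        if best is None:
            raise ComputationError("read too short to translate")
        raw, self_score, ratio = best
    else:
        raw, self_score, ratio = score_ratio(read, marker, scheme)
    return BsrRecord(read_id, marker_id, raw, self_score, ratio)


def estimate_marker_coverage(
    hits: list[BsrRecord] | int, marker_nt_length: int, read_length: int
) -> float:
    """Fold coverage estimate: passing read bases over marker length."""
    if marker_nt_length <= 0:
        raise InputError("marker_nt_length must be positive")
    n = hits if isinstance(hits, int) else len(hits)
    return n * read_length / marker_nt_length


@dataclass
class ScreenReport:
    """Verdict of the sequential two-marker triage for one dataset."""

    dataset_id: str
    stage1_marker: str = STAGE1_MARKER
    stage2_marker: str = STAGE2_MARKER
    stage1_hits: int = 0
    stage2_hits: int = 0
    stage1_coverage: float = 0.0
    stage2_coverage: float = 0.0
    stage2_reads_scored: int = 0  # instrumentation: 0 when stage 1 fails
    bsr_min: float = DEFAULT_BSR_MIN
    coverage_min: float = DEFAULT_COVERAGE_MIN
    verdict: str = "fail_stage1"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _marker_nt_length(marker: str, scheme: ScoringScheme) -> int:
    return 3 * len(marker) if scheme.mode == "protein" else len(marker)


def _stage_hits(reads, marker: str, marker_id: str, scheme, bsr_min: float):
    hits = []
    scored = 0
    for read_id, seq in reads:
        scored += 1
        record = bsr(seq, marker, scheme, read_id, marker_id)
        if record.bsr >= bsr_min:
            hits.append(record)
    return hits, scored


def screen_dataset(
    reads,
    marker_db: dict[str, str],
    scheme: ScoringScheme | None = None,
    bsr_min: float = DEFAULT_BSR_MIN,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
    dataset_id: str = "dataset",
    read_length: int | None = None,
) -> ScreenReport:
    """Two-stage sequential screen; stage 2 is skipped when stage 1 fails.

    ``reads`` is a sequence of ``(read_id, sequence)`` pairs (consumed up to
    twice, so pass a list).  ``read_length`` defaults to the mean read length
    of the dataset.
    """
    scheme = scheme or ScoringScheme.protein()
    for required in (STAGE1_MARKER, STAGE2_MARKER):
        if required not in marker_db:
            raise ConfigurationError(f"marker database lacks {required!r}")
    reads = list(reads)
    if read_length is None:
        read_length = (
            int(round(sum(len(s) for _, s in reads) / len(reads))) if reads else 0
        )
    report = ScreenReport(
        dataset_id=dataset_id, bsr_min=bsr_min, coverage_min=coverage_min
    )
    hits1, _ = _stage_hits(reads, marker_db[STAGE1_MARKER], STAGE1_MARKER, scheme, bsr_min)
    report.stage1_hits = len(hits1)
    report.stage1_coverage = estimate_marker_coverage(
        hits1, _marker_nt_length(marker_db[STAGE1_MARKER], scheme), read_length
    )
    if not report.stage1_coverage > coverage_min:
        report.verdict = "fail_stage1"
        return report
    hits2, scored = _stage_hits(
        reads, marker_db[STAGE2_MARKER], STAGE2_MARKER, scheme, bsr_min
    )
    report.stage2_reads_scored = scored
    report.stage2_hits = len(hits2)
    report.stage2_coverage = estimate_marker_coverage(
        hits2, _marker_nt_length(marker_db[STAGE2_MARKER], scheme), read_length
    )
    report.verdict = (
        "pass" if report.stage2_coverage > coverage_min else "fail_stage2"
    )
    return report
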