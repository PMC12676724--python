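"""Genome presence calling from per-base coverage.

A genome is called present when its observed breadth of coverage is
compatible with the breadth expected at its mean depth under near-uniform
read placement, ``expected_breadth = 1 - exp(-0.883 * depth)``.  The default
check is one-sided (breadth at least 85% of expectation); a literal
two-sided +/-15% band is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .aligncore import LocalHit
from .errors import InputError, ParameterError

DECAY_COEFFICIENT = 0.883
RELATIVE_TOLERANCE = 0.15


@dataclass(frozen=True)
class DetectionModel:
    k: float = DECAY_COEFFICIENT
    tolerance: float = RELATIVE_TOLERANCE
    sidedness: str = "one_sided_lower"  # or "two_sided"

    def __post_init__(self):
        if self.k <= 0:
            raise ParameterError("decay coefficient must be positive")
        if not (0.0 < self.tolerance < 1.0):
            raise ParameterError("tolerance must be in (0, 1)")
        if self.sidedness not in ("one_sided_lower", "two_sided"):
            raise ParameterError(f"unknown sidedness {self.sidedness!r}")


@dataclass
class CoverageProfile:
    genome_id: str
    length: int
    depth: np.ndarray  # per-position read depth

    @property
    def mean_depth(self) -> float:
        return float(self.depth.sum() / self.length)

    @property
    def breadth(self) -> float:
        return float((self.depth > 0).sum() / self.length)


def coverage_profile(
    hits: list[LocalHit | None],
    genome_length: int,
    circular: bool = False,
    genome_id: str = "genome",
) -> CoverageProfile:
    """Accumulate per-position depth over the reference intervals of hits.

    Intervals extending past the end of a circular genome wrap around the
    origin; on a linear genome they raise an input error.  ``None`` entries
    (unmapped reads) are skipped.
    """
    delta = np.zeros(genome_length + 1, dtype=np.int64)
    for hit in hits:
        if hit is None or hit.is_empty:
            continue
        start, end = hit.ref_interval
        if start < 0 or start >= genome_length or end < start:
            raise InputError(f"interval {hit.ref_interval} out of bounds")
        if end <= genome_length:
            delta[start] += 1
            delta[end] -= 1
        elif circular:
            delta[start] += 1
            delta[genome_length] -= 1
            delta[0] += 1
            delta[end - genome_length] -= 1
        else:
            raise InputError(
                f"interval {hit.ref_interval} beyond linear genome of {genome_length}"
            )
    depth = np.cumsum(delta[:-1])
    return CoverageProfile(genome_id, genome_length, depth)


def expected_breadth(depth: float, model: DetectionModel | None = None) -> float:
    """Breadth expected at a mean depth: ``1 - exp(-k * depth)``."""
    if depth < 0:
        raise InputError("depth must be nonnegative")
    model = model or DetectionModel()
    return 1.0 - math.exp(-model.k * depth)


@dataclass
class DetectionCall:
    genome_id: str
    length: int
    depth: float
    breadth: float
    expected: float
    ratio: float  # observed / expected breadth; 0 when depth is 0
    detected: bool

    def to_dict(self) -> dict:
        return {
            "genome": self.genome_id,
            "length": self.length,
            "depth": self.depth,
            "breadth": self.breadth,
            "expected_breadth": self.expected,
            "ratio": self.ratio,
            "detected": self.detected,
        }


def call_presence(
    profile: CoverageProfile, model: DetectionModel | None = None
) -> DetectionCall:
    model = model or DetectionModel()
    d = profile.mean_depth
    b = profile.breadth
    if d == 0:
        return DetectionCall(profile.genome_id, profile.length, 0.0, 0.0, 0.0, 0.0, False)
    b_exp = expected_breadth(d, model)
    ratio = b / b_exp
    if model.sidedness == "one_sided_lower":
        detected = b >= (1.0 - model.tolerance) * b_exp
    else:
        detected = abs(b - b_exp) <= model.tolerance * b_exp
    return DetectionCall(profile.genome_id, profile.length, d, b, b_exp, ratio, detected)
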