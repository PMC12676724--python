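"""Synthetic inputs with known ground truth.

Generates the tiny circular symbiont genomes with planted marker genes,
diverged relatives, read sets over a background community, fragmented
"assemblies" and multi-year taxon count tables that stand in for real
sequencing datasets, so every downstream stage can be tested offline.

Every generator is a pure function of its arguments and seed: the same seed
yields byte-identical output.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import InputError, ParameterError, SizingError

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# aa -> synonymous codons, bacterial code (table 11), sorted for determinism
_table = CodonTable.unambiguous_dna_by_id[11]
AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_table.forward_table.items()):
    AA_TO_CODONS.setdefault(aa, []).append(codon)
STOP_CODON = "TAA"

# Spacer block containing a TAA stop in all three reading frames.  Intergenic
# spacers are built from {A,C,T} only so that no start codon (ATG/GTG/TTG)
# can occur outside a planted gene; together these two constraints make each
# planted gene a maximal ORF recoverable at its exact recorded coordinates.
_STOP_BLOCK = "TAATTAATTAA"
_SPACER_ALPHABET = np.frombuffer(b"ACT", dtype=np.uint8)
MIN_SPACER = len(_STOP_BLOCK)


@dataclass
class GeneRecord:
    gene_id: str
    genome_id: str
    start: int  # 0-based, includes start codon
    end: int  # half-open, includes stop codon
    strand: str = "+"


@dataclass
class GroundTruth:
    """Oracle record accompanying each generated artifact."""

    genes: list[GeneRecord] = field(default_factory=list)
    circular: bool = False
    read_origins: dict[str, tuple[str, int]] = field(default_factory=dict)
    fragments: list[tuple[str, int, int]] = field(default_factory=list)
    overlap: int = 0
    blooms: list[tuple[str, object, object, float]] = field(default_factory=list)
    baselines: dict[str, float] = field(default_factory=dict)


@dataclass
class SimSpec:
    """Parameters of a planted-genome simulation scenario."""

    seed: int = 0
    genome_id: str = "symbiont"
    genome_length: int = 300_000
    marker_catalog: list[tuple[str, str]] = field(default_factory=list)
    background_genomes: int = 20
    background_length: int = 20_000
    read_length: int = 150
    depth_per_genome: dict[str, float] = field(default_factory=dict)
    error_rate: float = 0.0
    divergence: float = 0.0
    dispersion: float = 0.3

    def __post_init__(self):
        if not (0.0 <= self.error_rate < 1.0):
            raise ParameterError("error_rate must be in [0, 1)")
        if not (0.0 <= self.divergence < 1.0):
            raise ParameterError("divergence must be in [0, 1)")


def make_marker_catalog(
    n_completeness: int = 55,
    stage_markers: tuple[str, ...] = ("tlcA", "nosZ"),
    length_range: tuple[int, int] = (150, 250),
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Random marker proteins: the stage markers plus N completeness markers.

    All proteins start with M so the corresponding planted genes begin with
    ATG and are recoverable as ORFs.
    """
    rng = np.random.default_rng(seed)
    names = list(stage_markers) + [f"scm_{i:03d}" for i in range(1, n_completeness + 1)]
    catalog = []
    for name in names:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        body = "".join(rng.choice(list(_AA20), size=length - 1))
        catalog.append((name, "M" + body))
    return catalog


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Seeded-random synonymous reverse translation (code 11), stop appended."""
    codons = []
    for aa in protein:
        if aa == "*":
            raise InputError("internal stop in marker protein")
        options = AA_TO_CODONS.get(aa)
        if options is None:
            raise InputError(f"unknown amino acid {aa!r}")
        codons.append(options[int(rng.integers(len(options)))])
    codons.append(STOP_CODON)
    return "".join(codons)


def _random_spacer(length: int, rng: np.random.Generator) -> str:
    if length < MIN_SPACER:
        raise SizingError("spacer shorter than the mandatory stop block")
    tail = rng.choice(_SPACER_ALPHABET, size=length - MIN_SPACER)
    return _STOP_BLOCK + tail.tobytes().decode()


def generate_symbiont_genome(spec: SimSpec) -> tuple[str, GroundTruth]:
    """Circular genome carrying one copy of each catalog gene in order."""
    if not spec.marker_catalog:
        raise InputError("marker catalog is empty")
    rng = np.random.default_rng(spec.seed)
    gene_nt = {}
    for name, protein in spec.marker_catalog:
        nt = reverse_translate(protein, rng)
        if protein.startswith("M"):
            nt = "ATG" + nt[3:]
        gene_nt[name] = nt
    total_genes = sum(len(nt) for nt in gene_nt.values())
    n = len(spec.marker_catalog)
    slack = spec.genome_length - total_genes - MIN_SPACER * (n + 1)
    if slack < 0:
        raise SizingError(
            f"genome_length {spec.genome_length} too short for {n} genes "
            f"({total_genes} nt) plus minimal spacers"
        )
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    parts = []
    genes = []
    pos = 0
    for i, (name, _protein) in enumerate(spec.marker_catalog):
        spacer = _random_spacer(MIN_SPACER + int(extra[i]), rng)
        parts.append(spacer)
        pos += len(spacer)
        nt = gene_nt[name]
        genes.append(GeneRecord(name, spec.genome_id, pos, pos + len(nt)))
        parts.append(nt)
        pos += len(nt)
    parts.append(_random_spacer(MIN_SPACER + int(extra[n]), rng))
    genome = "".join(parts)
    assert len(genome) == spec.genome_length
    return genome, GroundTruth(genes=genes, circular=True)


def random_genome(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length).tobytes().decode()


def derive_species(genome: str, divergence: float, seed: int) -> str:
    """Equal-length relative with seeded random substitutions, gene order kept."""
    if not (0.0 <= divergence < 1.0):
        raise ParameterError("divergence must be in [0, 1)")
    if divergence == 0.0:
        return genome
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.encode(), dtype=np.uint8).copy()
    sites = np.nonzero(rng.random(len(arr)) < divergence)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in sites:
        choices = bases[bases != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


@dataclass
class FastqRecord:
    id: str
    seq: str
    qual: str


def simulate_reads(
    genomes: dict[str, str],
    abundances: dict[str, float],
    read_length: int,
    error_rate: float,
    total_reads: int,
    seed: int,
    circular: bool | dict[str, bool] = True,
) -> tuple[list[FastqRecord], GroundTruth]:
    """Substitution-only reads; constant quality 'I' (Phred+33, Q40).

    Genome assignment is multinomial on ``abundances``; start positions are
    uniform.  Reads from circular genomes are drawn on the doubled sequence
    and their origin reported modulo length.
    """
    if total_reads < 0:
        raise ParameterError("total_reads must be >= 0")
    if total_reads == 0:
        return [], GroundTruth()
    if not genomes:
        raise InputError("no genomes to simulate reads from")
    if not (0.0 <= error_rate < 1.0):
        raise ParameterError("error_rate must be in [0, 1)")
    ids = sorted(genomes)
    weights = np.array([abundances.get(g, 0.0) for g in ids], dtype=float)
    if weights.sum() <= 0:
        raise InputError("abundances sum to zero")
    weights /= weights.sum()
    if isinstance(circular, bool):
        circular = {g: circular for g in ids}
    rng = np.random.default_rng(seed)
    assignment = rng.choice(len(ids), size=total_reads, p=weights)
    qual = "I" * read_length
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    reads: list[FastqRecord] = []
    origins: dict[str, tuple[str, int]] = {}
    for i in range(total_reads):
        gid = ids[int(assignment[i])]
        seq = genomes[gid]
        length = len(seq)
        if length < read_length and not circular[gid]:
            raise InputError(f"genome {gid} shorter than read length")
        if circular[gid]:
            start = int(rng.integers(length))
            doubled = seq + seq[:read_length]
            fragment = doubled[start : start + read_length]
        else:
            start = int(rng.integers(length - read_length + 1))
            fragment = seq[start : start + read_length]
        if error_rate > 0:
            errs = np.nonzero(rng.random(read_length) < error_rate)[0]
            if len(errs):
                arr = np.frombuffer(fragment.encode(), dtype=np.uint8).copy()
                for j in errs:
                    choices = bases[bases != arr[j]]
                    arr[j] = choices[int(rng.integers(3))]
                fragment = arr.tobytes().decode()
        read_id = f"r{i:07d}"
        reads.append(FastqRecord(read_id, fragment, qual))
        origins[read_id] = (gid, start)
    return reads, GroundTruth(read_origins=origins)


def fragment_genome(
    genome: str,
    n_fragments: int,
    min_len: int,
    seed: int,
    circular: bool = False,
    overlap: int = 50,
    contig_prefix: str = "contig",
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Tile a genome into contigs.

    Linear mode: fragments partition the genome exactly.  Circular mode: the
    final fragment additionally carries the first ``overlap`` bases of the
    genome, so concatenating all fragments and trimming the declared overlap
    reconstructs the input (and a single-fragment output has equal terminal
    repeats, exercising circularity detection).
    """
    if n_fragments < 1:
        raise ParameterError("n_fragments must be >= 1")
    if min_len < 1 or n_fragments * min_len > len(genome):
        raise SizingError(
            f"cannot cut {len(genome)} nt into {n_fragments} fragments of >= {min_len} nt"
        )
    rng = np.random.default_rng(seed)
    slack = len(genome) - n_fragments * min_len
    extra = rng.multinomial(slack, np.full(n_fragments, 1.0 / n_fragments))
    lengths = [min_len + int(e) for e in extra]
    contigs = []
    fragments = []
    pos = 0
    for i, length in enumerate(lengths):
        seq = genome[pos : pos + length]
        if circular and i == n_fragments - 1:
            seq = seq + genome[:overlap]
        cid = f"{contig_prefix}_{i + 1:03d}"
        contigs.append((cid, seq))
        fragments.append((cid, pos, pos + length))
        pos += length
    return contigs, GroundTruth(
        fragments=fragments, circular=circular, overlap=overlap if circular else 0
    )


def _parse_date(d) -> _dt.date:
    if isinstance(d, _dt.date):
        return d
    try:
        return _dt.date.fromisoformat(str(d))
    except ValueError as exc:
        raise InputError(f"unparsable date {d!r}") from exc


def simulate_timeseries(
    taxa: list[str],
    dates: list,
    baseline_abundances: dict[str, float],
    bloom_spec: list[tuple[str, object, object, float]] | None = None,
    dispersion: float = 0.3,
    seed: int = 0,
    plant: str = "simulated",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Dated taxon count table with optional multiplicative bloom intervals.

    Counts are negative-binomial around the baseline mean with variance
    ``mu + dispersion * mu**2``; ``dispersion=0`` yields deterministic
    (rounded) counts.  Bloom intervals are inclusive on both ends.
    """
    dates = [_parse_date(d) for d in dates]
    if any(b >= a for a, b in zip(dates[1:], dates)):
        raise ParameterError("dates must be strictly increasing")
    bloom_spec = bloom_spec or []
    blooms = []
    for taxon, start, end, fold in bloom_spec:
        start, end = _parse_date(start), _parse_date(end)
        if taxon not in taxa:
            raise ParameterError(f"bloom taxon {taxon!r} not in taxa")
        if start > end:
            raise ParameterError("bloom start after end")
        if start < dates[0] or end > dates[-1]:
            raise ParameterError("bloom interval outside sampled date range")
        blooms.append((taxon, start, end, float(fold)))
    rng = np.random.default_rng(seed)
    rows = []
    for i, date in enumerate(dates):
        row = {"sample_id": f"s{i:04d}", "date": date.isoformat(), "plant": plant}
        for taxon in taxa:
            mean = float(baseline_abundances.get(taxon, 0.0))
            for btaxon, start, end, fold in blooms:
                if btaxon == taxon and start <= date <= end:
                    mean *= fold
            row[taxon] = _draw_count(mean, dispersion, rng)
        rows.append(row)
    table = pd.DataFrame(rows)
    return table, GroundTruth(blooms=blooms, baselines=dict(baseline_abundances))


def _draw_count(mean: float, dispersion: float, rng: np.random.Generator) -> int:
    if mean <= 0:
        return 0
    if dispersion == 0:
        return int(round(mean))
    r = 1.0 / dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))
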