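import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from endotrawl import simdata
from endotrawl.aligncore import ScoringScheme

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def nt_scheme():
    return ScoringScheme.nucleotide()


@pytest.fixture(scope="session")
def protein_scheme():
    return ScoringScheme.protein()


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def random_protein(rng, length, start_m=True):
    body = "".join(rng.choice(list(AA20), size=length - (1 if start_m else 0)))
    return ("M" + body) if start_m else body


@pytest.fixture(scope="session")
def small_scenario():
    """A compact planted-genome scenario shared by prescreen/recruit/quality
    tests: 20 kb genome, 10 completeness markers, depth ~10 reads."""
    catalog = simdata.make_marker_catalog(n_completeness=10, seed=11)
    spec = simdata.SimSpec(seed=11, genome_length=20_000, marker_catalog=catalog)
    genome, truth = simdata.generate_symbiont_genome(spec)
    genomes = {"symbiont": genome}
    abundances = {"symbiont": 10.0 * len(genome)}
    for i in range(3):
        gid = f"bg_{i}"
        genomes[gid] = simdata.random_genome(8000, 900 + i)
        abundances[gid] = 3.0 * 8000
    total_reads = int(sum(abundances.values()) / 150)
    reads, read_truth = simdata.simulate_reads(
        genomes, abundances, read_length=150, error_rate=0.01,
        total_reads=total_reads, seed=12,
    )
    return {
        "catalog": catalog,
        "genome": genome,
        "truth": truth,
        "genomes": genomes,
        "reads": [(r.id, r.seq) for r in reads],
        "read_truth": read_truth,
        "marker_db": dict(catalog),
    }
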