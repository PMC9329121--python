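from __future__ import annotations

import numpy as np
import pytest

from mutlineage.catalog import SBSRecord
from mutlineage.genome import ReferenceGenome
from mutlineage.simulate import SimulationConfig, simulate_genome


def make_record(
    chrom: str = "chr1",
    pos: int = 5,
    ref: str = "C",
    alt: str = "T",
    sample_id: str = "s1",
    mut_fwd: int = 8,
    mut_rev: int = 7,
    depth: int = 30,
    ref_sample_depth: int = 30,
    ref_sample_mut: int = 0,
    asmd: float = 200.0,
    clpm: float = 0.0,
    pass_flag: bool = True,
) -> SBSRecord:
    return SBSRecord(
        sample_id, chrom, pos, ref, alt, mut_fwd, mut_rev, depth,
        ref_sample_depth, ref_sample_mut, asmd, clpm, pass_flag,
    )


@pytest.fixture
def toy_genome() -> ReferenceGenome:
    return ReferenceGenome({"chr1": "TTCATTCA"})


@pytest.fixture(scope="session")
def genome_100kb() -> ReferenceGenome:
    cfg = SimulationConfig(chromosomes={"c1": 60_000, "c2": 40_000})
    return simulate_genome(cfg, seed=11)


@pytest.fixture(scope="session")
def genome_1mb() -> ReferenceGenome:
    cfg = SimulationConfig(chromosomes={"c1": 1_000_000})
    return simulate_genome(cfg, seed=12)


def random_records_on(
    genome: ReferenceGenome,
    n: int,
    seed: int,
    sample_ids: tuple[str, ...] = ("s1",),
    edge_margin: int = 2,
) -> list[SBSRecord]:
    """Random valid SBS records placed at non-N positions of a genome."""
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    out: list[SBSRecord] = []
    while len(out) < n:
        chrom = chroms[rng.integers(len(chroms))]
        seq = genome[chrom]
        pos = int(rng.integers(1 + edge_margin, len(seq) - edge_margin + 1))
        ref = seq[pos - 1]
        if ref == "N":
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        sid = sample_ids[int(rng.integers(len(sample_ids)))]
        out.append(make_record(chrom, pos, ref, alt, sample_id=sid))
    return out
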