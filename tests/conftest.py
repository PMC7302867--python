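from __future__ import annotations

import numpy as np
import pytest

from polytract import (
    PlantedTract,
    Territory,
    generate_background,
    plant_tracts,
)


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = "ACGTN") -> str:
    """Random sequence; non-uniform alphabets seed repeat-rich test cases."""
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture(scope="session")
def small_genome():
    """50 kb genome with a handful of hand-chosen planted tracts + truth."""
    background = generate_background(50_000, seed=11)
    plants = [
        PlantedTract(1_000, "A", 8),
        PlantedTract(2_000, "C", 6),
        PlantedTract(5_000, "CA", 4, 1),
        PlantedTract(9_000, "GC", 3),
        PlantedTract(12_000, "AAC", 4, 2),
        PlantedTract(20_000, "CGG", 3),
        # hinge pair: two A/T monomer runs split by one base
        PlantedTract(30_000, "T", 7),
        PlantedTract(30_008, "A", 6),
    ]
    genome, truth = plant_tracts(background, plants, seed=12)
    return genome, truth


@pytest.fixture()
def toy_territory():
    """Deterministic 100 kb genome with a 30% territory (300 x 100 nt)."""
    intervals = [(i * 333, i * 333 + 100) for i in range(300)]
    return Territory(
        N=100_000,
        n=30_000,
        intervals={"chr1": intervals},
        seq_lengths={"chr1": 100_000},
        subset="toy",
    )


TOY_GTF = """\
chr1\tensembl\tgene\t1001\t6000\t.\t+\t.\tgene_id "G1"; gene_biotype "protein_coding";
chr1\tensembl\ttranscript\t1001\t6000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\tensembl\texon\t1001\t2000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\tensembl\texon\t3001\t4000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\tensembl\texon\t5001\t6000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\tensembl\tfive_prime_utr\t1001\t1500\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\tensembl\tCDS\t1501\t2000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\tensembl\tCDS\t3001\t4000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\tensembl\tCDS\t5001\t5500\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\tensembl\tthree_prime_utr\t5501\t6000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\tensembl\tgene\t20001\t22000\t.\t-\t.\tgene_id "G2"; gene_biotype "lincRNA";
chr1\tensembl\ttranscript\t20001\t22000\t.\t-\t.\tgene_id "G2"; transcript_id "G2.t1";
chr1\tensembl\texon\t20001\t20500\t.\t-\t.\tgene_id "G2"; transcript_id "G2.t1";
chr1\tensembl\texon\t21501\t22000\t.\t-\t.\tgene_id "G2"; transcript_id "G2.t1";
"""


@pytest.fixture(scope="session")
def toy_gtf(tmp_path_factory):
    path = tmp_path_factory.mktemp("gtf") / "toy.gtf"
    path.write_text(TOY_GTF)
    return str(path)
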