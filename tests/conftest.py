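import numpy as np
import pytest

from syntenic import (
    AlignmentParams,
    FixtureSpec,
    PlantedGene,
    make_fixture_genome,
    mutate_protein,
    random_protein,
    run_synteny,
)


@pytest.fixture(scope="session")
def align_params():
    return AlignmentParams()


@pytest.fixture(scope="session")
def cluster_proteins():
    """Five unrelated proteins, a paralog of P2 and the P4+P5 fusion."""
    rng = np.random.default_rng(11)
    prot = {
        "P1": random_protein(rng, 110),
        "P2": random_protein(rng, 90),
        "P3": random_protein(rng, 120),
        "P4": random_protein(rng, 80),
        "P5": random_protein(rng, 100),
    }
    prot["P2b"] = mutate_protein(rng, prot["P2"], 0.75)
    prot["fusion"] = prot["P4"] + prot["P5"]
    return prot


def _cluster_spec(prot, accession, organism, fuse=False, minus=False):
    genes, pos = [], 11000
    order = [("p1", "P1"), ("p2", "P2"), ("p2b", "P2b"), ("p3", "P3")]
    for tag, key in order:
        strand = -1 if (minus and tag == "p3") else 1
        genes.append(PlantedGene(tag, prot[key], pos, strand=strand))
        pos += len(prot[key]) * 3 + 3 + 400
    if fuse:
        genes.append(PlantedGene("p45", prot["fusion"], pos, product="fused protein"))
    else:
        genes.append(PlantedGene("p4", prot["P4"], pos))
        pos += len(prot["P4"]) * 3 + 3 + 200
        genes.append(PlantedGene("p5", prot["P5"], pos))
    return FixtureSpec(
        accession=accession, organism=organism, length_bp=30000, genes=tuple(genes)
    )


@pytest.fixture(scope="session")
def cluster_genomes(cluster_proteins):
    """Three genomes carrying the planted 5-gene cluster + one cluster-free decoy."""
    g1, _ = make_fixture_genome(
        _cluster_spec(cluster_proteins, "SYN001", "Synthetica prima"), 1
    )
    g2, _ = make_fixture_genome(
        _cluster_spec(cluster_proteins, "SYN002", "Synthetica secunda", minus=True), 2
    )
    g3, _ = make_fixture_genome(
        _cluster_spec(cluster_proteins, "SYN003", "Synthetica tertia", fuse=True), 3
    )
    g4, _ = make_fixture_genome(
        FixtureSpec(accession="SYN004", organism="Vacua quarta", length_bp=20000), 4
    )
    return [g1, g2, g3, g4]


@pytest.fixture(scope="session")
def cluster_report(cluster_proteins, cluster_genomes):
    return run_synteny(cluster_proteins["P1"], cluster_genomes)


@pytest.fixture(scope="session")
def single_gene_genome(cluster_proteins):
    """30 kb genome with one planted gene whose hit center is exactly 15000."""
    p = cluster_proteins["P3"]  # 120 aa -> coding 360 bp
    start = 15000 - (3 * len(p)) // 2
    spec = FixtureSpec(
        accession="ONE001",
        organism="Monogena sola",
        length_bp=30000,
        genes=(PlantedGene("only", p, start),),
    )
    record, _ = make_fixture_genome(spec, 9)
    return record, p
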