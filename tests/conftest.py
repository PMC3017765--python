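"""Shared fixtures: hand-built toy loci and simulated families."""

from __future__ import annotations

import numpy as np
import pytest

from genefam import phylogeny as ph
from genefam.synthetic import SimulationConfig, simulate_family


def make_random_additive(rng, n=8, min_len=0.1, max_len=1.0):
    """A random binary tree with uniform branch lengths and its exact
    additive (path-length) distance matrix."""
    ids = [f"t{k}" for k in range(n)]
    root = ph.Node()
    a = ph.Node(ids[0], rng.uniform(min_len, max_len))
    b = ph.Node(ids[1], rng.uniform(min_len, max_len))
    root.add(a)
    root.add(b)
    edges = [a, b]
    for name in ids[2:]:
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = ph.Node(None, target.length / 2)
        target.length = target.length / 2
        parent.detach(target)
        parent.add(mid)
        mid.add(target)
        leaf = ph.Node(name, rng.uniform(min_len, max_len))
        mid.add(leaf)
        edges.extend([mid, leaf])
    tree = ph.Tree(root)

    def path_up(leaf):
        dists = {}
        node, dist = leaf, 0.0
        while node is not None:
            dists[id(node)] = dist
            dist += node.length
            node = node.parent
        return dists

    leaves = {lf.name: lf for lf in tree.root.leaves()}
    paths = {name: path_up(lf) for name, lf in leaves.items()}
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pj = paths[ids[j]]
            node, di = leaves[ids[i]], 0.0
            while id(node) not in pj:
                di += node.length
                node = node.parent
            d[i, j] = d[j, i] = di + pj[id(node)]
    return tree, ph.DistanceMatrix(ids, d)


TOY_CONFIG = dict(
    seed=11,
    n_genes=20,
    protein_length=150,
    n_ancestral_introns=5,
    intron_loss_prob=0.1,
    intron_gain_rate=0.1,
    indel_prob=0.005,
    intron_length_mean=400,
    intron_length_range=(68, 2000),
    frac_noncanonical=0.05,
    n_chromosomes=4,
    cluster_spec=[(6, 1), (4, 0)],
)


@pytest.fixture(scope="session")
def sim_family(tmp_path_factory):
    """A 20-gene simulated family with files on disk plus its truth set."""
    outdir = tmp_path_factory.mktemp("family")
    cfg = SimulationConfig(**TOY_CONFIG)
    paths, truth = simulate_family(cfg, outdir)
    return cfg, paths, truth


@pytest.fixture()
def toy_genome_files(tmp_path):
    """A two-gene toy locus: plus-strand two-exon gene with a GT/AG intron
    and a minus-strand two-exon gene with a planted GC donor.

    Layout (chrT, 0-based):
      geneP: exons [0,9) + [100,112), intron [9,100) starting GT ending AG
      geneM (minus strand): sense exons are the reverse complement of
      genomic [200,230); intron planted with GC donor on the sense strand.
    """
    rng = np.random.default_rng(42)
    filler = "".join("ACGT"[k] for k in rng.integers(0, 4, size=1000))
    # plus-strand gene: CDS = ATGAAA GGG TTT ..., split 9 + 12
    exon1 = "ATGAAAGGG"
    exon2 = "TTTCCCGGGTAA"
    intron_p = "GT" + filler[:87] + "AG"
    # minus-strand gene occupies [200, 200+len) on the genomic strand.
    # Sense CDS: ATGGTTCCA | GAG TTG TGA split 9 + 9; sense intron with GC
    m_exon1, m_exon2 = "ATGGTTCCA", "GAGTTGTGA"
    m_intron = "GC" + filler[100:150] + "AG"
    sense_pre = m_exon1 + m_intron + m_exon2
    from Bio.Seq import Seq

    minus_block = str(Seq(sense_pre).reverse_complement())
    chrom = (
        exon1 + intron_p + exon2
        + filler[200:288]  # spacer to position 200
        + minus_block
        + filler[400:500]
    )
    assert chrom[112:200] == filler[200:288]
    m0 = 200
    m_len = len(sense_pre)
    # genomic exon intervals for the minus gene (mirrored)
    m_ex2 = (m0, m0 + len(m_exon2))                      # 3' exon first
    m_ex1 = (m0 + m_len - len(m_exon1), m0 + m_len)      # 5' exon last
    fasta = tmp_path / "toy.fasta"
    fasta.write_text(">chrT toy\n" + chrom + "\n")
    gff = tmp_path / "toy.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chrT\ttoy\tgene\t1\t112\t.\t+\t.\tID=geneP_g\n"
        "chrT\ttoy\tmRNA\t1\t112\t.\t+\t.\tID=geneP;Parent=geneP_g\n"
        "chrT\ttoy\tCDS\t1\t9\t.\t+\t0\tParent=geneP\n"
        "chrT\ttoy\tCDS\t101\t112\t.\t+\t0\tParent=geneP\n"
        f"chrT\ttoy\tgene\t{m0 + 1}\t{m0 + m_len}\t.\t-\t.\tID=geneM_g\n"
        f"chrT\ttoy\tmRNA\t{m0 + 1}\t{m0 + m_len}\t.\t-\t.\t"
        "ID=geneM;Parent=geneM_g\n"
        f"chrT\ttoy\tCDS\t{m_ex2[0] + 1}\t{m_ex2[1]}\t.\t-\t0\tParent=geneM\n"
        f"chrT\ttoy\tCDS\t{m_ex1[0] + 1}\t{m_ex1[1]}\t.\t-\t0\tParent=geneM\n"
    )
    return {
        "fasta": fasta,
        "gff3": gff,
        "chrom": chrom,
        "plus_cds": exon1 + exon2,
        "minus_cds": m_exon1 + m_exon2,
        "minus_intron_len": len(m_intron),
    }
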