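# genefam

Tools for analysing the genomic architecture of a gene family: intron–exon
organisation, splice-site phase conservation, distance phylogeny, chromosomal
clustering, cross-species microsynteny and EST-based expression profiling.

It is written for the kind of study where a superfamily of paralogs — the
motivating case is the insect carboxyl/cholinesterases (CCEs), a family of
~70 genes in the silkworm *Bombyx mori* spanning detoxification esterases,
juvenile hormone esterase and the catalytically inactive neuroligins — is
characterised genome-wide from a FASTA assembly, GFF3 gene models, an EST hit
table and per-species ortholog maps.

## What it computes

**Intron architecture.** Introns are taken from the GFF3 exon structure and
validated against the canonical GT/AG spliceosomal rule (non-canonical sites
are flagged, never dropped). Each splice site is classified by phase —
phase 0 between two codons, phase 1 one base into a codon in the 3'
direction, phase 2 two bases in — i.e. `phase = cds_offset mod 3` where
`cds_offset` counts coding nucleotides upstream of the splice. Introns are
projected into a shared protein multiple alignment: with `r = ⌊cds_offset/3⌋`
complete upstream codons, the hosting residue is residue `r+1` of the
ungapped protein, and its 1-based alignment column `c` gives the
codon-expanded coordinate `aln_nt_pos = 3(c−1) + phase`. Sites with equal
phase within a small position tolerance (default 3 nt, one codon of
alignment jitter) are merged by single linkage into conserved intron groups
— the signature of introns inherited from a common ancestor.

**Phylogeny.** Pairwise distances are maximum-likelihood divergence times
under the Jones–Taylor–Thornton (JTT) empirical amino-acid model with
pairwise gap deletion, optimised by bounded scalar search. Trees are built
with Saitou–Nei neighbor joining, optionally refined by a
nearest-neighbor-interchange hill climb minimising total OLS branch length
(minimum evolution), and supported by a column-resampling bootstrap
(default 500 replicates); clades with support above a threshold (default
50%) are flagged.

**Genome map.** Family loci are chained into tandem clusters (two family
genes join a cluster when at most `max_interlopers` non-family genes lie
between them; default 1), with orientation patterns recorded, and clusters
are checked for concordance with flagged phylogenetic clades. Two species'
ortholog maps are compared for microsynteny events: copy-number changes
(duplication/loss) and chromosome co-membership changes (split/fusion).

**Expression.** EST clone hits (clone id × gene × tissue library) are
tabulated per gene and per tissue, binned into a clone-count frequency
distribution, and optionally tested for clade × tissue enrichment
(Fisher exact + Benjamini–Hochberg; off by default).

**Synthetic families.** A generator evolves a family along a Yule tree under
JTT with codon-aligned indels, ancestral introns subject to per-branch loss
and gain, planted GT/AG (and a configurable fraction of non-canonical)
splice sites, tandem clusters with interloper genes and negative-binomial
EST counts — emitting standard FASTA/GFF3/TSV plus a complete truth set, so
every stage is testable without downloads.

## Worked example

```python
from genefam import (SimulationConfig, simulate_family, load_genome,
                     load_gene_models, extract_introns, progressive_msa)
from genefam.intron_architecture import (project_all, find_conserved_sites,
                                         length_stats)

cfg = SimulationConfig(seed=42, n_genes=20, protein_length=200,
                       n_ancestral_introns=5, intron_loss_prob=0.1,
                       cluster_spec=[(6, 1), (4, 0)], n_chromosomes=4)
paths, truth = simulate_family(cfg, "family/")

genome = load_genome(paths["genome"])
models = [m for m in load_gene_models(paths["gff3"], genome)
          if m.gene_id in truth.proteins]
introns = [i for m in models for i in extract_introns(m, genome)]
aln = progressive_msa({m.gene_id: m.protein for m in models})
sites, _ = project_all(introns, aln)
groups = find_conserved_sites(sites)
stats = length_stats(introns, models)

print(f"{stats.n_introns} introns, {stats.n_intronless_genes} intronless "
      f"genes, mean length {stats.mean_length:.0f} nt "
      f"(range {stats.min_length}-{stats.max_length})")
for g in groups[:3]:
    print(f"conserved intron at alignment nt {g.canonical_pos} "
          f"(phase {g.phase}): {g.n_members}/20 genes")
```

prints

```
89 introns, 0 intronless genes, mean length 1382 nt (range 88-4802)
conserved intron at alignment nt 539 (phase 2): 20/20 genes
conserved intron at alignment nt 69 (phase 0): 16/20 genes
conserved intron at alignment nt 462 (phase 0): 13/20 genes
```

The first line summarises the extracted intron complement; each following
line is one conserved intron position — the 20/20 phase-2 group is an
ancestral intron retained in every simulated gene, the smaller groups are
ancestral introns eroded by loss along the tree.

The same analysis runs from the shell:

```sh
genefam simulate --seed 42 --out family/
genefam all --genome family/genome.fasta --gff3 family/genes.gff3 \
    --loci family/loci.tsv --est family/est_hits.tsv \
    --bootstrap 500 --seed 1 --out results/
```

which writes per-stage TSVs (introns, projected sites, conserved groups,
clusters, expression tables), the supported-clade newick tree and a
consolidated `report.json`.

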