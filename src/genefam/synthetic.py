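"""Synthetic gene families with known truth.

A family is evolved along a Yule tree under the JTT substitution model with
codon-aligned (whole-residue) indels, ancestral introns subject to per-branch
loss and gain, tandem chromosomal clusters with non-family interloper genes,
and tissue-biased EST clone counts.  Every emitted file (genome FASTA, GFF3,
EST TSV, ortholog map) is paired with a truth set, so each pipeline stage
can be checked against known answers.

Residue homology is tracked with rational-number site keys: root residues
get keys 0..L-1 and an insertion between two sites gets the midpoint key, so
sorting all keys across leaves yields the true multiple alignment and every
intron site can be projected exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .msa import Alignment
from .phylogeny import AA_ORDER, Node, Tree, jtt_transition_matrix, _PI
from .genome_map import GeneLocus

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_family",
    "simulate_two_clade_alignment",
    "worked_example_fixtures",
    "neuroligin_example_maps",
]

# Tissue libraries mirroring a larval/pupal EST collection.
DEFAULT_TISSUES = [
    "midgut", "corpora allata", "silk gland", "ovary", "brain",
    "pheromone gland", "wing", "fat body", "hemocyte", "testis",
    "compound eyes", "maxillary galea", "epidermis", "Malpighian tubules",
    "Verson's gland", "prothoracic gland",
]

_CODONS_FOR = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()


@dataclass
class SimulationConfig:
    """Study conditions for a simulated gene family.

    Defaults emulate a ~70-member insect esterase family: mean intron length
    1372 nt with extremes 68..13962 nt, a handful of ancestral introns with
    per-branch loss, tandem clusters of six (one interloper) and four genes,
    and negative-binomial EST clone counts averaging ~5 clones/gene over 16
    tissue libraries.
    """

    seed: int = 0
    n_genes: int = 69
    protein_length: int = 300
    birth_rate: float = 1.0
    branch_scale: float = 0.3
    n_ancestral_introns: int = 6
    intron_loss_prob: float = 0.15
    intron_gain_rate: float = 0.2
    indel_prob: float = 0.005
    intron_length_mean: float = 1372.0
    intron_length_range: tuple[int, int] = (68, 13962)
    frac_noncanonical: float = 0.05
    n_chromosomes: int = 8
    cluster_spec: list[tuple[int, int]] = field(
        default_factory=lambda: [(6, 1), (4, 0)]
    )
    n_tissues: int = 16
    tissue_concentration: float = 0.4
    clones_per_gene_mean: float = 5.1
    clones_per_gene_dispersion: float = 0.45

    def validate(self) -> None:
        for p in (self.intron_loss_prob, self.indel_prob,
                  self.frac_noncanonical):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.intron_length_range[0] < 4:
            raise ValueError("intron length minimum must be >= 4")
        if self.n_genes < 1 or self.protein_length < 10:
            raise ValueError("family and protein sizes too small")
        if sum(s for s, _ in self.cluster_spec) > self.n_genes:
            raise ValueError("cluster sizes exceed n_genes")
        if self.n_tissues > len(DEFAULT_TISSUES):
            raise ValueError(
                f"at most {len(DEFAULT_TISSUES)} tissue labels available"
            )


@dataclass
class TruthSet:
    """Ground truth paired with the emitted files."""

    tree_newick: str
    alignment: dict[str, str]
    ancestral_introns: list[dict]
    gene_introns: dict[str, list[dict]]
    loss_trials: int
    loss_events: int
    n_gain_events: int
    clusters: list[dict]
    loci: list[dict]
    est_counts: dict[str, dict[str, int]]
    proteins: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def _yule_tree(n: int, birth_rate: float, scale: float, rng) -> Tree:
    """Ultrametric pure-birth tree with ``n`` leaves, root-to-tip = scale."""
    root = Node()
    if n == 1:
        leaf = Node("gene001", scale)
        root.add(leaf)
        return Tree(root)
    a, b = Node(), Node()
    root.add(a)
    root.add(b)
    tips = [a, b]
    depth = {a: 0.0, b: 0.0}
    elapsed = 0.0
    while len(tips) < n:
        elapsed += rng.exponential(1.0 / (birth_rate * len(tips)))
        parent = tips[rng.integers(len(tips))]
        parent.length = elapsed - depth[parent]
        c1, c2 = Node(), Node()
        parent.add(c1)
        parent.add(c2)
        tips.remove(parent)
        tips.extend([c1, c2])
        depth[c1] = depth[c2] = elapsed
    elapsed += rng.exponential(1.0 / (birth_rate * len(tips)))
    for tip in tips:
        tip.length = elapsed - depth[tip]
    # Scale to the requested root-to-tip path length and name leaves.
    factor = scale / elapsed if elapsed > 0 else 0.0
    for node in root.walk():
        node.length *= factor
    for k, leaf in enumerate(root.leaves(), 1):
        leaf.name = f"gene{k:03d}"
    return Tree(root)


# ---------------------------------------------------------------------------
# Sequence + intron evolution
# ---------------------------------------------------------------------------

def _sample_categorical(rng, cumrows: np.ndarray, states: np.ndarray) -> np.ndarray:
    u = rng.random(len(states))
    return np.array(
        [np.searchsorted(cumrows[s], x) for s, x in zip(states, u)],
        dtype=np.int64,
    )


class _LineageState:
    __slots__ = ("keys", "aas", "introns")

    def __init__(self, keys, aas, introns):
        self.keys = keys          # list[Fraction], sorted
        self.aas = aas            # np.ndarray int codes, same length
        self.introns = introns    # list[dict] with anchor_key, phase, ...


def _evolve_branch(state: _LineageState, t: float, cfg, rng, tally) -> _LineageState:
    # 1. substitutions
    P = jtt_transition_matrix(t)
    cum = np.cumsum(P, axis=1)
    aas = _sample_categorical(rng, cum, state.aas)
    keys = list(state.keys)

    # 2. whole-residue deletions (codon-aligned by construction)
    keep = rng.random(len(keys)) >= cfg.indel_prob / 2.0
    keep[0] = True  # never delete the initiator residue
    keys = [k for k, ok in zip(keys, keep) if ok]
    aas = aas[keep]

    # 3. whole-residue insertions
    ins_at = np.nonzero(rng.random(len(keys)) < cfg.indel_prob / 2.0)[0]
    if len(ins_at):
        pi_cum = np.cumsum(_PI)
        new_keys = list(keys)
        new_aas = list(aas)
        for pos in sorted(ins_at, reverse=True):
            left = keys[pos]
            right = keys[pos + 1] if pos + 1 < len(keys) else left + 2
            mid = (Fraction(left) + Fraction(right)) / 2
            aa = int(np.searchsorted(pi_cum, rng.random()))
            new_keys.insert(pos + 1, mid)
            new_aas.insert(pos + 1, aa)
        keys = new_keys
        aas = np.array(new_aas, dtype=np.int64)

    key_set = set(keys)

    # 4. intron loss: anchor deletion removes the intron outright; surviving
    #    anchors then face an explicit Bernoulli(loss) trial.
    introns = []
    for intron in state.introns:
        if intron["anchor_key"] not in key_set:
            continue
        tally["loss_trials"] += 1
        if rng.random() < cfg.intron_loss_prob:
            tally["loss_events"] += 1
            continue
        introns.append(dict(intron))

    # 5. intron gain at random internal offsets, >= 2 residues from existing
    n_gain = rng.poisson(cfg.intron_gain_rate)
    key_index = {k: i for i, k in enumerate(keys)}
    for _ in range(n_gain):
        for _attempt in range(20):
            r = int(rng.integers(1, len(keys)))
            anchors = [key_index.get(iv["anchor_key"]) for iv in introns]
            if any(a is not None and abs(a - r) < 2 for a in anchors):
                continue
            phase = int(rng.integers(0, 3))
            tally["gains"] += 1
            introns.append({
                "intron_id": f"gain{tally['gains']:04d}",
                "anchor_key": keys[r],
                "phase": phase,
                "ancestral": False,
            })
            break
    return _LineageState(keys, aas, introns)


def _evolve_family(cfg: SimulationConfig, tree: Tree, rng, tally):
    L = cfg.protein_length
    pi_cum = np.cumsum(_PI)
    root_aas = np.searchsorted(pi_cum, rng.random(L)).astype(np.int64)
    root_keys = [Fraction(i) for i in range(L)]

    # Ancestral introns: anchors >= 3 residues apart, away from the termini.
    anchors: list[int] = []
    while len(anchors) < cfg.n_ancestral_introns:
        r = int(rng.integers(2, L - 2))
        if all(abs(r - a) >= 3 for a in anchors):
            anchors.append(r)
    ancestral = []
    for k, r in enumerate(sorted(anchors), 1):
        ancestral.append({
            "intron_id": f"anc{k:02d}",
            "anchor_key": root_keys[r],
            "phase": int(rng.integers(0, 3)),
            "ancestral": True,
        })
    root_state = _LineageState(root_keys, root_aas, [dict(i) for i in ancestral])

    states: dict[str, _LineageState] = {}

    def descend(node: Node, state: _LineageState) -> None:
        for child in node.children:
            child_state = _evolve_branch(state, child.length, cfg, rng, tally)
            if child.is_leaf():
                states[child.name] = child_state
            else:
                descend(child, child_state)

    descend(tree.root, root_state)
    return states, ancestral


def _truth_alignment(states: dict[str, _LineageState]) -> dict[str, str]:
    all_keys = sorted({k for s in states.values() for k in s.keys})
    col = {k: i for i, k in enumerate(all_keys)}
    out = {}
    for name, s in states.items():
        row = ["-"] * len(all_keys)
        for k, aa in zip(s.keys, s.aas):
            row[col[k]] = AA_ORDER[aa]
        out[name] = "".join(row)
    return out


# ---------------------------------------------------------------------------
# Genome emission
# ---------------------------------------------------------------------------

def _random_nt(rng, n: int) -> str:
    return "".join("ACGT"[k] for k in rng.integers(0, 4, size=n))


def _draw_intron_length(cfg: SimulationConfig, rng) -> int:
    lo, hi = cfg.intron_length_range
    length = lo + int(rng.exponential(max(cfg.intron_length_mean - lo, 1.0)))
    return min(length, hi)


def _gene_structure(name: str, state: _LineageState, cfg, rng):
    """Pre-mRNA (sense strand), exon segment lengths and intron records."""
    protein = "".join(AA_ORDER[a] for a in state.aas)
    codons = [ _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))]
               for aa in protein ]
    cds = "".join(codons) + "TAA"
    key_index = {k: i for i, k in enumerate(state.keys)}

    placed = []
    for intron in sorted(state.introns,
                         key=lambda iv: (key_index[iv["anchor_key"]], iv["phase"])):
        r = key_index[intron["anchor_key"]]
        offset = 3 * r + intron["phase"]
        if not 0 < offset < len(cds):
            continue
        noncanonical = bool(rng.random() < cfg.frac_noncanonical)
        length = _draw_intron_length(cfg, rng)
        inner = _random_nt(rng, length - 4)
        donor, acceptor = ("GC", "AG") if noncanonical else ("GT", "AG")
        placed.append({
            "intron_id": intron["intron_id"],
            "ancestral": intron["ancestral"],
            "cds_offset": offset,
            "phase": intron["phase"],
            "anchor_index": r,
            "length": length,
            "seq": donor + inner + acceptor,
            "canonical": not noncanonical,
        })

    pieces = []
    exon_lengths = []
    prev = 0
    for iv in placed:
        exon_lengths.append(iv["cds_offset"] - prev)
        prev = iv["cds_offset"]
    exon_lengths.append(len(cds) - prev)
    pos = 0
    pre_mrna = []
    for k, ex_len in enumerate(exon_lengths):
        pre_mrna.append(cds[pos:pos + ex_len])
        pos += ex_len
        if k < len(placed):
            pre_mrna.append(placed[k]["seq"])
    for ordinal, iv in enumerate(placed, 1):
        iv["ordinal"] = ordinal
        del iv["seq"]
    return "".join(pre_mrna), exon_lengths, placed, protein, cds


def _layout_genome(cfg, tree, gene_parts, rng):
    """Place genes on chromosomes per cluster_spec; returns loci + pieces."""
    leaf_order = [lf.name for lf in tree.root.leaves()]
    assigned: list[str] = []
    clusters_members: list[list[str]] = []

    for size, _n_int in cfg.cluster_spec:
        members = None
        for node in tree.root.walk():
            if node is tree.root or node.is_leaf():
                continue
            leaves = [lf.name for lf in node.leaves()]
            if len(leaves) == size and not (set(leaves) & set(assigned)):
                members = leaves
                break
        if members is None:
            members = [g for g in leaf_order if g not in assigned][:size]
        clusters_members.append(members)
        assigned.extend(members)
    singletons = [g for g in leaf_order if g not in assigned]

    chrom_parts: dict[str, list[str]] = {
        f"chr{k + 1:02d}": [] for k in range(cfg.n_chromosomes)
    }
    chrom_names = list(chrom_parts)
    loci: list[dict] = []
    truth_clusters: list[dict] = []
    spacer_count = 0

    def chrom_len(chrom):
        return sum(len(p) for p in chrom_parts[chrom])

    def place(chrom, name, strand, in_family, structure):
        pre_mrna, exon_lengths, introns, protein, cds = structure
        parts = chrom_parts[chrom]
        parts.append(_random_nt(rng, int(rng.integers(2000, 5001))))
        g0 = chrom_len(chrom)
        total = len(pre_mrna)
        seq = pre_mrna if strand == "+" else str(
            Seq(pre_mrna).reverse_complement()
        )
        parts.append(seq)
        sense_spans = []
        cursor = 0
        for k, ex_len in enumerate(exon_lengths):
            sense_spans.append((cursor, cursor + ex_len))
            cursor += ex_len
            if k < len(introns):
                cursor += introns[k]["length"]
        if strand == "+":
            genomic = [(g0 + a, g0 + b) for a, b in sense_spans]
        else:
            genomic = [(g0 + total - b, g0 + total - a) for a, b in sense_spans]
            genomic.sort()
        loci.append({
            "gene_id": name, "chrom": chrom, "start": g0, "end": g0 + total,
            "strand": strand, "in_family": in_family, "exons": genomic,
        })

    def make_spacer():
        nonlocal spacer_count
        spacer_count += 1
        name = f"spacer{spacer_count:03d}"
        aa_codes = np.searchsorted(np.cumsum(_PI), rng.random(80))
        protein = "".join(AA_ORDER[int(a)] for a in aa_codes)
        cds = "".join(
            _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))]
            for aa in protein
        ) + "TAA"
        return name, (cds, [len(cds)], [], protein, cds)

    ci = 0
    for members, (size, n_int) in zip(clusters_members, cfg.cluster_spec):
        chrom = chrom_names[ci % len(chrom_names)]
        ci += 1
        strands = (["+"] * size if ci == 1
                   else [rng.choice(["+", "-"]) for _ in members])
        inter_slots = sorted(
            rng.choice(max(size - 1, 1), size=min(n_int, max(size - 1, 1)),
                       replace=False)
        ) if n_int else []
        slot = 0
        for k, name in enumerate(members):
            place(chrom, name, strands[k], True, gene_parts[name])
            if slot < len(inter_slots) and inter_slots[slot] == k:
                sname, structure = make_spacer()
                place(chrom, sname, str(rng.choice(["+", "-"])), False,
                      structure)
                slot += 1
        truth_clusters.append({
            "chrom": chrom, "members": members, "n_interlopers": len(inter_slots),
        })

    for k, name in enumerate(singletons):
        chrom = chrom_names[(ci + k) % len(chrom_names)]
        for _ in range(2):  # >= 2 interlopers insulate singletons
            sname, structure = make_spacer()
            place(chrom, sname, str(rng.choice(["+", "-"])), False, structure)
        place(chrom, name, str(rng.choice(["+", "-"])), True,
              gene_parts[name])

    for chrom in chrom_names:
        chrom_parts[chrom].append(_random_nt(rng, 3000))
    chromosomes = {c: "".join(p) for c, p in chrom_parts.items()}
    return chromosomes, loci, truth_clusters


def _emit_files(outdir: Path, chromosomes, loci, est_records):
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fasta"
    with open(fasta, "w") as fh:
        for chrom in sorted(chromosomes):
            fh.write(f">{chrom}\n")
            seq = chromosomes[chrom]
            for k in range(0, len(seq), 80):
                fh.write(seq[k:k + 80] + "\n")
    gff = outdir / "genes.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            chrom, name = locus["chrom"], locus["gene_id"]
            start1, end1 = locus["start"] + 1, locus["end"]
            strand = locus["strand"]
            fh.write(f"{chrom}\tgenefam_sim\tgene\t{start1}\t{end1}\t.\t"
                     f"{strand}\t.\tID={name}_g\n")
            fh.write(f"{chrom}\tgenefam_sim\tmRNA\t{start1}\t{end1}\t.\t"
                     f"{strand}\t.\tID={name};Parent={name}_g\n")
            for a, b in locus["exons"]:
                fh.write(f"{chrom}\tgenefam_sim\tCDS\t{a + 1}\t{b}\t.\t"
                         f"{strand}\t0\tParent={name}\n")
    est = outdir / "est_hits.tsv"
    with open(est, "w") as fh:
        fh.write("clone_id\tgene_id\ttissue\n")
        for rec in est_records:
            fh.write("\t".join(rec) + "\n")
    loci_tsv = outdir / "loci.tsv"
    with open(loci_tsv, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\tin_family\n")
        for locus in loci:
            fh.write(
                f"{locus['gene_id']}\t{locus['chrom']}\t{locus['start']}\t"
                f"{locus['end']}\t{locus['strand']}\t{locus['in_family']}\n"
            )
    ortho = outdir / "ortholog_map_self.tsv"
    with open(ortho, "w") as fh:
        fh.write("group\tgene_id\tchrom\tstart\tend\tstrand\n")
        for locus in loci:
            if locus["in_family"]:
                fh.write(
                    f"{locus['gene_id']}\t{locus['gene_id']}\t{locus['chrom']}"
                    f"\t{locus['start']}\t{locus['end']}\t{locus['strand']}\n"
                )
    return {"genome": fasta, "gff3": gff, "est": est,
            "loci": loci_tsv, "ortholog_map": ortho}


def simulate_family(
    cfg: SimulationConfig, outdir: str | Path | None = None
) -> tuple[dict, TruthSet]:
    """Simulate a gene family; returns (paths-or-objects, truth).

    With ``outdir`` set, writes genome.fasta, genes.gff3, est_hits.tsv,
    loci.tsv, ortholog_map_self.tsv and truth.json there and returns their
    paths; otherwise returns the in-memory objects under the same keys.
    Byte-identical outputs for identical seed and config.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tally = {"loss_trials": 0, "loss_events": 0, "gains": 0}

    tree = _yule_tree(cfg.n_genes, cfg.birth_rate, cfg.branch_scale, rng)
    states, ancestral = _evolve_family(cfg, tree, rng, tally)
    truth_aln = _truth_alignment(states)

    gene_parts = {}
    proteins = {}
    gene_introns: dict[str, list[dict]] = {}
    for name in [lf.name for lf in tree.root.leaves()]:
        structure = _gene_structure(name, states[name], cfg, rng)
        gene_parts[name] = structure
        proteins[name] = structure[3]
        gene_introns[name] = [
            {k: iv[k] for k in ("intron_id", "ancestral", "cds_offset",
                                "phase", "anchor_index", "length",
                                "canonical", "ordinal")}
            for iv in structure[2]
        ]

    chromosomes, loci, truth_clusters = _layout_genome(
        cfg, tree, gene_parts, rng
    )

    # EST clone counts: negative binomial per gene, Dirichlet-multinomial
    # spread over tissues.
    tissues = DEFAULT_TISSUES[: cfg.n_tissues]
    k = cfg.clones_per_gene_dispersion
    p = k / (k + cfg.clones_per_gene_mean)
    est_counts: dict[str, dict[str, int]] = {}
    est_records: list[tuple[str, str, str]] = []
    clone_no = 0
    for name in sorted(proteins):
        total = int(rng.negative_binomial(k, p))
        probs = rng.dirichlet([cfg.tissue_concentration] * len(tissues))
        alloc = rng.multinomial(total, probs)
        est_counts[name] = {
            t: int(c) for t, c in zip(tissues, alloc) if c > 0
        }
        for tissue, count in zip(tissues, alloc):
            for _ in range(int(count)):
                clone_no += 1
                est_records.append((f"EST{clone_no:05d}", name, tissue))

    truth = TruthSet(
        tree_newick=tree.newick(),
        alignment=truth_aln,
        ancestral_introns=[
            {"intron_id": iv["intron_id"],
             "anchor_index": int(iv["anchor_key"]),
             "phase": iv["phase"]}
            for iv in ancestral
        ],
        gene_introns=gene_introns,
        loss_trials=tally["loss_trials"],
        loss_events=tally["loss_events"],
        n_gain_events=tally["gains"],
        clusters=truth_clusters,
        loci=[{k: v for k, v in locus.items() if k != "exons"}
              for locus in loci],
        est_counts=est_counts,
        proteins=proteins,
    )

    if outdir is None:
        return {
            "chromosomes": chromosomes,
            "loci": loci,
            "est_records": est_records,
            "tree": tree,
        }, truth
    paths = _emit_files(Path(outdir), chromosomes, loci, est_records)
    truth.to_json(Path(outdir) / "truth.json")
    paths["truth"] = Path(outdir) / "truth.json"
    return paths, truth


# ---------------------------------------------------------------------------
# Focused helpers for phylogeny validation
# ---------------------------------------------------------------------------

def simulate_pair(t: float, length: int, rng) -> tuple[str, str]:
    """Two proteins separated by divergence time ``t`` under JTT."""
    pi_cum = np.cumsum(_PI)
    a = np.searchsorted(pi_cum, rng.random(length)).astype(np.int64)
    cum = np.cumsum(jtt_transition_matrix(t), axis=1)
    b = _sample_categorical(rng, cum, a)
    return ("".join(AA_ORDER[x] for x in a),
            "".join(AA_ORDER[x] for x in b))


def simulate_two_clade_alignment(
    n_per_clade: int = 4,
    internal_length: float = 0.5,
    tip_length: float = 0.1,
    length: int = 300,
    seed: int | None = None,
) -> tuple[Alignment, frozenset, frozenset]:
    """Indel-free alignment from two star clades joined by a long branch.

    Returns the alignment and the two clade leaf sets; the internal branch
    of ``internal_length`` substitutions/site separates them.
    """
    rng = np.random.default_rng(seed)
    pi_cum = np.cumsum(_PI)
    root = np.searchsorted(pi_cum, rng.random(length)).astype(np.int64)
    half = np.cumsum(jtt_transition_matrix(internal_length / 2.0), axis=1)
    tip = np.cumsum(jtt_transition_matrix(tip_length), axis=1)
    anc_a = _sample_categorical(rng, half, root)
    anc_b = _sample_categorical(rng, half, root)
    ids, rows = [], []
    for label, anc in (("A", anc_a), ("B", anc_b)):
        for k in range(n_per_clade):
            leaf = _sample_categorical(rng, tip, anc)
            ids.append(f"{label}{k + 1}")
            rows.append("".join(AA_ORDER[x] for x in leaf))
    clade_a = frozenset(i for i in ids if i.startswith("A"))
    clade_b = frozenset(i for i in ids if i.startswith("B"))
    return Alignment(ids, rows), clade_a, clade_b


# ---------------------------------------------------------------------------
# Worked-example fixtures and toy ortholog maps
# ---------------------------------------------------------------------------

def worked_example_fixtures() -> dict[str, "pd.DataFrame"]:
    """The two packaged EST summary tables (clone-count bins; tissue counts)."""
    import pandas as pd
    from importlib.resources import files

    data = files("genefam") / "data"
    return {
        "clone_bins": pd.read_csv(
            str(data / "est_clone_count_bins.tsv"), sep="\t", dtype=str
        ).astype({"n_genes": int}),
        "tissue_counts": pd.read_csv(
            str(data / "est_tissue_counts.tsv"), sep="\t"
        ),
    }


def neuroligin_example_maps() -> tuple[dict, dict]:
    """Two-species toy ortholog maps with one duplication, split and fusion.

    Species A keeps groups Nlg1/3/4/5 on one chromosome and Nlg2 alone;
    species B duplicates Nlg4, separates Nlg5 from the Nlg1/3/4 segment and
    fuses it with the Nlg2 segment.
    """
    def locus(gene, chrom, start, strand="+", group=None):
        return GeneLocus(gene, chrom, start, start + 1000, strand,
                         ortholog_group=group)

    map_a = {
        "Nlg1": [locus("a_nlg1", "chr_a1", 1000, group="Nlg1")],
        "Nlg3": [locus("a_nlg3", "chr_a1", 5000, group="Nlg3")],
        "Nlg4": [locus("a_nlg4", "chr_a1", 9000, group="Nlg4")],
        "Nlg5": [locus("a_nlg5", "chr_a1", 13000, group="Nlg5")],
        "Nlg2": [locus("a_nlg2", "chr_a2", 3000, group="Nlg2")],
    }
    map_b = {
        "Nlg3": [locus("b_nlg3", "chr_b1", 1000, group="Nlg3")],
        "Nlg1": [locus("b_nlg1", "chr_b1", 5000, group="Nlg1")],
        "Nlg4": [locus("b_nlg4a", "chr_b1", 9000, group="Nlg4"),
                 locus("b_nlg4b", "chr_b1", 13000, group="Nlg4")],
        "Nlg2": [locus("b_nlg2", "chr_b2", 2000, group="Nlg2")],
        "Nlg5": [locus("b_nlg5", "chr_b2", 8000, group="Nlg5")],
    }
    return map_a, map_b
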