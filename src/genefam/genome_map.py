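"""Chromosomal distribution of a gene family: tandem-cluster detection,
cluster/phylogeny concordance, and cross-species microsynteny events.

Microsynteny events are inferred by direct comparison of copy numbers and of
the chromosome co-membership partitions of shared ortholog groups; this is a
descriptive comparison, not a minimal-rearrangement solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "GeneLocus",
    "GeneCluster",
    "SyntenyEvent",
    "detect_clusters",
    "cluster_phylogeny_concordance",
    "compare_synteny",
    "read_loci_tsv",
    "read_ortholog_map",
    "chromosome_end_proximity",
]

EVENT_KINDS = {"duplication", "loss", "split", "fusion", "conserved"}


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    in_family: bool = True
    ortholog_group: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} >= end {self.end}"
            )


@dataclass
class GeneCluster:
    chromosome: str
    members: list[GeneLocus]
    n_interlopers: int

    @property
    def orientation_pattern(self) -> str:
        return "".join(m.strand for m in self.members)

    @property
    def member_ids(self) -> list[str]:
        return [m.gene_id for m in self.members]

    @property
    def span(self) -> tuple[int, int]:
        return self.members[0].start, self.members[-1].end


@dataclass
class SyntenyEvent:
    kind: str
    ortholog_groups: frozenset[str]
    detail: str = ""

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.ortholog_groups:
            raise ValueError("event with empty ortholog group set")


def detect_clusters(
    loci: list[GeneLocus],
    max_interlopers: int = 1,
    max_gap_bp: int = 100_000,
) -> list[GeneCluster]:
    """Maximal chains of family loci on one chromosome.

    Two consecutive family loci join a chain when at most ``max_interlopers``
    non-family genes lie between them; if the input carries no non-family
    annotation at all, a genomic-gap criterion (``max_gap_bp``) is used
    instead.  Clusters need >= 2 members.
    """
    have_annotation = any(not l.in_family for l in loci)
    clusters: list[GeneCluster] = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)

    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda l: (l.start, l.gene_id))
        fam_pos = [k for k, l in enumerate(ordered) if l.in_family]
        chain: list[int] = []
        for k in fam_pos:
            if chain:
                prev = chain[-1]
                if have_annotation:
                    between = sum(
                        1 for l in ordered[prev + 1:k] if not l.in_family
                    )
                    joined = between <= max_interlopers
                else:
                    joined = ordered[k].start - ordered[prev].end <= max_gap_bp
                if not joined:
                    clusters.extend(_finish_chain(ordered, chain))
                    chain = []
            chain.append(k)
        clusters.extend(_finish_chain(ordered, chain))
    return clusters


def _finish_chain(ordered: list[GeneLocus], chain: list[int]) -> list[GeneCluster]:
    if len(chain) < 2:
        return []
    members = [ordered[k] for k in chain]
    inside = ordered[chain[0]: chain[-1] + 1]
    n_interlopers = sum(1 for l in inside if not l.in_family)
    return [GeneCluster(members[0].chromosome, members, n_interlopers)]


def cluster_phylogeny_concordance(
    clusters: list[GeneCluster],
    clades: list[frozenset],
    leaf_names: list[str] | None = None,
) -> tuple[list[bool], dict]:
    """Is each chromosomal cluster contained in some supported clade?

    Returns a per-cluster boolean list and a summary dict with concordant /
    total counts.  With ``leaf_names`` given, cluster genes absent from the
    tree raise.
    """
    flags = []
    for cluster in clusters:
        members = set(cluster.member_ids)
        if leaf_names is not None and not members <= set(leaf_names):
            missing = sorted(members - set(leaf_names))
            raise ValueError(f"cluster genes not in tree: {missing}")
        flags.append(any(members <= clade for clade in clades))
    summary = {"concordant": sum(flags), "total": len(flags)}
    return flags, summary


def compare_synteny(
    map_a: dict[str, list[GeneLocus]],
    map_b: dict[str, list[GeneLocus]],
) -> list[SyntenyEvent]:
    """Infer microsynteny events of species B relative to species A.

    * copy number: more copies of a group in B than A -> duplication in B;
      fewer -> loss in B.
    * partition: a block of groups co-chromosomal in A that lands on >= 2 B
      chromosomes -> split (one event per separated part beyond the
      largest); a B chromosome hosting blocks from >= 2 A chromosomes ->
      fusion (one event per merged source beyond the first).
    * groups whose chromosome context is identical in both species and whose
      copy number is unchanged -> conserved.

    Maps are ``ortholog_group -> list of loci``.
    """
    if not map_a or not map_b:
        raise ValueError("empty ortholog map")
    events: list[SyntenyEvent] = []

    copies_a = {g: len(v) for g, v in map_a.items()}
    copies_b = {g: len(v) for g, v in map_b.items()}
    for group in sorted(set(copies_a) | set(copies_b)):
        ca, cb = copies_a.get(group, 0), copies_b.get(group, 0)
        if cb > ca:
            events.append(SyntenyEvent(
                "duplication", frozenset([group]),
                f"{group}: {ca} copy(ies) in A, {cb} in B",
            ))
        elif ca > cb:
            events.append(SyntenyEvent(
                "loss", frozenset([group]),
                f"{group}: {ca} copy(ies) in A, {cb} in B",
            ))

    shared = sorted(set(copies_a) & set(copies_b))
    chrom_a = {g: sorted({l.chromosome for l in map_a[g]}) for g in shared}
    chrom_b = {g: sorted({l.chromosome for l in map_b[g]}) for g in shared}
    # Use the first chromosome per group per species (multi-chromosome groups
    # are rare and flagged as ambiguous below).
    blocks_a: dict[str, set[str]] = {}
    blocks_b: dict[str, set[str]] = {}
    ambiguous: list[str] = []
    for g in shared:
        if len(chrom_a[g]) > 1 or len(chrom_b[g]) > 1:
            ambiguous.append(g)
        blocks_a.setdefault(chrom_a[g][0], set()).add(g)
        blocks_b.setdefault(chrom_b[g][0], set()).add(g)
    group_chrom_b = {g: chrom_b[g][0] for g in shared}
    group_chrom_a = {g: chrom_a[g][0] for g in shared}

    # Splits: one A block scattered across several B chromosomes.
    for chrom, block in sorted(blocks_a.items()):
        parts: dict[str, set[str]] = {}
        for g in block:
            parts.setdefault(group_chrom_b[g], set()).add(g)
        if len(parts) < 2:
            continue
        ordered = sorted(parts.values(), key=lambda p: (-len(p), sorted(p)))
        anchor = ordered[0]
        for part in ordered[1:]:
            note = ""
            if any(g in ambiguous for g in block):
                note = " (ambiguous: multi-chromosome group)"
            events.append(SyntenyEvent(
                "split", frozenset(part),
                f"separated from {{{','.join(sorted(anchor))}}} "
                f"(A chromosome {chrom}){note}",
            ))

    # Fusions: one B chromosome hosting blocks from several A chromosomes.
    for chrom, block in sorted(blocks_b.items()):
        sources: dict[str, set[str]] = {}
        for g in block:
            sources.setdefault(group_chrom_a[g], set()).add(g)
        if len(sources) < 2:
            continue
        events.append(SyntenyEvent(
            "fusion", frozenset(block),
            "merged segments from A chromosomes "
            + ",".join(sorted(sources)) + f" onto B chromosome {chrom}",
        ))

    # Conserved: same copy number, intact A block mapping to a B chromosome
    # that receives nothing else.
    for g in shared:
        if copies_a[g] != copies_b[g]:
            continue
        a_block = blocks_a[group_chrom_a[g]]
        b_block = blocks_b[group_chrom_b[g]]
        if a_block == b_block:
            events.append(SyntenyEvent(
                "conserved", frozenset([g]),
                f"{g}: context {{{','.join(sorted(a_block))}}} intact",
            ))
    return events


def read_loci_tsv(path: str | Path) -> list[GeneLocus]:
    """Read loci from TSV (gene_id, chrom, start, end, strand[, in_family])."""
    df = pd.read_csv(path, sep="\t")
    loci = []
    for row in df.itertuples(index=False):
        loci.append(GeneLocus(
            gene_id=str(row.gene_id),
            chromosome=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
            in_family=bool(getattr(row, "in_family", True)),
        ))
    return loci


def read_ortholog_map(path: str | Path) -> dict[str, list[GeneLocus]]:
    """Read an ortholog map TSV (group, gene_id, chrom, start, end, strand)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[GeneLocus]] = {}
    for row in df.itertuples(index=False):
        locus = GeneLocus(
            gene_id=str(row.gene_id),
            chromosome=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
            ortholog_group=str(row.group),
        )
        out.setdefault(str(row.group), []).append(locus)
    return out


def chromosome_end_proximity(
    loci: list[GeneLocus], chrom_lengths: dict[str, int]
) -> pd.DataFrame:
    """Distance of each family locus to the nearest chromosome end, as a
    fraction of half the chromosome length (0 = at an end, 1 = centre).

    Reported descriptively only; no telomere/centromere call is made.
    """
    rows = []
    for locus in loci:
        if not locus.in_family:
            continue
        length = chrom_lengths[locus.chromosome]
        mid = (locus.start + locus.end) / 2
        dist = min(mid, length - mid)
        rows.append({
            "gene_id": locus.gene_id,
            "chrom": locus.chromosome,
            "end_proximity": dist / (length / 2),
        })
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "end_proximity"])


def events_to_jsonl(events: list[SyntenyEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps({
                "kind": ev.kind,
                "ortholog_groups": sorted(ev.ortholog_groups),
                "detail": ev.detail,
            }) + "\n")
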