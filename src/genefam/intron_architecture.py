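"""Splice-phase classification, projection of introns into alignment
coordinates, conserved intron-position detection, and length statistics.

Coordinate convention: a projected intron site lives at nucleotide position
``aln_nt_pos = 3*(column-1) + phase`` in the codon-expanded alignment, where
``column`` is the 1-based alignment column of the residue whose codon hosts
(or immediately follows) the splice.  This makes ``aln_nt_pos mod 3`` equal
to the splice phase by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genome_io import GeneModel, Intron
from .msa import GAP, Alignment

__all__ = [
    "IntronSite",
    "ConservedIntronGroup",
    "IntronLengthStats",
    "ProjectionError",
    "intron_phase",
    "project_intron",
    "project_all",
    "find_conserved_sites",
    "length_stats",
    "shared_intron_matrix",
]


class ProjectionError(ValueError):
    """An intron cannot be placed in the alignment frame."""


@dataclass(frozen=True)
class IntronSite:
    """An intron projected into codon-expanded alignment coordinates."""

    gene_id: str
    aln_nt_pos: int
    phase: int
    intron_ref: tuple[str, int]


@dataclass
class ConservedIntronGroup:
    """A cross-gene group of intron sites sharing position and phase."""

    canonical_pos: int
    phase: int
    members: frozenset[str]
    pos_range: tuple[int, int]
    sites: tuple[IntronSite, ...]

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class IntronLengthStats:
    n_introns: int
    n_intronless_genes: int
    mean_length: float | None
    min_length: int | None
    max_length: int | None
    histogram: list[tuple[tuple[int, int], int]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_introns": self.n_introns,
            "n_intronless_genes": self.n_intronless_genes,
            "mean_length": self.mean_length,
            "mean_length_rounded": (
                None if self.mean_length is None else round(self.mean_length)
            ),
            "min_length": self.min_length,
            "max_length": self.max_length,
            "histogram": [
                {"bin_start": lo, "bin_end": hi, "count": c}
                for (lo, hi), c in self.histogram
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def intron_phase(cds_offset: int) -> int:
    """Splice-site phase: 0 between codons, 1 one base into a codon in the
    3' direction, 2 two bases in."""
    if cds_offset <= 0:
        raise ValueError(f"cds_offset must be positive, got {cds_offset}")
    return cds_offset % 3


def project_intron(intron: Intron, aln: Alignment) -> IntronSite:
    """Project an intron onto the shared alignment frame.

    With ``r`` complete codons upstream of the splice and phase ``p``, the
    hosting/following residue is residue ``r+1`` of the ungapped protein;
    its 1-based alignment column ``c`` gives ``aln_nt_pos = 3*(c-1) + p``.
    Introns after the final codon cannot be anchored and raise
    :class:`ProjectionError`.
    """
    p = intron_phase(intron.cds_offset)
    r = intron.cds_offset // 3
    row = aln.row(intron.gene_id)
    # 1-based alignment column of ungapped residue r+1.
    seen = 0
    column = None
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            seen += 1
            if seen == r + 1:
                column = col
                break
    if column is None:
        raise ProjectionError(
            f"{intron.gene_id} intron {intron.ordinal}: hosting residue "
            f"{r + 1} beyond protein length {seen}"
        )
    pos = 3 * (column - 1) + p
    return IntronSite(
        gene_id=intron.gene_id,
        aln_nt_pos=pos,
        phase=p,
        intron_ref=(intron.gene_id, intron.ordinal),
    )


def project_all(
    introns: list[Intron], aln: Alignment
) -> tuple[list[IntronSite], list[Intron]]:
    """Project every intron; returns (sites, unprojectable introns)."""
    sites, skipped = [], []
    for intron in introns:
        try:
            sites.append(project_intron(intron, aln))
        except ProjectionError:
            skipped.append(intron)
    return sites, skipped


def find_conserved_sites(
    sites: list[IntronSite],
    min_members: int = 2,
    tolerance_nt: int = 3,
) -> list[ConservedIntronGroup]:
    """Single-linkage grouping of same-phase sites within ``tolerance_nt``.

    A gene contributes at most one intron per group (the member closest to
    the group median is kept; ties break towards the lower intron ordinal).
    Groups with at least ``min_members`` distinct genes are returned,
    sorted by member count descending then canonical position.
    """
    groups: list[ConservedIntronGroup] = []
    by_phase: dict[int, list[IntronSite]] = {}
    for site in sites:
        by_phase.setdefault(site.phase, []).append(site)

    for phase in sorted(by_phase):
        chain: list[IntronSite] = []
        ordered = sorted(by_phase[phase],
                         key=lambda s: (s.aln_nt_pos, s.gene_id, s.intron_ref))
        for site in ordered:
            if chain and site.aln_nt_pos - chain[-1].aln_nt_pos > tolerance_nt:
                groups.extend(_finalize_group(chain, min_members))
                chain = []
            chain.append(site)
        if chain:
            groups.extend(_finalize_group(chain, min_members))

    groups.sort(key=lambda g: (-g.n_members, g.canonical_pos))
    return groups


def _finalize_group(
    chain: list[IntronSite], min_members: int
) -> list[ConservedIntronGroup]:
    positions = sorted(s.aln_nt_pos for s in chain)
    median = positions[len(positions) // 2]
    kept: dict[str, IntronSite] = {}
    for site in chain:
        prev = kept.get(site.gene_id)
        if prev is None:
            kept[site.gene_id] = site
            continue
        key_new = (abs(site.aln_nt_pos - median), site.intron_ref[1])
        key_old = (abs(prev.aln_nt_pos - median), prev.intron_ref[1])
        if key_new < key_old:
            kept[site.gene_id] = site
    members = frozenset(kept)
    if len(members) < min_members:
        return []
    sites = tuple(sorted(kept.values(),
                         key=lambda s: (s.aln_nt_pos, s.gene_id)))
    pos = [s.aln_nt_pos for s in sites]
    return [
        ConservedIntronGroup(
            canonical_pos=min(pos),
            phase=chain[0].phase,
            members=members,
            pos_range=(min(pos), max(pos)),
            sites=sites,
        )
    ]


def length_stats(
    introns: list[Intron],
    genes: list[GeneModel],
    bin_width: int = 500,
) -> IntronLengthStats:
    """Intron-length summary over a gene set.

    ``n_intronless_genes`` counts input genes with no introns; the histogram
    uses fixed-width bins ``[k*bin_width, (k+1)*bin_width)`` from zero.
    """
    lengths = [i.length_nt for i in introns]
    with_introns = {i.gene_id for i in introns}
    n_intronless = sum(1 for g in genes if g.gene_id not in with_introns)
    if not lengths:
        return IntronLengthStats(0, n_intronless, None, None, None, [])
    histogram: list[tuple[tuple[int, int], int]] = []
    top = max(lengths)
    for lo in range(0, top + 1, bin_width):
        hi = lo + bin_width
        count = sum(1 for x in lengths if lo <= x < hi)
        histogram.append(((lo, hi), count))
    return IntronLengthStats(
        n_introns=len(lengths),
        n_intronless_genes=n_intronless,
        mean_length=float(sum(lengths)) / len(lengths),
        min_length=min(lengths),
        max_length=max(lengths),
        histogram=histogram,
    )


def shared_intron_matrix(
    groups: list[ConservedIntronGroup],
    genes: list[GeneModel] | list[str],
    top_k: int = 2,
) -> tuple[pd.DataFrame, int]:
    """Gene x group presence matrix plus a top-k ancestral-intron summary.

    Returns the boolean matrix (one column per group, labelled by canonical
    position and phase) and the number of genes containing at least one of
    the ``top_k`` most-populated groups.
    """
    gene_ids = [g if isinstance(g, str) else g.gene_id for g in genes]
    cols = [f"pos{g.canonical_pos}_p{g.phase}" for g in groups]
    data = {
        col: [gid in grp.members for gid in gene_ids]
        for col, grp in zip(cols, groups)
    }
    matrix = pd.DataFrame(data, index=gene_ids, columns=cols, dtype=bool)
    top = sorted(groups, key=lambda g: (-g.n_members, g.canonical_pos))[:top_k]
    covered = set().union(*(g.members for g in top)) if top else set()
    summary = sum(1 for gid in gene_ids if gid in covered)
    return matrix, summary


def sites_to_tsv(sites: list[IntronSite], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "aln_nt_pos": s.aln_nt_pos,
                "phase": s.phase,
                "intron_ordinal": s.intron_ref[1],
            }
            for s in sites
        ],
        columns=["gene_id", "aln_nt_pos", "phase", "intron_ordinal"],
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def groups_to_tsv(
    groups: list[ConservedIntronGroup], path: str | Path
) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "canonical_pos": g.canonical_pos,
                "phase": g.phase,
                "n_members": g.n_members,
                "pos_min": g.pos_range[0],
                "pos_max": g.pos_range[1],
                "members": ",".join(sorted(g.members)),
            }
            for g in groups
        ],
        columns=["canonical_pos", "phase", "n_members",
                 "pos_min", "pos_max", "members"],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
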