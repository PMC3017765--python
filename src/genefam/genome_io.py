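"""Genome FASTA / GFF3 input and gene-model construction.

Coordinates are 1-based closed on GFF3 disk I/O and 0-based half-open
internally; the conversion happens only at the parsing boundary.  Exons are
stored in transcription order (ascending genomic start on the plus strand,
descending on the minus strand).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "Intron",
    "GenomeIOError",
    "load_genome",
    "load_gene_models",
    "extract_introns",
    "write_introns_tsv",
]

# IUPAC nucleotide codes (plus gap characters never expected in a genome).
_IUPAC_NT = set("ACGTURYSWKMBDHVN")

INTRON_TSV_COLUMNS = [
    "gene_id", "ordinal", "chrom", "start", "end", "length",
    "donor", "acceptor", "cds_offset", "phase", "canonical",
]


class GenomeIOError(ValueError):
    """Malformed genome or gene-model input."""


@dataclass
class GeneModel:
    """A protein-coding gene model.

    ``exons`` are 0-based half-open genomic intervals in transcription order.
    ``cds_seq`` is the spliced coding sequence on the sense (mRNA) strand;
    ``protein`` its standard-code translation with the terminal stop removed.
    Models whose CDS length is not a multiple of three are flagged
    ``incomplete`` and are excluded from phase analysis by default.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_seq: str
    protein: str
    incomplete: bool = False
    internal_stop: bool = False

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)


@dataclass
class Intron:
    """One intron of a gene model, on the transcribed strand.

    ``cds_offset`` counts coding nucleotides upstream of the splice;
    ``phase`` is ``cds_offset mod 3``.  ``donor``/``acceptor`` are the first
    and last two intron nucleotides read 5'->3' on the transcribed strand;
    the canonical spliceosomal signature is GT...AG.
    """

    gene_id: str
    ordinal: int
    chromosome: str
    start: int
    end: int
    donor: str
    acceptor: str
    cds_offset: int
    phase: int = field(init=False)
    canonical: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.end - self.start < 4:
            raise GenomeIOError(
                f"{self.gene_id} intron {self.ordinal}: length "
                f"{self.end - self.start} < 4 nt"
            )
        if not 0 < self.cds_offset:
            raise GenomeIOError(
                f"{self.gene_id} intron {self.ordinal}: non-positive cds_offset"
            )
        self.phase = self.cds_offset % 3
        self.canonical = self.donor == "GT" and self.acceptor == "AG"

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def load_genome(fasta_path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into ``{chromosome: uppercase sequence}``.

    Sequences are keyed by the first whitespace-separated token of the
    header.  Duplicate ids and non-IUPAC characters raise ``GenomeIOError``.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in genome:
            raise GenomeIOError(f"duplicate sequence id {name!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC_NT
        if bad:
            raise GenomeIOError(
                f"non-IUPAC characters {sorted(bad)} in sequence {name!r}"
            )
        genome[name] = seq
    return genome


def _parse_gff3_records(path: Path) -> Iterable[tuple[str, str, int, int, str, dict]]:
    """Yield (chrom, type, start0, end0, strand, attributes) per feature."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GenomeIOError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = parts
            try:
                start1, end1 = int(start), int(end)
            except ValueError as exc:
                raise GenomeIOError(f"{path}:{lineno}: bad coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise GenomeIOError(f"{path}:{lineno}: bad interval {start}..{end}")
            attributes = {}
            for item in attrs.split(";"):
                if not item:
                    continue
                key, _, value = item.partition("=")
                attributes[key.strip()] = value
            # GFF3 is 1-based closed; internal coordinates 0-based half-open.
            yield chrom, ftype, start1 - 1, end1, strand, attributes


def load_gene_models(
    gff3_path: str | Path,
    genome: dict[str, str],
    collapse_variants: bool = True,
) -> list[GeneModel]:
    """Build one :class:`GeneModel` per mRNA from a GFF3 file.

    Only ``gene``/``mRNA``/``CDS`` features are used.  Minus-strand exons are
    reverse-complemented and ordered 5'->3' along the transcript.  With
    ``collapse_variants`` (default) alternative transcripts of a gene are
    collapsed to the one with the longest CDS.
    """
    path = Path(gff3_path)
    if not path.exists():
        raise FileNotFoundError(path)

    mrna_meta: dict[str, tuple[str, str, str]] = {}  # id -> (chrom, strand, gene)
    mrna_cds: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []

    for chrom, ftype, start, end, strand, attrs in _parse_gff3_records(path):
        if ftype == "mRNA":
            mrna_id = attrs.get("ID")
            if mrna_id is None:
                raise GenomeIOError(f"mRNA without ID attribute in {path}")
            gene_id = attrs.get("Parent", mrna_id)
            mrna_meta[mrna_id] = (chrom, strand, gene_id)
            mrna_cds.setdefault(mrna_id, [])
            order.append(mrna_id)
        elif ftype == "CDS":
            parent = attrs.get("Parent")
            if parent is None:
                raise GenomeIOError(f"CDS without Parent attribute in {path}")
            for pid in parent.split(","):
                mrna_cds.setdefault(pid, []).append((start, end))
                if pid not in mrna_meta:
                    mrna_meta[pid] = (chrom, strand, pid)
                    order.append(pid)

    models: list[GeneModel] = []
    for mrna_id in order:
        chrom, strand, gene_id = mrna_meta[mrna_id]
        segs = sorted(mrna_cds.get(mrna_id, []))
        if not segs:
            raise GenomeIOError(f"mRNA {mrna_id!r} has no CDS features")
        if chrom not in genome:
            raise GenomeIOError(f"mRNA {mrna_id!r}: unknown chromosome {chrom!r}")
        chrom_len = len(genome[chrom])
        for a, b in segs:
            if b > chrom_len:
                raise GenomeIOError(
                    f"mRNA {mrna_id!r}: CDS end {b} beyond chromosome "
                    f"{chrom!r} length {chrom_len}"
                )
        for (a1, b1), (a2, _b2) in zip(segs, segs[1:]):
            if a2 < b1:
                raise GenomeIOError(f"mRNA {mrna_id!r}: overlapping CDS segments")
        if strand not in "+-":
            raise GenomeIOError(f"mRNA {mrna_id!r}: bad strand {strand!r}")

        exons = segs if strand == "+" else segs[::-1]
        spliced = "".join(genome[chrom][a:b] for a, b in segs)
        cds = spliced if strand == "+" else str(Seq(spliced).reverse_complement())

        incomplete = len(cds) % 3 != 0
        trans_len = len(cds) - len(cds) % 3
        protein = str(Seq(cds[:trans_len]).translate())
        if protein.endswith("*"):
            protein = protein[:-1]
        internal_stop = "*" in protein
        if internal_stop:
            warnings.warn(f"gene model {mrna_id} has an internal stop codon")

        models.append(
            GeneModel(
                gene_id=mrna_id,
                chromosome=chrom,
                strand=strand,
                exons=exons,
                cds_seq=cds,
                protein=protein,
                incomplete=incomplete,
                internal_stop=internal_stop,
            )
        )

    if collapse_variants:
        best: dict[str, GeneModel] = {}
        kept_order: list[str] = []
        gene_of = {mid: mrna_meta[mid][2] for mid in order}
        for model in models:
            locus = gene_of[model.gene_id]
            if locus not in best:
                best[locus] = model
                kept_order.append(locus)
            elif model.cds_length > best[locus].cds_length:
                best[locus] = model
        models = [best[locus] for locus in kept_order]
    return models


def extract_introns(gene: GeneModel, genome: dict[str, str]) -> list[Intron]:
    """Extract the ``n_exons - 1`` introns of a gene model.

    Donor/acceptor dinucleotides are read on the transcribed strand; the
    canonical flag marks GT...AG introns.  Non-canonical introns are retained
    and flagged, never dropped.
    """
    if gene.n_exons == 0:
        raise GenomeIOError(f"{gene.gene_id}: gene model has no exons")
    chrom_seq = genome[gene.chromosome]
    introns: list[Intron] = []
    cds_offset = 0
    for ordinal, (up, down) in enumerate(zip(gene.exons, gene.exons[1:]), 1):
        cds_offset += up[1] - up[0]
        if gene.strand == "+":
            start, end = up[1], down[0]
        else:
            start, end = down[1], up[0]
        if end <= start:
            raise GenomeIOError(
                f"{gene.gene_id}: exons overlap or are out of order "
                f"around intron {ordinal}"
            )
        iseq = chrom_seq[start:end]
        if gene.strand == "-":
            iseq = str(Seq(iseq).reverse_complement())
        introns.append(
            Intron(
                gene_id=gene.gene_id,
                ordinal=ordinal,
                chromosome=gene.chromosome,
                start=start,
                end=end,
                donor=iseq[:2],
                acceptor=iseq[-2:],
                cds_offset=cds_offset,
            )
        )
    return introns


def write_introns_tsv(introns: list[Intron], path: str | Path) -> pd.DataFrame:
    """Write the intron table as TSV and return it as a DataFrame."""
    df = pd.DataFrame(
        [
            {
                "gene_id": i.gene_id,
                "ordinal": i.ordinal,
                "chrom": i.chromosome,
                "start": i.start,
                "end": i.end,
                "length": i.length_nt,
                "donor": i.donor,
                "acceptor": i.acceptor,
                "cds_offset": i.cds_offset,
                "phase": i.phase,
                "canonical": i.canonical,
            }
            for i in introns
        ],
        columns=INTRON_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
    return df
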