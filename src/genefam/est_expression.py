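"""EST clone tabulation: per-gene and per-tissue expression summaries and an
optional clade/tissue enrichment layer.

EST counts are a crude expression proxy (single-pass cDNA reads per tissue
library, with unknown library depths), so all summaries are descriptive
counts; the Fisher-exact enrichment test is an explicit extension and is off
by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ESTRecord",
    "ExpressionTable",
    "read_est_tsv",
    "tabulate",
    "clone_frequency_distribution",
    "tissue_summary",
    "clade_tissue_association",
    "CLONE_BIN_LABELS",
]

# Bin edges for the clone-count frequency distribution: singleton bins 0-14
# then an open ">15" bin.  There is no separate bin for exactly 15 clones;
# counts of 15 fall into ">15".
CLONE_BIN_LABELS = [str(k) for k in range(15)] + [">15"]


@dataclass(frozen=True)
class ESTRecord:
    clone_id: str
    gene_id: str
    tissue: str


@dataclass
class ExpressionTable:
    """Gene x tissue EST clone counts; genes with zero clones retained."""

    counts: pd.DataFrame  # index: gene_id, columns: tissue

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_clones(self) -> int:
        return int(self.counts.values.sum())

    def gene_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def read_est_tsv(path: str | Path) -> list[ESTRecord]:
    """Read EST hit records from TSV (clone_id, gene_id, tissue)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ESTRecord(row.clone_id, row.gene_id, row.tissue)
        for row in df.itertuples(index=False)
    ]


def tabulate(
    records: list[ESTRecord],
    family_genes: list[str],
) -> ExpressionTable:
    """Count EST clones per gene x tissue over a fixed family gene set.

    Records for genes outside the family are ignored; duplicate clone ids
    raise.  Every family gene appears in the table, zero rows included.
    """
    seen: set[str] = set()
    family = set(family_genes)
    tissues: list[str] = []
    cells: dict[tuple[str, str], int] = {}
    for rec in records:
        if rec.clone_id in seen:
            raise ValueError(f"duplicate clone_id {rec.clone_id!r}")
        seen.add(rec.clone_id)
        if rec.gene_id not in family:
            continue
        if rec.tissue not in tissues:
            tissues.append(rec.tissue)
        cells[(rec.gene_id, rec.tissue)] = cells.get((rec.gene_id, rec.tissue), 0) + 1
    counts = pd.DataFrame(
        0, index=list(family_genes), columns=tissues, dtype=int
    )
    for (gene, tissue), n in cells.items():
        counts.loc[gene, tissue] = n
    return ExpressionTable(counts)


def clone_frequency_distribution(table: ExpressionTable) -> pd.DataFrame:
    """Frequency distribution of genes by total clone count.

    Bins: 0, 1, ..., 14, then ">15" (counts >= 15).  Every gene falls in
    exactly one bin; bin counts sum to the family size.
    """
    totals = table.gene_totals()
    rows = []
    for label in CLONE_BIN_LABELS:
        if label == ">15":
            n = int((totals >= 15).sum())
        else:
            n = int((totals == int(label)).sum())
        rows.append({"n_est_clones": label, "n_genes": n})
    return pd.DataFrame(rows, columns=["n_est_clones", "n_genes"])


def tissue_summary(table: ExpressionTable) -> pd.DataFrame:
    """Per-tissue (n_genes_expressed, n_est_clones), sorted by clones
    descending (ties: gene count, then tissue name)."""
    rows = []
    for tissue in table.tissues:
        col = table.counts[tissue]
        rows.append({
            "tissue": tissue,
            "n_genes": int((col >= 1).sum()),
            "n_est_clones": int(col.sum()),
        })
    df = pd.DataFrame(rows, columns=["tissue", "n_genes", "n_est_clones"])
    return df.sort_values(
        ["n_est_clones", "n_genes", "tissue"],
        ascending=[False, False, True],
    ).reset_index(drop=True)


def clade_tissue_association(
    clades: list[frozenset],
    table: ExpressionTable,
    tissue: str,
    enrichment: bool = False,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-clade fraction of member genes with >= 1 clone in ``tissue``.

    With ``enrichment=True`` adds a two-sided Fisher exact test of clade
    membership vs tissue expression with Benjamini-Hochberg correction
    across clades.  (The enrichment layer is a package extension beyond
    descriptive tabulation.)
    """
    if tissue not in table.tissues:
        raise KeyError(f"unknown tissue {tissue!r}")
    genes = set(table.genes)
    expressed = set(table.counts.index[table.counts[tissue] >= 1])
    rows = []
    for clade in clades:
        members = set(clade)
        if not members <= genes:
            raise ValueError(
                f"clade genes not in table: {sorted(members - genes)}"
            )
        n_in = len(members & expressed)
        row = {
            "clade": ",".join(sorted(members)),
            "n_members": len(members),
            "n_expressed": n_in,
            "fraction": n_in / len(members),
        }
        if enrichment:
            out = genes - members
            tab = [
                [n_in, len(members) - n_in],
                [len(out & expressed), len(out - expressed)],
            ]
            row["p_value"] = float(fisher_exact(tab, alternative="two-sided")[1])
        rows.append(row)
    cols = ["clade", "n_members", "n_expressed", "fraction"]
    if enrichment:
        cols.append("p_value")
    df = pd.DataFrame(rows, columns=cols)
    if enrichment and len(df):
        reject, q, *_ = multipletests(df["p_value"], alpha=fdr, method="fdr_bh")
        df["q_value"] = q
        df["significant"] = reject
    return df
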