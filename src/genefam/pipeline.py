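"""End-to-end orchestration: genome -> introns -> alignment -> conserved
sites + phylogeny -> chromosome map -> expression, with a consolidated
JSON report."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from . import est_expression as est
from . import genome_io, genome_map, intron_architecture as ia, msa, phylogeny

logger = logging.getLogger("genefam")

__all__ = ["RunConfig", "StageError", "run"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    genome: str
    gff3: str
    outdir: str
    alignment: str | None = None
    est_table: str | None = None
    loci_table: str | None = None
    ortholog_map_a: str | None = None
    ortholog_map_b: str | None = None
    tolerance_nt: int = 3
    min_members: int = 2
    bootstrap_reps: int = 500
    seed: int | None = None
    support_threshold: float = 50.0
    max_interlopers: int = 1
    max_gap_bp: int = 100_000
    collapse_variants: bool = True
    run_phylogeny: bool = True
    run_expression: bool = True
    run_synteny: bool = True

    def validate(self) -> None:
        for attr in ("genome", "gff3"):
            path = getattr(self, attr)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"{attr} input missing: {path}")
        for attr in ("alignment", "est_table", "loci_table",
                     "ortholog_map_a", "ortholog_map_b"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{attr} input missing: {path}")
        if self.run_phylogeny and self.bootstrap_reps > 0 and self.seed is None:
            raise ValueError("seed required when bootstrap is enabled")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from YAML or JSON; keyword overrides win."""
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return inner
    return wrap


def run(cfg: RunConfig) -> dict:
    """Execute the pipeline; returns the report dict (also written as JSON)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    warn_counts = {"noncanonical_introns": 0, "incomplete_models": 0,
                   "saturated_distances": 0, "unprojected_introns": 0}
    report: dict = {
        "genefam_version": __version__,
        "parameters": asdict(cfg),
    }

    try:
        genome, models = _stage("genome_io")(_load_inputs)(cfg)
        loci = _stage("loci")(_loci)(cfg, models)
        family_ids = {l.gene_id for l in loci if l.in_family}
        family = [m for m in models if m.gene_id in family_ids]
        if not family:
            raise StageError(
                "loci", ValueError("no family gene models after filtering")
            )
        complete = [m for m in family if not m.incomplete]
        warn_counts["incomplete_models"] = len(family) - len(complete)

        introns = _stage("introns")(_extract_all)(complete, genome)
        genome_io.write_introns_tsv(introns, outdir / "introns.tsv")
        warn_counts["noncanonical_introns"] = sum(
            1 for i in introns if not i.canonical
        )

        aln = _stage("msa")(_alignment)(cfg, complete)
        msa.write_aligned_fasta(aln, outdir / "alignment.fasta")

        sites, skipped = _stage("map_sites")(ia.project_all)(introns, aln)
        warn_counts["unprojected_introns"] = len(skipped)
        ia.sites_to_tsv(sites, outdir / "intron_sites.tsv")
        groups = ia.find_conserved_sites(
            sites, min_members=cfg.min_members, tolerance_nt=cfg.tolerance_nt
        )
        ia.groups_to_tsv(groups, outdir / "conserved_sites.tsv")
        stats = ia.length_stats(introns, complete)
        stats.to_json(outdir / "intron_length_stats.json")
        matrix, top2 = ia.shared_intron_matrix(groups, complete)
        matrix.to_csv(outdir / "shared_intron_matrix.tsv", sep="\t")

        report["introns"] = {
            "n_introns": stats.n_introns,
            "n_intronless_genes": stats.n_intronless_genes,
            "mean_length": stats.mean_length,
            "min_length": stats.min_length,
            "max_length": stats.max_length,
            "n_conserved_sites": len(groups),
            "top_conserved": [
                {"canonical_pos": g.canonical_pos, "phase": g.phase,
                 "n_members": g.n_members}
                for g in groups[:5]
            ],
            "n_genes_with_top2_ancestral": top2,
        }

        clades: list[frozenset] = []
        if cfg.run_phylogeny and len(aln.seq_ids) >= 4 and cfg.bootstrap_reps:
            tree = _stage("phylogeny")(_bootstrap)(cfg, aln, warn_counts)
            (outdir / "tree.nwk").write_text(
                tree.newick(with_support=True) + "\n"
            )
            clades = phylogeny.flag_supported_clades(
                tree, cfg.support_threshold
            )
            report["phylogeny"] = {
                "n_leaves": len(tree.leaf_names),
                "n_supported_clades": len(clades),
                "supported_clades": [sorted(c) for c in clades],
            }

        clusters = genome_map.detect_clusters(
            loci, max_interlopers=cfg.max_interlopers,
            max_gap_bp=cfg.max_gap_bp,
        )
        cluster_rows = [
            {"chrom": c.chromosome, "members": c.member_ids,
             "orientation": c.orientation_pattern,
             "n_interlopers": c.n_interlopers}
            for c in clusters
        ]
        report["clusters"] = {"n_clusters": len(clusters),
                              "clusters": cluster_rows}
        if clades:
            flags, summary = genome_map.cluster_phylogeny_concordance(
                clusters, clades, leaf_names=aln.seq_ids
            )
            report["clusters"]["concordance"] = summary

        if cfg.run_synteny and cfg.ortholog_map_a and cfg.ortholog_map_b:
            events = _stage("synteny")(_synteny)(cfg)
            genome_map.events_to_jsonl(events, outdir / "synteny_events.jsonl")
            kinds: dict[str, int] = {}
            for ev in events:
                kinds[ev.kind] = kinds.get(ev.kind, 0) + 1
            report["synteny"] = {"n_events": len(events), "by_kind": kinds}

        if cfg.run_expression and cfg.est_table:
            table, freq, tissues = _stage("express")(_expression)(
                cfg, sorted(family_ids)
            )
            freq.to_csv(outdir / "clone_frequency.tsv", sep="\t", index=False)
            tissues.to_csv(outdir / "tissue_summary.tsv", sep="\t",
                           index=False)
            table.counts.to_csv(outdir / "expression_table.tsv", sep="\t")
            report["expression"] = {
                "n_clones": table.total_clones,
                "n_genes_with_clones": int((table.gene_totals() >= 1).sum()),
                "top_tissue": (
                    tissues.iloc[0].to_dict() if len(tissues) else None
                ),
            }
    finally:
        logger.removeHandler(handler)
        handler.close()

    report["warnings"] = warn_counts
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def _load_inputs(cfg: RunConfig):
    genome = genome_io.load_genome(cfg.genome)
    models = genome_io.load_gene_models(
        cfg.gff3, genome, collapse_variants=cfg.collapse_variants
    )
    return genome, models


def _extract_all(models, genome):
    introns = []
    for model in models:
        introns.extend(genome_io.extract_introns(model, genome))
    return introns


def _alignment(cfg: RunConfig, models):
    if cfg.alignment:
        return msa.read_aligned_fasta(cfg.alignment)
    return msa.progressive_msa({m.gene_id: m.protein for m in models})


def _bootstrap(cfg: RunConfig, aln, warn_counts):
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", phylogeny.SaturationWarning)
        tree = phylogeny.bootstrap_support(
            aln, n_reps=cfg.bootstrap_reps, seed=cfg.seed
        )
    warn_counts["saturated_distances"] += sum(
        1 for w in caught if issubclass(w.category, phylogeny.SaturationWarning)
    )
    return tree


def _loci(cfg: RunConfig, models):
    if cfg.loci_table:
        return genome_map.read_loci_tsv(cfg.loci_table)
    loci = []
    for m in models:
        start = min(a for a, _ in m.exons)
        end = max(b for _, b in m.exons)
        loci.append(genome_map.GeneLocus(
            m.gene_id, m.chromosome, start, end, m.strand, in_family=True,
        ))
    return loci


def _synteny(cfg: RunConfig):
    map_a = genome_map.read_ortholog_map(cfg.ortholog_map_a)
    map_b = genome_map.read_ortholog_map(cfg.ortholog_map_b)
    return genome_map.compare_synteny(map_a, map_b)


def _expression(cfg: RunConfig, family_ids):
    records = est.read_est_tsv(cfg.est_table)
    table = est.tabulate(records, family_ids)
    return (table, est.clone_frequency_distribution(table),
            est.tissue_summary(table))
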