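"""Phase classification, alignment projection and conserved-site grouping."""

import numpy as np
import pytest

from genefam import intron_architecture as ia
from genefam.genome_io import Intron
from genefam.msa import Alignment
from genefam.intron_architecture import ProjectionError


def make_intron(gene_id, cds_offset, ordinal=1, length=100):
    return Intron(
        gene_id=gene_id, ordinal=ordinal, chromosome="chr1",
        start=1000 * ordinal, end=1000 * ordinal + length,
        donor="GT", acceptor="AG", cds_offset=cds_offset,
    )


def brute_force_project(row, cds_offset):
    """Independent residue-by-residue homology walk to the hosting column."""
    r = cds_offset // 3
    phase = cds_offset % 3
    residues_seen = 0
    for col0, ch in enumerate(row):
        if ch != "-":
            residues_seen += 1
            if residues_seen == r + 1:
                return 3 * col0 + phase
    raise AssertionError("hosting residue beyond row")


class TestIntronPhase:
    def test_definition_examples(self):
        assert ia.intron_phase(6) == 0
        assert ia.intron_phase(7) == 1
        assert ia.intron_phase(8) == 2

    def test_exhaustive_against_mod_oracle(self):
        for offset in range(1, 301):
            assert ia.intron_phase(offset) == offset - 3 * (offset // 3)

    @pytest.mark.parametrize("bad", [0, -1, -300])
    def test_non_positive_offset_rejected(self, bad):
        with pytest.raises(ValueError):
            ia.intron_phase(bad)


class TestProjection:
    def test_ungapped_row_is_identity(self):
        aln = Alignment(["g1"], ["MKVLAWCDEF"])
        for offset in (3, 7, 14, 29):
            site = ia.project_intron(make_intron("g1", offset), aln)
            assert site.aln_nt_pos == offset
            assert site.phase == offset % 3

    def test_gap_before_hosting_residue_shifts_by_six(self):
        # residue 4 (r+1 with offset 9..11) sits after a 2-column gap
        aln0 = Alignment(["g1"], ["MKVLAW"])
        aln1 = Alignment(["g1"], ["MKV--LAW"])
        for offset in (9, 10, 11):
            s0 = ia.project_intron(make_intron("g1", offset), aln0)
            s1 = ia.project_intron(make_intron("g1", offset), aln1)
            assert s1.aln_nt_pos == s0.aln_nt_pos + 6

    def test_intron_after_final_codon_flagged(self):
        aln = Alignment(["g1"], ["MKV"])
        with pytest.raises(ProjectionError):
            ia.project_intron(make_intron("g1", 9), aln)  # r+1 = residue 4

    def test_brute_force_homology_walk_oracle(self):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(1000):
            n_res = int(rng.integers(2, 30))
            residues = rng.choice(aas, n_res)
            row = []
            for ch in residues:
                row.extend(["-"] * int(rng.integers(0, 3)))
                row.append(ch)
            row.extend(["-"] * int(rng.integers(0, 3)))
            row = "".join(row)
            aln = Alignment(["g"], [row])
            offset = int(rng.integers(1, 3 * n_res))
            site = ia.project_intron(make_intron("g", offset), aln)
            assert site.aln_nt_pos == brute_force_project(row, offset)
            assert site.aln_nt_pos % 3 == site.phase

    def test_projection_is_order_preserving(self):
        rng = np.random.default_rng(8)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            n_res = int(rng.integers(5, 25))
            row = []
            for ch in rng.choice(aas, n_res):
                row.extend(["-"] * int(rng.integers(0, 2)))
                row.append(str(ch))
            aln = Alignment(["g"], ["".join(row)])
            offsets = sorted(rng.choice(
                np.arange(1, 3 * n_res), size=min(5, 3 * n_res - 1),
                replace=False,
            ))
            positions = [
                ia.project_intron(make_intron("g", int(o)), aln).aln_nt_pos
                for o in offsets
            ]
            assert positions == sorted(positions)


class TestConservedSites:
    def test_far_apart_sites_yield_no_groups(self):
        sites = [
            ia.IntronSite(f"g{k}", 100 * k, (100 * k) % 3, (f"g{k}", 1))
            for k in range(1, 6)
        ]
        assert ia.find_conserved_sites(sites) == []

    def test_one_nt_jitter_same_phase_merges(self):
        # alignment jitter: same phase-0 intron landing one codon apart
        s1 = ia.IntronSite("g1", 229 * 3, 0, ("g1", 1))
        s2 = ia.IntronSite("g2", 229 * 3 + 3, 0, ("g2", 1))
        (group,) = ia.find_conserved_sites([s1, s2], tolerance_nt=3)
        assert group.members == frozenset({"g1", "g2"})
        assert group.canonical_pos == 229 * 3

    def test_same_position_different_phase_not_merged(self):
        s1 = ia.IntronSite("g1", 99, 0, ("g1", 1))
        s2 = ia.IntronSite("g2", 100, 1, ("g2", 1))
        assert ia.find_conserved_sites([s1, s2]) == []

    def test_gene_contributes_at_most_one_intron(self):
        sites = [
            ia.IntronSite("g1", 99, 0, ("g1", 1)),
            ia.IntronSite("g1", 102, 0, ("g1", 2)),
            ia.IntronSite("g2", 99, 0, ("g2", 1)),
        ]
        (group,) = ia.find_conserved_sites(sites)
        assert group.members == frozenset({"g1", "g2"})
        assert len(group.sites) == 2

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        sites = [
            ia.IntronSite(f"g{k}", int(p), int(p) % 3, (f"g{k}", 1))
            for k, p in enumerate(rng.integers(0, 300, size=40))
        ]
        ref = ia.find_conserved_sites(sites)
        for _ in range(5):
            perm = list(sites)
            rng.shuffle(perm)
            got = ia.find_conserved_sites(perm)
            assert [(g.canonical_pos, g.phase, g.members) for g in got] == \
                   [(g.canonical_pos, g.phase, g.members) for g in ref]

    def test_truth_alignment_recovers_ancestral_groups(self, sim_family):
        """Projecting the generator's introns on its truth alignment yields
        one group per surviving ancestral intron with the exact survivor
        membership."""
        _, _, truth = sim_family
        aln = Alignment(
            list(truth.alignment), list(truth.alignment.values())
        )
        sites = []
        for gene, ivs in truth.gene_introns.items():
            for iv in ivs:
                sites.append(ia.project_intron(
                    make_intron(gene, iv["cds_offset"], iv["ordinal"]), aln
                ))
        groups = ia.find_conserved_sites(sites)
        survivors = {}
        for gene, ivs in truth.gene_introns.items():
            for iv in ivs:
                if iv["ancestral"]:
                    survivors.setdefault(iv["intron_id"], set()).add(gene)
        recovered = {frozenset(g.members) for g in groups}
        for intron_id, members in survivors.items():
            if len(members) >= 2:
                assert frozenset(members) in recovered, intron_id


class TestLengthStats:
    def test_arithmetic_on_known_lengths(self):
        introns = [
            make_intron("g1", 3, 1, 68),
            make_intron("g2", 3, 1, 1372),
            make_intron("g3", 3, 1, 13962),
        ]
        stats = ia.length_stats(introns, [])
        assert stats.min_length == 68
        assert stats.max_length == 13962
        assert round(stats.mean_length) == 5134
        assert stats.n_introns == sum(c for _, c in stats.histogram)

    def test_no_introns(self):
        stats = ia.length_stats([], [])
        assert stats.n_introns == 0
        assert stats.mean_length is None
        assert stats.histogram == []

    def test_intronless_gene_count(self, sim_family):
        _, _, truth = sim_family
        from genefam.genome_io import GeneModel

        genes = [
            GeneModel(g, "c", "+", [(0, 3)], "ATG", "M")
            for g in truth.proteins
        ]
        introns = [
            make_intron(g, iv["cds_offset"], iv["ordinal"], iv["length"])
            for g, ivs in truth.gene_introns.items() for iv in ivs
        ]
        stats = ia.length_stats(introns, genes)
        expected = sum(
            1 for g in truth.proteins if not truth.gene_introns[g]
        )
        assert stats.n_intronless_genes == expected


class TestSharedIntronMatrix:
    def _group(self, pos, phase, members):
        sites = tuple(
            ia.IntronSite(m, pos, phase, (m, 1)) for m in sorted(members)
        )
        return ia.ConservedIntronGroup(pos, phase, frozenset(members),
                                       (pos, pos), sites)

    def test_single_group_covering_all(self):
        genes = [f"g{k}" for k in range(5)]
        matrix, summary = ia.shared_intron_matrix(
            [self._group(9, 0, genes)], genes, top_k=1
        )
        assert summary == 5
        assert matrix.values.all()

    def test_two_disjoint_groups(self):
        genes = [f"g{k}" for k in range(7)]
        groups = [
            self._group(9, 0, genes[:3]),
            self._group(33, 0, genes[3:5]),
        ]
        _, summary = ia.shared_intron_matrix(groups, genes, top_k=2)
        assert summary == 5

    def test_overlapping_groups_match_set_union(self):
        rng = np.random.default_rng(9)
        genes = [f"g{k}" for k in range(12)]
        groups = []
        for k in range(4):
            members = list(rng.choice(
                genes, size=int(rng.integers(2, 8)), replace=False
            ))
            groups.append(self._group(10 * k * 3, 0, members))
        for top_k in (1, 2, 3, 4):
            top = sorted(groups,
                         key=lambda g: (-g.n_members, g.canonical_pos))[:top_k]
            union = set().union(*(g.members for g in top))
            _, summary = ia.shared_intron_matrix(groups, genes, top_k=top_k)
            assert summary == len(union)
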