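"""JTT distances, neighbor joining, ME refinement and bootstrap."""

import io
import shutil
import subprocess

import numpy as np
import pytest

from genefam import phylogeny as ph
from genefam.msa import Alignment
from genefam.synthetic import simulate_pair, simulate_two_clade_alignment

from conftest import make_random_additive


class TestJTTModel:
    def test_transition_matrix_is_stochastic_and_reversible(self):
        for t in (0.01, 0.3, 2.0):
            P = ph.jtt_transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0)
            flux = ph._PI[:, None] * P
            assert np.allclose(flux, flux.T)

    def test_identical_rows_have_zero_distance(self):
        row = "MKVLAWCDEF" * 10
        assert ph.jtt_distance(row, row) == 0.0

    def test_pairwise_gap_deletion(self):
        a = "MKVLAW----"
        b = "MKVLAWCDEF"
        assert ph.jtt_distance(a, b) == 0.0

    def test_no_shared_columns_rejected(self):
        with pytest.raises(ph.PhylogenyError, match="no shared"):
            ph.jtt_distance("MK--", "--MK")

    def test_saturated_pair_capped_with_warning(self):
        # five shared columns, all different: no information to bound t
        a, b = "AAAAA", "RRRRR"
        with pytest.warns(ph.SaturationWarning):
            d = ph.jtt_distance(a, b)
        assert d == ph.MAX_DISTANCE

    def test_simulation_recovery_moderate_divergence(self):
        rng = np.random.default_rng(0)
        ests = [
            ph.jtt_distance(*simulate_pair(0.3, 400, rng)) for _ in range(30)
        ]
        assert abs(np.mean(ests) - 0.3) / 0.3 < 0.05

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_distances_match_phangorn(self, tmp_path):
        """Independent oracle: phangorn's ML JTT distances on a small
        alignment agree to 1e-3."""
        aln, _, _ = simulate_two_clade_alignment(2, 0.4, 0.15, 200, seed=5)
        fasta = tmp_path / "aln.fasta"
        fasta.write_text("".join(
            f">{i}\n{r}\n" for i, r in zip(aln.seq_ids, aln.rows)
        ))
        out = tmp_path / "dm.txt"
        script = (
            'suppressMessages(library(phangorn));'
            f'a <- read.phyDat("{fasta}", format="fasta", type="AA");'
            'd <- as.matrix(dist.ml(a, model="JTT"));'
            f'write.table(d, "{out}", col.names=FALSE, row.names=FALSE)'
        )
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        theirs = np.loadtxt(out)
        mine = ph.jtt_distance_matrix(aln).d
        assert np.abs(mine - theirs).max() < 1e-3


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        with pytest.raises(ph.PhylogenyError, match="symmetric"):
            ph.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ph.PhylogenyError, match="diagonal"):
            ph.DistanceMatrix(["a", "b"], np.array([[1, 1], [1, 0]]))

    def test_triangle_violations_reported_not_fixed(self):
        d = np.array([[0, 10, 1], [10, 0, 1], [1, 1, 0]], dtype=float)
        dm = ph.DistanceMatrix(["a", "b", "c"], d)
        assert dm.triangle_violations() > 0
        assert dm.d[0, 1] == 10  # untouched


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise path lengths
        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = ph.nj_tree(ph.DistanceMatrix(ids, d))
        assert set(tree.bipartitions()) == {frozenset({"A", "B"})}
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        (internal,) = tree.internal_nodes()
        assert internal.length == pytest.approx(1.0)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = ph.nj_tree(ph.DistanceMatrix(["a", "b", "c"], d))
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths == pytest.approx({"a": 1, "b": 2, "c": 3})

    def test_hundred_random_additive_topologies_recovered(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            true_tree, dm = make_random_additive(rng)
            est = ph.nj_tree(dm)
            assert set(est.bipartitions()) == set(true_tree.bipartitions())

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ph.PhylogenyError):
            ph.nj_tree(ph.DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_matches_dendropy_on_noisy_matrix(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(4)
        _, dm = make_random_additive(rng, n=7)
        noisy = dm.d + rng.uniform(0, 0.02, dm.d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        dm2 = ph.DistanceMatrix(dm.ids, noisy)
        mine = ph.nj_tree(dm2)
        csv = "," + ",".join(dm.ids) + "\n" + "\n".join(
            dm.ids[i] + "," + ",".join(str(x) for x in noisy[i])
            for i in range(len(dm.ids))
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=","
        )
        their_tree = pdm.nj_tree()
        theirs = set()
        all_leaves = frozenset(dm.ids)
        for edge in their_tree.preorder_edge_iter():
            node = edge.head_node
            if node.parent_node is None or node.is_leaf():
                continue
            below = frozenset(
                t.taxon.label for t in node.leaf_iter()
            )
            bp = ph.normalize_bipartition(below, all_leaves)
            if len(bp) >= 2:
                theirs.add(bp)
        assert set(mine.bipartitions()) == theirs


class TestMERefinement:
    def test_additive_input_unchanged(self):
        rng = np.random.default_rng(1)
        _, dm = make_random_additive(rng)
        tree = ph.nj_tree(dm)
        assert ph.me_refine(tree, dm) is tree

    def test_adjacent_swap_refined_back(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            _, dm = make_random_additive(rng)
            tree = ph.nj_tree(dm)
            perturbed = tree.copy()
            moves = ph._nni_moves(perturbed)
            ph._apply_swap(*moves[rng.integers(len(moves))])
            refined = ph.me_refine(perturbed, dm)
            assert set(refined.bipartitions()) == set(tree.bipartitions())

    def test_me_score_never_increases(self):
        rng = np.random.default_rng(3)
        _, dm = make_random_additive(rng)
        tree = ph.nj_tree(dm)
        perturbed = tree.copy()
        for mv in ph._nni_moves(perturbed)[:2]:
            ph._apply_swap(*mv)
        s_before = ph._me_score(perturbed, dm)
        refined = ph.me_refine(perturbed, dm)
        assert ph._me_score(refined, dm) <= s_before + 1e-9


class TestBootstrap:
    def test_deterministic_given_seed(self):
        aln, _, _ = simulate_two_clade_alignment(2, 0.5, 0.1, 120, seed=1)
        t1 = ph.bootstrap_support(aln, n_reps=30, seed=9)
        t2 = ph.bootstrap_support(aln, n_reps=30, seed=9)
        s1 = sorted(n.support for n in t1.internal_nodes())
        s2 = sorted(n.support for n in t2.internal_nodes())
        assert s1 == s2

    def test_identical_sequences_unresolved(self):
        aln = Alignment(
            [f"s{k}" for k in range(5)], ["MKVLAWCDEF" * 4] * 5
        )
        tree = ph.bootstrap_support(aln, n_reps=20, seed=0)
        assert all(n.support == 0.0 for n in tree.internal_nodes())

    def test_two_clades_supported_and_leaf_order_invariant(self):
        aln, ca, cb = simulate_two_clade_alignment(3, 0.6, 0.1, 200, seed=4)
        tree = ph.bootstrap_support(aln, n_reps=50, seed=1)
        clades = set(ph.flag_supported_clades(tree, 50))
        assert ca in clades or cb in clades
        # permuted leaf order
        order = list(range(len(aln.seq_ids)))[::-1]
        aln2 = Alignment([aln.seq_ids[k] for k in order],
                         [aln.rows[k] for k in order])
        tree2 = ph.bootstrap_support(aln2, n_reps=50, seed=1)
        bp1 = {bp: nd.support for bp, nd in tree.bipartitions().items()}
        bp2 = {bp: nd.support for bp, nd in tree2.bipartitions().items()}
        assert set(bp1) == set(bp2)

    def test_too_few_sequences_rejected(self):
        aln = Alignment(["a", "b", "c"], ["MK", "MK", "MK"])
        with pytest.raises(ph.PhylogenyError):
            ph.bootstrap_support(aln, n_reps=5, seed=0)


class TestFlagSupportedClades:
    def _tree_with_supports(self, supports):
        aln, _, _ = simulate_two_clade_alignment(2, 0.5, 0.1, 80, seed=2)
        tree = ph.bootstrap_support(aln, n_reps=10, seed=0)
        for node, s in zip(tree.internal_nodes(), supports):
            node.support = s
        return tree

    def test_all_supported_returns_all_bipartitions(self):
        tree = self._tree_with_supports([100.0] * 10)
        assert len(ph.flag_supported_clades(tree, 50)) == \
            len(tree.bipartitions())

    def test_none_supported_returns_empty(self):
        tree = self._tree_with_supports([40.0] * 10)
        assert ph.flag_supported_clades(tree, 50) == []

    def test_mixed_matches_brute_force_filter(self):
        tree = self._tree_with_supports([30.0, 80.0, 55.0, 45.0, 90.0])
        flagged = set(ph.flag_supported_clades(tree, 50))
        expected = {
            bp for bp, node in tree.bipartitions().items()
            if node.support > 50
        }
        assert flagged == expected

    def test_tree_without_supports_rejected(self):
        rng = np.random.default_rng(5)
        _, dm = make_random_additive(rng)
        tree = ph.nj_tree(dm)
        with pytest.raises(ph.PhylogenyError, match="support"):
            ph.flag_supported_clades(tree)
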