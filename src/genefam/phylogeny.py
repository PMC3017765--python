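"""Distance phylogeny: JTT maximum-likelihood distances, neighbor joining,
minimum-evolution NNI refinement and nonparametric bootstrap.

The JTT model is the Jones-Taylor-Thornton (1992) empirical amino-acid
replacement model.  The rate matrix Q is built from the published
exchangeabilities S and equilibrium frequencies pi as Q_ij = S_ij * pi_j,
normalised to one expected substitution per site per unit time, so branch
lengths and distances are in substitutions per site.  Pairwise distances are
maximum-likelihood estimates of the divergence time t over shared-residue
columns (pairwise gap deletion), found by bounded scalar optimisation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from ._jtt_data import AA_ORDER, JTT_EXCHANGEABILITIES, JTT_FREQUENCIES

__all__ = [
    "DistanceMatrix",
    "Node",
    "Tree",
    "PhylogenyError",
    "SaturationWarning",
    "jtt_rate_matrix",
    "jtt_transition_matrix",
    "jtt_distance",
    "jtt_distance_matrix",
    "nj_tree",
    "me_refine",
    "bootstrap_support",
    "flag_supported_clades",
]

MAX_DISTANCE = 10.0
_EPS_EDGE = 1e-12

_AA_INDEX = {aa: k for k, aa in enumerate(AA_ORDER)}


class PhylogenyError(ValueError):
    """Invalid phylogenetic input."""


class SaturationWarning(UserWarning):
    """A pairwise distance hit the saturation cap."""


# ---------------------------------------------------------------------------
# JTT model
# ---------------------------------------------------------------------------

def jtt_rate_matrix() -> tuple[np.ndarray, np.ndarray]:
    """Return (Q, pi): the normalised JTT rate matrix and frequencies."""
    pi = np.asarray(JTT_FREQUENCIES)
    S = np.zeros((20, 20))
    k = 0
    for j in range(19):
        for i in range(j + 1, 20):
            S[i, j] = S[j, i] = JTT_EXCHANGEABILITIES[k]
            k += 1
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # Normalise to 1 expected substitution/site/unit time.
    rate = -(pi * np.diag(Q)).sum()
    return Q / rate, pi


def _jtt_eigen():
    """Eigendecomposition of Q via its reversible symmetrisation."""
    Q, pi = jtt_rate_matrix()
    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]
    B = (B + B.T) / 2.0
    lam, U = np.linalg.eigh(B)
    left = U.T * sq[None, :]          # U^T D^{1/2}
    right = U / sq[:, None]           # D^{-1/2} U
    return lam, right, left, pi


_LAM, _RIGHT, _LEFT, _PI = _jtt_eigen()


def jtt_transition_matrix(t: float) -> np.ndarray:
    """P(t) = exp(Qt) under the JTT model; rows sum to 1."""
    if t < 0:
        raise PhylogenyError("negative time")
    P = (_RIGHT * np.exp(_LAM * t)[None, :]) @ _LEFT
    return np.clip(P, 1e-300, None)


def encode_protein_row(row: str) -> np.ndarray:
    """Encode a gapped protein row as integer codes; gaps/unknown -> -1."""
    return np.array([_AA_INDEX.get(ch, -1) for ch in row.upper()], dtype=np.int64)


def _pair_counts(code_a: np.ndarray, code_b: np.ndarray) -> np.ndarray:
    mask = (code_a >= 0) & (code_b >= 0)
    if not mask.any():
        raise PhylogenyError("no shared residue columns between rows")
    flat = code_a[mask] * 20 + code_b[mask]
    return np.bincount(flat, minlength=400).reshape(20, 20).astype(float)


def _ml_distance_from_counts(counts: np.ndarray) -> float:
    n_shared = counts.sum()
    n_diff = n_shared - np.trace(counts)
    if n_diff == 0:
        return 0.0

    def neg_ll(t: float) -> float:
        P = jtt_transition_matrix(t)
        return -float((counts * np.log(_PI[:, None] * P)).sum())

    res = minimize_scalar(neg_ll, bounds=(1e-8, MAX_DISTANCE),
                          method="bounded", options={"xatol": 1e-6})
    t_hat = float(res.x)
    if t_hat > MAX_DISTANCE - 1e-3:
        warnings.warn(
            f"distance saturated; capped at {MAX_DISTANCE}", SaturationWarning
        )
        return MAX_DISTANCE
    return t_hat


def jtt_distance(row_a: str, row_b: str) -> float:
    """ML divergence time between two equal-length gapped protein rows.

    Columns where either row has a gap are ignored (pairwise deletion).
    Raises if no shared residue columns remain; saturated pairs are capped
    at ``MAX_DISTANCE`` with a :class:`SaturationWarning`.
    """
    if len(row_a) != len(row_b):
        raise PhylogenyError("rows differ in length")
    return _ml_distance_from_counts(
        _pair_counts(encode_protein_row(row_a), encode_protein_row(row_b))
    )


def jtt_distance_matrix(aln) -> "DistanceMatrix":
    """Pairwise JTT ML distance matrix for an alignment."""
    ids = list(aln.seq_ids)
    codes = [encode_protein_row(r) for r in aln.rows]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _ml_distance_from_counts(
                _pair_counts(codes[i], codes[j])
            )
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# Distance matrix and tree containers
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise PhylogenyError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise PhylogenyError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise PhylogenyError("distance matrix diagonal not zero")
        if not np.isfinite(self.d).all():
            raise PhylogenyError("non-finite distances")
        if (self.d < -1e-12).any():
            raise PhylogenyError("negative distances")

    def triangle_violations(self, tol: float = 1e-9) -> int:
        """Count (i,j,k) triples violating d(i,j) <= d(i,k) + d(k,j)."""
        n = len(self.ids)
        count = 0
        for i, j, k in itertools.permutations(range(n), 3):
            if i < j and self.d[i, j] > self.d[i, k] + self.d[k, j] + tol:
                count += 1
        return count


class Node:
    """A tree node; ``length`` is the branch to the parent."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.support: float | None = None
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def detach(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf():
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()


class Tree:
    """An unrooted tree stored with a (possibly trifurcating) root node."""

    def __init__(self, root: Node):
        self.root = root

    @property
    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.root.walk()
                if not n.is_leaf() and n is not self.root]

    def bipartitions(self) -> dict[frozenset, Node]:
        """Map each internal edge to its min-side leaf bipartition.

        The side with fewer leaves is used; ties are broken towards the side
        containing the alphabetically first leaf.  Trivial (single-leaf)
        bipartitions are excluded.
        """
        all_leaves = frozenset(self.leaf_names)
        out: dict[frozenset, Node] = {}
        for node in self.internal_nodes():
            below = frozenset(lf.name for lf in node.leaves())
            bp = normalize_bipartition(below, all_leaves)
            if len(bp) >= 2:
                out[bp] = node
        return out

    def total_length(self) -> float:
        return sum(n.length for n in self.root.walk() if n is not self.root)

    def newick(self, with_support: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(ch) for ch in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.4g}"
            if node is self.root:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.support = node.support
            for ch in node.children:
                new.add(clone(ch))
            return new

        return Tree(clone(self.root))


def normalize_bipartition(side: frozenset, all_leaves: frozenset) -> frozenset:
    other = all_leaves - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return side if min(side) < min(other) else other


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Negative branch lengths are clamped to zero with the deficit moved to
    the adjacent (sister) branch so the cherry's path length is preserved.
    Deterministic: ties in the Q criterion break towards the smallest index
    pair.
    """
    n = len(dm.ids)
    if n < 3:
        raise PhylogenyError("neighbor joining needs >= 3 taxa")
    nodes: list[Node] = [Node(name) for name in dm.ids]
    d = dm.d.copy()
    active = list(range(n))

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = np.unravel_index(np.argmin(q), q.shape)
        ai, aj = sorted((int(best[0]), int(best[1])))
        i, j = active[ai], active[aj]
        li = 0.5 * d[i, j] + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp_pair(li, lj)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        # Distances from the new node to the remaining taxa.
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d[i, :] = new_d
        d[:, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    # Join the last three at a trifurcating root.
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    lens = [li, lj, lk]
    for a in range(3):
        if lens[a] < 0:
            b = int(np.argmax([lens[x] if x != a else -np.inf for x in range(3)]))
            lens[b] += lens[a]
            lens[a] = 0.0
    root = Node()
    for idx, ln in zip((i, j, k), lens):
        nodes[idx].length = max(ln, 0.0)
        root.add(nodes[idx])
    return Tree(root)


# ---------------------------------------------------------------------------
# Minimum evolution refinement (NNI + OLS)
# ---------------------------------------------------------------------------

def _ols_lengths(tree: Tree, dm: DistanceMatrix) -> tuple[np.ndarray, list[Node]]:
    """Ordinary least squares branch lengths for a fixed topology."""
    index = {name: k for k, name in enumerate(dm.ids)}
    edges = [n for n in tree.root.walk() if n is not tree.root]
    below = []
    for node in edges:
        below.append(frozenset(index[lf.name] for lf in node.leaves()))
    n = len(dm.ids)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    X = np.zeros((len(pairs), len(edges)))
    y = np.empty(len(pairs))
    for p, (i, j) in enumerate(pairs):
        y[p] = dm.d[i, j]
        for e, bl in enumerate(below):
            if (i in bl) != (j in bl):
                X[p, e] = 1.0
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    return b, edges


def _me_score(tree: Tree, dm: DistanceMatrix) -> float:
    b, _ = _ols_lengths(tree, dm)
    return float(b.sum())


def _nni_moves(tree: Tree) -> list[tuple[Node, Node]]:
    """Enumerate NNI swaps as (w, c): w a child of u, c a child of v."""
    moves = []
    for v in tree.internal_nodes():
        u = v.parent
        others = [ch for ch in u.children if ch is not v]
        if not others:
            continue
        w = others[0]
        for c in list(v.children):
            moves.append((w, c))
    return moves


def _apply_swap(w: Node, c: Node) -> None:
    u, v = w.parent, c.parent
    u.detach(w)
    v.detach(c)
    u.add(c)
    v.add(w)


def me_refine(tree: Tree, dm: DistanceMatrix, max_iter: int = 50) -> Tree:
    """Nearest-neighbor-interchange hill climb minimising total OLS length.

    Returns the input tree unchanged when no interchange improves the
    minimum-evolution criterion; otherwise branch lengths of the refined
    tree are the OLS estimates clamped at zero.
    """
    current = tree.copy()
    score = _me_score(current, dm)
    improved_any = False
    for _ in range(max_iter):
        best_gain = 1e-10
        best_move = None
        for w, c in _nni_moves(current):
            _apply_swap(w, c)
            s = _me_score(current, dm)
            _apply_swap(c, w)  # revert
            if score - s > best_gain:
                best_gain = score - s
                best_move = (w, c)
        if best_move is None:
            break
        _apply_swap(*best_move)
        score -= best_gain
        improved_any = True
    if not improved_any:
        return tree
    b, edges = _ols_lengths(current, dm)
    for length, node in zip(b, edges):
        node.length = max(float(length), 0.0)
    return current


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _resolved_bipartitions(tree: Tree) -> set[frozenset]:
    """Bipartitions of internal edges with length > 0 (zero-length edges are
    treated as unresolved polytomies)."""
    all_leaves = frozenset(tree.leaf_names)
    out = set()
    for node in tree.internal_nodes():
        if node.length > _EPS_EDGE:
            below = frozenset(lf.name for lf in node.leaves())
            out.add(normalize_bipartition(below, all_leaves))
    return out


def bootstrap_support(
    aln,
    n_reps: int = 500,
    seed: int | None = None,
    refine: bool = False,
) -> Tree:
    """Column-resampling bootstrap supports on the NJ (optionally ME) tree.

    Support of an internal edge is 100x the fraction of replicate trees that
    contain the same leaf bipartition.  Deterministic given ``seed``.
    """
    if len(aln.seq_ids) < 4:
        raise PhylogenyError("bootstrap needs >= 4 sequences")
    rng = np.random.default_rng(seed)
    dm = jtt_distance_matrix(aln)
    tree = nj_tree(dm)
    if refine:
        tree = me_refine(tree, dm)

    codes = np.array([encode_protein_row(r) for r in aln.rows])
    n_cols = codes.shape[1]
    counts: dict[frozenset, int] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SaturationWarning)
        for _ in range(n_reps):
            cols = rng.integers(0, n_cols, size=n_cols)
            sample = codes[:, cols]
            n = len(aln.seq_ids)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = _ml_distance_from_counts(
                        _pair_counts(sample[i], sample[j])
                    )
            rep_tree = nj_tree(DistanceMatrix(list(aln.seq_ids), d))
            for bp in _resolved_bipartitions(rep_tree):
                counts[bp] = counts.get(bp, 0) + 1

    all_leaves = frozenset(tree.leaf_names)
    for node in tree.internal_nodes():
        below = frozenset(lf.name for lf in node.leaves())
        bp = normalize_bipartition(below, all_leaves)
        node.support = 100.0 * counts.get(bp, 0) / n_reps
    return tree


def flag_supported_clades(tree: Tree, threshold: float = 50.0) -> list[frozenset]:
    """Leaf sets of internal edges with bootstrap support > threshold.

    Each clade is the min-side of its bipartition; results are sorted by
    size then lexicographically for determinism.
    """
    internals = tree.internal_nodes()
    if not internals or all(n.support is None for n in internals):
        raise PhylogenyError("tree has no bootstrap supports")
    all_leaves = frozenset(tree.leaf_names)
    clades = []
    for node in internals:
        if node.support is not None and node.support > threshold:
            below = frozenset(lf.name for lf in node.leaves())
            clades.append(normalize_bipartition(below, all_leaves))
    return sorted(set(clades), key=lambda c: (len(c), sorted(c)))
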