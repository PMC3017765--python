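"""Protein multiple sequence alignment.

External alignments (e.g. from ClustalW/MAFFT) are first-class input via
:func:`read_aligned_fasta`; the built-in progressive aligner exists so the
rest of the pipeline is testable without external tools.  Gap convention:
the first gap character of a run costs ``gap_open``, each further character
``gap_extend`` (both negative).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .phylogeny import DistanceMatrix, nj_tree

__all__ = [
    "Alignment",
    "AlignmentError",
    "pairwise_align",
    "progressive_msa",
    "read_aligned_fasta",
    "write_aligned_fasta",
]

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class AlignmentError(ValueError):
    """Invalid alignment input."""


@dataclass
class Alignment:
    """An equal-row-length gapped protein alignment."""

    seq_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.seq_ids) != len(self.rows):
            raise AlignmentError("seq_ids and rows differ in length")
        if len(set(self.seq_ids)) != len(self.seq_ids):
            raise AlignmentError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged rows: lengths {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.seq_ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")


def _matrix_array(matrix) -> np.ndarray:
    """Dense 20x20 score array over AMINO_ACIDS for a Biopython matrix."""
    arr = np.zeros((len(AMINO_ACIDS), len(AMINO_ACIDS)))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            arr[i, j] = float(matrix[a, b])
    return arr


_AA_CODE = {aa: k for k, aa in enumerate(AMINO_ACIDS)}


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_CODE[ch] for ch in seq], dtype=np.int64)


def _profile_counts(rows: list[str]) -> np.ndarray:
    """Per-column residue counts (n_cols x 20); gaps contribute nothing."""
    n_cols = len(rows[0])
    counts = np.zeros((n_cols, len(AMINO_ACIDS)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != GAP:
                counts[j, _AA_CODE[ch]] += 1.0
    return counts


def _validate_protein(seq: str) -> str:
    if not seq:
        raise AlignmentError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise AlignmentError(f"unknown residue characters {sorted(bad)}")
    return seq


def _affine_align_profiles(
    S: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[int], float]:
    """Gotoh affine-gap global alignment given a column-pair score matrix.

    ``S[i, j]`` scores pairing column i of A with column j of B.  Returns
    the traceback as a list of moves (0 diagonal, 1 up/gap-in-B, 2 left/
    gap-in-A) from start to end, plus the optimal score.  Tie-break:
    diagonal, then up, then left.

    The fill is vectorised per row; the in-row left-gap state Y is a
    running maximum because it chains only through ``gap_extend``:
    Y[i,j] = max_{k<j} (max(M[i,k], X[i,k]) + gap_open + (j-1-k) ext).
    """
    n, m = S.shape
    NEG = -np.inf
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consume A / move up)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A (consume B / move left)
    M[0, 0] = 0.0
    Y[0, 1:] = gap_open + np.arange(m) * gap_extend
    jdx = np.arange(m + 1)
    for i in range(1, n + 1):
        M[i, 1:] = np.maximum.reduce(
            [M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]]
        ) + S[i - 1, :]
        X[i, :] = np.maximum.reduce(
            [M[i - 1, :] + gap_open, X[i - 1, :] + gap_extend,
             Y[i - 1, :] + gap_open]
        )
        b = np.maximum(M[i, :], X[i, :]) + gap_open - jdx * gap_extend
        prefix = np.maximum.accumulate(b)
        Y[i, 1:] = prefix[:-1] + (jdx[1:] - 1) * gap_extend
        # guard against -inf + inf arithmetic on impossible states
        Y[i, 0] = NEG

    # Traceback, preferring diagonal > up > left at every tie.
    moves: list[int] = []
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    score = float([M[n, m], X[n, m], Y[n, m]][state])
    while i > 0 or j > 0:
        if state == 0:
            s = S[i - 1, j - 1]
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            for k, p in enumerate(prev):
                if abs(p + s - M[i, j]) < 1e-9:
                    state = k
                    break
            moves.append(0)
            i, j = i - 1, j - 1
        elif state == 1:
            cands = [M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                     Y[i - 1, j] + gap_open]
            cur = X[i, j]
            for k, p in enumerate(cands):
                if abs(p - cur) < 1e-9:
                    state = k
                    break
            moves.append(1)
            i -= 1
        else:
            cands = [M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                     X[i, j - 1] + gap_open]
            cur = Y[i, j]
            order = [0, 2, 1]  # source states for the candidates above
            for k, p in enumerate(cands):
                if abs(p - cur) < 1e-9:
                    state = order[k]
                    break
            moves.append(2)
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    moves.reverse()
    return moves, score


def pairwise_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> tuple[str, str, float]:
    """Global (Needleman-Wunsch, affine-gap) optimal alignment of two proteins.

    Returns ``(aligned_a, aligned_b, score)``.  Default scoring is BLOSUM62
    with gap open -10 and extend -0.5.
    """
    matrix = _BLOSUM62 if matrix is None else matrix
    a = _validate_protein(a)
    b = _validate_protein(b)
    arr = _matrix_array(matrix)
    S = arr[np.ix_(_encode(a), _encode(b))]
    moves, score = _affine_align_profiles(S, gap_open, gap_extend)
    out_a, out_b = [], []
    i = j = 0
    for mv in moves:
        if mv == 0:
            out_a.append(a[i]); out_b.append(b[j]); i += 1; j += 1
        elif mv == 1:
            out_a.append(a[i]); out_b.append(GAP); i += 1
        else:
            out_a.append(GAP); out_b.append(b[j]); j += 1
    return "".join(out_a), "".join(out_b), score


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - fraction of shared k-mers (counted with multiplicity)."""
    if len(a) < k or len(b) < k:
        return 0.0 if a == b else 1.0
    ca = Counter(a[i:i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i:i + k] for i in range(len(b) - k + 1))
    shared = sum((ca & cb).values())
    denom = min(len(a), len(b)) - k + 1
    return 1.0 - shared / denom


def _merge_profiles(
    ids_a: list[str], rows_a: list[str],
    ids_b: list[str], rows_b: list[str],
    matrix, gap_open: float, gap_extend: float,
) -> tuple[list[str], list[str]]:
    # Average-of-pairs column score; gap-residue pairs contribute 0.
    arr = _matrix_array(matrix)
    counts_a = _profile_counts(rows_a)
    counts_b = _profile_counts(rows_b)
    S = (counts_a @ arr @ counts_b.T) / (len(rows_a) * len(rows_b))
    moves, _ = _affine_align_profiles(S, gap_open, gap_extend)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for mv in moves:
        if mv == 0:
            for r, row in zip(out_a, rows_a):
                r.append(row[i])
            for r, row in zip(out_b, rows_b):
                r.append(row[j])
            i += 1; j += 1
        elif mv == 1:
            for r, row in zip(out_a, rows_a):
                r.append(row[i])
            for r in out_b:
                r.append(GAP)
            i += 1
        else:
            for r in out_a:
                r.append(GAP)
            for r, row in zip(out_b, rows_b):
                r.append(row[j])
            j += 1
    return ids_a + ids_b, ["".join(r) for r in out_a + out_b]


def progressive_msa(
    proteins: dict[str, str],
    matrix=None,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> Alignment:
    """Progressive multiple alignment guided by an NJ tree on 3-mer distance.

    Profiles are merged in guide-tree postorder; stripping gaps from any row
    reproduces the corresponding input protein exactly.
    """
    if len(proteins) < 2:
        raise AlignmentError("progressive_msa needs >= 2 sequences")
    matrix = _BLOSUM62 if matrix is None else matrix
    ids = list(proteins)
    seqs = {i: _validate_protein(s) for i, s in proteins.items()}

    if len(ids) == 2:
        a, b, _ = pairwise_align(seqs[ids[0]], seqs[ids[1]],
                                 matrix, gap_open, gap_extend)
        return Alignment(ids, [a, b])

    d = np.zeros((len(ids), len(ids)))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d[i, j] = d[j, i] = _kmer_distance(seqs[ids[i]], seqs[ids[j]])
    guide = nj_tree(DistanceMatrix(ids, d))

    profiles: dict[int, tuple[list[str], list[str]]] = {}

    def build(node) -> int:
        """Return a profile key for this guide-tree node (postorder)."""
        if not node.children:
            key = len(profiles)
            profiles[key] = ([node.name], [seqs[node.name]])
            return key
        keys = [build(ch) for ch in node.children]
        key = keys[0]
        for other in keys[1:]:
            ids_a, rows_a = profiles[key]
            ids_b, rows_b = profiles[other]
            merged = _merge_profiles(ids_a, rows_a, ids_b, rows_b,
                                     matrix, gap_open, gap_extend)
            key = len(profiles)
            profiles[key] = merged
        return key

    final_ids, final_rows = profiles[build(guide.root)]
    # Restore input order.
    index = {sid: k for k, sid in enumerate(final_ids)}
    ordered_rows = [final_rows[index[sid]] for sid in ids]
    return Alignment(ids, ordered_rows)


def read_aligned_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA; validates equal row lengths, uppercases."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentError(f"no records in {path}")
    return Alignment(ids, rows)


def write_aligned_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.seq_ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")
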