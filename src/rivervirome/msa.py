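"""Progressive multiple alignment of peptides with gap-site masking.

A small MUSCLE-style stand-in: pairwise k-mer distances build a UPGMA
guide tree, profiles are merged bottom-up with affine-gap
Needleman-Wunsch (BLOSUM62, gap open 8 / extend 1, profile columns
scored by the average substitution score over residue pairs), and
alignment columns whose gap fraction strictly exceeds 0.5 are removed
("temporarily", i.e. only from the alignment handed to tree building).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import AA_INDEX, _MATRIX
from .trees import DistanceMatrix, TreeNode, neighbor_joining, upgma

GAP_OPEN = 8
GAP_EXTEND = 1


@dataclass
class MultipleAlignment:
    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def _kmer_set(seq: str, k: int = 3) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - |shared k-mers| / min(|kmers_a|, |kmers_b|)."""
    ka, kb = _kmer_set(a, k), _kmer_set(b, k)
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _col_score(col_a: str, col_b: str) -> float:
    """Average BLOSUM62 score over residue pairs; gap pairs score 0."""
    total, n = 0.0, 0
    for x in col_a:
        if x == "-":
            continue
        xi = AA_INDEX.get(x, AA_INDEX["X"])
        for y in col_b:
            if y == "-":
                continue
            total += _MATRIX[xi, AA_INDEX.get(y, AA_INDEX["X"])]
            n += 1
    return total / n if n else 0.0


def _align_profiles(a_rows: list[str], b_rows: list[str]
                    ) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two alignment profiles."""
    A = ["".join(r[c] for r in a_rows) for c in range(len(a_rows[0]))]
    B = ["".join(r[c] for r in b_rows) for c in range(len(b_rows[0]))]
    m, n = len(A), len(B)
    NEG = -1e18
    open_cost = GAP_OPEN + GAP_EXTEND
    ext = GAP_EXTEND
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in B (A column vs gaps)
    Y = np.full((m + 1, n + 1), NEG)  # gap in A
    ptrM = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrX = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrY = np.zeros((m + 1, n + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = -open_cost - ext * (i - 1)
        ptrX[i, 0] = 2 if i > 1 else 1
    for j in range(1, n + 1):
        Y[0, j] = -open_cost - ext * (j - 1)
        ptrY[0, j] = 3 if j > 1 else 1
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = _col_score(A[i - 1], B[j - 1])
            opts = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            b = int(np.argmax(opts))
            M[i, j] = opts[b] + s
            ptrM[i, j] = b + 1
            ox = (M[i - 1, j] - open_cost, X[i - 1, j] - ext)
            bx = int(np.argmax(ox))
            X[i, j] = ox[bx]
            ptrX[i, j] = 1 if bx == 0 else 2
            oy = (M[i, j - 1] - open_cost, Y[i, j - 1] - ext)
            by = int(np.argmax(oy))
            Y[i, j] = oy[by]
            ptrY[i, j] = 1 if by == 0 else 3
    state = int(np.argmax((M[m, n], X[m, n], Y[m, n]))) + 1
    i, j = m, n
    cols: list[tuple[int, int]] = []  # (a_col or -1, b_col or -1)
    while i > 0 or j > 0:
        if state == 1:
            cols.append((i - 1, j - 1))
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 2:
            cols.append((i - 1, -1))
            state = 1 if ptrX[i, j] == 1 else 2
            i -= 1
        else:
            cols.append((-1, j - 1))
            state = 1 if ptrY[i, j] == 1 else 3
            j -= 1
    cols.reverse()
    new_a = []
    for k in range(len(a_rows)):
        new_a.append("".join(A[ca][k] if ca >= 0 else "-" for ca, _ in cols))
    new_b = []
    for k in range(len(b_rows)):
        new_b.append("".join(B[cb][k] if cb >= 0 else "-" for _, cb in cols))
    return new_a, new_b


def progressive_align(items: list[tuple[str, str]]) -> MultipleAlignment:
    """Align (label, peptide) pairs along a UPGMA k-mer guide tree."""
    if len(items) < 2:
        raise ValueError("need >= 2 sequences")
    labels = [l for l, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    seqs = dict(items)
    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kmer_distance(items[i][1], items[j][1])
    guide = upgma(DistanceMatrix(labels=labels, d=d))

    def merge(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.label], [seqs[node.label]]
        parts = [merge(c) for c in node.children]
        lab, rows = parts[0]
        for lab2, rows2 in parts[1:]:
            rows, rows2 = _align_profiles(rows, rows2)
            lab = lab + lab2
            rows = rows + rows2
        return lab, rows

    lab, rows = merge(guide)
    # restore input order
    order = {l: i for i, l in enumerate(lab)}
    rows = [rows[order[l]] for l in labels]
    return MultipleAlignment(labels=labels, rows=rows)


def mask_gappy_columns(msa: MultipleAlignment,
                       max_gap_frac: float = 0.5) -> MultipleAlignment:
    """Drop columns whose gap fraction strictly exceeds ``max_gap_frac``."""
    n = len(msa.rows)
    keep = [
        c for c in range(msa.n_cols)
        if sum(1 for r in msa.rows if r[c] == "-") / n <= max_gap_frac
    ]
    rows = ["".join(r[c] for c in keep) for r in msa.rows]
    return MultipleAlignment(labels=list(msa.labels), rows=rows)


def align_and_mask(items: list[tuple[str, str]]) -> MultipleAlignment:
    """Progressive alignment followed by >50%-gap column removal."""
    return mask_gappy_columns(progressive_align(items))


def p_distance_matrix(msa: MultipleAlignment) -> DistanceMatrix:
    """Pairwise mismatch fractions over mutually non-gap columns."""
    n = len(msa.rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = msa.rows[i], msa.rows[j]
            shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if shared:
                mism = sum(1 for x, y in shared if x != y)
                d[i, j] = d[j, i] = mism / len(shared)
            else:
                d[i, j] = d[j, i] = 1.0
    return DistanceMatrix(labels=list(msa.labels), d=d)


def nj_tree(msa: MultipleAlignment) -> TreeNode:
    """Neighbor-joining tree on alignment p-distances."""
    if len(msa.rows) < 3:
        raise ValueError("need >= 3 aligned sequences")
    return neighbor_joining(p_distance_matrix(msa))
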