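"""Protein alignment scoring: BLOSUM62, ungapped X-drop extension,
banded Smith-Waterman, and Karlin-Altschul E-value statistics.

The scoring scheme fixes BLOSUM62 with BLAST-style affine gap costs
(a gap of length L costs open + extend*L) and the published gapped
Karlin-Altschul constants lambda=0.267, K=0.041, so E-values are fully
deterministic:  E = K * m * n * exp(-lambda * S)  and
bit = (lambda*S - ln K) / ln 2, hence E = m * n * 2**(-bit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

#: alphabet of the packed substitution matrix (BLOSUM62 order in Biopython)
_B62 = substitution_matrices.load("BLOSUM62")
ALPHABET = str(_B62.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_MATRIX = np.array(_B62, dtype=np.int64)


def _as_index(pep: str) -> np.ndarray:
    x_idx = AA_INDEX["X"]
    return np.array([AA_INDEX.get(a, x_idx) for a in pep], dtype=np.int64)


@dataclass
class ScoringScheme:
    """BLOSUM62 scoring with affine gaps and fixed gapped K-A constants."""

    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    matrix: np.ndarray = field(default_factory=lambda: _MATRIX, repr=False)

    def score_pair(self, a: str, b: str) -> int:
        return int(self.matrix[AA_INDEX.get(a, AA_INDEX["X"]),
                               AA_INDEX.get(b, AA_INDEX["X"])])

    def bit_score(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.K)) / math.log(2.0)

    def e_value(self, raw: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * raw)


@dataclass
class LocalAlignment:
    """Best local alignment found by extension or banded DP."""

    score: int
    q_start: int
    q_end: int  # half-open
    s_start: int
    s_end: int
    n_ident: int
    n_aligned: int

    @property
    def pct_identity(self) -> float:
        if self.n_aligned == 0:
            return 0.0
        return 100.0 * self.n_ident / self.n_aligned


def ungapped_extend(q: str, s: str, qi: int, si: int, k: int,
                    scheme: ScoringScheme, xdrop: int = 20) -> LocalAlignment:
    """Extend an exact k-mer seed at (qi, si) without gaps, X-drop pruned.

    Returns the maximal-scoring ungapped segment containing the seed.
    """
    mat = scheme.matrix
    score = 0
    for off in range(k):
        score += mat[AA_INDEX.get(q[qi + off], 22), AA_INDEX.get(s[si + off], 22)]
    best = score
    best_right = k  # length to the right of qi
    cur = score
    i, j = qi + k, si + k
    while i < len(q) and j < len(s):
        cur += mat[AA_INDEX.get(q[i], 22), AA_INDEX.get(s[j], 22)]
        i += 1
        j += 1
        if cur > best:
            best = cur
            best_right = i - qi
        elif best - cur > xdrop:
            break
    cur = best
    best_left = 0  # extension to the left of qi
    i, j = qi - 1, si - 1
    running = best
    while i >= 0 and j >= 0:
        running += mat[AA_INDEX.get(q[i], 22), AA_INDEX.get(s[j], 22)]
        if running > cur:
            cur = running
            best_left = qi - i
        elif cur - running > xdrop:
            break
        i -= 1
        j -= 1
    q_start = qi - best_left
    q_end = qi + best_right
    s_start = si - best_left
    s_end = si + best_right
    n_al = q_end - q_start
    n_id = sum(1 for a, b in zip(q[q_start:q_end], s[s_start:s_end]) if a == b)
    return LocalAlignment(int(cur), q_start, q_end, s_start, s_end, n_id, n_al)


def banded_smith_waterman(q: str, s: str, diag: int, band: int,
                          scheme: ScoringScheme) -> LocalAlignment:
    """Affine-gap local alignment restricted to diagonals ``diag +- band``.

    ``diag`` is q_index - s_index of the seed.  Gap of length L costs
    open + extend*L (BLAST convention).  Returns the single best local
    alignment with a traceback for identity counting.
    """
    mat = scheme.matrix
    open_cost = scheme.gap_open + scheme.gap_extend
    ext_cost = scheme.gap_extend
    m, n = len(q), len(s)
    width = 2 * band + 1
    NEG = -(10 ** 9)
    # H/E/F over (i, b) where s_j = i - diag - band + b
    H = [[NEG] * width for _ in range(m + 1)]
    E = [[NEG] * width for _ in range(m + 1)]  # gap in s (up moves)
    F = [[NEG] * width for _ in range(m + 1)]  # gap in q (left moves)
    ptr = [[0] * width for _ in range(m + 1)]  # 0 stop,1 diag,2 up,3 left
    qi_idx = _as_index(q)
    si_idx = _as_index(s)
    best = (0, 0, 0)  # score, i, b
    for i in range(1, m + 1):
        Hi, Hp = H[i], H[i - 1]
        Ei, Ep = E[i], E[i - 1]
        Fi = F[i]
        Pi = ptr[i]
        base = i - diag - band  # s_j for b=0 is base+0  (1-based j = base+b)
        for b in range(width):
            j = base + b
            if j < 1 or j > n:
                continue
            sub = mat[qi_idx[i - 1], si_idx[j - 1]]
            # diag predecessor is (i-1, same b) since both i and j shift
            hd = Hp[b] if Hp[b] != NEG else 0
            diag_score = max(Hp[b], 0) + sub
            # up: (i-1, j) -> b+1 in row i-1
            e_prev = NEG
            if b + 1 < width:
                e_prev = max(Ep[b + 1] - ext_cost,
                             Hp[b + 1] - open_cost)
            Ei[b] = e_prev
            # left: (i, j-1) -> b-1 in row i
            f_prev = NEG
            if b - 1 >= 0:
                f_prev = max(Fi[b - 1] - ext_cost,
                             Hi[b - 1] - open_cost)
            Fi[b] = f_prev
            h = max(0, diag_score, Ei[b], Fi[b])
            Hi[b] = h
            if h == 0:
                Pi[b] = 0
            elif h == diag_score:
                Pi[b] = 1
            elif h == Ei[b]:
                Pi[b] = 2
            else:
                Pi[b] = 3
            if h > best[0]:
                best = (h, i, b)
    score, bi, bb = best
    if score <= 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0)
    # traceback
    i, b = bi, bb
    q_end = i
    s_end = i - diag - band + b
    n_id = 0
    n_al = 0
    while i > 0:
        p = ptr[i][b]
        if p == 0:
            break
        if p == 1:
            j = i - diag - band + b
            n_al += 1
            if q[i - 1] == s[j - 1]:
                n_id += 1
            i -= 1
        elif p == 2:
            n_al += 1
            i -= 1
            b += 1
            # consume the gap run: walk up while E was the source
            # (single-step approximation is fine for scoring/identity)
        else:
            n_al += 1
            b -= 1
        if b < 0 or b >= width:
            break
    q_start = i
    s_start = i - diag - band + b
    return LocalAlignment(int(score), q_start, q_end, max(s_start, 0), s_end,
                          n_id, n_al)


def smith_waterman_full(q: str, s: str, scheme: ScoringScheme) -> int:
    """Unbanded, seedless affine-gap local alignment score (small inputs).

    Used as the reference scorer for short peptides; O(m*n).
    """
    open_cost = scheme.gap_open + scheme.gap_extend
    ext_cost = scheme.gap_extend
    mat = scheme.matrix
    m, n = len(q), len(s)
    NEG = -(10 ** 9)
    qi = _as_index(q)
    si = _as_index(s)
    Hp = [0] * (n + 1)
    Ep = [NEG] * (n + 1)
    best = 0
    for i in range(1, m + 1):
        Hc = [0] * (n + 1)
        Ec = [NEG] * (n + 1)
        f = NEG
        row = mat[qi[i - 1]]
        for j in range(1, n + 1):
            e = max(Ep[j] - ext_cost, Hp[j] - open_cost)
            f = max(f - ext_cost, Hc[j - 1] - open_cost)
            h = max(0, Hp[j - 1] + row[si[j - 1]], e, f)
            Hc[j] = h
            Ec[j] = e
            if h > best:
                best = h
        Hp, Ep = Hc, Ec
    return int(best)
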