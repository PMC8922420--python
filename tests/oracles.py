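"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: deduplication by
all-pairs window comparison, assembly by exhaustive best-overlap-first
agglomeration over all suffix-prefix lengths, and profile-HMM scoring
by explicit path enumeration.
"""

from __future__ import annotations

import itertools
import math

from rivervirome.records import reverse_complement


def dedup_groups(reads, window):
    """Groups of read ids under all-pairs window-substring comparison."""
    start, end = window

    def key(r):
        return r.seq[start - 1:end] if len(r.seq) >= end else r.seq[start - 1:]

    n = len(reads)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if key(reads[i]) == key(reads[j]):
                parent[find(i)] = find(j)
    groups = {}
    for i, r in enumerate(reads):
        groups.setdefault(find(i), set()).add(r.read_id)
    return {frozenset(g) for g in groups.values()}


def _all_overlaps(x: str, y: str, min_overlap: int, max_mismatch_frac: float):
    """All qualifying suffix(x)-prefix(y) overlap lengths."""
    out = []
    for L in range(min_overlap, min(len(x), len(y)) + 1):
        a, b = x[-L:], y[:L]
        mism = sum(1 for p, q in zip(a, b) if p != q)
        if mism <= max_mismatch_frac * L:
            out.append(L)
    return out


def greedy_assemble(reads, min_overlap=30, min_identity=0.98,
                    min_contig_len=250):
    """Exhaustive best-overlap-first agglomeration (small inputs only).

    Returns (contig sequence multiset canonicalised by strand,
    member-count list) matching the package's greedy semantics: longest
    overlap first, ties by lexicographically smallest id pair, reverse
    complements considered.
    """
    seqs = {r.read_id: r.seq for r in reads}
    members = {r.read_id: [r.read_id] for r in reads}
    frac = 1.0 - min_identity
    counter = itertools.count()
    while True:
        best = None
        for xid, yid in itertools.permutations(sorted(seqs), 2):
            for orient in ("+", "-"):
                y = seqs[yid] if orient == "+" else reverse_complement(seqs[yid])
                for L in _all_overlaps(seqs[xid], y, min_overlap, frac):
                    key = (-L, tuple(sorted((xid, yid))), xid, yid, orient)
                    if best is None or key < best[0]:
                        best = (key, xid, yid, orient, L)
        if best is None:
            break
        _, xid, yid, orient, L = best
        y = seqs[yid] if orient == "+" else reverse_complement(seqs[yid])
        merged = seqs[xid] + y[L:]
        new_id = f"bf{next(counter):04d}"
        members[new_id] = members.pop(xid) + members.pop(yid)
        seqs[new_id] = merged
        del seqs[xid]
        del seqs[yid]
    contigs = []
    singlets = []
    for sid, seq in seqs.items():
        if len(members[sid]) > 1 and len(seq) >= min_contig_len:
            contigs.append((min(seq, reverse_complement(seq)),
                            len(members[sid])))
        else:
            singlets.extend(members[sid])
    return sorted(contigs), sorted(singlets)


def enumerate_hmm_score(hmm, pep: str):
    """(viterbi, forward) by explicit path enumeration, small models only.

    Paths enter at M1 at some position, optionally pass through insert
    states between consecutive matches or skip interior positions via
    delete states, and exit at ML.  Mirrors the package's model
    semantics exactly but scores every path explicitly.
    """
    import numpy as np

    L = hmm.length
    assert L in (2, 3), "enumeration written for tiny models"
    lo = np.log(hmm.match_emis / hmm.background)
    lt = np.log(hmm.trans)
    n = len(pep)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    idx = [aa.index(c) for c in pep]
    scores = []
    if L == 2:
        for s in range(n):
            for e in range(s + 1, n):
                sc = lo[0][idx[s]] + lo[1][idx[e]]
                k = e - s - 1  # inserted residues
                if k == 0:
                    sc += lt[0][0]  # M1->M2
                else:
                    sc += lt[0][1] + (k - 1) * lt[0][4] + lt[0][3]
                scores.append(sc)
    else:  # L == 3
        for s in range(n):
            # M1 D2 M3: next residue immediately after s
            if s + 1 < n:
                sc = (lo[0][idx[s]] + lt[0][2] + lt[1][5] + lo[2][idx[s + 1]])
                scores.append(sc)
            for m2 in range(s + 1, n):
                for m3 in range(m2 + 1, n):
                    sc = lo[0][idx[s]] + lo[1][idx[m2]] + lo[2][idx[m3]]
                    k1 = m2 - s - 1
                    sc += (lt[0][0] if k1 == 0
                           else lt[0][1] + (k1 - 1) * lt[0][4] + lt[0][3])
                    k2 = m3 - m2 - 1
                    sc += (lt[1][0] if k2 == 0
                           else lt[1][1] + (k2 - 1) * lt[1][4] + lt[1][3])
                    scores.append(sc)
    if not scores:
        return float("-inf"), float("-inf")
    vit = max(scores) / math.log(2)
    fwd = math.log(sum(math.exp(s) for s in scores)) / math.log(2)
    return vit, fwd
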