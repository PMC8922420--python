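"""Greedy overlap-layout-consensus assembly and read-back mapping.

Per library, cleaned reads are merged greedily: the pair of sequences
with the longest suffix-prefix overlap (>= ``min_overlap`` bases at
>= ``min_overlap_identity``) is merged first, ties broken by the
lexicographically smallest id pair; the consensus takes the majority
base with a quality-sum tie-break.  Reverse-complement overlaps are
considered; the canonical orientation is that of the first-merged
sequence.  Merging repeats until no qualifying overlap remains.
Sequences never merged stay singlets, and contigs shorter than
``min_contig_len`` are demoted back to their member reads (the
length-based chimera filter).

Candidate overlaps are discovered with a strided k-mer index (w=16,
stride 8), which guarantees detection of every exact suffix-prefix
overlap of >= 23 bases; mismatch-tolerant overlaps are found whenever
the leading 23 bases of the overlap are exact.  Verification always
applies the full identity threshold.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .records import Contig, Read, reverse_complement

_W = 16          # seed k-mer width
_STRIDE = 8      # index stride; detection floor is _W + _STRIDE - 1 = 23 nt


@dataclass
class AssemblyConfig:
    min_overlap: int = 30
    min_overlap_identity: float = 0.98
    min_contig_len: int = 250
    map_min_identity: float = 0.95
    map_min_aligned: int = 50

    def __post_init__(self) -> None:
        for x in (self.min_overlap_identity, self.map_min_identity):
            if not 0.0 < x <= 1.0:
                raise ValueError("identity thresholds must be in (0, 1]")


class _SeqState:
    """Mutable assembly unit: consensus string plus per-base vote tallies."""

    __slots__ = ("sid", "seq", "rc", "cov", "qsum", "conflicts", "members")

    def __init__(self, sid: str, seq: str, qual: list[int] | np.ndarray,
                 members: list[str]):
        self.sid = sid
        self.seq = seq
        self.rc = reverse_complement(seq)
        self.cov = np.ones(len(seq), dtype=np.int32)
        self.qsum = np.asarray(qual, dtype=np.int64).copy()
        # sparse per-position minority votes: pos -> {base: [count, qualsum]}
        self.conflicts: dict[int, dict[str, list[int]]] = {}
        self.members = members


def _count_mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return mism
    return mism


def _merge_states(x: _SeqState, y: _SeqState, orient: str, L: int,
                  new_id: str) -> _SeqState:
    """Merge x.suffix with y(orient).prefix over L bases."""
    if orient == "-":
        y_seq = y.rc
        y_cov = y.cov[::-1]
        y_qsum = y.qsum[::-1]
        comp = str.maketrans("ACGTN", "TGCAN")
        y_conf = {
            len(y.seq) - 1 - p: {b.translate(comp): v for b, v in d.items()}
            for p, d in y.conflicts.items()
        }
    else:
        y_seq, y_cov, y_qsum, y_conf = y.seq, y.cov, y.qsum, dict(y.conflicts)
    nx = len(x.seq)
    off = nx - L  # y position 0 sits at x position off
    new_seq = list(x.seq + y_seq[L:])
    cov = np.concatenate([x.cov, y_cov[L:]])
    qsum = np.concatenate([x.qsum, y_qsum[L:]])
    conflicts = dict(x.conflicts)
    for p, d in y_conf.items():
        gp = off + p
        tgt = conflicts.setdefault(gp, {})
        for b, (c, q) in d.items():
            cur = tgt.setdefault(b, [0, 0])
            cur[0] += c
            cur[1] += q
    # overlay y's overlap votes onto x's suffix
    for k in range(L):
        gp = off + k
        xb = new_seq[gp]
        yb = y_seq[k]
        if yb == xb:
            cov[gp] += y_cov[k]
            qsum[gp] += y_qsum[k]
        else:
            tgt = conflicts.setdefault(gp, {})
            cur = tgt.setdefault(yb, [0, 0])
            cur[0] += int(y_cov[k])
            cur[1] += int(y_qsum[k])
            # recompute consensus: majority count, quality-sum tie-break,
            # lexicographic base as final tie-break
            cands = [(int(cov[gp]), int(qsum[gp]), xb)] + [
                (c, q, b) for b, (c, q) in tgt.items()
            ]
            cands.sort(key=lambda t: (-t[0], -t[1], t[2]))
            win = cands[0][2]
            if win != xb:
                tgt[xb] = [int(cov[gp]), int(qsum[gp])]
                wc, wq = tgt.pop(win)
                cov[gp] = wc
                qsum[gp] = wq
                new_seq[gp] = win
    out = _SeqState.__new__(_SeqState)
    out.sid = new_id
    out.seq = "".join(new_seq)
    out.rc = reverse_complement(out.seq)
    out.cov = cov
    out.qsum = qsum
    out.conflicts = conflicts
    out.members = x.members + y.members
    return out


class _OverlapFinder:
    """Strided k-mer indexes over active sequences for candidate discovery."""

    def __init__(self, cfg: AssemblyConfig):
        self.cfg = cfg
        # w-mer at stride positions of seq.fwd -> [(sid, pos)]
        self.body: dict[str, list[tuple[str, int]]] = {}
        # prefix w-mers (offsets 0.._STRIDE-1, both orients) -> [(sid, orient, o)]
        self.pref: dict[str, list[tuple[str, str, int]]] = {}

    def add(self, st: _SeqState) -> None:
        seq = st.seq
        for p in range(0, len(seq) - _W + 1, _STRIDE):
            self.body.setdefault(seq[p:p + _W], []).append((st.sid, p))
        for orient, s in (("+", st.seq), ("-", st.rc)):
            for o in range(min(_STRIDE, max(len(s) - _W + 1, 0))):
                self.pref.setdefault(s[o:o + _W], []).append((st.sid, orient, o))

    def candidates(self, st: _SeqState, active: dict[str, _SeqState]
                   ) -> list[tuple[int, str, str, str, str]]:
        """(L, x_id, y_id, y_orient) candidates involving ``st``.

        Returned as tuples (L, xid, yid, orient, kind-tag); the caller
        verifies identity before queueing.
        """
        out = set()
        cfg = self.cfg
        # st as the RIGHT partner: other.suffix + st(orient).prefix
        for orient, s in (("+", st.seq), ("-", st.rc)):
            for o in range(min(_STRIDE, max(len(s) - _W + 1, 0))):
                for xid, p in self.body.get(s[o:o + _W], ()):  # noqa: B020
                    if xid == st.sid or xid not in active:
                        continue
                    x = active[xid]
                    shift = p - o  # st base 0 at x position shift
                    if shift < 0:
                        continue
                    L = len(x.seq) - shift
                    if L < cfg.min_overlap or L > len(s):
                        continue
                    out.add((L, xid, st.sid, orient))
        # st as the LEFT partner: st.suffix + other(orient).prefix
        for st_orient, s in (("+", st.seq), ("-", st.rc)):
            for p in range(0, len(s) - _W + 1, _STRIDE):
                for yid, orient, o in self.pref.get(s[p:p + _W], ()):
                    if yid == st.sid or yid not in active:
                        continue
                    y = active[yid]
                    start = p - o  # other's base 0 at s position start
                    if start < 0:
                        continue
                    L = len(s) - start
                    y_len = len(y.seq)
                    if L < cfg.min_overlap or L > y_len:
                        continue
                    if st_orient == "+":
                        out.add((L, st.sid, yid, orient))
                    else:
                        # st.rc.suffix + y(orient).prefix is the reverse
                        # complement of y(-orient).suffix + st(+).prefix
                        flip = "-" if orient == "+" else "+"
                        out.add((L, yid, st.sid, flip))
        return [(L, a, b, t, "") for (L, a, b, t) in out]


def _verify(x: _SeqState, y: _SeqState, orient: str, L: int,
            cfg: AssemblyConfig) -> bool:
    y_seq = y.seq if orient == "+" else y.rc
    if L > len(x.seq) or L > len(y_seq):
        return False
    limit = int((1.0 - cfg.min_overlap_identity) * L)
    return _count_mismatches(x.seq[len(x.seq) - L:], y_seq[:L], limit) <= limit


def assemble(reads: list[Read], cfg: AssemblyConfig | None = None,
             library: str | None = None) -> tuple[list[Contig], list[Read]]:
    """Greedy longest-overlap-first assembly of one library's reads."""
    cfg = cfg or AssemblyConfig()
    if not reads:
        return [], []
    library = library or reads[0].library
    active: dict[str, _SeqState] = {}
    for r in reads:
        if len(r) >= _W:
            active[r.read_id] = _SeqState(r.read_id, r.seq, r.qual, [r.read_id])
    finder = _OverlapFinder(cfg)
    for st in active.values():
        finder.add(st)
    heap: list[tuple[int, tuple[str, str], str, str, str]] = []
    seen: set[tuple[str, str, str, int]] = set()

    def queue_candidates(st: _SeqState) -> None:
        for L, xid, yid, orient, _ in finder.candidates(st, active):
            key = (xid, yid, orient, L)
            if key in seen:
                continue
            seen.add(key)
            pair = tuple(sorted((xid, yid)))
            heapq.heappush(heap, (-L, pair, xid, yid, orient))

    for st in list(active.values()):
        queue_candidates(st)
    n_contigs = 0
    while heap:
        negL, _pair, xid, yid, orient = heapq.heappop(heap)
        if xid not in active or yid not in active or xid == yid:
            continue
        L = -negL
        x, y = active[xid], active[yid]
        if not _verify(x, y, orient, L, cfg):
            continue
        new_id = f"ctg{n_contigs:06d}"
        n_contigs += 1
        merged = _merge_states(x, y, orient, L, new_id)
        del active[xid]
        del active[yid]
        active[new_id] = merged
        finder.add(merged)
        queue_candidates(merged)
    contigs: list[Contig] = []
    singlets: list[Read] = []
    consumed: set[str] = set()
    multi = [st for st in active.values() if len(st.members) > 1]
    multi.sort(key=lambda s: (-len(s.seq), s.members[0]))
    kept_idx = 0
    for st in multi:
        if len(st.seq) >= cfg.min_contig_len:
            contigs.append(
                Contig(
                    contig_id=f"{library}_c{kept_idx:05d}",
                    library=library,
                    seq=st.seq,
                    member_read_ids=sorted(st.members),
                )
            )
            kept_idx += 1
            consumed.update(st.members)
        # short contigs fall through: members return as singlets
    for r in reads:
        if r.read_id not in consumed:
            singlets.append(r)
    return contigs, singlets


@dataclass
class MappingReport:
    library: str
    n_reads: int
    n_mapped: int
    per_contig: dict[str, int] = field(default_factory=dict)

    @property
    def pct_mapped(self) -> float:
        return 100.0 * self.n_mapped / self.n_reads if self.n_reads else 0.0


def map_reads_back(reads: list[Read], contigs: list[Contig],
                   cfg: AssemblyConfig | None = None) -> MappingReport:
    """Count reads with an ungapped alignment to some contig.

    A read maps if either strand aligns to a contig over
    >= ``map_min_aligned`` bases at >= ``map_min_identity`` (ungapped).
    Each read is credited to the first matching contig; contig
    ``n_reads_mapped`` fields are updated in place.
    """
    cfg = cfg or AssemblyConfig()
    library = reads[0].library if reads else ""
    report = MappingReport(library=library, n_reads=len(reads), n_mapped=0)
    if not contigs or not reads:
        return report
    k = 20
    index: dict[str, tuple[int, int]] = {}
    for ci, c in enumerate(contigs):
        s = c.seq
        for p in range(0, len(s) - k + 1):
            kmer = s[p:p + k]
            if kmer not in index:
                index[kmer] = (ci, p)
    for c in contigs:
        report.per_contig[c.contig_id] = 0
    for r in reads:
        hit_contig = None
        for seq in (r.seq, reverse_complement(r.seq)):
            if len(seq) < k:
                continue
            for probe in range(0, len(seq) - k + 1, k):
                got = index.get(seq[probe:probe + k])
                if got is None:
                    continue
                ci, cp = got
                contig = contigs[ci]
                offset = cp - probe
                rs = max(0, -offset)
                re_ = min(len(seq), len(contig.seq) - offset)
                if re_ - rs < cfg.map_min_aligned:
                    continue
                limit = int((1.0 - cfg.map_min_identity) * (re_ - rs))
                mism = _count_mismatches(
                    seq[rs:re_], contig.seq[rs + offset:re_ + offset], limit
                )
                if mism <= limit:
                    hit_contig = contig
                    break
            if hit_contig:
                break
        if hit_contig:
            report.n_mapped += 1
            report.per_contig[hit_contig.contig_id] += 1
    for c in contigs:
        c.n_reads_mapped = report.per_contig.get(c.contig_id, 0)
    return report
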