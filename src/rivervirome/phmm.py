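"""Minimal profile HMMs for remote-homology rescue.

A lightweight Plan7-style profile: match states M1..ML with 20-symbol
emission distributions, insert states I1..I(L-1) emitting the
background, and interior delete states D2..D(L-1).  Alignment is
global in the model and local in the sequence: a path enters at M1 at
any sequence position and exits from ML, with free (zero log-odds)
flanks on both sides.

Scores are log-odds against the background in bits.  Viterbi uses a
max-product recurrence and the forward score a sum-product recurrence,
both vectorised over model positions; the in-row delete chain is
handled with a prefix-scan (maximum.accumulate / logaddexp.accumulate).

Profiles serialise to a small plain-text format (NAME/LENGTH/
BACKGROUND/MATCH/TRANS lines) so HMM sets can live as ordinary files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA = {a: i for i, a in enumerate(ALPHABET)}
# Structurally-forbidden transitions use a large finite penalty rather than
# -inf so that prefix-scan arithmetic stays NaN-free; real scores are O(1e3),
# so anything below ~-1e5 can never win or pass a cutoff.
_NEG = -1.0e6


@dataclass
class ProfileHMM:
    name: str
    match_emis: np.ndarray     # (L, 20) probabilities
    background: np.ndarray     # (20,) probabilities
    trans: np.ndarray          # (L, 7) probabilities: mm mi md im ii dm dd

    def __post_init__(self) -> None:
        self.match_emis = np.asarray(self.match_emis, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        if self.match_emis.shape[1] != 20:
            raise ValueError("match emissions must have 20 columns")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background does not sum to 1")
        sums = self.match_emis.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("match emissions do not sum to 1")

    @property
    def length(self) -> int:
        return self.match_emis.shape[0]

    # -- construction -------------------------------------------------

    @classmethod
    def from_aligned(cls, name: str, rows: list[str],
                     pseudocount: float = 0.5) -> "ProfileHMM":
        """Build from equal-length (gapped) aligned sequences.

        Columns with more than 50% gaps become insert columns; the rest
        are match columns.  Emissions and transitions are
        pseudocount-smoothed counts; the background is uniform.
        """
        if not rows:
            raise ValueError("no sequences")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise ValueError("rows differ in length")
        n = len(rows)
        is_match = [
            sum(1 for r in rows if r[c] == "-") <= 0.5 * n for c in range(width)
        ]
        L = sum(is_match)
        if L == 0:
            raise ValueError("no match columns")
        emis = np.full((L, 20), pseudocount, dtype=float)
        # transition counts per model position: mm mi md im ii dm dd
        tcounts = np.full((L, 7), 0.0)
        tcounts[:, [0, 1, 2]] += pseudocount          # from M
        tcounts[:, [3, 4]] += pseudocount             # from I
        tcounts[:, [5, 6]] += pseudocount             # from D
        match_cols = [c for c in range(width) if is_match[c]]
        col_to_j = {c: j for j, c in enumerate(match_cols)}
        for r in rows:
            # emissions
            for j, c in enumerate(match_cols):
                if r[c] in _AA:
                    emis[j, _AA[r[c]]] += 1.0
            # transitions: walk the row's state path
            prev_state, prev_j = None, -1
            for c in range(width):
                if is_match[c]:
                    j = col_to_j[c]
                    state = "M" if r[c] != "-" else "D"
                else:
                    if r[c] == "-":
                        continue
                    state = "I"
                    j = prev_j
                if prev_state is not None and prev_j >= 0:
                    col = {"MM": 0, "MI": 1, "MD": 2, "IM": 3, "II": 4,
                           "DM": 5, "DD": 6}.get(prev_state + state)
                    if col is not None:
                        tcounts[prev_j, col] += 1.0
                prev_state, prev_j = state, j
        # normalise transition triples by source state
        trans = tcounts.copy()
        trans[:, 0:3] /= trans[:, 0:3].sum(axis=1, keepdims=True)
        trans[:, 3:5] /= trans[:, 3:5].sum(axis=1, keepdims=True)
        trans[:, 5:7] /= trans[:, 5:7].sum(axis=1, keepdims=True)
        emis /= emis.sum(axis=1, keepdims=True)
        bg = np.full(20, 1.0 / 20.0)
        return cls(name=name, match_emis=emis, background=bg, trans=trans)

    # -- serialisation -------------------------------------------------

    def to_text(self) -> str:
        lines = ["PHMM 1", f"NAME {self.name}", f"LENGTH {self.length}",
                 f"ALPHABET {ALPHABET}",
                 "BACKGROUND " + " ".join(f"{p:.8g}" for p in self.background)]
        for j in range(self.length):
            lines.append(
                f"MATCH {j + 1} " + " ".join(f"{p:.8g}" for p in self.match_emis[j])
            )
            lines.append(
                f"TRANS {j + 1} " + " ".join(f"{p:.8g}" for p in self.trans[j])
            )
        lines.append("END")
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "ProfileHMM":
        name, length, bg = None, None, None
        emis_rows, trans_rows = {}, {}
        for line in text.splitlines():
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "NAME":
                name = parts[1]
            elif parts[0] == "LENGTH":
                length = int(parts[1])
            elif parts[0] == "BACKGROUND":
                bg = np.array([float(x) for x in parts[1:]])
            elif parts[0] == "MATCH":
                emis_rows[int(parts[1])] = [float(x) for x in parts[2:]]
            elif parts[0] == "TRANS":
                trans_rows[int(parts[1])] = [float(x) for x in parts[2:]]
        if name is None or length is None or bg is None:
            raise ValueError("malformed profile HMM text")
        emis = np.array([emis_rows[j + 1] for j in range(length)])
        trans = np.array([trans_rows[j + 1] for j in range(length)])
        # renormalise away the serialisation rounding
        emis /= emis.sum(axis=1, keepdims=True)
        bg = bg / bg.sum()
        trans[:, 0:3] /= trans[:, 0:3].sum(axis=1, keepdims=True)
        trans[:, 3:5] /= trans[:, 3:5].sum(axis=1, keepdims=True)
        trans[:, 5:7] /= trans[:, 5:7].sum(axis=1, keepdims=True)
        return cls(name=name, match_emis=emis, background=bg, trans=trans)

    @classmethod
    def read(cls, path) -> "ProfileHMM":
        return cls.from_text(Path(path).read_text())

    # -- scoring -------------------------------------------------------

    def _tables(self):
        """Cached log-space emission odds and transition tables."""
        cached = getattr(self, "_cache", None)
        if cached is not None:
            return cached
        with np.errstate(divide="ignore"):
            lo = np.log(self.match_emis / self.background)
            lt = np.log(self.trans)
        lo = np.where(np.isfinite(lo), lo, _NEG)
        lt = np.where(np.isfinite(lt), lt, _NEG)
        L = self.length
        tmm, tmi, tmd, tim, tii, tdm, tdd = (lt[:, c].copy() for c in range(7))
        # structural constraints: no I after last match, deletes interior
        tmi[L - 1] = _NEG
        tim[L - 1] = _NEG
        tii[L - 1] = _NEG
        if L >= 2:
            tmd[L - 2] = _NEG        # would create D_L
        tmd[L - 1] = _NEG
        tdd[L - 2:] = _NEG
        tdm[0] = _NEG                # D_1 does not exist
        tdd[0] = _NEG
        cache = (lo, tmm, tmi, tmd, tim, tii, tdm, tdd)
        self._cache = cache
        return cache

    def _dp(self, pep: str, mode: str) -> float:
        if not pep:
            raise ValueError("empty peptide")
        if "*" in pep:
            raise ValueError("peptide contains a stop '*'")
        lo, tmm, tmi, tmd, tim, tii, tdm, tdd = self._tables()
        L = self.length
        use_max = mode == "viterbi"
        # C[j] = sum of D->D log-probs tdd[1..j]; the delete chain
        # D[j] = max/sum over j' of (M[j'] + tmd[j'] - C[j']) + C[j-1]
        C = np.zeros(L)
        if L >= 2:
            C[1:] = np.cumsum(tdd[1:])
        M = np.full(L, _NEG)
        I = np.full(L, _NEG)
        D = np.full(L, _NEG)
        best = _NEG
        for ch in pep:
            x = _AA.get(ch)
            e = lo[:, x] if x is not None else np.zeros(L)
            Mn = np.full(L, _NEG)
            if use_max:
                core = np.maximum(np.maximum(M[:-1] + tmm[:-1],
                                             I[:-1] + tim[:-1]),
                                  D[:-1] + tdm[:-1])
            else:
                core = np.logaddexp(np.logaddexp(M[:-1] + tmm[:-1],
                                                 I[:-1] + tim[:-1]),
                                    D[:-1] + tdm[:-1])
            Mn[0] = e[0]                     # entry from B (free flank)
            Mn[1:] = e[1:] + np.maximum(core, _NEG)
            if use_max:
                In = np.maximum(M + tmi, I + tii)
            else:
                In = np.logaddexp(M + tmi, I + tii)
            # in-row delete chain via prefix scan
            Dn = np.full(L, _NEG)
            if L >= 2:
                A = Mn + tmd - C
                A = np.maximum(A, _NEG)
                if use_max:
                    P = np.maximum.accumulate(A)
                else:
                    P = np.logaddexp.accumulate(A)
                Dn[1:] = np.maximum(P[:-1] + C[:-1], _NEG)
            M, I, D = Mn, np.maximum(In, _NEG), Dn
            if use_max:
                best = max(best, float(M[L - 1]))
            else:
                best = float(np.logaddexp(best, M[L - 1]))
        return best / math.log(2.0)

    def viterbi_score(self, pep: str) -> float:
        return self._dp(pep, "viterbi")

    def forward_score(self, pep: str) -> float:
        return self._dp(pep, "forward")


def hmm_score(pep: str, hmm: ProfileHMM) -> tuple[float, float]:
    """(Viterbi, forward) log-odds scores in bits."""
    return hmm.viterbi_score(pep), hmm.forward_score(pep)


def write_hmms(hmms: list[ProfileHMM], directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for h in hmms:
        h.write(d / f"{h.name}.phmm")


def read_hmms(directory) -> list[ProfileHMM]:
    return [ProfileHMM.read(p) for p in sorted(Path(directory).glob("*.phmm"))]
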