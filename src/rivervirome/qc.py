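"""Read cleaning: window deduplication, quality-tail and adapter trimming.

Cleaning rules, applied per library in this order:

1. **Deduplication** — reads are duplicates when bases 5-55 (1-based,
   inclusive) are identical; one member of each duplicate group is kept,
   chosen uniformly at random under the seed.  Reads shorter than the
   window end use their full sequence from base 5 as the key, so short
   reads remain dedup-able.
2. **Quality-tail trimming** — the maximal 3' suffix in which *every*
   base is below Phred 10 is removed.
3. **Adapter trimming** — a VecScreen-style stand-in: if a suffix of the
   read matches a prefix of any adapter over >= 10 aligned bases with a
   mismatch fraction <= 0.1 (ungapped), the matching suffix is removed;
   the longest qualifying match wins.

Reads shorter than ``min_length`` after trimming are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._rng import spawn_rng
from .records import Read


@dataclass
class QcConfig:
    dedup_window: tuple[int, int] = (5, 55)  # 1-based inclusive
    phred_threshold: int = 10
    adapters: list[str] = field(default_factory=list)
    adapter_min_match: int = 10
    adapter_max_mismatch_frac: float = 0.1
    min_length: int = 50

    def __post_init__(self) -> None:
        start, end = self.dedup_window
        if start < 1 or start > end:
            raise ValueError("dedup window must satisfy 1 <= start <= end")
        if self.phred_threshold < 0:
            raise ValueError("phred threshold must be >= 0")


@dataclass
class QcReport:
    library: str
    n_raw: int = 0
    n_dup_removed: int = 0
    n_qtrimmed: int = 0
    n_adapter_trimmed: int = 0
    n_short_dropped: int = 0
    n_kept: int = 0
    mean_length: float = 0.0
    gc_percent: float = 0.0


def window_key(read: Read, cfg: QcConfig) -> str:
    start, end = cfg.dedup_window
    return read.seq[start - 1:end]


def deduplicate(reads: list[Read], cfg: QcConfig, seed: int
                ) -> tuple[list[Read], int]:
    """Keep one uniformly random member per duplicate group.

    Output order is input order restricted to kept reads; the kept-set
    as a set of groups is seed-independent (only the representative
    choice varies).
    """
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(reads):
        groups.setdefault(window_key(r, cfg), []).append(i)
    rng = spawn_rng(seed, "dedup")
    keep: set[int] = set()
    # iterate groups in first-occurrence order for determinism
    for key in groups:
        members = groups[key]
        keep.add(members[int(rng.integers(len(members)))])
    kept = [r for i, r in enumerate(reads) if i in keep]
    return kept, len(reads) - len(kept)


def trim_quality_tail(read: Read, cfg: QcConfig) -> Read:
    """Remove the maximal 3' suffix whose bases are all below threshold."""
    cut = len(read.qual)
    while cut > 0 and read.qual[cut - 1] < cfg.phred_threshold:
        cut -= 1
    if cut == len(read.qual):
        return read
    return Read(read.read_id, read.library, read.seq[:cut], read.qual[:cut])


def _suffix_match_len(seq: str, adapter: str, cfg: QcConfig) -> int:
    """Longest suffix-of-read vs prefix-of-adapter ungapped match length."""
    best = 0
    max_l = min(len(seq), len(adapter))
    for L in range(cfg.adapter_min_match, max_l + 1):
        tail = seq[len(seq) - L:]
        mism = sum(1 for a, b in zip(tail, adapter[:L]) if a != b)
        if mism <= cfg.adapter_max_mismatch_frac * L:
            best = L
    return best


def trim_adapters(read: Read, cfg: QcConfig) -> Read:
    """Remove the longest qualifying 3' adapter match across all adapters."""
    best = 0
    for adapter in cfg.adapters:
        best = max(best, _suffix_match_len(read.seq, adapter, cfg))
    if best == 0:
        return read
    cut = len(read.seq) - best
    return Read(read.read_id, read.library, read.seq[:cut], read.qual[:cut])


def qc_library(reads: list[Read], cfg: QcConfig, seed: int
               ) -> tuple[list[Read], QcReport]:
    """Dedup -> quality trim -> adapter trim -> length filter."""
    library = reads[0].library if reads else ""
    report = QcReport(library=library, n_raw=len(reads))
    if reads:
        total = sum(len(r) for r in reads)
        gc = sum(r.seq.count("G") + r.seq.count("C") for r in reads)
        report.mean_length = total / len(reads)
        report.gc_percent = 100.0 * gc / total if total else 0.0
    kept, n_dup = deduplicate(reads, cfg, seed)
    report.n_dup_removed = n_dup
    out: list[Read] = []
    for r in kept:
        t = trim_quality_tail(r, cfg)
        if len(t) < len(r):
            report.n_qtrimmed += 1
        a = trim_adapters(t, cfg)
        if len(a) < len(t):
            report.n_adapter_trimmed += 1
        if len(a) >= cfg.min_length:
            out.append(a)
        else:
            report.n_short_dropped += 1
    report.n_kept = len(out)
    return out, report
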