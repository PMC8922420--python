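"""Viral community profiles and ecology statistics.

Given per-query classifications, builds libraries x taxa read-count
profiles at family or species rank and derives the community analyses:
analytic (hypergeometric) rarefaction, Bray-Curtis dissimilarity,
principal coordinates analysis, UPGMA dendrograms, the Friedman
rank-sum test (mid-ranks with the standard tie correction), shared /
unique species bookkeeping and top-k species tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .homology import Classification
from .trees import DistanceMatrix, TreeNode, upgma as _upgma

UNCLASSIFIED = "unclassified"


@dataclass
class TaxProfile:
    """Libraries x taxa count matrix at one rank, with taxon metadata."""

    rank: str  # 'family' or 'species'
    counts: pd.DataFrame  # index: libraries, columns: taxa, integer counts
    taxon_meta: pd.DataFrame  # index: taxa; columns genome_type, host

    def __post_init__(self) -> None:
        if self.rank not in ("family", "species"):
            raise ValueError(f"invalid rank {self.rank!r}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def drop_reserved(self) -> "TaxProfile":
        keep = [t for t in self.taxa if t != UNCLASSIFIED]
        return TaxProfile(self.rank, self.counts[keep],
                          self.taxon_meta.loc[[t for t in keep
                                               if t in self.taxon_meta.index]])


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    tie_corrected: bool


def build_profiles(classifications: list[Classification], rank: str,
                   libraries: list[str] | None = None) -> TaxProfile:
    """Aggregate viral-classified queries into a count profile.

    Contigs contribute their mapped-read totals, singlets one read
    each.  HMM-rescued queries have no taxonomy below the profile's
    rank and are tallied under the reserved 'unclassified' taxon.
    """
    if rank not in ("family", "species"):
        raise ValueError(f"invalid rank {rank!r}")
    libs = list(libraries) if libraries else sorted(
        {c.library for c in classifications}
    )
    cells: dict[tuple[str, str], int] = {}
    meta: dict[str, tuple[str, str]] = {}
    for c in classifications:
        if c.verdict == "viral" and c.best_viral is not None:
            taxon = (c.best_viral.family if rank == "family"
                     else c.best_viral.species)
            meta[taxon] = (c.best_viral.genome_type, c.best_viral.host)
        elif c.verdict == "viral_by_hmm":
            taxon = UNCLASSIFIED
        else:
            continue
        cells[(c.library, taxon)] = cells.get((c.library, taxon), 0) + c.n_reads
    taxa = sorted({t for (_l, t) in cells} - {UNCLASSIFIED})
    if any(t == UNCLASSIFIED for (_l, t) in cells):
        taxa.append(UNCLASSIFIED)
    counts = pd.DataFrame(0, index=libs, columns=taxa, dtype=int)
    for (lib, taxon), n in cells.items():
        if lib in counts.index:
            counts.loc[lib, taxon] += n
    meta_df = pd.DataFrame(
        {t: {"genome_type": meta.get(t, ("", ""))[0],
             "host": meta.get(t, ("", ""))[1]} for t in taxa}
    ).T
    return TaxProfile(rank, counts, meta_df)


def family_counts_by_genome_type(profile: TaxProfile) -> dict[str, int]:
    """Distinct detected families per genome type (dsDNA/ssDNA/RNA)."""
    out = {"dsDNA": 0, "ssDNA": 0, "RNA": 0}
    detected = [t for t in profile.taxa
                if t != UNCLASSIFIED and profile.counts[t].sum() > 0]
    for t in detected:
        g = profile.taxon_meta.loc[t, "genome_type"]
        if g in out:
            out[g] += 1
    return out


def rarefaction_curve(counts: dict[str, int], depths: list[int]
                      ) -> list[tuple[int, float]]:
    """Analytic rarefaction E[S_n] = sum_i 1 - C(N-N_i, n)/C(N, n)."""
    ns = np.array([c for c in counts.values() if c > 0], dtype=float)
    N = ns.sum()
    out = []
    for n in depths:
        if n > N:
            raise ValueError(f"depth {n} exceeds total count {int(N)}")
        if n == 0:
            out.append((0, 0.0))
            continue
        # log C(N-Ni, n) - log C(N, n), with C(a, n)=0 when a < n
        with np.errstate(invalid="ignore"):
            a = N - ns
            ok = a >= n
            log_ratio = np.full(ns.shape, -np.inf)
            log_ratio[ok] = (
                gammaln(a[ok] + 1) - gammaln(n + 1) - gammaln(a[ok] - n + 1)
                - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
            )
        expected = float(np.sum(1.0 - np.exp(log_ratio)))
        out.append((int(n), expected))
    return out


def bray_curtis(profile: TaxProfile) -> DistanceMatrix:
    """d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); 0 for two empty rows."""
    libs = profile.libraries
    if len(libs) < 2:
        raise ValueError("need >= 2 libraries")
    X = profile.counts.values.astype(float)
    n = len(libs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = float(np.sum(X[i] + X[j]))
            num = float(np.sum(np.abs(X[i] - X[j])))
            d[i, j] = d[j, i] = (num / denom) if denom > 0 else 0.0
    return DistanceMatrix(labels=libs, d=d)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # labels x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Classical metric scaling (Gower centring of -D^2/2).

    Coordinates are returned for positive eigenvalues only, ordered by
    eigenvalue; negative eigenvalues are reported unchanged in
    ``eigenvalues``.  Variance explained is relative to the positive
    part of the spectrum.
    """
    D = np.asarray(dm.d, dtype=float)
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > 1e-12
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    pos_sum = evals[pos].sum()
    prop = np.divide(evals[pos], pos_sum) if pos_sum > 0 else evals[pos]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=dm.labels, columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
    )


def upgma_tree(dm: DistanceMatrix) -> TreeNode:
    return _upgma(dm)


def friedman_matrix(X: np.ndarray) -> TestResult:
    """Friedman rank-sum test on a blocks x treatments matrix.

    Mid-ranks within blocks; chi^2_F = [12/(b k (k+1))] sum R_j^2
    - 3 b (k+1), divided by the tie correction
    1 - sum(t^3 - t) / (b k (k^3 - k)); p from chi^2 with k-1 df.
    """
    X = np.asarray(X, dtype=float)
    b, k = X.shape
    if b < 2 or k < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    ranks = stats.rankdata(X, axis=1)
    Rj = ranks.sum(axis=0)
    chi2 = 12.0 / (b * k * (k + 1)) * float(np.sum(Rj ** 2)) - 3.0 * b * (k + 1)
    # tie correction over blocks
    tie_sum = 0.0
    any_tie = False
    for row in X:
        _vals, cnts = np.unique(row, return_counts=True)
        if np.any(cnts > 1):
            any_tie = True
        tie_sum += float(np.sum(cnts ** 3 - cnts))
    denom = 1.0 - tie_sum / (b * (k ** 3 - k))
    if denom <= 0:
        # all rows completely tied: no discrimination at all
        return TestResult(0.0, k - 1, 1.0, True)
    chi2 /= denom
    p = float(stats.chi2.sf(chi2, k - 1))
    return TestResult(float(chi2), k - 1, p, any_tie)


def friedman_test(profile: TaxProfile) -> TestResult:
    """Friedman test with taxa as blocks and libraries as treatments."""
    X = profile.counts.values.T.astype(float)  # blocks=taxa rows
    return friedman_matrix(X)


@dataclass
class SharedSpeciesReport:
    region_counts: dict[tuple[str, ...], int] = field(default_factory=dict)
    core_species: list[str] = field(default_factory=list)
    union_size: int = 0
    per_library_fraction: dict[str, float] = field(default_factory=dict)
    per_library_richness: dict[str, int] = field(default_factory=dict)


def shared_species(profile: TaxProfile) -> SharedSpeciesReport:
    """Exact Venn region counts of the presence/absence set system."""
    libs = profile.libraries
    if len(libs) < 2:
        raise ValueError("need >= 2 libraries")
    present: dict[str, set[str]] = {}
    taxa = [t for t in profile.taxa if t != UNCLASSIFIED]
    for lib in libs:
        present[lib] = {t for t in taxa if profile.counts.loc[lib, t] > 0}
    union: set[str] = set().union(*present.values()) if present else set()
    core = set(taxa)
    for lib in libs:
        core &= present[lib]
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(libs) + 1):
        for combo in combinations(libs, r):
            inside = set(taxa)
            for lib in combo:
                inside &= present[lib]
            for lib in libs:
                if lib not in combo:
                    inside -= present[lib]
            if inside:
                regions[tuple(combo)] = len(inside)
    report = SharedSpeciesReport(
        region_counts=regions,
        core_species=sorted(core),
        union_size=len(union),
    )
    for lib in libs:
        n = len(present[lib])
        report.per_library_richness[lib] = n
        report.per_library_fraction[lib] = (len(core) / n) if n else 0.0
    return report


def top_species(profile: TaxProfile, k: int = 10) -> dict[str, pd.DataFrame]:
    """Per-library top-k species with relative abundance and shared flags.

    Relative abundance is the species count over the library's total
    viral-assigned reads (including the reserved unclassified tally).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if profile.rank != "species":
        raise ValueError("top_species requires a species-rank profile")
    libs = profile.libraries
    taxa = [t for t in profile.taxa if t != UNCLASSIFIED]
    shared = {
        t for t in taxa if all(profile.counts.loc[lib, t] > 0 for lib in libs)
    }
    out: dict[str, pd.DataFrame] = {}
    for lib in libs:
        total = int(profile.counts.loc[lib].sum())
        rows = []
        ranked = sorted(taxa, key=lambda t: (-profile.counts.loc[lib, t], t))
        for t in ranked[:k]:
            c = int(profile.counts.loc[lib, t])
            if c == 0:
                continue
            rows.append({
                "species": t,
                "count": c,
                "relative_abundance": c / total if total else 0.0,
                "shared_in_all": t in shared,
            })
        out[lib] = pd.DataFrame(rows)
    return out
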