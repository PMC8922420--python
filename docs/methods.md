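# Methods

This note documents the models, parameter choices and numerical
decisions behind the package, and what the synthetic benchmark does and
does not demonstrate.

## The synthetic study design

The generator emulates a six-site river-water virome survey with a
negative control.  The defaults are the package's study conditions:

| parameter | default | why |
|---|---|---|
| sample libraries | 6 × 10,000 reads | six sampling sites at a desk-scale read depth (~60k reads total) |
| control library | 105 reads | ≈1.05% of the mean sample library, the scale at which a clean extraction control sits |
| read length | 250 nt single-end | MiSeq-class chemistry; pairing is metadata only, no pipeline stage uses it |
| duplicate rate | 0.2 | a typical PCR/optical duplicate burden; exercises the window dedup |
| quality decay | linear Q38 → Q8 | puts only the last ~15–20 bases under the Phred-10 trim threshold, giving ≈233 nt post-trim reads |
| adapter read-through | 5% of reads, TruSeq adapter | enough 3′ adapter to exercise trimming without dominating |
| non-viral fraction | 0.35 | viromes are enriched but never pure; the background drives the competitive filter |
| mock community | 17 families: 9 dsDNA, 4 ssDNA, 4 RNA | the family structure of the survey being emulated, one species per family by default |
| NVNR database | 50 proteins, 20% decoys | decoys share exact 14-mer windows with viral proteins (~50% identity mosaics), so false-positive removal has real work to do |

Viral genomes are 4 kb uniform-random sequences with implanted ORFs —
one hallmark gene (TerL, MCP, NS1, Rep or RdRp, as appropriate for the
family) plus six accessory genes — separated by 30 nt spacers, so the
genomes are gene-dense (~90% coding) the way real viral genomes are.
Gene-dense genomes matter: they guarantee that essentially every
≥500 nt contig overlaps coding sequence and is therefore classifiable,
and they keep the per-family classification loss rate uniform across
families.  Hallmark proteins within a group descend from a common
ancestor peptide by 25% point substitution, which gives the homology
search, the profile HMMs and the phylogenies realistic (divergent but
unambiguous) signal.  All randomness flows from one seed through
per-operation tagged streams, so every output is reproducible
byte-for-byte.

Per-site abundances start from a fixed family-weight table dominated by
tailed phages (Siphoviridae 35%, Podoviridae 13%, Myoviridae 9%, …)
with per-site log-normal jitter (σ = 0.35); the Nanjing site's
*Parvoviridae* weight is multiplied by 10 to give one site a
distinctive invertebrate-virus signature.

**What the generator does not model:** sequencing errors (substitutions
or indels) beyond quality decay, paired-end structure, chimeric reads,
strain-level variation, uneven genome sizes, or real database
redundancy.  Passing the synthetic benchmark therefore shows that the
pipeline's logic is correct under an idealised error model, not that it
would match a production toolchain's sensitivity on real reads.

## Cleaning rules

Deduplication keys on bases 5–55, 1-based inclusive (a 51 nt key);
reads shorter than 55 nt use their full sequence from base 5, which
keeps short reads dedup-able.  One member per key group is kept,
chosen uniformly at random under the seed; output order is input
order.  Quality trimming removes the maximal 3′ suffix in which every
base is below Phred 10 — the simplest faithful reading of a
threshold-only rule, not the BWA running-sum algorithm.  Adapter
trimming is ungapped read-suffix vs adapter-prefix matching (≥10
aligned bases, ≤10% mismatches, longest match wins); true VecScreen is
a BLASTn parameterisation and deliberately out of scope.  Stages run
dedup → quality → adapter; reads under 50 nt afterwards are dropped.

## Assembly

Greedy overlap-layout-consensus: all suffix–prefix overlaps ≥30 nt at
≥98% identity (both orientations) are candidates; the longest is merged
first, ties broken by the lexicographically smallest id pair; the
consensus takes the majority base with a quality-sum tie-break and the
canonical orientation of the first-merged sequence.  Candidate
discovery uses a strided 16-mer index (stride 8), which detects every
exact overlap of ≥23 nt; overlaps with mismatches are found when the
leading 23 bases of the overlap are exact — on the generator's
error-free reads the two are equivalent, and the test suite checks
equivalence against an exhaustive brute-force agglomerator.  "Chimera
filtering by length" is implemented as a minimum contig length of
250 nt; sub-threshold contigs dissolve back into their member reads.
Read-back mapping calls a raw read mapped when either strand has an
ungapped alignment of ≥50 bases at ≥95% identity to some contig.

## Translated search and classification

Six reading frames; exact 4-mer amino-acid seeds; one ungapped X-drop
(X = 20) extension per diagonal; extensions reaching 40 raw score are
re-aligned by banded Smith–Waterman (band ±16 around the seed
diagonal) under BLOSUM62 with BLAST-style affine gaps (a gap of length
L costs 11 + L).  The best local score per (query, subject) yields
E = K·m·n·e^(−λS) with m the scoring frame's peptide length, n the
total database residues, and the NCBI gapped constants λ = 0.267,
K = 0.041 fixed rather than calibrated per search — determinism over
marginal accuracy.  The 40-score gapped trigger sits far below the
~60–85 raw score any reportable hit needs at these database sizes, so
it prunes only noise.

The competitive filter is conservative by construction: a tie in bit
score between the best viral and best NVNR hit is non-viral.  The NVNR
comparison runs only for queries that have a significant viral hit;
queries without one go to the profile-HMM stage, and HMM-positive
queries are not NVNR-screened.  Consequently background contigs
without any viral similarity end as *unclassified*, not *non_viral* —
specificity is therefore measured on decoy contigs, which do draw
viral hits by construction.

## Profile HMMs

Plan7-style with match, insert and interior delete states; entry at
M1, exit at ML, free (zero log-odds) flanks — global in the model,
local in the sequence.  Insert emissions equal the uniform background,
so inserts cost only their transitions.  Viterbi and forward are
vectorised over model positions; the in-row delete chain is a prefix
scan (`maximum.accumulate` / `logaddexp.accumulate`), with
structurally forbidden transitions carrying a large finite penalty
(−10⁶ nats) so the scans stay NaN-free.  Profiles are trained from the
hallmark members (≥50%-gap columns become inserts, pseudocount 0.5)
and serialised to a plain-text format.  Classification scores every
stop-free translated segment of ≥30 aa — random frames are chopped by
stops every ~20 residues, so this filter removes most of the cost
while never touching a real protein-coding frame — and rescues queries
at ≥25 Viterbi bits, a cutoff sitting far above the near-zero scores
of unrelated segments and far below the 100+ bits of true members.

## Community statistics

Rarefaction is the analytic hypergeometric form computed with
log-gamma functions.  PCoA is classical scaling (Gower centring of
−D²/2); negative eigenvalues are reported, not corrected, and variance
explained is normalised over the positive spectrum.  UPGMA uses
size-weighted average linkage with half-merge-distance heights and
lexicographic tie-breaks.  The Friedman test treats taxa as blocks and
libraries as treatments, uses within-block mid-ranks and the standard
tie-correction divisor 1 − Σ(t³−t)/(b(k³−k)), and takes p from the
χ²(k−1) tail; the suite verifies it against an independent
implementation and calibrates its type-I error (α = 0.05 within
[0.035, 0.065]) under a within-row permutation null at b = 30, k = 6 —
a block count at which the χ² approximation is adequate.

Relative abundances divide by viral-assigned reads, not raw reads;
contigs contribute their mapped-read totals and singlets one read
each; HMM-rescued queries land in a reserved "unclassified" taxon.

The abundance-fidelity check compares pooled per-family classified
fractions against the pooled design weights.  The z denominator uses
an effective sample size deflated by the duplicate rate, because
mapped-read counting re-counts PCR duplicates and the plain
multinomial standard error would be too small for the estimator
actually measured.  Pooling over libraries is the level at which
"per-family abundance" is defined here; per-library, per-taxon
fidelity of the generator itself is tested separately on non-duplicate
emitted reads, where the exact multinomial SE applies.

## Annotation and phylogeny

ORFs: both strands, all frames, ATG starts, standard code, minimum
300 nt including the stop codon (nucleotide units — the convention
under which a ~100-residue gene passes); nested ORFs sharing a stop
report the longest; ORFs truncated by a contig edge (missing stop, or
a 5′ frame segment with no upstream stop and no ATG requirement)
are reported with `complete=False`, and only complete ORFs enter
phylogenies.  Contigs whose best hits cover disjoint intervals of the
same database subject are joined with a 100-N spacer (the run length
is arbitrary but recorded, and N runs are ignorable downstream);
contig ends are extended by overhanging reads (≥20 nt junction at
≥95% identity, exact-anchor candidate discovery, tolerant
verification).  The progressive aligner uses 3-mer-distance UPGMA
guide trees and profile–profile Needleman-Wunsch (BLOSUM62, gap 8/1);
columns with strictly more than 50% gaps are masked before tree
building.  Trees are Saitou–Nei neighbor joining on p-distances with
negative branch lengths clamped to zero; database reference proteins
of the same hallmark gene join the study ORFs in each tree, so even
sparsely sampled genes reach the three-leaf minimum.  Bayesian and
maximum-likelihood tree building are out of scope; NJ is the
distance-based stand-in, and the corresponding MCMC settings (10⁶
generations, 25% burn-in) are recorded here but unused.

## Problem sizes and determinism

The default run — ~60,105 reads, 119 viral + 50 NVNR proteins, five
HMMs — completes in under three minutes on one CPU; the test suite,
which includes one full run plus two small end-to-end runs, in about
three and a half.  Re-running any configuration with the same seed
reproduces all non-figure outputs byte-for-byte: random streams are
spawned per (seed, operation, library) tag, dictionary orders are
deterministic, and all ties break lexicographically.

## Known limitations

* The seed-and-extend search can in principle miss a gapped local
  alignment whose every ungapped segment scores below the trigger;
  irrelevant at these database sizes, but a difference from
  full Smith-Waterman on adversarial inputs.
* The competitive filter never labels a query *non_viral* unless it
  first hit the viral database; a pure-background census therefore
  undercounts non-viral calls (they stay unclassified).
* Banded traceback reports gap runs step-wise, so percent identity on
  heavily gapped alignments is approximate; scores are exact.
* UPGMA's O(n³) loop and the Venn bitmask enumeration assume a handful
  of libraries (≤8), which is the design point of the study shape.
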