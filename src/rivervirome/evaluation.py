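"""Ground-truth evaluation of a synthetic pipeline run.

Because every simulated read header encodes its source genome, a
completed :class:`~rivervirome.pipeline.RunReport` can be scored
against the simulation's own ground truth: classification sensitivity
on viral contigs, specificity on decoy contigs, fidelity of the
recovered family abundances, hallmark-gene recovery and control-library
cleanliness.  These metrics quantify what the pipeline recovers under
the idealised error model of the generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import RunReport, library_abundance
from .records import reverse_complement
from .synthetic import HALLMARK_GROUPS, parse_read_header


def _contig_sources(report: RunReport):
    """Map each contig to the set of source genomes of its member reads."""
    out = {}
    for lab, res in report.libraries.items():
        for c in res.contigs:
            out[c.contig_id] = {parse_read_header(m)["source"]
                                for m in c.member_read_ids}
    return out


@dataclass
class RecoveryMetrics:
    viral_contigs_total: int
    viral_contigs_correct: int
    decoy_contigs_total: int
    decoy_contigs_correct: int
    hallmarks_total: int
    hallmarks_recovered: int
    family_z: dict[str, float]
    control_viral_reads: int

    @property
    def viral_sensitivity_pct(self) -> float:
        return (100.0 * self.viral_contigs_correct / self.viral_contigs_total
                if self.viral_contigs_total else 0.0)

    @property
    def decoy_specificity_pct(self) -> float:
        return (100.0 * self.decoy_contigs_correct / self.decoy_contigs_total
                if self.decoy_contigs_total else 0.0)

    @property
    def hallmark_recovery_pct(self) -> float:
        return (100.0 * self.hallmarks_recovered / self.hallmarks_total
                if self.hallmarks_total else 0.0)

    @property
    def max_abs_family_z(self) -> float:
        return max((abs(z) for z in self.family_z.values()), default=0.0)


def evaluate_run(report: RunReport, min_contig_len: int = 500
                 ) -> RecoveryMetrics:
    species = {t.species_name for t in report.taxa}
    decoy_genomes = {b.name for b in report.background if b.is_decoy_genome}
    sources = _contig_sources(report)
    verdict = {}
    for res in report.libraries.values():
        for c in res.classifications:
            verdict[c.query_id] = c.verdict
    # -- contig-level sensitivity / specificity
    v_tot = v_ok = d_tot = d_ok = 0
    sample_labels = [s.label for s in report.config.libraries
                     if not s.is_control]
    for lab in sample_labels:
        for c in report.libraries[lab].contigs:
            src = sources[c.contig_id]
            v = verdict.get(c.contig_id, "unclassified")
            if src <= species and len(c.seq) >= min_contig_len:
                v_tot += 1
                v_ok += v in ("viral", "viral_by_hmm")
            if src and src <= decoy_genomes:
                d_tot += 1
                d_ok += v == "non_viral"
    # -- pooled per-family abundance vs design
    family_z = _family_abundance_z(report, sample_labels)
    # -- hallmark recovery
    h_tot, h_ok = _hallmark_recovery(report, sample_labels)
    # -- control
    ctl_viral = 0
    for spec in report.config.libraries:
        if spec.is_control:
            ctl_viral = sum(
                c.n_reads for c in report.libraries[spec.label].classifications
                if c.verdict in ("viral", "viral_by_hmm")
            )
    return RecoveryMetrics(
        viral_contigs_total=v_tot, viral_contigs_correct=v_ok,
        decoy_contigs_total=d_tot, decoy_contigs_correct=d_ok,
        hallmarks_total=h_tot, hallmarks_recovered=h_ok,
        family_z=family_z, control_viral_reads=ctl_viral,
    )


def _family_abundance_z(report: RunReport, sample_labels: list[str]
                        ) -> dict[str, float]:
    """Pooled per-family z-scores of classified vs designed abundance.

    The classified counts weight contigs by mapped raw reads, which
    re-counts PCR duplicates; the effective number of independent
    source draws is therefore the classified total deflated by the
    duplicate rate, and the z denominator uses that effective N.
    """
    if report.family_profile is None:
        return {}
    fam_of = {t.species_name: t.family for t in report.taxa}
    counts = report.family_profile.drop_reserved().counts
    pooled = counts.sum(axis=0)
    N = float(pooled.sum())
    if N == 0:
        return {}
    n_eff = N * (1.0 - report.config.duplicate_rate)
    # pooled design: average of per-library family weights, weighted by
    # each library's classified total
    lib_totals = counts.sum(axis=1)
    design: dict[str, float] = {}
    for lab in sample_labels:
        w = library_abundance(report.config, lab, report.taxa)
        share = float(lib_totals.get(lab, 0)) / N
        for sp, v in w.items():
            design[fam_of[sp]] = design.get(fam_of[sp], 0.0) + v * share
    out = {}
    for fam, p in design.items():
        obs = float(pooled.get(fam, 0)) / N
        se = np.sqrt(p * (1 - p) / n_eff)
        out[fam] = (obs - p) / se if se > 0 else 0.0
    return out


def _hallmark_recovery(report: RunReport, sample_labels: list[str]
                       ) -> tuple[int, int]:
    """Implanted complete hallmark genes inside assembled viral contigs.

    A (library, taxon) hallmark counts toward the denominator when some
    contig of that library lies fully inside the taxon's genome and
    spans the hallmark ORF; it is recovered when the pooled hallmark
    sets contain its exact peptide under the correct gene label.
    """
    recovered_peps: dict[str, set[str]] = {}
    for hs in report.hallmark_sets:
        recovered_peps.setdefault(hs.gene, set()).update(
            pep.rstrip("*") for _oid, pep, _c in hs.members
        )
    tot = ok = 0
    genomes = {t.species_name: t for t in report.taxa}
    for lab in sample_labels:
        res = report.libraries[lab]
        # genome intervals covered by this library's contigs, per taxon
        for t in report.taxa:
            hall = [(g, s, e) for (g, s, e, _st) in t.orf_coords
                    if g in HALLMARK_GROUPS]
            if not hall:
                continue
            gene, hs_start, hs_end = hall[0]
            covered = False
            g = genomes[t.species_name].genome_seq
            for c in res.contigs:
                pos = g.find(c.seq)
                if pos < 0:
                    pos_rc = g.find(reverse_complement(c.seq))
                    if pos_rc < 0:
                        continue
                    lo, hi = pos_rc, pos_rc + len(c.seq)
                else:
                    lo, hi = pos, pos + len(c.seq)
                if lo <= hs_start and hi >= hs_end:
                    covered = True
                    break
            if not covered:
                continue
            tot += 1
            pep = dict((gname, p) for gname, p in t.proteins)[gene]
            # ORF prediction may extend the N-terminus to an upstream
            # in-frame ATG, so accept any peptide containing the implant
            if any(pep in p for p in recovered_peps.get(gene, ())):
                ok += 1
    return tot, ok


def friedman_null_calibration(b: int = 30, k: int = 6, reps: int = 2000,
                              alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I error of the Friedman test under a permutation null.

    Draws one blocks x treatments log-normal abundance matrix, then
    permutes each row independently ``reps`` times; returns the
    fraction of permutations with p < alpha.
    """
    from ._rng import spawn_rng
    from .community import friedman_matrix

    rng = spawn_rng(seed, "friedman-null")
    X = np.exp(rng.normal(0.0, 1.0, size=(b, k)))
    hits = 0
    for _ in range(reps):
        Y = np.array([rng.permutation(row) for row in X])
        if friedman_matrix(Y).p_value < alpha:
            hits += 1
    return hits / reps
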