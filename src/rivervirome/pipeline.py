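"""End-to-end orchestration: simulate -> QC -> assemble -> classify ->
community ecology -> annotation/phylogeny, with per-library summaries.

One ``RunConfig`` drives the whole run.  By default the run simulates
its own inputs: a 17-family mock community, a viral protein database,
an NVNR database with decoys, hallmark profile HMMs, six sample
libraries named after the six river sampling sites and a near-empty
negative control.  All randomness flows from the single config seed,
and re-running the same config reproduces every non-plot output
byte-for-byte.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import community as comm
from ._rng import spawn_rng
from .assembly import AssemblyConfig, MappingReport, assemble, map_reads_back
from .homology import (
    Classification,
    ProteinDatabase,
    classify_all,
)
from .msa import align_and_mask, nj_tree
from .phmm import read_hmms, write_hmms
from .qc import QcConfig, QcReport, qc_library
from .records import (
    Contig,
    Read,
    read_fastq,
    read_protein_fasta,
    write_fastq,
    write_protein_fasta,
)
from .scoring import ScoringScheme
from .synthetic import (
    CommunityDesign,
    build_background_genomes,
    build_hallmark_hmms,
    build_mock_community,
    reference_sets_from_taxa,
    simulate_library,
)

SAMPLE_SITES = ["Anqing", "Wuhu", "Nanjing", "Zhenjiang", "Changzhou", "Nantong"]

#: baseline per-family abundance weights for the mock river community,
#: dominated by tailed phages as in freshwater viromes
BASE_FAMILY_WEIGHTS = {
    "Siphoviridae": 0.35, "Podoviridae": 0.13, "Myoviridae": 0.09,
    "Herelleviridae": 0.05, "Ackermannviridae": 0.04,
    "Autographiviridae": 0.05, "Phycodnaviridae": 0.012,
    "Mimiviridae": 0.006, "Lavidaviridae": 0.004,
    "Microviridae": 0.04, "Parvoviridae": 0.012, "Circoviridae": 0.006,
    "Genomoviridae": 0.004, "Astroviridae": 0.005, "Hepeviridae": 0.003,
    "Dicistroviridae": 0.008, "Virgaviridae": 0.015,
}


@dataclass
class LibrarySpec:
    label: str
    n_reads: int = 10_000
    nucleic_acid: str = "DNA"  # metadata only (DNA vs RNA workup)
    is_control: bool = False
    fastq: str | None = None  # pre-existing reads; simulated when None


@dataclass
class RunConfig:
    outdir: str
    seed: int = 1
    libraries: list[LibrarySpec] = field(default_factory=list)
    n_viral_taxa: int = 17
    n_nvnr_proteins: int = 50
    decoy_fraction: float = 0.2
    non_viral_fraction: float = 0.35
    duplicate_rate: float = 0.2
    adapter_fraction: float = 0.05
    adapter_seq: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
    quality_start: int = 38
    quality_end: int = 8
    read_length: int = 250
    e_cutoff: float = 1e-5
    hmm_bitscore_cutoff: float = 25.0
    min_orf_size: int = 300
    qc: QcConfig = field(default_factory=QcConfig)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    viral_db: str | None = None
    nvnr_db: str | None = None
    hmm_dir: str | None = None

    def __post_init__(self) -> None:
        labels = [l.label for l in self.libraries]
        if len(set(labels)) != len(labels):
            raise ValueError("library labels must be unique")
        if sum(1 for l in self.libraries if l.is_control) > 1:
            raise ValueError("at most one control library")
        if not self.qc.adapters and self.adapter_seq:
            self.qc.adapters = [self.adapter_seq]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        libs = [LibrarySpec(**l) for l in raw.pop("libraries", [])]
        qc_cfg = QcConfig(**raw.pop("qc", {}))
        if "dedup_window" in raw:
            qc_cfg.dedup_window = tuple(raw.pop("dedup_window"))
        asm_cfg = AssemblyConfig(**raw.pop("assembly", {}))
        return cls(libraries=libs, qc=qc_cfg, assembly=asm_cfg, **raw)


def default_config(outdir, seed: int = 1) -> RunConfig:
    """The standard six-site + control synthetic run (~60k reads)."""
    libs = [LibrarySpec(label=s, n_reads=10_000,
                        nucleic_acid="RNA" if s == "Nantong" else "DNA")
            for s in SAMPLE_SITES]
    libs.append(LibrarySpec(label="Control", n_reads=105, is_control=True))
    return RunConfig(outdir=str(outdir), seed=seed, libraries=libs)


def library_abundance(config: RunConfig, label: str,
                      taxa) -> dict[str, float]:
    """Per-species weights: baseline family weights with per-site jitter.

    Nanjing is given an elevated *Parvoviridae* load, mirroring the
    distinctive invertebrate-virus signature of that site.
    """
    rng = spawn_rng(config.seed, "abundance", label)
    weights: dict[str, float] = {}
    fam_counts: dict[str, int] = {}
    for t in taxa:
        fam_counts[t.family] = fam_counts.get(t.family, 0) + 1
    for t in taxa:
        base = BASE_FAMILY_WEIGHTS.get(t.family, 0.01) / fam_counts[t.family]
        if label == "Nanjing" and t.family == "Parvoviridae":
            base *= 10.0
        jitter = float(np.exp(rng.normal(0.0, 0.35)))
        weights[t.species_name] = base * jitter
    total = sum(weights.values())
    return {k: v / total for k, v in sorted(weights.items())}


@dataclass
class LibrarySummary:
    label: str
    is_control: bool
    n_raw: int
    mean_read_length: float
    gc_percent: float
    n_viral_contigs: int
    pct_reads_mapped_to_viral_contigs: float
    n_viral_reads: int
    n_families: int
    n_species: int


@dataclass
class LibraryResult:
    spec: LibrarySpec
    design: CommunityDesign | None
    raw_reads: list[Read]
    clean_reads: list[Read]
    qc_report: QcReport
    contigs: list[Contig]
    singlets: list[Read]
    mapping: MappingReport
    classifications: list[Classification]


@dataclass
class RunReport:
    config: RunConfig
    taxa: list
    truth: pd.DataFrame
    viral_records: list
    nvnr_records: list
    background: list
    hmms: list
    libraries: dict[str, LibraryResult]
    family_profile: comm.TaxProfile | None
    species_profile: comm.TaxProfile | None
    bray_curtis: object
    pcoa: object
    upgma_newick: str
    friedman: comm.TestResult | None
    rarefaction: dict[str, list[tuple[int, float]]]
    shared: comm.SharedSpeciesReport | None
    top10: dict[str, pd.DataFrame]
    hallmark_sets: list[ann.HallmarkSet]
    trees: dict[str, str]
    summaries: list[LibrarySummary]
    family_triple: dict[str, int]
    control_ratio: float | None
    control_viral_reads: int | None


def _gc_percent(reads: list[Read]) -> float:
    total = sum(len(r) for r in reads)
    if not total:
        return 0.0
    gc = sum(r.seq.count("G") + r.seq.count("C") for r in reads)
    return 100.0 * gc / total


def control_contamination_check(control_n_raw: int,
                                sample_n_raws: list[int],
                                control_viral_reads: int
                                ) -> tuple[float, int]:
    """Control read ratio (percent, 2 dp) and viral read count in control.

    Warns when the control contains any viral-classified read.
    """
    if not sample_n_raws:
        raise ValueError("need at least one sample library")
    mean_raw = sum(sample_n_raws) / len(sample_n_raws)
    ratio = round(100.0 * control_n_raw / mean_raw, 2) if mean_raw else 0.0
    if control_viral_reads > 0:
        warnings.warn(
            f"control library contains {control_viral_reads} viral reads",
            stacklevel=2,
        )
    return ratio, control_viral_reads


def run_pipeline(config: RunConfig, progress: bool = False) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = ScoringScheme()

    def log(msg: str) -> None:
        if progress:
            print(f"[rivervirome] {msg}", flush=True)

    # ---------------- reference data ----------------
    taxa = build_mock_community(config.n_viral_taxa, config.seed)
    if config.viral_db and config.nvnr_db:
        viral_records = read_protein_fasta(config.viral_db)
        nvnr_records = read_protein_fasta(config.nvnr_db)
        truth = pd.DataFrame()
    else:
        viral_records, nvnr_records, truth = reference_sets_from_taxa(
            taxa, config.n_nvnr_proteins, config.seed,
            decoy_fraction=config.decoy_fraction,
        )
    background = build_background_genomes(nvnr_records, truth, config.seed) \
        if not truth.empty else []
    if config.hmm_dir:
        hmms = read_hmms(config.hmm_dir)
    else:
        hmms = build_hallmark_hmms(taxa, config.seed)
    db_dir = outdir / "db"
    db_dir.mkdir(exist_ok=True)
    write_protein_fasta(viral_records, db_dir / "viral_db.faa")
    write_protein_fasta(nvnr_records, db_dir / "nvnr_db.faa")
    if not truth.empty:
        truth.to_csv(db_dir / "truth.tsv", sep="\t", index=False)
    write_hmms(hmms, db_dir / "hmms")
    viral_db = ProteinDatabase(viral_records)
    nvnr_db = ProteinDatabase(nvnr_records)
    log(f"references: {len(viral_records)} viral proteins, "
        f"{len(nvnr_records)} NVNR, {len(hmms)} HMMs")

    # ---------------- per-library stages ----------------
    lib_results: dict[str, LibraryResult] = {}
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    contig_dir = outdir / "contigs"
    contig_dir.mkdir(exist_ok=True)
    for spec in config.libraries:
        label = spec.label
        if spec.fastq:
            raw = read_fastq(spec.fastq, label)
            design = None
        else:
            abund = ({} if spec.is_control
                     else library_abundance(config, label, taxa))
            design = CommunityDesign(
                library_label=label,
                abundance=abund,
                non_viral_fraction=(1.0 if spec.is_control
                                    else config.non_viral_fraction),
                n_reads=spec.n_reads,
                duplicate_rate=config.duplicate_rate,
                adapter_seq=config.adapter_seq,
                adapter_fraction=config.adapter_fraction,
                quality_start=config.quality_start,
                quality_end=config.quality_end,
                read_length=config.read_length,
                seed=config.seed,
            )
            raw = simulate_library(design, taxa, background)
            write_fastq(raw, reads_dir / f"{label}.fastq")
        clean, qc_rep = qc_library(raw, config.qc, config.seed)
        log(f"{label}: {len(raw)} raw -> {len(clean)} clean")
        contigs, singlets = assemble(clean, config.assembly, library=label)
        mapping = map_reads_back(raw, contigs, config.assembly)
        log(f"{label}: {len(contigs)} contigs, {len(singlets)} singlets, "
            f"{mapping.pct_mapped:.1f}% reads mapped")
        cls = classify_all(contigs, singlets, viral_db, nvnr_db, hmms,
                           scheme, config.hmm_bitscore_cutoff, config.e_cutoff)
        n_viral = sum(1 for c in cls
                      if c.verdict in ("viral", "viral_by_hmm"))
        log(f"{label}: {n_viral} viral-classified queries")
        lib_results[label] = LibraryResult(
            spec=spec, design=design, raw_reads=raw, clean_reads=clean,
            qc_report=qc_rep, contigs=contigs, singlets=singlets,
            mapping=mapping, classifications=cls,
        )
        if contigs:
            from .records import write_nucleotide_fasta
            write_nucleotide_fasta([(c.contig_id, c.seq) for c in contigs],
                                   contig_dir / f"{label}.fasta")

    # ---------------- community ecology (samples only) ----------------
    sample_labels = [s.label for s in config.libraries if not s.is_control]
    sample_cls = [c for lab in sample_labels
                  for c in lib_results[lab].classifications]
    family_profile = species_profile = None
    bray = pcoa_res = None
    upgma_nwk = ""
    friedman_res = None
    rarefaction: dict[str, list[tuple[int, float]]] = {}
    shared_rep = None
    top10: dict[str, pd.DataFrame] = {}
    if sample_cls and len(sample_labels) >= 2:
        family_profile = comm.build_profiles(sample_cls, "family",
                                             sample_labels)
        species_profile = comm.build_profiles(sample_cls, "species",
                                              sample_labels)
        counted = family_profile.drop_reserved()
        if counted.taxa:
            bray = comm.bray_curtis(counted)
            pcoa_res = comm.pcoa(bray)
            upgma_nwk = comm.upgma_tree(bray).to_newick()
            friedman_res = comm.friedman_test(counted)
        sp = species_profile.drop_reserved()
        for lab in sample_labels:
            counts = {t: int(sp.counts.loc[lab, t]) for t in sp.taxa
                      if sp.counts.loc[lab, t] > 0}
            total = sum(counts.values())
            depths = sorted({min(int(x), total)
                             for x in np.linspace(0, total, 21)})
            rarefaction[lab] = comm.rarefaction_curve(counts, depths)
        if sp.taxa:
            shared_rep = comm.shared_species(sp)
            top10 = comm.top_species(species_profile, k=10)
    log("community statistics done")

    # ---------------- annotation & phylogeny ----------------
    hallmark_sets: list[ann.HallmarkSet] = []
    all_orfs: list[ann.OrfRecord] = []
    trees_out: dict[str, str] = {}
    pooled_members: dict[str, ann.HallmarkSet] = {}
    for lab in sample_labels:
        res = lib_results[lab]
        viral_ids = {c.query_id for c in res.classifications
                     if c.is_contig and c.verdict in ("viral", "viral_by_hmm")}
        viral_contigs = [c for c in res.contigs if c.contig_id in viral_ids]
        best_hits = {c.query_id: c.best_viral for c in res.classifications
                     if c.is_contig and c.best_viral is not None}
        merged = ann.merge_nonoverlapping_contigs(viral_contigs, best_hits)
        extended = [ann.extend_by_mapping(c, res.singlets, rounds=2)
                    for c in merged]
        for c in extended:
            if len(c.seq) < config.min_orf_size:
                continue
            orfs = ann.predict_orfs(c, config.min_orf_size)
            orfs = ann.annotate_orfs(orfs, viral_db, scheme, config.e_cutoff)
            all_orfs.extend(orfs)
    for hs in ann.extract_hallmarks(all_orfs):
        pooled_members.setdefault(
            hs.gene, ann.HallmarkSet(hs.gene, hs.group)
        ).members.extend(hs.members)
    hallmark_sets = [pooled_members[g] for g in sorted(pooled_members)]
    tree_dir = outdir / "trees"
    tree_dir.mkdir(exist_ok=True)
    for hs in hallmark_sets:
        complete = [(oid, pep.rstrip("*")) for oid, pep, comp in hs.members
                    if comp]
        seen_labels: set[str] = set()
        items = []
        for oid, pep in complete:
            lab = oid.replace("|", "_").replace("(", "_").replace(")", "")
            lab = lab.replace(":", "_").replace(",", "_").replace(";", "_")
            if lab in seen_labels:
                continue
            seen_labels.add(lab)
            items.append((lab, pep))
        # reference proteins of the same hallmark gene join the tree,
        # mirroring the use of database reference strains
        for rec in viral_records:
            if rec.gene == hs.gene:
                lab = f"ref_{rec.rec_id}"
                if lab not in seen_labels:
                    seen_labels.add(lab)
                    items.append((lab, rec.seq))
        if len(items) >= 3:
            msa = align_and_mask(items)
            nwk = nj_tree(msa).to_newick()
            trees_out[hs.gene] = nwk
            (tree_dir / f"{hs.gene}_nj.nwk").write_text(nwk + "\n")
    log(f"annotation: {len(all_orfs)} ORFs, "
        f"{len(hallmark_sets)} hallmark gene sets, {len(trees_out)} trees")

    # ---------------- summaries ----------------
    summaries: list[LibrarySummary] = []
    for spec in config.libraries:
        res = lib_results[spec.label]
        viral_cls = [c for c in res.classifications
                     if c.verdict in ("viral", "viral_by_hmm")]
        viral_contig_ids = {c.query_id for c in viral_cls if c.is_contig}
        viral_mapped = sum(res.mapping.per_contig.get(cid, 0)
                           for cid in viral_contig_ids)
        fams = {c.best_viral.family for c in viral_cls
                if c.best_viral is not None}
        sps = {c.best_viral.species for c in viral_cls
               if c.best_viral is not None}
        n_raw = len(res.raw_reads)
        summaries.append(
            LibrarySummary(
                label=spec.label,
                is_control=spec.is_control,
                n_raw=n_raw,
                mean_read_length=(sum(len(r) for r in res.raw_reads) / n_raw
                                  if n_raw else 0.0),
                gc_percent=_gc_percent(res.raw_reads),
                n_viral_contigs=len(viral_contig_ids),
                pct_reads_mapped_to_viral_contigs=(
                    100.0 * viral_mapped / n_raw if n_raw else 0.0),
                n_viral_reads=sum(c.n_reads for c in viral_cls),
                n_families=len(fams),
                n_species=len(sps),
            )
        )
    triple = (comm.family_counts_by_genome_type(family_profile)
              if family_profile is not None else {"dsDNA": 0, "ssDNA": 0,
                                                  "RNA": 0})
    control_ratio = control_viral = None
    controls = [s for s in summaries if s.is_control]
    samples = [s for s in summaries if not s.is_control]
    if controls and samples:
        control_ratio, control_viral = control_contamination_check(
            controls[0].n_raw, [s.n_raw for s in samples],
            controls[0].n_viral_reads,
        )
    report = RunReport(
        config=config, taxa=taxa, truth=truth,
        viral_records=viral_records, nvnr_records=nvnr_records,
        background=background, hmms=hmms, libraries=lib_results,
        family_profile=family_profile, species_profile=species_profile,
        bray_curtis=bray, pcoa=pcoa_res, upgma_newick=upgma_nwk,
        friedman=friedman_res, rarefaction=rarefaction, shared=shared_rep,
        top10=top10, hallmark_sets=hallmark_sets, trees=trees_out,
        summaries=summaries, family_triple=triple,
        control_ratio=control_ratio, control_viral_reads=control_viral,
    )
    write_outputs(report, outdir)
    log("run complete")
    return report


def write_outputs(report: RunReport, outdir: Path) -> None:
    outdir = Path(outdir)
    # QC report
    pd.DataFrame([asdict(r.qc_report) for r in report.libraries.values()]
                 ).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    # classifications
    rows = []
    for res in report.libraries.values():
        for c in res.classifications:
            rows.append({
                "query_id": c.query_id, "library": c.library,
                "is_contig": c.is_contig, "n_reads": c.n_reads,
                "verdict": c.verdict,
                "species": c.best_viral.species if c.best_viral else "",
                "family": c.best_viral.family if c.best_viral else "",
                "evalue": c.best_viral.e_value if c.best_viral else "",
                "hmm": c.hmm_name or "",
            })
    pd.DataFrame(rows).to_csv(outdir / "classifications.tsv", sep="\t",
                              index=False)
    if report.family_profile is not None:
        report.family_profile.counts.to_csv(outdir / "family_profile.tsv",
                                            sep="\t")
        report.species_profile.counts.to_csv(outdir / "species_profile.tsv",
                                             sep="\t")
    if report.bray_curtis is not None:
        pd.DataFrame(report.bray_curtis.d, index=report.bray_curtis.labels,
                     columns=report.bray_curtis.labels
                     ).to_csv(outdir / "bray_curtis.tsv", sep="\t")
        report.pcoa.coordinates.to_csv(outdir / "pcoa.tsv", sep="\t")
        (outdir / "upgma.nwk").write_text(report.upgma_newick + "\n")
    if report.friedman is not None:
        (outdir / "friedman.json").write_text(json.dumps(
            asdict(report.friedman), sort_keys=True, indent=1) + "\n")
    if report.rarefaction:
        rows = [{"library": lab, "depth": d, "expected_species": s}
                for lab, curve in sorted(report.rarefaction.items())
                for d, s in curve]
        pd.DataFrame(rows).to_csv(outdir / "rarefaction.tsv", sep="\t",
                                  index=False)
    summary = pd.DataFrame([asdict(s) for s in report.summaries])
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    blob = {
        "family_triple": report.family_triple,
        "n_families_total": int(sum(report.family_triple.values())),
        "control_ratio_pct": report.control_ratio,
        "control_viral_reads": report.control_viral_reads,
        "shared_species_core": (len(report.shared.core_species)
                                if report.shared else None),
        "species_union": report.shared.union_size if report.shared else None,
        "friedman_p": report.friedman.p_value if report.friedman else None,
        "hallmark_genes": [h.gene for h in report.hallmark_sets],
        "seed": report.config.seed,
    }
    (outdir / "report.json").write_text(
        json.dumps(blob, sort_keys=True, indent=1) + "\n")
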