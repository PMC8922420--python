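#!/usr/bin/env python
"""Stage 4: translated homology classification.

Six-frame seed-and-extend search of every contig and singlet against
the viral protein database (E < 1e-5), competitive filtering against
the NVNR database, and profile-HMM rescue of queries without viral
hits.  The full per-query table goes to scratch/; a per-library verdict
summary goes to results/.
"""

import json

import pandas as pd

from _common import ASM, CLS, DATA, RESULTS, config, ensure_dirs
from rivervirome.homology import ProteinDatabase, classify_all
from rivervirome.phmm import read_hmms
from rivervirome.records import (
    Contig,
    read_fastq,
    read_nucleotide_fasta,
    read_protein_fasta,
)


def main() -> None:
    ensure_dirs(CLS, RESULTS)
    cfg = config()
    viral_db = ProteinDatabase(read_protein_fasta(DATA / "viral_db.faa"))
    nvnr_db = ProteinDatabase(read_protein_fasta(DATA / "nvnr_db.faa"))
    hmms = read_hmms(DATA / "hmms")
    all_rows = []
    summary = []
    for spec in cfg.libraries:
        members = json.loads(
            (ASM / f"{spec.label}.members.json").read_text())
        contigs = [
            Contig(name, spec.label, seq,
                   members[name]["members"],
                   members[name]["n_reads_mapped"])
            for name, seq in read_nucleotide_fasta(
                ASM / f"{spec.label}.contigs.fasta")
        ]
        singlets = read_fastq(ASM / f"{spec.label}.singlets.fastq",
                              spec.label)
        cls = classify_all(contigs, singlets, viral_db, nvnr_db, hmms,
                           hmm_bitscore_cutoff=cfg.hmm_bitscore_cutoff,
                           e_cutoff=cfg.e_cutoff)
        counts = {}
        for c in cls:
            counts[c.verdict] = counts.get(c.verdict, 0) + 1
            h = c.best_viral
            all_rows.append({
                "query_id": c.query_id, "library": c.library,
                "is_contig": c.is_contig, "n_reads": c.n_reads,
                "verdict": c.verdict,
                "species": h.species if h else "",
                "family": h.family if h else "",
                "genome_type": h.genome_type if h else "",
                "host": h.host if h else "",
                "pct_identity": round(h.pct_identity, 2) if h else "",
                "evalue": h.e_value if h else "",
                "hmm": c.hmm_name or "",
                "hmm_score": c.hmm_score or "",
            })
        summary.append({"library": spec.label, **counts})
        print(f"{spec.label}: {counts}")
    pd.DataFrame(all_rows).to_csv(CLS / "classifications.tsv", sep="\t",
                                  index=False)
    pd.DataFrame(summary).fillna(0).to_csv(
        RESULTS / "04_classification_summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
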