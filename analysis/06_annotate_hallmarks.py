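#!/usr/bin/env python
"""Stage 6: extend/merge viral contigs, predict ORFs, tag hallmarks.

Viral-classified contigs are merged when they hit disjoint parts of the
same database protein, extended with overhanging singlet reads, and
scanned for ORFs (>=300 nt, ATG starts, standard code).  ORFs are
annotated against the viral protein database; hallmark genes (MCP,
NS1, Rep, TerL, RdRp) are collected per gene for phylogeny.  ORF
coordinates (GFF3) and hallmark FASTA go to scratch/; the hallmark
inventory goes to results/.
"""

import json

import pandas as pd

from _common import ANN, ASM, CLS, DATA, RESULTS, config, ensure_dirs
from rivervirome import annotation as ann
from rivervirome.homology import ProteinDatabase
from rivervirome.records import (
    Contig,
    read_fastq,
    read_nucleotide_fasta,
    read_protein_fasta,
)


def main() -> None:
    ensure_dirs(ANN, RESULTS)
    cfg = config()
    viral_db = ProteinDatabase(read_protein_fasta(DATA / "viral_db.faa"))
    cls = pd.read_csv(CLS / "classifications.tsv", sep="\t",
                      keep_default_na=False)
    viral_ids = set(cls[(cls.verdict.isin(["viral", "viral_by_hmm"]))
                        & cls.is_contig].query_id)
    all_orfs = []
    for spec in cfg.libraries:
        if spec.is_control:
            continue
        members = json.loads((ASM / f"{spec.label}.members.json").read_text())
        contigs = [Contig(n, spec.label, s, members[n]["members"],
                          members[n]["n_reads_mapped"])
                   for n, s in read_nucleotide_fasta(
                       ASM / f"{spec.label}.contigs.fasta")
                   if n in viral_ids]
        singlets = read_fastq(ASM / f"{spec.label}.singlets.fastq",
                              spec.label)
        extended = [ann.extend_by_mapping(c, singlets, rounds=2)
                    for c in contigs]
        n_orfs = 0
        for c in extended:
            if len(c.seq) < cfg.min_orf_size:
                continue
            orfs = ann.predict_orfs(c, cfg.min_orf_size)
            orfs = ann.annotate_orfs(orfs, viral_db, e_cutoff=cfg.e_cutoff)
            all_orfs.extend(orfs)
            n_orfs += len(orfs)
        print(f"{spec.label}: {len(contigs)} viral contigs, {n_orfs} ORFs")
    (ANN / "orfs.gff3").write_text(ann.orfs_to_gff3(all_orfs))
    sets = ann.extract_hallmarks(all_orfs)
    rows = []
    fasta_lines = []
    for hs in sets:
        for oid, pep, complete in hs.members:
            rows.append({"gene": hs.gene, "group": hs.group, "orf_id": oid,
                         "length_aa": len(pep.rstrip("*")),
                         "complete": complete})
            fasta_lines.append(f">{hs.gene}|{oid}\n{pep.rstrip('*')}")
    (ANN / "hallmarks.faa").write_text("\n".join(fasta_lines) + "\n")
    pd.DataFrame(rows).to_csv(RESULTS / "06_hallmarks.tsv", sep="\t",
                              index=False)
    for hs in sets:
        n_complete = sum(1 for _o, _p, c in hs.members if c)
        print(f"{hs.gene} ({hs.group}): {len(hs.members)} ORFs, "
              f"{n_complete} complete")


if __name__ == "__main__":
    main()
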