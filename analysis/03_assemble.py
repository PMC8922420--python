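#!/usr/bin/env python
"""Stage 3: greedy overlap assembly per library.

Merges cleaned reads longest-overlap-first into contigs, applies the
length-based chimera filter, and maps the raw reads back to measure the
mapped fraction.  Contigs and singlets go to scratch/; the assembly
table goes to results/.
"""

import json

import pandas as pd

from _common import ASM, CLEAN, DATA, RESULTS, config, ensure_dirs
from rivervirome.assembly import assemble, map_reads_back
from rivervirome.records import read_fastq, write_fastq, write_nucleotide_fasta


def main() -> None:
    ensure_dirs(ASM, RESULTS)
    cfg = config()
    rows = []
    for spec in cfg.libraries:
        clean = read_fastq(CLEAN / f"{spec.label}.fastq", spec.label)
        raw = read_fastq(DATA / f"{spec.label}.fastq", spec.label)
        contigs, singlets = assemble(clean, cfg.assembly, library=spec.label)
        mapping = map_reads_back(raw, contigs, cfg.assembly)
        write_nucleotide_fasta([(c.contig_id, c.seq) for c in contigs],
                               ASM / f"{spec.label}.contigs.fasta")
        write_fastq(singlets, ASM / f"{spec.label}.singlets.fastq")
        (ASM / f"{spec.label}.members.json").write_text(json.dumps(
            {c.contig_id: {"members": c.member_read_ids,
                           "n_reads_mapped": c.n_reads_mapped}
             for c in contigs}, sort_keys=True))
        lens = sorted(len(c.seq) for c in contigs)
        rows.append({
            "library": spec.label, "n_clean_reads": len(clean),
            "n_contigs": len(contigs), "n_singlets": len(singlets),
            "min_contig": lens[0] if lens else 0,
            "max_contig": lens[-1] if lens else 0,
            "pct_raw_reads_mapped": round(mapping.pct_mapped, 2),
        })
        print(f"{spec.label}: {len(contigs)} contigs "
              f"({lens[0] if lens else 0}-{lens[-1] if lens else 0} bp), "
              f"{len(singlets)} singlets, "
              f"{mapping.pct_mapped:.1f}% raw reads mapped")
    pd.DataFrame(rows).to_csv(RESULTS / "03_assembly_stats.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
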