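#!/usr/bin/env python
"""Stage 1: build the mock river community and simulate the libraries.

Emulates six ~10,000-read freshwater libraries (named after the six
sampling cities) plus a ~1% negative control, drawn from a 17-family
viral mock community (9 dsDNA, 4 ssDNA, 4 RNA) over a non-viral
background, with PCR duplicates, 3' quality decay and residual
adapters.  Reads, databases and profile HMMs go to scratch/; the
community and design tables go to results/.
"""

import pandas as pd

from _common import DATA, RESULTS, SEED, config, ensure_dirs, references
from rivervirome.phmm import write_hmms
from rivervirome.pipeline import library_abundance
from rivervirome.records import write_fastq, write_protein_fasta
from rivervirome.synthetic import CommunityDesign, simulate_library


def main() -> None:
    ensure_dirs(DATA, RESULTS)
    cfg = config()
    taxa, viral, nvnr, truth, background, hmms = references()
    write_protein_fasta(viral, DATA / "viral_db.faa")
    write_protein_fasta(nvnr, DATA / "nvnr_db.faa")
    truth.to_csv(DATA / "truth.tsv", sep="\t", index=False)
    write_hmms(hmms, DATA / "hmms")
    pd.DataFrame([
        {"species": t.species_name, "family": t.family,
         "genome_type": t.genome_type, "host": t.host_group,
         "genome_length": len(t.genome_seq), "n_proteins": len(t.proteins)}
        for t in taxa
    ]).to_csv(RESULTS / "01_mock_community.tsv", sep="\t", index=False)
    rows = []
    for spec in cfg.libraries:
        abund = {} if spec.is_control else library_abundance(cfg, spec.label,
                                                             taxa)
        design = CommunityDesign(
            library_label=spec.label, abundance=abund,
            non_viral_fraction=1.0 if spec.is_control
            else cfg.non_viral_fraction,
            n_reads=spec.n_reads, duplicate_rate=cfg.duplicate_rate,
            adapter_seq=cfg.adapter_seq,
            adapter_fraction=cfg.adapter_fraction,
            quality_start=cfg.quality_start, quality_end=cfg.quality_end,
            seed=SEED,
        )
        reads = simulate_library(design, taxa, background)
        write_fastq(reads, DATA / f"{spec.label}.fastq")
        rows.append({"library": spec.label, "n_reads": len(reads),
                     "is_control": spec.is_control,
                     "nucleic_acid": spec.nucleic_acid})
        print(f"{spec.label}: {len(reads)} reads")
    pd.DataFrame(rows).to_csv(RESULTS / "01_library_design.tsv", sep="\t",
                              index=False)
    print(f"community: {len(taxa)} taxa, {len(viral)} viral proteins, "
          f"{len(nvnr)} NVNR proteins, {len(hmms)} hallmark HMMs")


if __name__ == "__main__":
    main()
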