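#!/usr/bin/env python
"""Stage 2: clean every library.

Window deduplication (bases 5-55), Phred-10 quality-tail trimming and
VecScreen-style 3' adapter trimming, in that order.  Clean FASTQs go to
scratch/; the per-library QC table goes to results/.
"""

from dataclasses import asdict

import pandas as pd

from _common import CLEAN, DATA, RESULTS, SEED, config, ensure_dirs
from rivervirome.qc import qc_library
from rivervirome.records import read_fastq, write_fastq


def main() -> None:
    ensure_dirs(CLEAN, RESULTS)
    cfg = config()
    rows = []
    for spec in cfg.libraries:
        reads = read_fastq(DATA / f"{spec.label}.fastq", spec.label)
        clean, report = qc_library(reads, cfg.qc, SEED)
        write_fastq(clean, CLEAN / f"{spec.label}.fastq")
        rows.append(asdict(report))
        print(f"{spec.label}: {report.n_raw} raw, "
              f"{report.n_dup_removed} duplicates removed, "
              f"{report.n_kept} kept "
              f"(mean length {report.mean_length:.1f}, "
              f"GC {report.gc_percent:.1f}%)")
    pd.DataFrame(rows).to_csv(RESULTS / "02_qc_report.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
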