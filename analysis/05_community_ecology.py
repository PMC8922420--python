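#!/usr/bin/env python
"""Stage 5: community profiles and ecology of the six sample viromes.

Builds family and species read-count profiles from the classifications,
then computes rarefaction curves, the Bray-Curtis matrix, PCoA, the
UPGMA dendrogram, the Friedman rank-sum test, shared/unique species and
the top-10 species per library.  Tables and trees go to results/;
figures go to scratch/.
"""

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from _common import CLS, RESULTS, SCRATCH, config, ensure_dirs
from rivervirome import community as comm
from rivervirome import plots
from rivervirome.homology import Classification, Hit


def _reload_classifications(path) -> list[Classification]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        hit = None
        if row.verdict == "viral":
            hit = Hit("q", "s", row.species, row.family, row.genome_type,
                      row.host, "", 0, 0.0, 0.0, 0.0, 0, 0, 0, 0, 1)
        c = Classification(row.query_id, row.verdict, best_viral=hit)
        c.library = row.library
        c.n_reads = int(row.n_reads)
        c.is_contig = bool(row.is_contig)
        out.append(c)
    return out


def main() -> None:
    ensure_dirs(RESULTS, SCRATCH / "figures")
    cfg = config()
    sample_labels = [s.label for s in cfg.libraries if not s.is_control]
    cls = [c for c in _reload_classifications(CLS / "classifications.tsv")
           if c.library in sample_labels]
    fam = comm.build_profiles(cls, "family", sample_labels)
    sp = comm.build_profiles(cls, "species", sample_labels)
    fam.counts.to_csv(RESULTS / "05_family_profile.tsv", sep="\t")
    sp.counts.to_csv(RESULTS / "05_species_profile.tsv", sep="\t")
    triple = comm.family_counts_by_genome_type(fam)
    print(f"families by genome type: {triple} "
          f"(total {sum(triple.values())})")

    counted = fam.drop_reserved()
    bray = comm.bray_curtis(counted)
    pd.DataFrame(bray.d, index=bray.labels, columns=bray.labels).to_csv(
        RESULTS / "05_bray_curtis.tsv", sep="\t")
    pres = comm.pcoa(bray)
    pres.coordinates.to_csv(RESULTS / "05_pcoa.tsv", sep="\t")
    nwk = comm.upgma_tree(bray).to_newick()
    (RESULTS / "05_upgma.nwk").write_text(nwk + "\n")
    fr = comm.friedman_test(counted)
    (RESULTS / "05_friedman.json").write_text(
        json.dumps(asdict(fr), indent=1, sort_keys=True) + "\n")
    print(f"Friedman chi2={fr.statistic:.3f} df={fr.df} p={fr.p_value:.3f}"
          f" -> {'no ' if fr.p_value > 0.05 else ''}significant"
          " difference among the six viromes")

    spc = sp.drop_reserved()
    curves = {}
    rows = []
    for lab in sample_labels:
        counts = {t: int(spc.counts.loc[lab, t]) for t in spc.taxa
                  if spc.counts.loc[lab, t] > 0}
        total = sum(counts.values())
        depths = sorted({int(x) for x in np.linspace(0, total, 21)})
        curves[lab] = comm.rarefaction_curve(counts, depths)
        rows += [{"library": lab, "depth": d, "expected_species": s}
                 for d, s in curves[lab]]
    pd.DataFrame(rows).to_csv(RESULTS / "05_rarefaction.tsv", sep="\t",
                              index=False)
    shared = comm.shared_species(spc)
    (RESULTS / "05_shared_species.json").write_text(json.dumps({
        "core_species": shared.core_species,
        "union_size": shared.union_size,
        "per_library_fraction": shared.per_library_fraction,
        "region_counts": {"+".join(k): v
                          for k, v in shared.region_counts.items()},
    }, indent=1, sort_keys=True) + "\n")
    print(f"species union {shared.union_size}, "
          f"core (all six) {len(shared.core_species)}")
    top = comm.top_species(sp, k=10)
    pd.concat([df.assign(library=lab) for lab, df in top.items()]
              ).to_csv(RESULTS / "05_top10_species.tsv", sep="\t",
                       index=False)

    figs = SCRATCH / "figures"
    plots.family_heatmap(fam, figs / "family_heatmap.png")
    plots.rarefaction_plot(curves, figs / "rarefaction.png")
    plots.pcoa_plot(pres, figs / "pcoa.png")
    plots.top_species_bars(top, figs / "top10.png")
    print(f"figures in {figs}")


if __name__ == "__main__":
    main()
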