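#!/usr/bin/env python
"""Stage 7: hallmark-gene phylogenies.

For each hallmark gene with at least three usable sequences, aligns the
complete study ORFs together with the database reference proteins of
the same gene (progressive alignment, BLOSUM62), removes columns with
more than 50% gaps, and builds a neighbor-joining tree on p-distances.
Newick trees go to results/.
"""

from _common import ANN, RESULTS, ensure_dirs, references
from rivervirome.msa import align_and_mask, nj_tree


def main() -> None:
    ensure_dirs(RESULTS)
    _taxa, viral, _nvnr, _truth, _bg, _hmms = references()
    members: dict[str, list[tuple[str, str]]] = {}
    for line in (ANN / "hallmarks.faa").read_text().split(">"):
        if not line.strip():
            continue
        header, seq = line.split("\n", 1)
        gene, oid = header.split("|", 1)
        label = oid.replace("|", "_").replace("(", "_").replace(")", "_")
        label = label.replace(":", "_").replace(",", "_").replace(";", "_")
        members.setdefault(gene, []).append((label, seq.replace("\n", "")))
    for gene, items in sorted(members.items()):
        seen = {l for l, _ in items}
        for rec in viral:
            if rec.gene == gene and f"ref_{rec.rec_id}" not in seen:
                items.append((f"ref_{rec.rec_id}", rec.seq))
        # drop duplicate labels, keep first
        uniq = {}
        for l, s in items:
            uniq.setdefault(l, s)
        items = list(uniq.items())
        if len(items) < 3:
            print(f"{gene}: only {len(items)} sequences, no tree")
            continue
        msa = align_and_mask(items)
        nwk = nj_tree(msa).to_newick()
        out = RESULTS / f"07_{gene}_nj.nwk"
        out.write_text(nwk + "\n")
        print(f"{gene}: {len(items)} sequences, "
              f"{msa.n_cols} masked alignment columns -> {out.name}")


if __name__ == "__main__":
    main()
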