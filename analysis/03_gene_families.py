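"""Gene families (50/50 rule), BBH ortholog barcodes, pan/core genome.

Aligns all proteome pairs, partitions proteins into gene families, derives
per-protein presence barcodes via non-greedy bidirectional best hits, counts
full 1:1 ortholog groups and clade-shared genes, and writes the genomic
pan/core curves.
"""

import json
from pathlib import Path

import numpy as np

from panlink import genefamilies as gf
from panlink import pancore

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    proteomes = {
        path.stem: gf.read_proteome_fasta(path)
        for path in sorted((RESULTS / "world" / "proteomes").glob("*.faa"))
    }
    n_proteins = sum(len(v) for v in proteomes.values())
    print(f"{len(proteomes)} proteomes, {n_proteins} proteins")

    hits = gf.all_pairwise_hits(proteomes)
    print(f"{len(hits)} pairwise hits")

    families = gf.build_families(proteomes, hits)
    summary = gf.family_summary(families, proteomes)
    print(f"gene families: pan {summary['pan']}, core {summary['core']} "
          f"({summary['core'] / summary['pan']:.0%}), "
          f"singletons {summary['singleton']} "
          f"({summary['singleton'] / summary['pan']:.0%})")

    barcodes, groups = gf.bbh_orthologs(proteomes, hits)
    print(f"1:1 BBH ortholog groups across all strains: {len(groups)} "
          f"(conservative non-greedy pairing, at or below the core count)")

    with open(RESULTS / "barcodes.tsv", "w") as fh:
        fh.write("protein_id\tbarcode\n")
        for pid in sorted(barcodes):
            fh.write(f"{pid}\t{barcodes[pid]}\n")
    with open(RESULTS / "families.tsv", "w") as fh:
        fh.write("family_index\tprotein_ids\n")
        for i, fam in enumerate(families):
            fh.write(f"{i}\t{';'.join(fam)}\n")

    # pan/core curves over the family presence matrix, clustered order
    strains = sorted(proteomes)
    strain_of = {r.protein_id: s for s, recs in proteomes.items() for r in recs}
    bits = np.zeros((len(strains), len(families)), dtype=bool)
    for j, fam in enumerate(families):
        for pid in fam:
            bits[strains.index(strain_of[pid]), j] = True
    matrix = pancore.PresenceMatrix(strains, [f"fam{j}" for j in range(len(families))], bits)
    curves = pancore.pan_core(matrix, pancore.cluster_order(matrix))
    curves.to_frame().to_csv(RESULTS / "pancore_genome.csv", index=False)

    # clade-shared counts over the two-clade hierarchy (icicle-plot data)
    ledger = json.loads((RESULTS / "world" / "ledger.json").read_text())
    clade_a = [s for i, s in enumerate(ledger["strain_ids"]) if i < 7]
    clade_b = [s for i, s in enumerate(ledger["strain_ids"]) if i >= 7]
    counts = gf.clade_shared_counts(
        barcodes, strain_of, strains, [clade_a, clade_b]
    )
    shared = {"|".join(node): v for node, v in counts.items() if v}
    (RESULTS / "clade_shared_counts.json").write_text(json.dumps(shared, indent=1))
    root = counts.get(tuple(sorted(strains)), 0)
    print(f"genes shared by all strains as 1:1 orthologs: {root}; "
          f"clade-exclusive: {counts.get(tuple(sorted(clade_a)), 0)} / "
          f"{counts.get(tuple(sorted(clade_b)), 0)}")


if __name__ == "__main__":
    main()
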