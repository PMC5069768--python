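"""Full-scale reproduction of the genomic counts from deposited assemblies.

Recomputes pan / core / singleton gene-family counts (50/50 rule) and the
number of 1:1 BBH ortholog groups from the thirteen deposited draft
assemblies (GenBank whole-genome shotgun accessions AUXS01000000 through
AUYC01000000 plus the strain 2ta16 assembly).  The assemblies are NOT
bundled here: download them (e.g. with NCBI datasets) into a directory of
nucleotide FASTA files, one per strain, and pass that directory.  Gene
calling uses the external ``prodigal`` binary and the all-vs-all comparison
uses BLAST+; expect on the order of hours on one CPU.

Usage: python analysis/09_deposited_genomes.py /path/to/assemblies
"""

import json
import sys
from pathlib import Path

from panlink.experiments import deposited_genome_counts

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(assembly_dir: str) -> None:
    counts = deposited_genome_counts(assembly_dir, workdir=RESULTS / "deposited_work")
    print(f"pan-genome families: {counts['pan_families']}")
    print(f"core families (all strains): {counts['core_families']}")
    print(f"singleton families: {counts['singleton_families']}")
    print(f"1:1 BBH ortholog groups: {counts['bbh_groups']}")
    (RESULTS / "deposited_genome_counts.json").write_text(
        json.dumps(counts, indent=1)
    )


if __name__ == "__main__":
    if len(sys.argv) != 2:
        sys.exit(__doc__)
    main(sys.argv[1])
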