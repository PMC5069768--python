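"""Generate the planted 13-strain world used by the downstream analyses.

Writes per-strain proteome FASTAs, ESI+/ESI- feature tables with medium
blanks, MS/MS spectra (MGF) and the ground-truth ledger under
``results/world/``.  The world mirrors the study conditions at reduced
scale: two clades, a near-clonal pair, one 11-gene halogenated cluster
conserved in seven strains with a 6-member product family, and 40 extra
halogenated features restricted to the same strains.
"""

import sys
from pathlib import Path

from panlink.worldgen import WorldConfig, generate_world, write_world

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    config = WorldConfig.small(seed=seed)
    world = generate_world(config)
    outdir = RESULTS / "world"
    write_world(world, outdir)
    ledger = world.ledger
    cluster = ledger["clusters"][0]
    print(f"world {ledger['world_id']}: {len(world.strain_ids)} strains, "
          f"{len(ledger['family_patterns'])} gene families, "
          f"{len(ledger['feature_patterns'])} features, "
          f"{len(world.spectra)} MS/MS spectra")
    print(f"planted cluster {cluster['cluster_id']}: "
          f"{len(cluster['gene_families'])} genes in pattern "
          f"{cluster['strain_pattern']}, "
          f"{len(cluster['linked_features'])} linked features, "
          f"{len(ledger['halogenated_features'])} halogenated features total")
    print(f"artifacts under {outdir}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
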