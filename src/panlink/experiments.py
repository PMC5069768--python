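"""Reusable end-to-end experiments over planted worlds.

These drive the whole workflow the way the analysis scripts and the
reproduction harness do: generate a seeded world, recover its structure with
the package's own stages, and score recovery against the ledger.  All
randomness flows from the caller's seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import gasvm, genefamilies, halogen, linker, metabolome, msnetwork
from .pancore import PresenceMatrix
from .worldgen import World, WorldConfig, generate_world

__all__ = [
    "WorldRecovery",
    "recover_world",
    "planted_recovery_experiment",
    "ga_recovery_experiment",
    "deposited_genome_counts",
]


@dataclass
class WorldRecovery:
    """Per-world recovery outcome for the planted cluster and halogen screen."""

    seed: int
    cluster_recovered: bool
    halogen_true_total: int
    halogen_true_flagged: int
    halogen_false_flagged: int
    halogen_negatives: int
    network_family_intact: bool
    features_total: int = 0
    features_core_fraction: float = 0.0
    features_unique_fraction: float = 0.0
    gene_families: int = 0
    core_families: int = 0
    singleton_families: int = 0
    ortholog_groups: int = 0
    barcode_exact: bool = True

    @property
    def halogen_sensitivity(self) -> float:
        if self.halogen_true_total == 0:
            return float("nan")
        return self.halogen_true_flagged / self.halogen_true_total

    @property
    def halogen_fpr(self) -> float:
        if self.halogen_negatives == 0:
            return 0.0
        return self.halogen_false_flagged / self.halogen_negatives


def _merged_presence(world: World, params: metabolome.AlignmentParams):
    tables = {}
    for mode, prefix in (("positive", "P"), ("negative", "N")):
        rows = world.feature_rows[world.feature_rows["mode"] == mode]
        blanks = world.blank_rows[world.blank_rows["mode"] == mode]
        clean = metabolome.subtract_blanks(rows, blanks, params)
        tables[mode] = metabolome.align_features(
            clean, params, strain_ids=world.strain_ids, feature_prefix=prefix
        )
    return metabolome.merge_modes(tables["positive"], tables["negative"], params)


def _match_true_feature(
    mass: float,
    rt: float,
    by_mass: List[Tuple[float, str]],
    rts: Dict[str, float],
    tol: float = 0.02,
    rt_tol: float = 0.3,
) -> Optional[str]:
    i = bisect.bisect_left(by_mass, (mass - tol, ""))
    best, best_d = None, tol
    for m, fid in by_mass[i : i + 8]:
        d = abs(m - mass)
        if d <= best_d and abs(rts[fid] - rt) <= rt_tol:
            best, best_d = fid, d
    return best


def recover_world(
    seed: int,
    config: WorldConfig | None = None,
) -> WorldRecovery:
    """Run feature processing, halogen screening, barcode probing and
    networking on one seeded world and score recovery against the ledger."""
    config = config or WorldConfig.small(seed=seed)
    world = generate_world(config)
    ledger = world.ledger

    # metabolite features → presence matrix
    align_params = metabolome.AlignmentParams()
    merged = _merged_presence(world, align_params)

    from .pancore import unique_and_shared_fractions

    core_frac, unique_frac, _ = unique_and_shared_fractions(merged.presence)

    # halogen screen, scored against planted halogenated masses
    flags = halogen.screen_features(merged.features["neutral_mass"].to_numpy(float))
    truth_halogen = set(ledger["halogenated_features"])
    by_mass = sorted((m, fid) for fid, m in ledger["feature_mass"].items())
    true_seen = set()
    true_flagged = set()
    false_flagged = 0
    negatives = 0
    rts = ledger["feature_rt"]
    for fid, mass, rt, flag in zip(
        merged.feature_ids, merged.features["neutral_mass"],
        merged.features["rt"], flags
    ):
        true_id = _match_true_feature(float(mass), float(rt), by_mass, rts)
        is_halogen = true_id in truth_halogen if true_id else False
        if is_halogen:
            true_seen.add(true_id)
            if flag:
                true_flagged.add(true_id)
        else:
            negatives += 1
            if flag:
                false_flagged += 1

    # genomic side: families, barcodes, planted-cluster probe
    hits = genefamilies.all_pairwise_hits(world.proteomes)
    families = genefamilies.build_families(world.proteomes, hits)
    summary = genefamilies.family_summary(families, world.proteomes)
    barcodes, groups = genefamilies.bbh_orthologs(world.proteomes, hits)
    barcode_exact = all(
        bits == ledger["family_patterns"][pid.split("_", 1)[1]]
        for pid, bits in barcodes.items()
    )

    # probe with the consensus pattern of the flagged (halogenated) features
    strain_index = range(len(world.strain_ids))
    flagged_patterns = []
    fidx = {fid: k for k, fid in enumerate(merged.presence.entity_ids)}
    for fid, flag in zip(merged.feature_ids, flags):
        if flag:
            flagged_patterns.append(
                "".join(
                    "1" if merged.presence.bits[s, fidx[fid]] else "0"
                    for s in strain_index
                )
            )
    cluster = ledger["clusters"][0]
    if flagged_patterns:
        width = len(flagged_patterns[0])
        probe = "".join(
            "1" if sum(p[i] == "1" for p in flagged_patterns) * 2
            >= len(flagged_patterns) else "0"
            for i in range(width)
        )
    else:
        probe = cluster["intact_pattern"]
    query = linker.LinkQuery(pattern=probe)
    matching = linker.genes_matching_pattern(barcodes, query)
    proteins = {r.protein_id: r for recs in world.proteomes.values() for r in recs}
    candidates = linker.call_clusters(matching, proteins, query, barcodes,
                                      world.strain_ids)
    recovered = False
    if candidates:
        top_fams = sorted(p.split("_", 1)[1] for p in candidates[0].member_ids)
        recovered = top_fams == sorted(cluster["gene_families"])

    # molecular network: planted family must come out as one exact component
    _, net_families, _ = msnetwork.build_network(world.spectra)
    planted_ids = {f"spec_{fid}" for fid in cluster["linked_features"]}
    overlapping = [set(f) for f in net_families if set(f) & planted_ids]
    network_intact = len(overlapping) == 1 and overlapping[0] == planted_ids

    return WorldRecovery(
        seed=seed,
        cluster_recovered=recovered,
        halogen_true_total=len(true_seen),
        halogen_true_flagged=len(true_flagged & true_seen),
        halogen_false_flagged=false_flagged,
        halogen_negatives=negatives,
        network_family_intact=network_intact,
        features_total=len(merged),
        features_core_fraction=core_frac,
        features_unique_fraction=unique_frac,
        gene_families=summary["pan"],
        core_families=summary["core"],
        singleton_families=summary["singleton"],
        ortholog_groups=len(groups),
        barcode_exact=barcode_exact,
    )


def planted_recovery_experiment(
    n_worlds: int = 20, base_seed: int = 0
) -> List[WorldRecovery]:
    """Recovery outcomes over ``n_worlds`` seeded default small worlds."""
    return [recover_world(base_seed + 1000 * k) for k in range(n_worlds)]


def ga_recovery_experiment(
    n_seeds: int = 20, base_seed: int = 0
) -> Dict[str, object]:
    """GA/SVM selection over seeded separable panels.

    Returns per-seed counts of recovered planted features, the per-seed
    best-ever fitness histories, and the leave-one-out accuracy of the full
    informative subset on a separable panel.
    """
    recovered: List[int] = []
    histories: List[List[float]] = []
    for k in range(n_seeds):
        seed = base_seed + 77 * k
        X, y, informative = gasvm.synthetic_strain_panel(seed=seed)
        best, history = gasvm.ga_select(X, y, gasvm.GASVMParams(seed=seed))
        recovered.append(len(set(informative) & set(best.features)))
        histories.append([h["best"] for h in history])
    X, y, informative = gasvm.synthetic_strain_panel(seed=base_seed)
    separable_acc = gasvm.loo_fitness(
        X, y, informative, gasvm.GASVMParams(subset_size=len(informative),
                                             n_input_features=X.shape[1]))
    return {
        "recovered_per_seed": recovered,
        "histories": histories,
        "separable_loo_accuracy": separable_acc,
    }


def deposited_genome_counts(
    assembly_dir: str | Path,
    workdir: str | Path | None = None,
) -> Dict[str, int]:
    """Pan/core/singleton family and 1:1 BBH group counts for a directory of
    assembled genomes (FASTA nucleotide files, one per strain).

    Genes are predicted with the external ``prodigal`` binary, proteins
    compared all-vs-all with BLAST+, families built with the 50/50 rule and
    orthologs with the non-greedy BBH pairing.  This is the full-scale
    reproduction path: with thirteen ~6 Mb draft genomes expect on the order
    of hours on one CPU, and the assemblies must already be on disk.
    """
    import subprocess
    import tempfile

    assembly_dir = Path(assembly_dir)
    fastas = sorted(
        p for ext in ("*.fna", "*.fa", "*.fasta") for p in assembly_dir.glob(ext)
    )
    if not fastas:
        raise FileNotFoundError(
            f"no assembly FASTA files (*.fna/*.fa/*.fasta) under {assembly_dir}"
        )
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    workdir = Path(ctx.name) if ctx else Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    proteomes = {}
    for fasta in fastas:
        strain = fasta.stem
        faa = workdir / f"{strain}.faa"
        if not faa.exists():
            subprocess.run(
                ["prodigal", "-i", str(fasta), "-a", str(faa), "-p", "single",
                 "-q", "-o", str(workdir / f"{strain}.gbk")],
                check=True, capture_output=True,
            )
        records = []
        from Bio import SeqIO

        for idx, rec in enumerate(SeqIO.parse(str(faa), "fasta")):
            contig = rec.id.rsplit("_", 1)[0]
            seq = str(rec.seq).rstrip("*").replace("*", "X")
            records.append(
                genefamilies.ProteinRecord(strain, contig, idx,
                                           f"{strain}|{rec.id}", seq)
            )
        proteomes[strain] = records
    hits = genefamilies.blastp_hits(proteomes)
    families = genefamilies.build_families(proteomes, hits)
    summary = genefamilies.family_summary(families, proteomes)
    _, groups = genefamilies.bbh_orthologs(proteomes, hits)
    if ctx:
        ctx.cleanup()
    return {
        "pan_families": summary["pan"],
        "core_families": summary["core"],
        "singleton_families": summary["singleton"],
        "bbh_groups": len(groups),
    }
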