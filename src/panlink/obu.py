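"""Operational biosynthetic units: grouping predicted pathways across strains.

Per-strain biosynthetic pathway predictions (gene lists on a contig, with a
free-text type label and a partial flag for contig-edge truncations) are
consumed as input.  Two pathways belong to the same OBU when at least 80% of
the genes of the smaller pathway have homologues in the other at >=60% amino
acid identity; OBUs are the connected components of that relation.  OBUs
made solely of partial pathways whose strain conservation pattern duplicates
another OBU's are merged into it, avoiding overestimation of pathway
diversity from contig splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import networkx as nx

from .genefamilies import PairwiseHit

__all__ = [
    "PathwayPrediction",
    "OBUParams",
    "OBU",
    "pathway_pair_same_obu",
    "group_obus",
    "merge_partials",
    "read_pathway_tsv",
    "write_obu_tsv",
]


@dataclass(frozen=True)
class PathwayPrediction:
    pathway_id: str
    strain_id: str
    contig_id: str
    gene_ids: Tuple[str, ...]
    type_label: str = ""
    partial: bool = False

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 1:
            raise ValueError("a pathway needs at least one gene")


@dataclass(frozen=True)
class OBUParams:
    min_gene_fraction: float = 0.80  # inclusive
    min_identity: float = 60.0  # percent, inclusive

    def __post_init__(self) -> None:
        if not (0.0 < self.min_gene_fraction <= 1.0):
            raise ValueError("min_gene_fraction must be in (0, 1]")
        if not (0.0 < self.min_identity <= 100.0):
            raise ValueError("min_identity must be in (0, 100]")


@dataclass
class OBU:
    obu_id: str
    pathway_ids: List[str]
    barcode: str  # OR of member strain bits
    type_labels: List[str] = field(default_factory=list)
    all_partial: bool = False


def _best_identity_index(
    hits: Sequence[PairwiseHit],
) -> Dict[Tuple[str, str], float]:
    """(query, subject) -> best percent identity among hits for that pair."""
    index: Dict[Tuple[str, str], float] = {}
    for hit in hits:
        key = (hit.query_id, hit.subject_id)
        if hit.percent_identity > index.get(key, -1.0):
            index[key] = hit.percent_identity
    return index


def pathway_pair_same_obu(
    p1: PathwayPrediction,
    p2: PathwayPrediction,
    hits: "Sequence[PairwiseHit] | Mapping[Tuple[str, str], float]",
    params: OBUParams | None = None,
) -> bool:
    """Decide whether two pathways are the same operational biosynthetic unit.

    The fraction denominator is the smaller pathway's gene count, which
    tolerates contig-split partial pathways.  A gene counts as covered when
    its best homologue in the other pathway reaches the identity floor; one
    subject gene may serve several queries.  Both thresholds are inclusive.
    """
    params = params or OBUParams()
    index = hits if isinstance(hits, Mapping) else _best_identity_index(hits)
    small, large = (p1, p2) if len(p1.gene_ids) <= len(p2.gene_ids) else (p2, p1)
    covered = 0
    for gene in small.gene_ids:
        best = max(
            (index.get((gene, other), -1.0) for other in large.gene_ids),
            default=-1.0,
        )
        if best >= params.min_identity:
            covered += 1
    return covered >= params.min_gene_fraction * len(small.gene_ids)


def group_obus(
    pathways: Sequence[PathwayPrediction],
    hits: "Sequence[PairwiseHit] | Mapping[Tuple[str, str], float]",
    strain_ids: Sequence[str],
    params: OBUParams | None = None,
) -> List[OBU]:
    """Connected components of the pairwise same-OBU relation.

    Because similarity is transitively closed, two dissimilar pathways can be
    chained through an intermediate; this mirrors the recursive grouping used
    when assembling pathways split between contigs.  Output is deterministic
    and independent of pathway input order.
    """
    params = params or OBUParams()
    index = hits if isinstance(hits, Mapping) else _best_identity_index(hits)
    ordered = sorted(pathways, key=lambda p: p.pathway_id)
    if len({p.pathway_id for p in ordered}) != len(ordered):
        raise ValueError("duplicate pathway ids")
    strain_pos = {s: i for i, s in enumerate(sorted(strain_ids))}
    graph = nx.Graph()
    graph.add_nodes_from(p.pathway_id for p in ordered)
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if pathway_pair_same_obu(ordered[i], ordered[j], index, params):
                graph.add_edge(ordered[i].pathway_id, ordered[j].pathway_id)
    by_id = {p.pathway_id: p for p in ordered}
    obus = []
    components = sorted(sorted(c) for c in nx.connected_components(graph))
    for k, component in enumerate(components, start=1):
        bits = ["0"] * len(strain_pos)
        labels = []
        for pid in component:
            pathway = by_id[pid]
            bits[strain_pos[pathway.strain_id]] = "1"
            if pathway.type_label:
                labels.append(pathway.type_label)
        obus.append(
            OBU(
                obu_id=f"OBU{k:03d}",
                pathway_ids=list(component),
                barcode="".join(bits),
                type_labels=sorted(set(labels)),
                all_partial=all(by_id[pid].partial for pid in component),
            )
        )
    return obus


def merge_partials(obus: Sequence[OBU]) -> List[OBU]:
    """Fold all-partial OBUs into an OBU with the identical strain barcode.

    Only OBUs consisting solely of partial (contig-truncated) pathways are
    candidates; each is merged into the first non-candidate OBU sharing its
    exact barcode, if any.  The OBU count never increases.
    """
    keep: List[OBU] = []
    partial_only: List[OBU] = []
    for obu in obus:
        (partial_only if obu.all_partial else keep).append(obu)
    by_barcode: Dict[str, OBU] = {}
    for obu in keep:
        by_barcode.setdefault(obu.barcode, obu)
    merged: List[OBU] = [
        OBU(o.obu_id, list(o.pathway_ids), o.barcode, list(o.type_labels), o.all_partial)
        for o in keep
    ]
    lookup = {o.obu_id: o for o in merged}
    for obu in partial_only:
        target = by_barcode.get(obu.barcode)
        if target is None:
            merged.append(obu)
            by_barcode[obu.barcode] = obu
            lookup[obu.obu_id] = obu
        else:
            host = lookup[target.obu_id]
            host.pathway_ids = sorted(host.pathway_ids + obu.pathway_ids)
            host.type_labels = sorted(set(host.type_labels) | set(obu.type_labels))
    return merged


# ---------------------------------------------------------------------------
# I/O

def read_pathway_tsv(path: str | Path) -> List[PathwayPrediction]:
    """TSV columns: pathway_id, strain_id, contig_id, type_label, partial,
    gene_ids (semicolon-separated protein ids)."""
    pathways = []
    lines = Path(path).read_text().splitlines()
    header = lines[0].strip().split("\t")
    expected = ["pathway_id", "strain_id", "contig_id", "type_label", "partial", "gene_ids"]
    if header != expected:
        raise ValueError(f"pathway TSV header {header} != {expected}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 6:
            raise ValueError(f"line {lineno}: expected 6 columns")
        pathways.append(
            PathwayPrediction(
                pathway_id=fields[0],
                strain_id=fields[1],
                contig_id=fields[2],
                type_label=fields[3],
                partial=fields[4].lower() in ("1", "true", "yes"),
                gene_ids=tuple(g for g in fields[5].split(";") if g),
            )
        )
    return pathways


def write_obu_tsv(obus: Sequence[OBU], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("obu_id\tbarcode\tn_pathways\ttype_labels\tpathway_ids\n")
        for obu in obus:
            fh.write(
                f"{obu.obu_id}\t{obu.barcode}\t{len(obu.pathway_ids)}\t"
                f"{','.join(obu.type_labels)}\t{';'.join(obu.pathway_ids)}\n"
            )
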