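"""Chemotype ↔ genotype linking: the discovery core of the workflow.

Given per-protein presence/absence barcodes and a query pattern (typically
the strain distribution of a metabolite family — e.g. the strains producing
halogenated features), find the genes matching that pattern and call
candidate biosynthetic gene clusters as genomic runs of matching genes.
The reverse direction queries the feature presence matrix with a gene
cluster's pattern to recover its product family.  A within-contig
permutation test guards against coincidental barcode matches forming
apparent clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .genefamilies import ProteinRecord
from .pancore import PresenceMatrix

__all__ = [
    "LinkQuery",
    "CandidateCluster",
    "hamming",
    "genes_matching_pattern",
    "call_clusters",
    "features_matching_pattern",
    "match_significance",
]


@dataclass(frozen=True)
class LinkQuery:
    """Pattern probe: which barcode to look for and how to assemble clusters.

    ``max_hamming`` relaxes the match for presence-rule noise/dropout;
    ``max_gap`` allows non-matching genes inside a called cluster (real
    clusters contain genes shared more widely than the diagnostic pattern);
    ``min_cluster_genes`` suppresses trivially short runs.
    """

    pattern: str
    max_hamming: int = 0
    min_cluster_genes: int = 3
    max_gap: int = 2

    def __post_init__(self) -> None:
        if set(self.pattern) - {"0", "1"}:
            raise ValueError("pattern must be a bit string")
        if not (0 <= self.max_hamming < len(self.pattern)):
            raise ValueError("max_hamming must be below the pattern width")
        if self.min_cluster_genes < 1 or self.max_gap < 0:
            raise ValueError("invalid cluster assembly parameters")


@dataclass
class CandidateCluster:
    strain_id: str
    contig_id: str
    start_index: int
    end_index: int  # inclusive
    member_ids: List[str]
    pattern: str
    score: int
    # strains set in member barcodes beyond the query pattern (broken-cluster
    # style diagnostics: genes present where the chemistry is absent)
    extra_strains: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("interval inverted")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("bit strings of unequal width")
    return sum(x != y for x, y in zip(a, b))


def genes_matching_pattern(
    barcodes: Mapping[str, str], query: LinkQuery
) -> List[str]:
    """Protein ids whose barcode lies within ``max_hamming`` of the pattern."""
    return sorted(
        pid for pid, bits in barcodes.items()
        if hamming(bits, query.pattern) <= query.max_hamming
    )


def call_clusters(
    matching: Sequence[str],
    proteins: "Mapping[str, ProteinRecord] | Sequence[ProteinRecord]",
    query: LinkQuery,
    barcodes: Mapping[str, str] | None = None,
    strain_ids: Sequence[str] | None = None,
) -> List[CandidateCluster]:
    """Assemble matching genes into candidate clusters by genomic adjacency.

    Within each contig, maximal runs of matching genes with at most
    ``max_gap`` intervening non-matching genes between consecutive members
    are kept when they contain at least ``min_cluster_genes`` members.
    Candidates are ranked by member count, ties broken by strain then
    contig id.  When ``barcodes`` and ``strain_ids`` are supplied, each
    candidate reports the strains set in member barcodes beyond the query
    pattern — the broken-cluster diagnostic (genes present, product absent).
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.protein_id: p for p in proteins}
    matching_set = set(matching)
    by_contig: Dict[Tuple[str, str], List[ProteinRecord]] = {}
    for pid in matching_set:
        rec = proteins[pid]
        by_contig.setdefault((rec.strain_id, rec.contig_id), []).append(rec)

    candidates: List[CandidateCluster] = []
    for (strain, contig), recs in by_contig.items():
        recs.sort(key=lambda r: r.gene_index)
        run: List[ProteinRecord] = []
        for rec in recs:
            if run and rec.gene_index - run[-1].gene_index - 1 > query.max_gap:
                candidates.extend(_close_run(run, strain, contig, query, barcodes, strain_ids))
                run = []
            run.append(rec)
        candidates.extend(_close_run(run, strain, contig, query, barcodes, strain_ids))
    candidates.sort(key=lambda c: (-c.score, c.strain_id, c.contig_id, c.start_index))
    return candidates


def _close_run(
    run: List[ProteinRecord],
    strain: str,
    contig: str,
    query: LinkQuery,
    barcodes: Mapping[str, str] | None,
    strain_ids: Sequence[str] | None,
) -> List[CandidateCluster]:
    if len(run) < query.min_cluster_genes:
        return []
    extra: List[str] = []
    if barcodes is not None and strain_ids is not None:
        strains = sorted(strain_ids)
        beyond = set()
        for rec in run:
            bits = barcodes.get(rec.protein_id)
            if bits is None:
                continue
            for s, b, q in zip(strains, bits, query.pattern):
                if b == "1" and q == "0":
                    beyond.add(s)
        extra = sorted(beyond)
    return [
        CandidateCluster(
            strain_id=strain,
            contig_id=contig,
            start_index=run[0].gene_index,
            end_index=run[-1].gene_index,
            member_ids=[r.protein_id for r in run],
            pattern=query.pattern,
            score=len(run),
            extra_strains=extra,
        )
    ]


def features_matching_pattern(
    matrix: PresenceMatrix, pattern: str, max_hamming: int = 0
) -> List[str]:
    """Feature ids whose presence barcode is within ``max_hamming`` of pattern.

    Monotone in ``max_hamming``: relaxing the threshold only adds features.
    """
    if len(pattern) != matrix.n_strains:
        raise ValueError("pattern width does not match the matrix")
    target = np.array([c == "1" for c in pattern])
    dist = (matrix.bits != target[:, None]).sum(axis=0)
    return sorted(
        eid for eid, d in zip(matrix.entity_ids, dist) if d <= max_hamming
    )


def match_significance(
    query: LinkQuery,
    barcodes: Mapping[str, str],
    proteins: "Mapping[str, ProteinRecord] | Sequence[ProteinRecord]",
    n_permutations: int = 999,
    seed: int = 0,
) -> Tuple[float, int]:
    """Empirical p-value for the largest observed cluster of matching genes.

    The null keeps which genes match the pattern but shuffles gene order
    within every contig (preserving contig length structure), then re-calls
    clusters; ``p = (1 + #permutations with max run >= observed) /
    (1 + n_permutations)``.  Returns ``(p_value, observed_max_run)``.
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    if not isinstance(proteins, Mapping):
        proteins = {p.protein_id: p for p in proteins}
    matching = set(genes_matching_pattern(barcodes, query))

    # group all genes by contig, flag matching ones
    contigs: Dict[Tuple[str, str], List[str]] = {}
    for pid, rec in proteins.items():
        contigs.setdefault((rec.strain_id, rec.contig_id), []).append(pid)
    for key in contigs:
        contigs[key].sort(key=lambda pid: proteins[pid].gene_index)

    def max_run(flag_lists: List[np.ndarray]) -> int:
        best = 0
        for flags in flag_lists:
            run = 0
            gap = 0
            for f in flags:
                if f:
                    run += 1  # gaps interrupt but do not count as members
                    gap = 0
                    best = max(best, run)
                else:
                    gap += 1
                    if gap > query.max_gap:
                        run = 0
                        gap = 0
        return best

    flag_lists = [
        np.array([pid in matching for pid in pids]) for pids in contigs.values()
    ]
    observed = max_run(flag_lists)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        permuted = [rng.permutation(flags) for flags in flag_lists]
        if max_run(permuted) >= observed:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_permutations)
    return p_value, observed
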