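"""Protein similarity, 50/50-rule gene families, BBH orthologs and barcodes.

The comparative-genomics side of the workflow reduces a set of bacterial
proteomes to two complementary summaries:

* **gene families** — single-linkage components under the 50/50 rule
  (pairwise identity > 50% over at least 50% of the longer gene), giving
  pan/core/singleton family counts;
* **1:1 ortholog groups** — conservative non-greedy bidirectional best hits
  (BBH) in every ordered proteome pair, from which each protein receives a
  fixed-width presence/absence *barcode* across strains.  These barcodes are
  the genomic patterns that metabolite distributions are matched against.

Alignments come either from the builtin Smith–Waterman engine (BLOSUM62,
affine gaps, shared k-mer prefilter) or from external 12-column tabular
reports (the classic BLAST ``outfmt 6`` dialect).
"""

from __future__ import annotations

import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import networkx as nx
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "ProteinRecord",
    "PairwiseHit",
    "FamilyParams",
    "read_proteome_fasta",
    "write_proteome_fasta",
    "pairwise_hits",
    "all_pairwise_hits",
    "parse_tabular_hits",
    "blastp_hits",
    "build_families",
    "family_summary",
    "bbh_orthologs",
    "clade_shared_counts",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein with its genomic address (contig + ordinal index)."""

    strain_id: str
    contig_id: str
    gene_index: int
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if self.gene_index < 0:
            raise ValueError("gene_index must be non-negative")
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in {self.protein_id}")


@dataclass(frozen=True)
class PairwiseHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent identity out of [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment length must be >= 1")


@dataclass(frozen=True)
class FamilyParams:
    """50/50 family rule: identity strictly > ``min_identity`` percent over at
    least ``min_coverage_of_longest`` of the longer gene's length."""

    min_identity: float = 50.0
    min_coverage_of_longest: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 100.0):
            raise ValueError("min_identity must be in (0, 100]")
        if not (0.0 < self.min_coverage_of_longest <= 1.0):
            raise ValueError("min_coverage_of_longest must be in (0, 1]")


# ---------------------------------------------------------------------------
# FASTA I/O (headers: strain|contig|gene_index|protein_id)

def read_proteome_fasta(path: str | Path) -> List[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) != 4:
            raise ValueError(
                f"header {rec.id!r} is not strain|contig|gene_index|protein_id"
            )
        strain, contig, gene_index, protein_id = fields
        records.append(
            ProteinRecord(strain, contig, int(gene_index), protein_id, str(rec.seq))
        )
    return records


def write_proteome_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f"{rec.strain_id}|{rec.contig_id}|{rec.gene_index}|{rec.protein_id}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Builtin alignment engine

def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _kmer_set(sequence: str, k: int) -> set:
    return {sequence[i : i + k] for i in range(len(sequence) - k + 1)}


def _align_pair(aligner: PairwiseAligner, a: ProteinRecord, b: ProteinRecord):
    alignments = aligner.align(a.sequence, b.sequence)
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    # local alignment: columns = matches + mismatches + internal gaps
    length = counts.identities + counts.mismatches + counts.internal_gaps
    identities = counts.identities
    if length == 0:
        return None
    identity = 100.0 * identities / length
    return PairwiseHit(a.protein_id, b.protein_id, identity, length, float(aln.score))


def pairwise_hits(
    proteome_a: Sequence[ProteinRecord],
    proteome_b: Sequence[ProteinRecord],
    engine: str = "builtin",
    k: int = 5,
    min_shared_kmers: int = 3,
) -> List[PairwiseHit]:
    """Local-alignment hits from each protein of A against proteome B.

    The builtin engine aligns only candidate pairs sharing at least
    ``min_shared_kmers`` length-``k`` words (a word prefilter in the spirit
    of seeded search); unrelated sequences almost never share two 5-mers, so
    the quadratic alignment cost is paid only near true homology.
    """
    if engine != "builtin":
        raise ValueError("pairwise_hits computes builtin alignments; "
                         "use parse_tabular_hits for external reports")
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be nonempty")
    aligner = _make_aligner()
    # invert B into a k-mer index
    index: Dict[str, List[int]] = defaultdict(list)
    for j, rec in enumerate(proteome_b):
        for kmer in _kmer_set(rec.sequence, k):
            index[kmer].append(j)
    hits: List[PairwiseHit] = []
    for rec_a in proteome_a:
        counts: Dict[int, int] = defaultdict(int)
        for kmer in _kmer_set(rec_a.sequence, k):
            for j in index.get(kmer, ()):
                counts[j] += 1
        for j, c in counts.items():
            if c < min_shared_kmers:
                continue
            rec_b = proteome_b[j]
            if rec_a.protein_id == rec_b.protein_id:
                continue
            hit = _align_pair(aligner, rec_a, rec_b)
            if hit is not None:
                hits.append(hit)
    return hits


def all_pairwise_hits(
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    engine: str = "builtin",
    **kwargs,
) -> List[PairwiseHit]:
    """Hits for every ordered strain pair (A→B and B→A), self-pairs excluded.

    Local alignment is symmetric, so each unordered pair is aligned once and
    the reverse hit mirrored, halving the alignment cost.
    """
    strains = sorted(proteomes)
    hits: List[PairwiseHit] = []
    for i, qa in enumerate(strains):
        for qb in strains[i + 1 :]:
            forward = pairwise_hits(proteomes[qa], proteomes[qb], engine, **kwargs)
            hits.extend(forward)
            hits.extend(
                PairwiseHit(h.subject_id, h.query_id, h.percent_identity,
                            h.alignment_length, h.score)
                for h in forward
            )
    return hits


def parse_tabular_hits(lines: "Iterable[str] | str | Path") -> List[PairwiseHit]:
    """Parse a 12-column tabular alignment report (outfmt-6 dialect).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Malformed lines raise with the line number.
    """
    if isinstance(lines, (str, Path)):
        lines = Path(lines).read_text().splitlines()
    hits = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ValueError(f"line {lineno}: expected 12 columns, got {len(fields)}")
        try:
            hits.append(
                PairwiseHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    score=float(fields[11]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return hits


def blastp_hits(
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    evalue: float = 1e-5,
) -> List[PairwiseHit]:
    """All-vs-all hits via an external ``blastp`` binary (if on PATH).

    Convenience adapter for running the same analysis with BLAST instead of
    the builtin engine; self-hits are removed so downstream logic matches.
    """
    records = [rec for recs in proteomes.values() for rec in recs]
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "all.faa"
        with open(fasta, "w") as fh:
            for rec in records:
                fh.write(f">{rec.protein_id}\n{rec.sequence}\n")
        db = Path(tmp) / "db"
        subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "prot", "-out", str(db)],
            check=True, capture_output=True,
        )
        out = Path(tmp) / "hits.tsv"
        subprocess.run(
            ["blastp", "-query", str(fasta), "-db", str(db), "-outfmt", "6",
             "-evalue", str(evalue), "-out", str(out)],
            check=True, capture_output=True,
        )
        hits = parse_tabular_hits(out)
    return [h for h in hits if h.query_id != h.subject_id]


# ---------------------------------------------------------------------------
# 50/50 gene families

def build_families(
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    hits: Sequence[PairwiseHit],
    params: FamilyParams | None = None,
) -> List[List[str]]:
    """Partition all proteins into gene families under the 50/50 rule.

    Two genes are linked when identity is strictly greater than
    ``min_identity`` and the alignment spans at least
    ``min_coverage_of_longest`` of the longer full sequence; families are the
    connected components (single linkage).  Every protein appears in exactly
    one family; proteins with no qualifying hit form singleton families.
    Families are returned with members sorted, ordered by first member.
    """
    params = params or FamilyParams()
    lengths = {
        rec.protein_id: len(rec.sequence)
        for recs in proteomes.values()
        for rec in recs
    }
    graph = nx.Graph()
    graph.add_nodes_from(lengths)
    for hit in hits:
        if hit.query_id not in lengths or hit.subject_id not in lengths:
            raise ValueError(f"hit references unknown protein {hit.query_id}/{hit.subject_id}")
        longest = max(lengths[hit.query_id], lengths[hit.subject_id])
        if (
            hit.percent_identity > params.min_identity
            and hit.alignment_length >= params.min_coverage_of_longest * longest
        ):
            graph.add_edge(hit.query_id, hit.subject_id)
    families = [sorted(c) for c in nx.connected_components(graph)]
    return sorted(families, key=lambda fam: fam[0])


def family_summary(
    families: Sequence[Sequence[str]],
    proteomes: Mapping[str, Sequence[ProteinRecord]],
) -> Dict[str, int]:
    """Pan/core/singleton family counts for a family partition."""
    strain_of = {
        rec.protein_id: strain
        for strain, recs in proteomes.items()
        for rec in recs
    }
    n_strains = len(proteomes)
    core = singleton = 0
    for fam in families:
        strains = {strain_of[p] for p in fam}
        if len(strains) == n_strains:
            core += 1
        if len(strains) == 1:
            singleton += 1
    return {"pan": len(families), "core": core, "singleton": singleton}


# ---------------------------------------------------------------------------
# Bidirectional best hits, barcodes, 1:1 ortholog groups

def _best_hits_by_strain(
    hits: Sequence[PairwiseHit],
    strain_of: Mapping[str, str],
) -> Dict[Tuple[str, str], str | None]:
    """(query protein, subject strain) -> best-scoring subject, None on ties.

    Exact score ties yield no best hit (non-greedy, conservative pairing).
    """
    best: Dict[Tuple[str, str], Tuple[float, str | None]] = {}
    for hit in hits:
        key = (hit.query_id, strain_of[hit.subject_id])
        cur = best.get(key)
        if cur is None or hit.score > cur[0]:
            best[key] = (hit.score, hit.subject_id)
        elif hit.score == cur[0] and hit.subject_id != cur[1]:
            best[key] = (hit.score, None)
    return {key: subject for key, (_, subject) in best.items()}


def bbh_orthologs(
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    hits: Sequence[PairwiseHit],
    min_identity: float = 30.0,
    min_coverage: float = 0.5,
) -> Tuple[Dict[str, str], List[Dict[str, str]]]:
    """Per-protein presence barcodes and full 1:1 ortholog groups.

    Returns ``(barcodes, groups)`` where ``barcodes`` maps each protein id to
    a bit string over strains in sorted strain order (a protein's own strain
    bit is always set; bit for strain B is set iff the protein has a BBH in
    B), and ``groups`` is the list of full 1:1 ortholog groups: one protein
    per strain, every pair of which is a mutual BBH (a clique), mapping
    strain id -> protein id.

    Hits below ``min_identity`` percent, or spanning less than
    ``min_coverage`` of the longer sequence, are ignored: when a genuine
    ortholog is absent, the best remaining hit is typically a short
    twilight-zone local alignment to an unrelated protein, and two such
    accidents are readily reciprocal.  The floors keep those from inflating
    barcodes.
    """
    strains = sorted(proteomes)
    lengths = {
        rec.protein_id: len(rec.sequence)
        for recs in proteomes.values()
        for rec in recs
    }
    hits = [
        h for h in hits
        if h.percent_identity >= min_identity
        and h.alignment_length
        >= min_coverage * max(lengths[h.query_id], lengths[h.subject_id])
    ]
    strain_index = {s: i for i, s in enumerate(strains)}
    strain_of = {
        rec.protein_id: strain
        for strain, recs in proteomes.items()
        for rec in recs
    }
    best = _best_hits_by_strain(hits, strain_of)

    def bbh(protein: str, other_strain: str) -> str | None:
        q = best.get((protein, other_strain))
        if q is None:
            return None
        back = best.get((q, strain_of[protein]))
        return q if back == protein else None

    barcodes: Dict[str, str] = {}
    partner: Dict[Tuple[str, str], str | None] = {}
    for strain, recs in proteomes.items():
        for rec in recs:
            bits = ["0"] * len(strains)
            bits[strain_index[strain]] = "1"
            for other in strains:
                if other == strain:
                    continue
                mate = bbh(rec.protein_id, other)
                partner[(rec.protein_id, other)] = mate
                if mate is not None:
                    bits[strain_index[other]] = "1"
            barcodes[rec.protein_id] = "".join(bits)

    # full 1:1 groups: follow the BBH map out of the first strain and demand
    # clique consistency across every ordered pair
    groups: List[Dict[str, str]] = []
    anchor = strains[0]
    for rec in sorted(proteomes[anchor], key=lambda r: r.protein_id):
        if barcodes[rec.protein_id].count("1") != len(strains):
            continue
        members = {anchor: rec.protein_id}
        for other in strains[1:]:
            mate = partner[(rec.protein_id, other)]
            if mate is None:
                break
            members[other] = mate
        if len(members) != len(strains):
            continue
        consistent = all(
            partner.get((members[a], b)) == members[b]
            for a in strains
            for b in strains
            if a != b and (a != anchor)
        )
        if consistent:
            groups.append(members)
    return barcodes, groups


# ---------------------------------------------------------------------------
# Clade-shared gene counts (icicle-plot data)

def _hierarchy_nodes(hierarchy) -> List[Tuple[str, ...]]:
    """Flatten a nested strain hierarchy into per-node strain sets.

    ``hierarchy`` is either a strain id (leaf) or a sequence of subtrees.
    Returns sorted strain tuples, parents before children.
    """
    nodes: List[Tuple[str, ...]] = []

    def visit(node) -> Tuple[str, ...]:
        if isinstance(node, str):
            leaf = (node,)
            nodes.append(leaf)
            return leaf
        strains: List[str] = []
        child_sets = [visit(child) for child in node]
        for cs in child_sets:
            strains.extend(cs)
        this = tuple(sorted(strains))
        nodes.append(this)
        return this

    visit(hierarchy)
    # parents before children, deduplicated
    seen = set()
    ordered = []
    for node in sorted(nodes, key=len, reverse=True):
        if node not in seen:
            seen.add(node)
            ordered.append(node)
    return ordered


def clade_shared_counts(
    barcodes: Mapping[str, str],
    protein_strains: Mapping[str, str],
    strain_ids: Sequence[str],
    hierarchy,
) -> Dict[Tuple[str, ...], int]:
    """Count ortholog groups shared by exactly each hierarchy node's strain set.

    A group is counted once: via its representative protein in the
    lexicographically first strain of the shared set (each member of a
    consistent group carries the same barcode, so any representative would
    give the same count).
    """
    strains = sorted(strain_ids)
    counts: Dict[Tuple[str, ...], int] = {
        node: 0 for node in _hierarchy_nodes(hierarchy)
    }
    for protein, bits in barcodes.items():
        if len(bits) != len(strains):
            raise ValueError(f"barcode width mismatch for {protein}")
        shared = tuple(s for s, b in zip(strains, bits) if b == "1")
        if not shared or protein_strains[protein] != shared[0]:
            continue
        if shared in counts:
            counts[shared] += 1
    return counts
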