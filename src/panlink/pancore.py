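"""Pan/core accumulation analysis over strains × entities presence matrices.

The same machinery serves the genomic side (strains × gene families) and the
metabolomic side (strains × molecular features): a pan curve (cumulative
union), a core curve (cumulative intersection), per-position new-entity
counts, singleton/core fractions, and the strain-coverage search used to
pick maximally orthogonal strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "PresenceMatrix",
    "PanCoreResult",
    "pan_core",
    "cluster_order",
    "unique_and_shared_fractions",
    "subset_coverage",
    "best_pair_coverage",
]


@dataclass
class PresenceMatrix:
    """Boolean strains × entities matrix, the shared currency of both -omes."""

    strain_ids: List[str]
    entity_ids: List[str]
    bits: np.ndarray  # shape (n_strains, n_entities), bool

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ValueError("duplicate strain ids")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity ids")
        if self.bits.shape != (len(self.strain_ids), len(self.entity_ids)):
            raise ValueError(
                f"bits shape {self.bits.shape} inconsistent with "
                f"{len(self.strain_ids)} strains x {len(self.entity_ids)} entities"
            )

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    def row(self, strain_id: str) -> np.ndarray:
        return self.bits[self.strain_ids.index(strain_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bits, index=self.strain_ids, columns=self.entity_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PresenceMatrix":
        return cls(
            strain_ids=[str(i) for i in frame.index],
            entity_ids=[str(c) for c in frame.columns],
            bits=frame.to_numpy(dtype=bool),
        )

    @classmethod
    def from_patterns(
        cls, patterns: Dict[str, str], strain_ids: Sequence[str]
    ) -> "PresenceMatrix":
        """Build from entity -> bit-string (one character per strain)."""
        entity_ids = list(patterns)
        bits = np.zeros((len(strain_ids), len(entity_ids)), dtype=bool)
        for j, eid in enumerate(entity_ids):
            pattern = patterns[eid]
            if len(pattern) != len(strain_ids):
                raise ValueError(f"pattern width mismatch for {eid}")
            bits[:, j] = [c == "1" for c in pattern]
        return cls(list(strain_ids), entity_ids, bits)


@dataclass
class PanCoreResult:
    order: List[str]
    pan_curve: List[int]
    core_curve: List[int]
    new_counts: List[int]
    unique_per_strain: Dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.order) + 1),
                "strain_id": self.order,
                "pan": self.pan_curve,
                "core": self.core_curve,
                "new": self.new_counts,
            }
        )


def pan_core(matrix: PresenceMatrix, order: Sequence[str] | None = None) -> PanCoreResult:
    """Pan/core accumulation curves for a given strain ordering.

    ``pan[i]`` is the size of the union of the first ``i+1`` strains' entity
    sets, ``core[i]`` the size of their intersection, and ``new[i]`` the
    increment ``pan[i] - pan[i-1]`` (the bars of an accumulation plot).
    """
    if order is None:
        order = cluster_order(matrix) if matrix.n_strains > 1 else list(matrix.strain_ids)
    if sorted(order) != sorted(matrix.strain_ids):
        raise ValueError("order must be a permutation of the matrix strain ids")
    idx = [matrix.strain_ids.index(s) for s in order]
    union = np.zeros(matrix.n_entities, dtype=bool)
    inter = np.ones(matrix.n_entities, dtype=bool)
    pan, core, new = [], [], []
    for i in idx:
        prev = int(union.sum())
        union |= matrix.bits[i]
        inter &= matrix.bits[i]
        pan.append(int(union.sum()))
        core.append(int(inter.sum()))
        new.append(pan[-1] - prev)
    unique = _unique_per_strain(matrix)
    return PanCoreResult(list(order), pan, core, new, unique)


def _unique_per_strain(matrix: PresenceMatrix) -> Dict[str, int]:
    singleton = matrix.bits.sum(axis=0) == 1
    return {
        strain: int((matrix.bits[i] & singleton).sum())
        for i, strain in enumerate(matrix.strain_ids)
    }


def cluster_order(
    matrix: PresenceMatrix,
    distance: str = "jaccard",
    linkage_method: str = "average",
) -> List[str]:
    """Dendrogram leaf order of strains clustered on their presence profiles.

    Strains are sorted lexicographically before computing distances so the
    result is invariant to the input row order (ties in the dendrogram are
    then broken deterministically by strain id).
    """
    if matrix.n_strains < 2:
        raise ValueError("need at least two strains to cluster")
    if distance not in ("jaccard", "manhattan"):
        raise ValueError(f"unsupported distance {distance!r}")
    if linkage_method not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    order_ids = sorted(matrix.strain_ids)
    rows = np.array([matrix.row(s) for s in order_ids], dtype=bool)
    metric = "jaccard" if distance == "jaccard" else "cityblock"
    dists = pdist(rows.astype(float), metric=metric)
    tree = linkage(dists, method=linkage_method)
    leaves = leaves_list(tree)
    return [order_ids[i] for i in leaves]


def unique_and_shared_fractions(
    matrix: PresenceMatrix,
) -> Tuple[float, float, Dict[str, int]]:
    """(core fraction, unique fraction, per-strain unique counts).

    Core fraction = entities present in every strain / all entities; unique
    fraction = entities with exactly one set bit / all entities.
    """
    if matrix.n_entities == 0:
        raise ValueError("empty matrix")
    presence_counts = matrix.bits.sum(axis=0)
    core = float((presence_counts == matrix.n_strains).mean())
    unique = float((presence_counts == 1).mean())
    return core, unique, _unique_per_strain(matrix)


def subset_coverage(
    matrix: PresenceMatrix,
    subset: Iterable[str],
    reference_entities: Sequence[str] | None = None,
) -> float:
    """Fraction of reference entities covered by at least one subset strain."""
    subset = list(subset)
    unknown = set(subset) - set(matrix.strain_ids)
    if unknown:
        raise ValueError(f"unknown strains {sorted(unknown)}")
    if reference_entities is None:
        reference_entities = matrix.entity_ids
    if len(reference_entities) == 0:
        raise ValueError("empty reference entity set")
    col_index = {e: j for j, e in enumerate(matrix.entity_ids)}
    cols = [col_index[e] for e in reference_entities]
    if not subset:
        return 0.0
    rows = [matrix.strain_ids.index(s) for s in subset]
    covered = matrix.bits[np.ix_(rows, cols)].any(axis=0)
    return float(covered.mean())


def best_pair_coverage(
    matrix: PresenceMatrix, reference_entities: Sequence[str] | None = None
) -> Tuple[Tuple[str, str], float]:
    """Exhaustive search for the strain pair covering most reference entities.

    Ties are broken by lexicographic pair order, mirroring the exercise of
    selecting two maximally orthogonal strains for follow-up chemistry.
    """
    best_pair, best_cov = None, -1.0
    for a, b in combinations(sorted(matrix.strain_ids), 2):
        cov = subset_coverage(matrix, [a, b], reference_entities)
        if cov > best_cov:
            best_pair, best_cov = (a, b), cov
    if best_pair is None:
        raise ValueError("need at least two strains")
    return best_pair, best_cov
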