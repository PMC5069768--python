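"""MS/MS molecular networking with a modified cosine score.

Two fragmentation spectra of structural analogues share many fragment ions,
some at identical m/z and some offset by exactly the precursor mass
difference (the part of the molecule carrying the modification).  The
modified cosine allows both match types, scores the best one-to-one peak
pairing on square-root-transformed intensities, and molecular families are
the connected components of the thresholded similarity graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import networkx as nx
import numpy as np
from pyteomics import mgf as _mgf
from scipy.optimize import linear_sum_assignment

__all__ = [
    "FragmentSpectrum",
    "NetworkParams",
    "modified_cosine",
    "build_network",
    "annotate_nodes",
    "read_mgf",
    "write_mgf",
    "write_edge_list",
    "write_graphml",
]


@dataclass
class FragmentSpectrum:
    spectrum_id: str
    precursor_mz: float
    peaks: List[Tuple[float, float]]  # (m/z, intensity), sorted by m/z
    charge: int = 1
    rt: float = 0.0
    strain_id: str | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)
        if any(i <= 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be positive")

    @property
    def mzs(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


@dataclass(frozen=True)
class NetworkParams:
    cosine_threshold: float = 0.7
    fragment_tol: float = 0.3
    min_matched_peaks: int = 6
    intensity_transform: str = "sqrt"

    def __post_init__(self) -> None:
        if not (0.0 <= self.cosine_threshold <= 1.0):
            raise ValueError("cosine threshold must be in [0, 1]")
        if self.intensity_transform not in ("sqrt", "none"):
            raise ValueError("intensity transform must be 'sqrt' or 'none'")


def _transform(intensities: np.ndarray, how: str) -> np.ndarray:
    return np.sqrt(intensities) if how == "sqrt" else intensities.astype(float)


def _candidate_pairs(
    s1: FragmentSpectrum, s2: FragmentSpectrum, tol: float
) -> List[Tuple[int, int]]:
    """Peak index pairs matchable directly or via the precursor mass shift."""
    delta = s1.precursor_mz - s2.precursor_mz
    pairs = []
    for i, (mz1, _) in enumerate(s1.peaks):
        for j, (mz2, _) in enumerate(s2.peaks):
            if abs(mz1 - mz2) <= tol or abs(mz1 - (mz2 + delta)) <= tol:
                pairs.append((i, j))
    return pairs


def modified_cosine(
    s1: FragmentSpectrum,
    s2: FragmentSpectrum,
    params: NetworkParams | None = None,
    method: str = "greedy",
) -> Tuple[float, int]:
    """Modified cosine similarity and the number of matched peak pairs.

    ``method='greedy'`` takes candidate pairs in descending intensity-product
    order, each peak used at most once (classic networking behaviour);
    ``method='optimal'`` solves the maximum-weight one-to-one assignment
    exactly and serves as the oracle for the greedy path.
    """
    params = params or NetworkParams()
    if not s1.peaks or not s2.peaks:
        raise ValueError("spectra must be nonempty")
    t1 = _transform(s1.intensities, params.intensity_transform)
    t2 = _transform(s2.intensities, params.intensity_transform)
    norm = math.sqrt(float(t1 @ t1)) * math.sqrt(float(t2 @ t2))
    pairs = _candidate_pairs(s1, s2, params.fragment_tol)
    if not pairs or norm == 0:
        return 0.0, 0
    if method == "greedy":
        ranked = sorted(
            pairs, key=lambda ij: (-t1[ij[0]] * t2[ij[1]], ij[0], ij[1])
        )
        used1: set = set()
        used2: set = set()
        total = 0.0
        matched = 0
        for i, j in ranked:
            if i in used1 or j in used2:
                continue
            used1.add(i)
            used2.add(j)
            total += t1[i] * t2[j]
            matched += 1
    elif method == "optimal":
        profit = np.zeros((len(s1.peaks), len(s2.peaks)))
        for i, j in pairs:
            profit[i, j] = t1[i] * t2[j]
        rows, cols = linear_sum_assignment(profit, maximize=True)
        total = 0.0
        matched = 0
        for i, j in zip(rows, cols):
            if profit[i, j] > 0:
                total += profit[i, j]
                matched += 1
    else:
        raise ValueError(f"unknown pairing method {method!r}")
    score = min(total / norm, 1.0)
    return float(score), matched


def build_network(
    spectra: Sequence[FragmentSpectrum],
    params: NetworkParams | None = None,
) -> Tuple[nx.Graph, List[List[str]], List[str]]:
    """Threshold the pairwise modified-cosine graph into molecular families.

    Returns ``(graph, families, singletons)``: the graph holds every
    spectrum as a node with retained edges (score strictly above the cosine
    threshold and enough matched peaks); families are connected components
    with at least two members (sorted); remaining nodes are singletons.
    """
    params = params or NetworkParams()
    if len(spectra) < 2:
        raise ValueError("need at least two spectra")
    ids = [s.spectrum_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate spectrum ids")
    graph = nx.Graph()
    for s in spectra:
        graph.add_node(
            s.spectrum_id, precursor_mz=s.precursor_mz, strain_id=s.strain_id
        )
    ordered = sorted(spectra, key=lambda s: s.spectrum_id)
    for a_idx in range(len(ordered)):
        for b_idx in range(a_idx + 1, len(ordered)):
            s1, s2 = ordered[a_idx], ordered[b_idx]
            score, matched = modified_cosine(s1, s2, params)
            if score > params.cosine_threshold and matched >= params.min_matched_peaks:
                graph.add_edge(
                    s1.spectrum_id,
                    s2.spectrum_id,
                    cosine=round(score, 6),
                    matched_peaks=matched,
                    delta_mz=round(s1.precursor_mz - s2.precursor_mz, 4),
                )
    components = [sorted(c) for c in nx.connected_components(graph)]
    families = sorted([c for c in components if len(c) >= 2])
    singletons = sorted(n for c in components if len(c) == 1 for n in c)
    return graph, families, singletons


def annotate_nodes(
    graph: nx.Graph,
    presence: Dict[str, str],
    spectrum_features: Dict[str, str],
    n_strains: int,
) -> List[str]:
    """Label network nodes core/shared/unique by their feature's strain span.

    ``presence`` maps feature id -> presence bit string; ``spectrum_features``
    maps spectrum id -> feature id.  Spectra with no matching feature are
    labeled ``unknown`` and returned as warnings.
    """
    warnings = []
    for node in graph.nodes:
        feature = spectrum_features.get(node)
        bits = presence.get(feature) if feature is not None else None
        if bits is None:
            graph.nodes[node]["presence_class"] = "unknown"
            warnings.append(node)
            continue
        count = bits.count("1")
        if count == n_strains:
            label = "core"
        elif count == 1:
            label = "unique"
        else:
            label = "shared"
        graph.nodes[node]["presence_class"] = label
        graph.nodes[node]["presence"] = bits
    return warnings


# ---------------------------------------------------------------------------
# I/O

def read_mgf(path: str | Path) -> List[FragmentSpectrum]:
    spectra = []
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            charge = int(params["charge"][0]) if "charge" in params else 1
            spectra.append(
                FragmentSpectrum(
                    spectrum_id=str(params.get("title", f"scan{len(spectra)}")),
                    precursor_mz=float(params["pepmass"][0]),
                    peaks=list(zip(entry["m/z array"], entry["intensity array"])),
                    charge=charge,
                    rt=rt,
                    strain_id=params.get("strain") or None,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[FragmentSpectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        params = {
            "title": s.spectrum_id,
            "pepmass": s.precursor_mz,
            "charge": s.charge,
            "rtinseconds": round(s.rt * 60.0, 3),
        }
        if s.strain_id:
            params["strain"] = s.strain_id
        entries.append(
            {
                "params": params,
                "m/z array": s.mzs,
                "intensity array": s.intensities,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """GraphML export (node attributes preserved; None strain ids dropped)."""
    clean = graph.copy()
    for _, data in clean.nodes(data=True):
        for key in [k for k, v in data.items() if v is None]:
            del data[key]
    nx.write_graphml(clean, str(path))


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Cytoscape-importable TSV edge list."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tcosine\tmatched_peaks\tdelta_mz\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{data['cosine']}\t{data['matched_peaks']}\t{data['delta_mz']}\n"
            )
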