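"""Untargeted-metabolomics feature processing into a presence matrix.

Raw per-sample feature lists (neutral mass, retention time, intensity) are
blank-subtracted against medium controls, aligned across samples by
single-linkage within mass (ppm) and retention-time tolerances, merged
across ESI+/ESI- ionisation modes, and optionally reduced to the N most
intense features.  The end product is a strains × features boolean
``PresenceMatrix``, directly comparable to the gene-family presence matrix
of the genomic side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .pancore import PresenceMatrix

__all__ = [
    "AlignmentParams",
    "AlignedFeatureTable",
    "read_feature_table",
    "subtract_blanks",
    "align_features",
    "merge_modes",
    "top_n_by_intensity",
]

logger = logging.getLogger(__name__)

RAW_COLUMNS = ["sample_id", "strain_id", "replicate", "mode", "neutral_mass", "rt", "intensity"]


@dataclass(frozen=True)
class AlignmentParams:
    """Mass/RT matching tolerances and the per-strain presence rule.

    ``presence_rule='any_replicate'`` marks a strain as producing a feature
    when any of its replicate extracts contains it; ``'all_replicates'``
    requires every replicate.
    """

    mass_tol_ppm: float = 20.0
    rt_tol: float = 0.2  # minutes
    presence_rule: str = "any_replicate"

    def __post_init__(self) -> None:
        if self.mass_tol_ppm <= 0 or self.rt_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.presence_rule not in ("any_replicate", "all_replicates"):
            raise ValueError(f"unknown presence rule {self.presence_rule!r}")


@dataclass
class AlignedFeatureTable:
    """Aligned features with per-sample intensities and strain presence."""

    features: pd.DataFrame  # index feature_id; columns neutral_mass, rt, mode
    intensities: pd.DataFrame  # features x samples (NaN = absent)
    presence: PresenceMatrix  # strains x features

    @property
    def feature_ids(self) -> List[str]:
        return list(self.features.index)

    def __len__(self) -> int:
        return len(self.features)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format feature CSV/TSV (columns as in RAW_COLUMNS)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep)
    missing = set(RAW_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"feature table {path} missing columns {sorted(missing)}")
    return table


def _match_any(
    masses: np.ndarray,
    rts: np.ndarray,
    ref_masses: np.ndarray,
    ref_rts: np.ndarray,
    params: AlignmentParams,
) -> np.ndarray:
    """Boolean mask: does each (mass, rt) match any reference within tolerance?"""
    if len(ref_masses) == 0:
        return np.zeros(len(masses), dtype=bool)
    order = np.argsort(ref_masses)
    ref_masses = ref_masses[order]
    ref_rts = ref_rts[order]
    out = np.zeros(len(masses), dtype=bool)
    for k, (m, rt) in enumerate(zip(masses, rts)):
        tol = params.mass_tol_ppm * 1e-6 * m
        lo = np.searchsorted(ref_masses, m - tol * 1.001, side="left")
        hi = np.searchsorted(ref_masses, m + tol * 1.001, side="right")
        for idx in range(lo, hi):
            pair_tol = params.mass_tol_ppm * 1e-6 * max(m, ref_masses[idx])
            if abs(m - ref_masses[idx]) <= pair_tol and abs(rt - ref_rts[idx]) <= params.rt_tol:
                out[k] = True
                break
    return out


def subtract_blanks(
    features: pd.DataFrame,
    blank_features: pd.DataFrame,
    params: AlignmentParams | None = None,
) -> pd.DataFrame:
    """Remove features matching a medium-blank feature in mass and RT.

    Idempotent: removing blanks twice removes nothing further.
    """
    params = params or AlignmentParams()
    if len(blank_features) == 0 or len(features) == 0:
        return features.copy()
    is_blank = _match_any(
        features["neutral_mass"].to_numpy(float),
        features["rt"].to_numpy(float),
        blank_features["neutral_mass"].to_numpy(float),
        blank_features["rt"].to_numpy(float),
        params,
    )
    removed = int(is_blank.sum())
    logger.info("blank subtraction removed %d of %d feature rows", removed, len(features))
    return features.loc[~is_blank].copy()


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _group_rows(
    masses: np.ndarray, rts: np.ndarray, params: AlignmentParams
) -> np.ndarray:
    """Single-linkage component label per row under mass/RT tolerances."""
    n = len(masses)
    order = np.argsort(masses, kind="stable")
    uf = _UnionFind(n)
    sorted_masses = masses[order]
    for a in range(n):
        m_a = sorted_masses[a]
        for b in range(a + 1, n):
            m_b = sorted_masses[b]
            tol = params.mass_tol_ppm * 1e-6 * max(m_a, m_b)
            if m_b - m_a > tol:
                break
            if abs(rts[order[a]] - rts[order[b]]) <= params.rt_tol:
                uf.union(order[a], order[b])
    labels = np.array([uf.find(i) for i in range(n)])
    return labels


def align_features(
    samples: "pd.DataFrame | Sequence[pd.DataFrame]",
    params: AlignmentParams | None = None,
    strain_ids: Sequence[str] | None = None,
    feature_prefix: str = "F",
) -> AlignedFeatureTable:
    """Group per-sample feature rows into aligned cross-sample features.

    Rows are linked single-linkage whenever both the mass difference (ppm of
    the larger mass) and the RT difference fall within tolerance; each
    component becomes one feature whose mass and RT are intensity-weighted
    means of its member rows.  The per-strain presence bit follows
    ``params.presence_rule`` over that strain's replicate samples; features
    present in no strain under the rule are dropped, so the presence matrix
    has no all-zero rows.
    """
    params = params or AlignmentParams()
    if not isinstance(samples, pd.DataFrame):
        if len(samples) == 0:
            raise ValueError("need at least one sample table")
        samples = pd.concat(samples, ignore_index=True)
    table = samples.reset_index(drop=True)
    if len(table) == 0:
        raise ValueError("empty feature table")
    modes = set(table["mode"].unique())
    mode = modes.pop() if len(modes) == 1 else "mixed"

    labels = _group_rows(
        table["neutral_mass"].to_numpy(float), table["rt"].to_numpy(float), params
    )
    table = table.assign(_group=labels)

    strains = (
        sorted(strain_ids)
        if strain_ids is not None
        else sorted(table["strain_id"].unique())
    )
    replicates = {
        strain: sorted(sub["sample_id"].unique())
        for strain, sub in table.groupby("strain_id")
    }
    all_samples = sorted(table["sample_id"].unique())

    rows = []
    for _, group in table.groupby("_group"):
        weights = group["intensity"].to_numpy(float)
        wsum = weights.sum()
        mass = float((group["neutral_mass"] * weights).sum() / wsum)
        rt = float((group["rt"] * weights).sum() / wsum)
        sample_intensity = group.groupby("sample_id")["intensity"].sum()
        present_samples = set(sample_intensity.index)
        bits = []
        for strain in strains:
            reps = replicates.get(strain, [])
            if not reps:
                bits.append(False)
                continue
            hit = [r in present_samples for r in reps]
            bits.append(all(hit) if params.presence_rule == "all_replicates" else any(hit))
        rows.append((mass, rt, sample_intensity, bits, len(group)))

    rows.sort(key=lambda r: (r[0], r[1]))
    kept = [r for r in rows if any(r[3])]
    n_digits = max(4, len(str(len(kept))))
    feature_ids = [f"{feature_prefix}{i:0{n_digits}d}" for i in range(1, len(kept) + 1)]
    features = pd.DataFrame(
        {
            "neutral_mass": [r[0] for r in kept],
            "rt": [r[1] for r in kept],
            "mode": mode,
            "n_members": [r[4] for r in kept],
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    intensities = pd.DataFrame(np.nan, index=features.index, columns=all_samples)
    for fid, r in zip(feature_ids, kept):
        for sample, val in r[2].items():
            intensities.loc[fid, sample] = val
    bits = np.array([r[3] for r in kept], dtype=bool).T
    if bits.size == 0:
        bits = np.zeros((len(strains), 0), dtype=bool)
    presence = PresenceMatrix(strains, feature_ids, bits)
    return AlignedFeatureTable(features, intensities, presence)


def merge_modes(
    pos: AlignedFeatureTable,
    neg: AlignedFeatureTable,
    params: AlignmentParams | None = None,
) -> AlignedFeatureTable:
    """Collapse cross-mode feature pairs within tolerance into merged features.

    Matching is greedy on ascending mass difference and one-to-one, so
    ``len(merged) == len(pos) + len(neg) - n_matched``.  Presence bits are
    OR-ed; intensities are summed where both modes observed a sample.
    Symmetric in its two arguments up to feature_id relabeling.
    """
    params = params or AlignmentParams()
    if pos.presence.strain_ids != neg.presence.strain_ids:
        raise ValueError("mode tables cover different strain sets")
    p_mass = pos.features["neutral_mass"].to_numpy(float)
    p_rt = pos.features["rt"].to_numpy(float)
    n_mass = neg.features["neutral_mass"].to_numpy(float)
    n_rt = neg.features["rt"].to_numpy(float)

    candidates = []
    for i in range(len(p_mass)):
        tol_i = params.mass_tol_ppm * 1e-6 * p_mass[i]
        for j in range(len(n_mass)):
            tol = max(tol_i, params.mass_tol_ppm * 1e-6 * n_mass[j])
            dm = abs(p_mass[i] - n_mass[j])
            if dm <= tol and abs(p_rt[i] - n_rt[j]) <= params.rt_tol:
                candidates.append((dm, i, j))
    candidates.sort()
    matched_p: Dict[int, int] = {}
    matched_n: Dict[int, int] = {}
    for _, i, j in candidates:
        if i in matched_p or j in matched_n:
            continue
        matched_p[i] = j
        matched_n[j] = i

    all_samples = sorted(set(pos.intensities.columns) | set(neg.intensities.columns))
    strains = pos.presence.strain_ids
    rows = []
    for i in range(len(p_mass)):
        p_int = pos.intensities.iloc[i]
        p_bits = pos.presence.bits[:, i]
        if i in matched_p:
            j = matched_p[i]
            n_int = neg.intensities.iloc[j]
            combined = p_int.reindex(all_samples).fillna(0) + n_int.reindex(all_samples).fillna(0)
            combined[combined == 0] = np.nan
            w_p = np.nansum(p_int.to_numpy(float))
            w_n = np.nansum(n_int.to_numpy(float))
            mass = (p_mass[i] * w_p + n_mass[j] * w_n) / (w_p + w_n)
            rt = (p_rt[i] * w_p + n_rt[j] * w_n) / (w_p + w_n)
            rows.append((mass, rt, "merged", combined, p_bits | neg.presence.bits[:, j]))
        else:
            rows.append((p_mass[i], p_rt[i], pos.features["mode"].iloc[i],
                         p_int.reindex(all_samples), p_bits))
    for j in range(len(n_mass)):
        if j in matched_n:
            continue
        rows.append((n_mass[j], n_rt[j], neg.features["mode"].iloc[j],
                     neg.intensities.iloc[j].reindex(all_samples), neg.presence.bits[:, j]))

    rows.sort(key=lambda r: (r[0], r[1]))
    n_digits = max(4, len(str(len(rows))))
    feature_ids = [f"M{i:0{n_digits}d}" for i in range(1, len(rows) + 1)]
    features = pd.DataFrame(
        {
            "neutral_mass": [r[0] for r in rows],
            "rt": [r[1] for r in rows],
            "mode": [r[2] for r in rows],
            "n_members": 1,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    intensities = pd.DataFrame(
        [r[3].to_numpy(float) for r in rows], index=features.index, columns=all_samples
    )
    bits = np.array([r[4] for r in rows], dtype=bool).T
    presence = PresenceMatrix(list(strains), feature_ids, bits)
    logger.info(
        "mode merge: %d positive + %d negative - %d matched = %d features",
        len(pos), len(neg), len(matched_p), len(rows),
    )
    return AlignedFeatureTable(features, intensities, presence)


def top_n_by_intensity(table: AlignedFeatureTable, n: int) -> AlignedFeatureTable:
    """Keep the n features with the largest maximum intensity across samples.

    Ties break toward the lexicographically smaller feature id.  Asking for
    more features than exist returns the full table with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(table):
        logger.warning("top_n=%d exceeds table size %d; returning all", n, len(table))
        n = len(table)
    max_int = table.intensities.max(axis=1, skipna=True)
    ranked = sorted(table.feature_ids, key=lambda fid: (-max_int[fid], fid))
    keep = sorted(ranked[:n])
    features = table.features.loc[keep]
    intensities = table.intensities.loc[keep]
    cols = [table.presence.entity_ids.index(fid) for fid in keep]
    presence = PresenceMatrix(
        list(table.presence.strain_ids), keep, table.presence.bits[:, cols]
    )
    return AlignedFeatureTable(features, intensities, presence)
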