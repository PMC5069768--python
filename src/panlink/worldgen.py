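"""Seeded synthetic "planted world" generator with a ground-truth ledger.

Emulates the statistical structure of a group of closely related marine
bacterial strains profiled by draft-genome sequencing and untargeted
LC-HRMS: 13 strains in two clades with a near-clonal pair, ~5,100 genes per
strain of which roughly a third are core and a quarter singletons, ~2,000
molecular features per strain of which ~2% are core and ~30% unique, planted
biosynthetic gene clusters whose strain distribution matches a planted
metabolite family, halogenated masses placed inside the mass-defect screen
window, and fragment spectra that form molecular families under the
modified cosine.  Every planted fact is recorded in a ledger so downstream
recovery is checkable without any external data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .genefamilies import ProteinRecord, write_proteome_fasta
from .halogen import MassDefectParams, mass_defect
from .msnetwork import FragmentSpectrum, write_mgf

__all__ = ["PlantedCluster", "WorldConfig", "World", "generate_world",
           "generate_spectrum", "write_world"]

AMINO = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.frombuffer(AMINO.encode(), dtype="S1")
CH2 = 14.015650
PROTON = 1.00727646


@dataclass(frozen=True)
class PlantedCluster:
    """A biosynthetic gene cluster planted with a known strain distribution.

    ``strain_pattern`` gives the strains carrying the cluster's genes;
    ``broken_in`` lists strain indices where the cluster is present but
    non-functional (a disrupted gene), so the linked metabolite family is
    produced only in the *intact* strains (pattern minus broken).
    """

    cluster_id: str
    n_genes: int = 11
    strain_pattern: str = "1111111000000"
    n_linked_features: int = 6
    halogenated: bool = True
    broken_in: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.strain_pattern.count("1") < 1:
            raise ValueError("strain_pattern needs at least one set bit")
        if set(self.strain_pattern) - {"0", "1"}:
            raise ValueError("strain_pattern must be a bit string")
        for idx in self.broken_in:
            if idx >= len(self.strain_pattern) or self.strain_pattern[idx] != "1":
                raise ValueError("broken_in strains must carry the cluster")
        if self.n_genes < 1 or self.n_linked_features < 0:
            raise ValueError("counts must be positive")

    @property
    def intact_pattern(self) -> str:
        return "".join(
            "0" if i in self.broken_in else b
            for i, b in enumerate(self.strain_pattern)
        )


def _default_clusters() -> Tuple[PlantedCluster, ...]:
    return (PlantedCluster("bmp_like"),)


@dataclass(frozen=True)
class WorldConfig:
    """Generator parameters; defaults mirror the 13-strain study conditions."""

    n_strains: int = 13
    clade_split: Tuple[Tuple[int, ...], Tuple[int, ...]] = (
        tuple(range(7)), tuple(range(7, 13))
    )
    clonal_pairs: Tuple[Tuple[int, int], ...] = ((0, 1),)
    n_core_families: int = 3322
    n_accessory_families: int = 4328
    n_singletons_per_strain: int = 179
    genes_per_contig: int = 200
    planted_clusters: Tuple[PlantedCluster, ...] = field(default_factory=_default_clusters)
    features_per_strain: int = 2000
    core_feature_fraction: float = 0.02
    unique_feature_fraction: float = 0.30
    n_halogenated_features: int = 40
    blank_features: int = 50
    mass_range: Tuple[float, float] = (150.0, 1200.0)
    rt_range: Tuple[float, float] = (0.5, 20.0)
    intensity_lognormal: Tuple[float, float] = (12.0, 1.5)
    dropout_rate: float = 0.05
    n_replicates: int = 2
    # fractions of features seen in ESI+ only / ESI- only / both modes
    mode_fractions: Tuple[float, float, float] = (0.70, 0.064, 0.236)
    ancestor_length: Tuple[int, int] = (150, 600)
    substitution_rate: float = 0.12
    accessory_gene_prob: float = 0.35
    clonal_gene_copy_prob: float = 0.99
    clonal_feature_copy_prob: float = 0.75
    clonal_singleton_factor: float = 0.1
    mass_noise_ppm: float = 2.0
    rt_noise: float = 0.02
    seed: int = 0

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "WorldConfig":
        """Scaled-down world preserving the 13-strain structure and the
        planted cluster / molecular family / halogen content, sized so the
        alignment-heavy genomic stages run in seconds."""
        params = dict(
            n_core_families=30,
            n_accessory_families=60,
            n_singletons_per_strain=3,
            genes_per_contig=40,
            features_per_strain=120,
            blank_features=15,
            ancestor_length=(120, 300),
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    def validate(self) -> None:
        if self.n_strains < 2:
            raise ValueError("need at least two strains")
        covered = sorted(i for clade in self.clade_split for i in clade)
        if covered != list(range(self.n_strains)):
            raise ValueError("clade_split must cover every strain exactly once")
        for frac in (
            self.core_feature_fraction,
            self.unique_feature_fraction,
            self.dropout_rate,
            self.accessory_gene_prob,
            self.clonal_gene_copy_prob,
            self.clonal_feature_copy_prob,
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("proportions must lie in [0, 1]")
        if self.core_feature_fraction + self.unique_feature_fraction > 1.0:
            raise ValueError("core + unique feature fractions exceed 1")
        for cluster in self.planted_clusters:
            if len(cluster.strain_pattern) != self.n_strains:
                raise ValueError(
                    f"cluster {cluster.cluster_id}: pattern width "
                    f"{len(cluster.strain_pattern)} != {self.n_strains} strains"
                )
            if cluster.n_genes > self.genes_per_contig:
                raise ValueError(
                    f"cluster {cluster.cluster_id}: {cluster.n_genes} genes cannot "
                    f"fit on one contig of {self.genes_per_contig} genes"
                )
        for a, b in self.clonal_pairs:
            if not (0 <= a < self.n_strains and 0 <= b < self.n_strains) or a == b:
                raise ValueError("invalid clonal pair")
        if self.mass_range[0] >= self.mass_range[1] or self.rt_range[0] >= self.rt_range[1]:
            raise ValueError("invalid mass or RT range")
        if self.n_replicates < 1 or self.genes_per_contig < 1:
            raise ValueError("counts must be positive")
        # sequence-space feasibility: distinct random ancestors must be available
        n_families = (
            self.n_core_families
            + self.n_accessory_families
            + self.n_strains * self.n_singletons_per_strain
            + sum(c.n_genes for c in self.planted_clusters)
        )
        if n_families > 20 ** min(6, self.ancestor_length[0]):
            raise ValueError("more families requested than sequence space supports")


@dataclass
class World:
    config: WorldConfig
    strain_ids: List[str]
    proteomes: Dict[str, List[ProteinRecord]]
    feature_rows: pd.DataFrame  # long format, biological samples, both modes
    blank_rows: pd.DataFrame  # long format, medium-blank samples
    spectra: List[FragmentSpectrum]
    ledger: Dict


# ---------------------------------------------------------------------------
# genome side

def _mutate(ancestor: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    mask = rng.random(len(ancestor)) < rate
    shifted = (ancestor + rng.integers(1, 20, size=len(ancestor))) % 20
    return np.where(mask, shifted, ancestor)


def _to_seq(arr: np.ndarray) -> str:
    return _AA_ARR[arr].tobytes().decode()


def _sample_family_patterns(config: WorldConfig, rng: np.random.Generator):
    """family_id -> bit string, plus per-cluster gene family ids."""
    n = config.n_strains
    patterns: Dict[str, str] = {}
    width = max(5, len(str(config.n_core_families + config.n_accessory_families)))
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"F{counter:0{width}d}"

    for _ in range(config.n_core_families):
        patterns[next_id()] = "1" * n
    for _ in range(config.n_accessory_families):
        while True:
            bits = rng.random(n) < config.accessory_gene_prob
            for a, b in config.clonal_pairs:
                if rng.random() < config.clonal_gene_copy_prob:
                    bits[b] = bits[a]
            k = int(bits.sum())
            if 2 <= k <= n - 1:
                break
        patterns[next_id()] = "".join("1" if b else "0" for b in bits)
    clonal_strains = {s for pair in config.clonal_pairs for s in pair}
    for i in range(n):
        count = config.n_singletons_per_strain
        if i in clonal_strains:
            count = max(1, round(count * config.clonal_singleton_factor))
        for _ in range(count):
            patterns[next_id()] = "".join("1" if j == i else "0" for j in range(n))
    cluster_genes: Dict[str, List[str]] = {}
    for cluster in config.planted_clusters:
        fam_ids = [f"{cluster.cluster_id}_g{k:02d}" for k in range(1, cluster.n_genes + 1)]
        for fid in fam_ids:
            patterns[fid] = cluster.strain_pattern
        cluster_genes[cluster.cluster_id] = fam_ids
    return patterns, cluster_genes


def _generate_proteomes(
    config: WorldConfig,
    strain_ids: List[str],
    patterns: Dict[str, str],
    cluster_genes: Dict[str, List[str]],
    rng: np.random.Generator,
) -> Dict[str, List[ProteinRecord]]:
    lo, hi = config.ancestor_length
    sequences: Dict[str, Dict[str, str]] = {}  # family -> strain -> seq
    for fid in patterns:
        length = int(rng.integers(lo, hi + 1))
        ancestor = rng.integers(0, 20, size=length)
        per_strain = {}
        for i, bit in enumerate(patterns[fid]):
            if bit == "1":
                per_strain[strain_ids[i]] = _to_seq(
                    _mutate(ancestor, config.substitution_rate, rng)
                )
        sequences[fid] = per_strain

    all_cluster_fids = {fid for fids in cluster_genes.values() for fid in fids}
    proteomes: Dict[str, List[ProteinRecord]] = {}
    for i, strain in enumerate(strain_ids):
        plain = [
            fid for fid, pat in patterns.items()
            if pat[i] == "1" and fid not in all_cluster_fids
        ]
        order = list(rng.permutation(plain))
        contigs: List[List[str]] = [
            order[j : j + config.genes_per_contig]
            for j in range(0, len(order), config.genes_per_contig)
        ] or [[]]
        for cluster in config.planted_clusters:
            if cluster.strain_pattern[i] != "1":
                continue
            fids = cluster_genes[cluster.cluster_id]
            ci = int(rng.integers(0, len(contigs)))
            offset = int(rng.integers(0, len(contigs[ci]) + 1))
            contigs[ci] = contigs[ci][:offset] + list(fids) + contigs[ci][offset:]
        records = []
        for ci, contig in enumerate(contigs):
            contig_id = f"{strain}_c{ci + 1:02d}"
            for gi, fid in enumerate(contig):
                records.append(
                    ProteinRecord(
                        strain_id=strain,
                        contig_id=contig_id,
                        gene_index=gi,
                        protein_id=f"{strain}_{fid}",
                        sequence=sequences[fid][strain],
                    )
                )
        proteomes[strain] = records
    return proteomes


# ---------------------------------------------------------------------------
# metabolome side

def _expected_popcount(config: WorldConfig) -> float:
    n = config.n_strains
    accessory_frac = 1.0 - config.core_feature_fraction - config.unique_feature_fraction
    mean_subset = 2.0 + max(n - 3, 0) * 0.25
    return (
        config.core_feature_fraction * n
        + config.unique_feature_fraction * 1.0
        + accessory_frac * mean_subset
    )


def _draw_plain_mass(
    rng: np.random.Generator,
    config: WorldConfig,
    window: MassDefectParams,
    taken: List[Tuple[float, float]],
    rt: float,
) -> float:
    """A mass outside the halogen defect window and clear of existing features."""
    for _ in range(1000):
        m = float(rng.uniform(*config.mass_range))
        defect = mass_defect(m, window.defect_definition)
        if abs(defect - window.expected_defect(m)) <= window.tolerance * 1.5:
            continue
        if _collides(m, rt, taken):
            continue
        return m
    raise RuntimeError("could not place a non-halogenated mass")


def _draw_halogen_mass(
    rng: np.random.Generator,
    config: WorldConfig,
    window: MassDefectParams,
    taken: List[Tuple[float, float]],
    rt: float,
    nominal_range: Tuple[int, int] | None = None,
) -> float:
    lo, hi = nominal_range or (
        int(config.mass_range[0]) + 1, int(config.mass_range[1]) - 1
    )
    for _ in range(1000):
        nominal = int(rng.integers(lo, hi))
        defect = window.expected_defect(float(nominal)) + float(
            rng.uniform(-0.5, 0.5) * window.tolerance
        )
        m = nominal + defect
        if not _collides(m, rt, taken):
            return m
    raise RuntimeError("could not place a halogenated mass")


def _collides(mass: float, rt: float, taken: List[Tuple[float, float]]) -> bool:
    # keep true features separable at the default alignment tolerances
    for m, r in taken:
        if abs(mass - m) < 0.05 and abs(rt - r) < 0.5:
            return True
    return False


def _assign_mode(rng: np.random.Generator, config: WorldConfig) -> Tuple[str, ...]:
    r = float(rng.random())
    p_pos, p_neg, _ = config.mode_fractions
    if r < p_pos:
        return ("positive",)
    if r < p_pos + p_neg:
        return ("negative",)
    return ("positive", "negative")


def generate_spectrum(
    formula_mass: float,
    scaffold_peaks: Sequence[Tuple[float, float]],
    analogue_shift: float,
    n_noise_peaks: int,
    seed: "int | np.random.Generator",
    shifted_indices: Sequence[int] | None = None,
    spectrum_id: str = "spec",
    rt: float = 0.0,
    strain_id: str | None = None,
) -> FragmentSpectrum:
    """Fragment spectrum of an analogue built from a family scaffold.

    The precursor is the protonated neutral mass.  Peaks listed in
    ``shifted_indices`` move by ``analogue_shift`` (the varying moiety of the
    analogue series), the rest stay put, so two analogues built from the same
    scaffold and shifted subset pair every scaffold peak under the modified
    cosine (directly or via the precursor delta).  Low-intensity noise peaks
    are added on top.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    precursor = formula_mass + PROTON
    if any(m >= precursor for m, _ in scaffold_peaks):
        raise ValueError("scaffold peaks must lie below the precursor m/z")
    if shifted_indices is None:
        shifted_indices = []
    peaks = []
    for idx, (m, inten) in enumerate(scaffold_peaks):
        mz = m + analogue_shift if idx in shifted_indices else m
        if 10.0 < mz < precursor - 1.0:
            peaks.append((mz, inten))
    for _ in range(n_noise_peaks):
        peaks.append(
            (float(rng.uniform(30.0, precursor - 5.0)), float(rng.uniform(0.01, 0.05)))
        )
    return FragmentSpectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor,
        peaks=peaks,
        rt=rt,
        strain_id=strain_id,
    )


# ---------------------------------------------------------------------------
# world assembly

def generate_world(config: WorldConfig | None = None) -> World:
    """Generate a complete planted world; deterministic for a fixed seed."""
    config = config or WorldConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_strains
    strain_ids = [f"S{i + 1:02d}" for i in range(n)]
    window = MassDefectParams()

    family_patterns, cluster_genes = _sample_family_patterns(config, rng)
    proteomes = _generate_proteomes(config, strain_ids, family_patterns, cluster_genes, rng)

    # --- feature catalogue ------------------------------------------------
    total_plain = max(
        1, round(config.features_per_strain * n / _expected_popcount(config))
    )
    n_core = round(total_plain * config.core_feature_fraction)
    n_unique = round(total_plain * config.unique_feature_fraction)
    n_accessory = total_plain - n_core - n_unique

    catalogue = []  # (feature_id, mass, rt, pattern, origin, halogenated)
    taken: List[Tuple[float, float]] = []
    counter = 0
    id_width = max(5, len(str(total_plain + 200)))

    def add_feature(pattern: str, origin: str, halogenated: bool,
                    mass: float | None = None,
                    nominal_range: Tuple[int, int] | None = None) -> str:
        nonlocal counter
        counter += 1
        fid = f"M{counter:0{id_width}d}"
        rt = float(rng.uniform(*config.rt_range))
        if mass is None:
            if halogenated:
                mass = _draw_halogen_mass(rng, config, window, taken, rt, nominal_range)
            else:
                mass = _draw_plain_mass(rng, config, window, taken, rt)
        taken.append((mass, rt))
        catalogue.append((fid, mass, rt, pattern, origin, halogenated))
        return fid

    for _ in range(n_core):
        add_feature("1" * n, "core", False)
    for _ in range(n_unique):
        strain = int(rng.integers(0, n))
        add_feature("".join("1" if j == strain else "0" for j in range(n)), "unique", False)
    for _ in range(n_accessory):
        size = 2 + int(rng.binomial(max(n - 3, 0), 0.25))
        members = set(rng.choice(n, size=min(size, n - 1), replace=False).tolist())
        bits = [i in members for i in range(n)]
        for a, b in config.clonal_pairs:
            if rng.random() < config.clonal_feature_copy_prob:
                bits[b] = bits[a]
        if not any(bits):
            bits[int(rng.integers(0, n))] = True
        add_feature("".join("1" if b else "0" for b in bits), "accessory", False)

    cluster_features: Dict[str, List[str]] = {}
    cluster_masses: Dict[str, List[float]] = {}
    for cluster in config.planted_clusters:
        fids, masses = [], []
        base = None
        for k in range(cluster.n_linked_features):
            if cluster.halogenated:
                # keep analogue masses in a band above the first member so the
                # shared fragment scaffold stays below every precursor
                nominal_range = None
                if masses:
                    nominal_range = (int(masses[0]) + 2, int(masses[0]) + 120)
                fid = add_feature(
                    cluster.intact_pattern, f"cluster:{cluster.cluster_id}", True,
                    nominal_range=nominal_range,
                )
            else:
                if base is None:
                    rt = float(rng.uniform(*config.rt_range))
                    base = _draw_plain_mass(rng, config, window, taken, rt)
                    mass = base
                else:
                    mass = base + k * CH2
                fid = add_feature(
                    cluster.intact_pattern, f"cluster:{cluster.cluster_id}", False, mass=mass
                )
            fids.append(fid)
            masses.append(catalogue[-1][1])
        cluster_features[cluster.cluster_id] = fids
        cluster_masses[cluster.cluster_id] = masses

    # extra halogenated features share the halogenated cluster's intact
    # pattern (the halogenation machinery is strain-restricted); with no such
    # cluster they fall back to accessory-style random subsets
    halogen_pattern = None
    for cluster in config.planted_clusters:
        if cluster.halogenated:
            halogen_pattern = cluster.intact_pattern
            break
    halogen_extra = []
    for _ in range(config.n_halogenated_features):
        if halogen_pattern is not None:
            pattern = halogen_pattern
        else:
            size = 2 + int(rng.binomial(max(n - 3, 0), 0.25))
            members = set(rng.choice(n, size=min(size, n - 1), replace=False).tolist())
            pattern = "".join("1" if i in members else "0" for i in range(n))
        halogen_extra.append(add_feature(pattern, "halogen_screen", True))

    blank_ids = [add_feature("1" * n, "blank", False) for _ in range(config.blank_features)]

    # --- sample rows ------------------------------------------------------
    mu, sigma = config.intensity_lognormal
    base_intensity = {fid: float(rng.lognormal(mu, sigma)) for fid, *_ in catalogue}
    modes = {fid: _assign_mode(rng, config) for fid, *_ in catalogue}

    bio_rows, blank_rows = [], []
    for fid, mass, rt, pattern, origin, _halo in catalogue:
        is_blank = origin == "blank"
        for i, strain in enumerate(strain_ids):
            if pattern[i] != "1":
                continue
            for rep in range(1, config.n_replicates + 1):
                if not is_blank and rng.random() < config.dropout_rate:
                    continue
                obs_mass = mass * (1.0 + rng.normal(0.0, config.mass_noise_ppm * 1e-6))
                obs_rt = rt + float(rng.normal(0.0, config.rt_noise))
                inten = base_intensity[fid] * float(rng.lognormal(0.0, 0.3))
                for mode in modes[fid]:
                    bio_rows.append(
                        (f"{strain}_r{rep}", strain, rep, mode, obs_mass, obs_rt, inten, fid)
                    )
        if is_blank:
            for rep in range(1, config.n_replicates + 1):
                obs_mass = mass * (1.0 + rng.normal(0.0, config.mass_noise_ppm * 1e-6))
                obs_rt = rt + float(rng.normal(0.0, config.rt_noise))
                inten = base_intensity[fid] * float(rng.lognormal(0.0, 0.3))
                for mode in modes[fid]:
                    blank_rows.append(
                        (f"BLANK_r{rep}", "BLANK", rep, mode, obs_mass, obs_rt, inten, fid)
                    )

    columns = ["sample_id", "strain_id", "replicate", "mode", "neutral_mass",
               "rt", "intensity", "true_feature_id"]
    feature_rows = pd.DataFrame(bio_rows, columns=columns)
    blank_frame = pd.DataFrame(blank_rows, columns=columns)

    # --- spectra ----------------------------------------------------------
    info = {fid: (mass, rt, pattern) for fid, mass, rt, pattern, _o, _h in catalogue}
    spectra: List[FragmentSpectrum] = []
    spectrum_features: Dict[str, str] = {}
    for cluster in config.planted_clusters:
        fids = cluster_features[cluster.cluster_id]
        if not fids:
            continue
        masses = cluster_masses[cluster.cluster_id]
        base_mass = masses[0]
        n_peaks = 10
        scaffold = sorted(
            (float(rng.uniform(50.0, base_mass * 0.8)), float(rng.uniform(0.2, 1.0)))
            for _ in range(n_peaks)
        )
        n_shift = int(rng.integers(3, 6))
        shifted = list(rng.choice(n_peaks, size=n_shift, replace=False))
        first_strain = strain_ids[cluster.intact_pattern.index("1")] \
            if "1" in cluster.intact_pattern else None
        for fid, mass in zip(fids, masses):
            sid = f"spec_{fid}"
            spectra.append(
                generate_spectrum(
                    mass, scaffold, mass - base_mass, 3, rng,
                    shifted_indices=shifted, spectrum_id=sid,
                    rt=info[fid][1], strain_id=first_strain,
                )
            )
            spectrum_features[sid] = fid
    # unrelated singleton spectra from plain features
    plain_ids = [fid for fid, _m, _r, _p, origin, _h in catalogue
                 if origin in ("core", "accessory", "unique")]
    n_noise_spectra = min(15, len(plain_ids))
    for fid in list(rng.choice(plain_ids, size=n_noise_spectra, replace=False)):
        mass, rt, pattern = info[fid]
        scaffold = sorted(
            (float(rng.uniform(50.0, mass * 0.8)), float(rng.uniform(0.2, 1.0)))
            for _ in range(8)
        )
        sid = f"spec_{fid}"
        strain = strain_ids[pattern.index("1")]
        spectra.append(
            generate_spectrum(mass, scaffold, 0.0, 3, rng,
                              spectrum_id=sid, rt=rt, strain_id=strain)
        )
        spectrum_features[sid] = fid

    world_id = hashlib.md5(
        json.dumps(_config_to_dict(config), sort_keys=True).encode()
    ).hexdigest()[:12]
    ledger = {
        "world_id": world_id,
        "strain_ids": strain_ids,
        "family_patterns": family_patterns,
        "feature_patterns": {fid: pattern for fid, _m, _r, pattern, _o, _h in catalogue},
        "feature_origin": {fid: origin for fid, _m, _r, _p, origin, _h in catalogue},
        "feature_mass": {fid: mass for fid, mass, *_ in catalogue},
        "feature_rt": {fid: rt for fid, _m, rt, *_ in catalogue},
        "halogenated_features": [fid for fid, _m, _r, _p, _o, halo in catalogue if halo],
        "blank_feature_ids": blank_ids,
        "halogen_screen_features": halogen_extra,
        "spectrum_features": spectrum_features,
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "gene_families": cluster_genes[c.cluster_id],
                "strain_pattern": c.strain_pattern,
                "intact_pattern": c.intact_pattern,
                "broken_in": list(c.broken_in),
                "halogenated": c.halogenated,
                "linked_features": cluster_features[c.cluster_id],
            }
            for c in config.planted_clusters
        ],
    }
    return World(config, strain_ids, proteomes, feature_rows, blank_frame, spectra, ledger)


# ---------------------------------------------------------------------------
# persistence

def write_world(world: World, outdir: str | Path) -> None:
    """Write the world as plain-text artifacts: FASTA, CSV, MGF, JSON, YAML."""
    outdir = Path(outdir)
    (outdir / "proteomes").mkdir(parents=True, exist_ok=True)
    for strain, records in world.proteomes.items():
        write_proteome_fasta(records, outdir / "proteomes" / f"{strain}.faa")
    for mode, tag in (("positive", "pos"), ("negative", "neg")):
        world.feature_rows[world.feature_rows["mode"] == mode].to_csv(
            outdir / f"features_{tag}.csv", index=False
        )
        world.blank_rows[world.blank_rows["mode"] == mode].to_csv(
            outdir / f"blanks_{tag}.csv", index=False
        )
    write_mgf(world.spectra, outdir / "spectra.mgf")
    with open(outdir / "ledger.json", "w") as fh:
        json.dump(world.ledger, fh, indent=1, sort_keys=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(world.config), fh, sort_keys=True)


def _config_to_dict(config: WorldConfig) -> Dict:
    raw = asdict(config)
    raw["planted_clusters"] = [asdict(c) for c in config.planted_clusters]
    return json.loads(json.dumps(raw))  # tuples -> lists for clean YAML


def config_from_dict(raw: Dict) -> WorldConfig:
    raw = dict(raw)
    clusters = tuple(
        PlantedCluster(**{**c, "broken_in": tuple(c.get("broken_in", ()))})
        for c in raw.pop("planted_clusters", [])
    )

    def tup(x):
        return tuple(tuple(i) if isinstance(i, list) else i for i in x)

    for key in ("clade_split", "clonal_pairs"):
        if key in raw:
            raw[key] = tup(raw[key])
    for key in ("mass_range", "rt_range", "intensity_lognormal", "mode_fractions",
                "ancestor_length"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return WorldConfig(planted_clusters=clusters, **raw)
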