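"""Planted-world generator: determinism, ledger consistency, identity rules."""

import numpy as np
import pytest

from panlink.genefamilies import all_pairwise_hits, pairwise_hits
from panlink.halogen import MassDefectParams, defect_window_pass
from panlink.msnetwork import NetworkParams, modified_cosine
from panlink.worldgen import (
    PlantedCluster,
    WorldConfig,
    config_from_dict,
    _config_to_dict,
    generate_spectrum,
    generate_world,
    write_world,
)


def test_fixed_seed_reproduces_world_byte_identically(tmp_path):
    config = WorldConfig.small(seed=5)
    w1 = generate_world(config)
    w2 = generate_world(WorldConfig.small(seed=5))
    assert w1.feature_rows.equals(w2.feature_rows)
    assert w1.blank_rows.equals(w2.blank_rows)
    assert w1.ledger == w2.ledger
    for strain in w1.strain_ids:
        assert w1.proteomes[strain] == w2.proteomes[strain]
    assert [(s.spectrum_id, s.peaks) for s in w1.spectra] == [
        (s.spectrum_id, s.peaks) for s in w2.spectra
    ]
    # and the on-disk artifacts agree too
    write_world(w1, tmp_path / "a")
    write_world(w2, tmp_path / "b")
    for rel in ["ledger.json", "features_pos.csv", "spectra.mgf", "config.yaml",
                "proteomes/S01.faa"]:
        assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()


def test_different_seeds_differ():
    w1 = generate_world(WorldConfig.small(seed=1))
    w2 = generate_world(WorldConfig.small(seed=2))
    assert not w1.feature_rows.equals(w2.feature_rows)


def test_clonal_pair_shares_most_gene_families(small_world):
    a, b = small_world.config.clonal_pairs[0]
    patterns = small_world.ledger["family_patterns"].values()
    both = sum(1 for p in patterns if p[a] == "1" and p[b] == "1")
    either = sum(1 for p in patterns if p[a] == "1" or p[b] == "1")
    assert both / either > 0.9


def test_ledger_cluster_consistency(small_world):
    """Strains carrying all cluster genes == strain_pattern; linked features
    present exactly in intact strains (before dropout)."""
    ledger = small_world.ledger
    for cluster in ledger["clusters"]:
        carrier_sets = []
        for fid in cluster["gene_families"]:
            carrier_sets.append(ledger["family_patterns"][fid])
        carriers = "".join(
            "1" if all(p[i] == "1" for p in carrier_sets) else "0"
            for i in range(len(small_world.strain_ids))
        )
        assert carriers == cluster["strain_pattern"]
        for fid in cluster["linked_features"]:
            assert ledger["feature_patterns"][fid] == cluster["intact_pattern"]


def test_cluster_genes_contiguous_on_one_contig(small_world):
    ledger = small_world.ledger
    for cluster in ledger["clusters"]:
        fam_ids = set(cluster["gene_families"])
        for i, bit in enumerate(cluster["strain_pattern"]):
            if bit != "1":
                continue
            strain = small_world.strain_ids[i]
            members = [
                r for r in small_world.proteomes[strain]
                if r.protein_id.split("_", 1)[1] in fam_ids
            ]
            assert len(members) == len(fam_ids)
            assert len({m.contig_id for m in members}) == 1
            indices = sorted(m.gene_index for m in members)
            assert indices == list(range(indices[0], indices[0] + len(members)))


def test_broken_cluster_suppresses_features_not_genes():
    cluster = PlantedCluster(
        "probe", n_genes=5, strain_pattern="1111100000000",
        n_linked_features=3, halogenated=False, broken_in=(3, 4),
    )
    config = WorldConfig.small(seed=9, planted_clusters=(cluster,))
    world = generate_world(config)
    entry = world.ledger["clusters"][0]
    assert entry["intact_pattern"] == "1110000000000"
    for fid in entry["linked_features"]:
        assert world.ledger["feature_patterns"][fid] == "1110000000000"
    # the genes themselves are still present in the broken strains
    for fid in entry["gene_families"]:
        assert world.ledger["family_patterns"][fid] == "1111100000000"


def test_identity_rules_by_exhaustive_alignment(tiny_world):
    """Within-family pairs satisfy the 50/50 rule; cross-family pairs fail it."""
    hits = all_pairwise_hits(tiny_world.proteomes)
    lengths = {
        r.protein_id: len(r.sequence)
        for recs in tiny_world.proteomes.values() for r in recs
    }
    fam_of = {pid: pid.split("_", 1)[1] for pid in lengths}
    truth = tiny_world.ledger["family_patterns"]
    seen_pairs = set()
    for h in hits:
        same = fam_of[h.query_id] == fam_of[h.subject_id]
        longest = max(lengths[h.query_id], lengths[h.subject_id])
        passes = h.percent_identity > 50.0 and h.alignment_length >= 0.5 * longest
        assert passes == same, (h, same)
        if same:
            seen_pairs.add(frozenset((h.query_id, h.subject_id)))
    # every within-family pair produced a hit at all
    strains = tiny_world.strain_ids
    expected_pairs = set()
    for fid, pattern in truth.items():
        members = [f"{strains[i]}_{fid}" for i, b in enumerate(pattern) if b == "1"]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                expected_pairs.add(frozenset((members[i], members[j])))
    assert seen_pairs == expected_pairs


def test_halogenated_features_sit_inside_window_others_outside(small_world):
    ledger = small_world.ledger
    window = MassDefectParams()
    halogenated = set(ledger["halogenated_features"])
    for fid, mass in ledger["feature_mass"].items():
        if fid in halogenated:
            assert defect_window_pass(mass, window)
        else:
            assert not defect_window_pass(mass, window)


def test_core_feature_fraction_across_seeds():
    fractions = []
    for seed in range(20):
        config = WorldConfig.small(
            seed=seed, n_core_families=2, n_accessory_families=2,
            n_singletons_per_strain=1,
        )
        world = generate_world(config)
        origins = world.ledger["feature_origin"]
        patterns = world.ledger["feature_patterns"]
        non_blank = [patterns[f] for f in patterns if origins[f] != "blank"]
        fractions.append(
            sum(p == "1" * 13 for p in non_blank) / len(non_blank)
        )
    assert np.mean(fractions) == pytest.approx(0.02, abs=0.015)


def test_infeasible_configs_rejected():
    with pytest.raises(ValueError, match="clade_split"):
        generate_world(WorldConfig.small(clade_split=((0, 1), (2, 3))))
    with pytest.raises(ValueError, match="fit on one contig"):
        generate_world(WorldConfig.small(genes_per_contig=5))
    with pytest.raises(ValueError, match="pattern width"):
        WorldConfig(
            n_strains=4, clade_split=((0, 1), (2, 3)), clonal_pairs=(),
            planted_clusters=(PlantedCluster("x", strain_pattern="11"),),
        ).validate()
    with pytest.raises(ValueError):
        PlantedCluster("x", strain_pattern="0000000000000")
    with pytest.raises(ValueError):
        PlantedCluster("x", strain_pattern="1110000000000", broken_in=(5,))


def test_config_roundtrips_through_dict():
    config = WorldConfig.small(seed=4)
    assert config_from_dict(_config_to_dict(config)) == config


class TestGenerateSpectrum:
    def scaffold(self):
        rng = np.random.default_rng(0)
        return sorted((float(m), float(i)) for m, i in
                      zip(rng.uniform(60, 300, 8), rng.uniform(0.2, 1.0, 8)))

    def test_zero_shift_no_noise_reproduces_scaffold(self):
        scaffold = self.scaffold()
        spec = generate_spectrum(400.0, scaffold, 0.0, 0, seed=1)
        assert spec.peaks == sorted(scaffold)
        assert spec.precursor_mz == pytest.approx(401.00728, abs=1e-4)

    def test_analogues_link_above_threshold(self):
        scaffold = self.scaffold()
        shifted = [0, 1, 2]
        s1 = generate_spectrum(400.0, scaffold, 0.0, 2, seed=1,
                               shifted_indices=shifted, spectrum_id="a")
        s2 = generate_spectrum(414.0157, scaffold, 14.0157, 2, seed=2,
                               shifted_indices=shifted, spectrum_id="b")
        score, matched = modified_cosine(s1, s2, NetworkParams())
        assert score > 0.7
        assert matched >= 6

    def test_unrelated_scaffolds_score_low(self):
        rng = np.random.default_rng(5)
        other = sorted((float(m), float(i)) for m, i in
                       zip(rng.uniform(60, 300, 8), rng.uniform(0.2, 1.0, 8)))
        s1 = generate_spectrum(400.0, self.scaffold(), 0.0, 2, seed=1, spectrum_id="a")
        s2 = generate_spectrum(523.7, other, 0.0, 2, seed=2, spectrum_id="b")
        score, _ = modified_cosine(s1, s2, NetworkParams())
        assert score < 0.3

    def test_scaffold_above_precursor_rejected(self):
        with pytest.raises(ValueError, match="below the precursor"):
            generate_spectrum(100.0, [(150.0, 1.0)], 0.0, 0, seed=1)
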