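"""Modified cosine, pairing oracle, network construction and annotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panlink.msnetwork import (
    FragmentSpectrum,
    NetworkParams,
    annotate_nodes,
    build_network,
    modified_cosine,
    read_mgf,
    write_edge_list,
    write_mgf,
)


def spectrum(sid, precursor, peaks, strain=None):
    return FragmentSpectrum(sid, precursor, peaks, strain_id=strain)


PARAMS = NetworkParams(fragment_tol=0.3, min_matched_peaks=1)


class TestModifiedCosine:
    def test_identical_spectra_score_one(self):
        s = spectrum("a", 400.0, [(100.0, 5.0), (150.0, 2.0), (200.0, 9.0)])
        score, matched = modified_cosine(s, s, PARAMS)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert matched == 3

    def test_disjoint_spectra_score_zero(self):
        s1 = spectrum("a", 400.0, [(100.0, 1.0), (150.0, 1.0)])
        s2 = spectrum("b", 400.0, [(220.0, 1.0), (320.0, 1.0)])
        assert modified_cosine(s1, s2, PARAMS) == (0.0, 0)

    def test_precursor_shift_pairs_offset_peaks(self):
        # one peak matches directly, the other through the precursor delta
        s1 = spectrum("a", 200.0, [(100.0, 1.0), (150.0, 1.0)])
        s2 = spectrum("b", 210.0, [(100.0, 1.0), (160.0, 1.0)])
        score, matched = modified_cosine(s1, s2, PARAMS)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert matched == 2

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            s1 = spectrum("a", 400.0, [(float(m), float(i)) for m, i in
                                       zip(rng.uniform(50, 390, 6), rng.uniform(0.1, 1, 6))])
            s2 = spectrum("b", 412.5, [(float(m), float(i)) for m, i in
                                       zip(rng.uniform(50, 400, 6), rng.uniform(0.1, 1, 6))])
            assert modified_cosine(s1, s2, PARAMS) == modified_cosine(s2, s1, PARAMS)[:2]

    def test_intensity_transform_none(self):
        params = NetworkParams(intensity_transform="none", min_matched_peaks=1)
        s1 = spectrum("a", 400.0, [(100.0, 4.0), (200.0, 1.0)])
        s2 = spectrum("b", 400.0, [(100.0, 4.0), (300.0, 1.0)])
        score, _ = modified_cosine(s1, s2, params)
        assert score == pytest.approx(16 / 17)

    def test_empty_spectrum_rejected(self):
        s = spectrum("a", 400.0, [(100.0, 1.0)])
        with pytest.raises(ValueError):
            modified_cosine(s, FragmentSpectrum("b", 400.0, []), PARAMS)

    def test_greedy_matches_optimal_assignment_on_small_spectra(self):
        rng = np.random.default_rng(1)
        worse = 0
        for _ in range(200):
            n1, n2 = rng.integers(2, 9), rng.integers(2, 9)
            s1 = spectrum("a", float(rng.uniform(300, 500)),
                          [(float(m), float(i)) for m, i in
                           zip(rng.uniform(50, 290, n1), rng.uniform(0.1, 1, n1))])
            s2 = spectrum("b", s1.precursor_mz + float(rng.uniform(-30, 30)),
                          [(float(m), float(i)) for m, i in
                           zip(rng.uniform(50, 290, n2), rng.uniform(0.1, 1, n2))])
            greedy, _ = modified_cosine(s1, s2, PARAMS, method="greedy")
            optimal, _ = modified_cosine(s1, s2, PARAMS, method="optimal")
            assert greedy <= optimal + 1e-9
            if optimal - greedy > 1e-9:
                worse += 1
        # the greedy heuristic is near-optimal on small spectra
        assert worse <= 10


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None)
def test_self_similarity_is_one_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 12))
    s = FragmentSpectrum(
        "s", float(rng.uniform(200, 800)),
        [(float(m), float(i)) for m, i in
         zip(rng.uniform(50, 190, n), rng.uniform(0.05, 1, n))],
    )
    score, matched = modified_cosine(s, s, NetworkParams(min_matched_peaks=1))
    assert score == pytest.approx(1.0, abs=1e-9)
    assert matched == n


class TestBuildNetwork:
    def family(self, base, n, prefix, rng):
        scaffold = [(float(m), float(i)) for m, i in
                    zip(rng.uniform(50, base * 0.7, 8), rng.uniform(0.3, 1, 8))]
        return [
            spectrum(f"{prefix}{k}", base + 14.0157 * k + 1.00728,
                     [(m + (14.0157 * k if j < 3 else 0.0), i)
                      for j, (m, i) in enumerate(scaffold)])
            for k in range(n)
        ]

    def test_identical_spectra_form_clique_family(self):
        peaks = [(100.0 + 10 * i, 1.0) for i in range(8)]
        spectra = [spectrum(f"s{k}", 400.0, peaks) for k in range(4)]
        graph, families, singletons = build_network(spectra, NetworkParams())
        assert families == [["s0", "s1", "s2", "s3"]]
        assert singletons == []
        assert graph.number_of_edges() == 6

    def test_planted_family_is_one_component(self):
        rng = np.random.default_rng(3)
        fam = self.family(420.0, 5, "fam", rng)
        other = self.family(777.3, 3, "other", rng)
        graph, families, singletons = build_network(fam + other, NetworkParams())
        assert sorted(families) == [
            ["fam0", "fam1", "fam2", "fam3", "fam4"],
            ["other0", "other1", "other2"],
        ]

    def test_strict_threshold_one_removes_edges(self):
        rng = np.random.default_rng(4)
        spectra = self.family(420.0, 3, "s", rng)
        noisy = [
            FragmentSpectrum(s.spectrum_id, s.precursor_mz,
                             s.peaks + [(float(rng.uniform(30, 300)), 0.2)])
            for s in spectra
        ]
        _, families, singletons = build_network(
            noisy, NetworkParams(cosine_threshold=1.0)
        )
        assert families == []
        assert len(singletons) == 3

    def test_edge_set_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        spectra = self.family(420.0, 4, "s", rng) + self.family(700.0, 3, "t", rng)
        g1, _, _ = build_network(spectra, NetworkParams())
        g2, _, _ = build_network(spectra[::-1], NetworkParams())
        assert {frozenset(e) for e in g1.edges} == {frozenset(e) for e in g2.edges}

    def test_world_planted_family_single_component(self, small_world):
        graph, families, _ = build_network(small_world.spectra, NetworkParams())
        cluster = small_world.ledger["clusters"][0]
        planted_ids = {f"spec_{fid}" for fid in cluster["linked_features"]}
        matching = [set(f) for f in families if set(f) & planted_ids]
        assert len(matching) == 1
        assert matching[0] == planted_ids


class TestAnnotateNodes:
    def test_presence_classes(self):
        peaks = [(100.0 + 10 * i, 1.0) for i in range(8)]
        spectra = [spectrum("s_core", 400.0, peaks),
                   spectrum("s_uni", 800.0, [(50.0, 1.0)] )]
        graph, _, _ = build_network(spectra, NetworkParams())
        warnings = annotate_nodes(
            graph,
            presence={"fA": "111", "fB": "010"},
            spectrum_features={"s_core": "fA", "s_uni": "fB"},
            n_strains=3,
        )
        assert warnings == []
        assert graph.nodes["s_core"]["presence_class"] == "core"
        assert graph.nodes["s_uni"]["presence_class"] == "unique"

    def test_unmatched_spectrum_flagged_unknown(self):
        spectra = [spectrum("a", 400.0, [(100.0, 1.0)]),
                   spectrum("b", 500.0, [(200.0, 1.0)])]
        graph, _, _ = build_network(spectra, NetworkParams())
        warnings = annotate_nodes(graph, {}, {}, 3)
        assert sorted(warnings) == ["a", "b"]
        assert graph.nodes["a"]["presence_class"] == "unknown"

    def test_planted_family_share_pattern(self, small_world):
        graph, _, _ = build_network(small_world.spectra, NetworkParams())
        warnings = annotate_nodes(
            graph,
            small_world.ledger["feature_patterns"],
            small_world.ledger["spectrum_features"],
            len(small_world.strain_ids),
        )
        assert warnings == []
        cluster = small_world.ledger["clusters"][0]
        for fid in cluster["linked_features"]:
            node = graph.nodes[f"spec_{fid}"]
            assert node["presence"] == cluster["intact_pattern"]
            assert node["presence_class"] == "shared"


def test_matchms_cross_check(small_world):
    """Independent oracle: matchms' ModifiedCosine on the planted spectra."""
    matchms = pytest.importorskip("matchms")
    from matchms import Spectrum
    from matchms.similarity import ModifiedCosine

    params = NetworkParams(fragment_tol=0.3, min_matched_peaks=1)
    similarity = ModifiedCosine(tolerance=params.fragment_tol)
    spectra = small_world.spectra[:8]
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            s1, s2 = spectra[i], spectra[j]
            ours, _ = modified_cosine(s1, s2, params, method="optimal")
            m1 = Spectrum(mz=s1.mzs, intensities=s1.intensities,
                          metadata={"precursor_mz": s1.precursor_mz})
            m2 = Spectrum(mz=s2.mzs, intensities=s2.intensities,
                          metadata={"precursor_mz": s2.precursor_mz})
            theirs = float(similarity.pair(m1, m2)["score"])
            assert ours == pytest.approx(theirs, abs=0.05)


def test_mgf_roundtrip_and_edge_list(tmp_path, small_world):
    path = tmp_path / "spectra.mgf"
    write_mgf(small_world.spectra, path)
    loaded = read_mgf(path)
    assert [s.spectrum_id for s in loaded] == [s.spectrum_id for s in small_world.spectra]
    assert loaded[0].precursor_mz == pytest.approx(
        small_world.spectra[0].precursor_mz, abs=1e-4
    )
    assert loaded[0].rt == pytest.approx(small_world.spectra[0].rt, abs=1e-3)
    graph, _, _ = build_network(loaded, NetworkParams())
    edge_path = tmp_path / "edges.tsv"
    write_edge_list(graph, edge_path)
    lines = edge_path.read_text().splitlines()
    assert lines[0].startswith("source\ttarget")
    assert len(lines) == graph.number_of_edges() + 1
    import networkx as nx

    from panlink.msnetwork import write_graphml

    gml_path = tmp_path / "network.graphml"
    write_graphml(graph, gml_path)
    reloaded = nx.read_graphml(gml_path)
    assert reloaded.number_of_edges() == graph.number_of_edges()
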