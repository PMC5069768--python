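"""Alignment engine, 50/50 families, BBH barcodes and clade counts."""

import numpy as np
import pytest

from panlink.genefamilies import (
    FamilyParams,
    PairwiseHit,
    ProteinRecord,
    all_pairwise_hits,
    bbh_orthologs,
    blastp_hits,
    build_families,
    clade_shared_counts,
    family_summary,
    pairwise_hits,
    parse_tabular_hits,
    read_proteome_fasta,
    write_proteome_fasta,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def protein(strain, pid, seq, contig="c1", idx=0):
    return ProteinRecord(strain, contig, idx, pid, seq)


def mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = AA[(AA.index(out[p]) + 1 + rng.integers(0, 18)) % 20]
    return "".join(out)


class TestBuiltinAligner:
    def test_identical_sequences_full_identity(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(AA), 120))
        hits = pairwise_hits([protein("A", "a1", seq)], [protein("B", "b1", seq)])
        assert len(hits) == 1
        assert hits[0].percent_identity == 100.0
        assert hits[0].alignment_length == 120

    def test_no_shared_kmers_no_hit(self):
        a = protein("A", "a1", "A" * 100)
        b = protein("B", "b1", "W" * 100)
        assert pairwise_hits([a], [b]) == []

    def test_controlled_divergence_identity(self):
        # 40 substitutions in the middle of a 100-residue pair, ends intact so
        # the local alignment spans the full length: identity 60 over 100
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list(AA), 100))
        other = mutate(seq, rng.choice(np.arange(20, 80), 40, replace=False), rng)
        hits = pairwise_hits([protein("A", "a1", seq)], [protein("B", "b1", other)])
        assert len(hits) == 1
        assert hits[0].percent_identity == pytest.approx(60.0, abs=2.0)
        assert hits[0].alignment_length >= 95


class TestTabularParsing:
    def test_roundtrip_and_errors(self, tmp_path):
        line = "q1\ts1\t75.00\t200\t50\t0\t1\t200\t1\t200\t1e-50\t300.5"
        hits = parse_tabular_hits([line])
        assert hits[0] == PairwiseHit("q1", "s1", 75.0, 200, 300.5)
        with pytest.raises(ValueError, match="line 1"):
            parse_tabular_hits(["only\tfour\tcolumns\there"])
        with pytest.raises(ValueError, match="line 2"):
            parse_tabular_hits([line, line.replace("200", "xx", 1)])

    def test_comments_and_blanks_skipped(self):
        line = "q1\ts1\t75.00\t200\t50\t0\t1\t200\t1\t200\t1e-50\t300.5"
        assert len(parse_tabular_hits(["# header", "", line])) == 1


class TestFamilies:
    def test_fifty_fifty_rule_edges(self):
        a = protein("A", "a1", "M" * 100)
        b = protein("B", "b1", "M" * 100)
        proteomes = {"A": [a], "B": [b]}
        # identity 60 over 80% of longest -> same family
        hits = [PairwiseHit("a1", "b1", 60.0, 80, 100.0)]
        assert build_families(proteomes, hits) == [["a1", "b1"]]
        # same identity, only 40% coverage -> separate families
        hits = [PairwiseHit("a1", "b1", 60.0, 40, 100.0)]
        assert build_families(proteomes, hits) == [["a1"], ["b1"]]
        # exactly 50.0% identity fails the strictly-greater rule
        hits = [PairwiseHit("a1", "b1", 50.0, 100, 100.0)]
        assert build_families(proteomes, hits) == [["a1"], ["b1"]]

    def test_coverage_uses_longer_sequence(self):
        a = protein("A", "a1", "M" * 200)
        b = protein("B", "b1", "M" * 100)
        proteomes = {"A": [a], "B": [b]}
        # 90 aligned residues cover 90% of the short gene but only 45% of the long one
        hits = [PairwiseHit("a1", "b1", 80.0, 90, 100.0)]
        assert build_families(proteomes, hits) == [["a1"], ["b1"]]

    def test_planted_world_families_match_ledger(self, small_world, small_world_hits):
        families = build_families(small_world.proteomes, small_world_hits)
        truth = small_world.ledger["family_patterns"]
        strains = small_world.strain_ids
        expected = {
            frozenset(
                f"{strains[i]}_{fid}" for i, b in enumerate(pattern) if b == "1"
            )
            for fid, pattern in truth.items()
        }
        assert {frozenset(f) for f in families} == expected
        summary = family_summary(families, small_world.proteomes)
        assert summary["pan"] == len(truth)
        assert summary["core"] == sum(1 for p in truth.values() if set(p) == {"1"})


class TestBBH:
    def toy_proteomes(self, rng, n_strains=3, n_genes=3, drop=None):
        ancestors = ["".join(rng.choice(list(AA), 200)) for _ in range(n_genes)]
        proteomes = {}
        for s in range(n_strains):
            strain = f"S{s}"
            records = []
            for g, anc in enumerate(ancestors):
                if drop and (strain, g) in drop:
                    continue
                seq = mutate(anc, rng.choice(200, 20, replace=False), rng)
                records.append(ProteinRecord(strain, "c1", g, f"{strain}_g{g}", seq))
            proteomes[strain] = records
        return proteomes

    def test_identical_proteomes_full_groups(self):
        rng = np.random.default_rng(2)
        proteomes = self.toy_proteomes(rng)
        hits = all_pairwise_hits(proteomes)
        barcodes, groups = bbh_orthologs(proteomes, hits)
        assert all(bits == "111" for bits in barcodes.values())
        assert len(groups) == 3

    def test_missing_gene_breaks_one_bit(self):
        rng = np.random.default_rng(3)
        proteomes = self.toy_proteomes(rng, drop={("S2", 0)})
        hits = all_pairwise_hits(proteomes)
        barcodes, groups = bbh_orthologs(proteomes, hits)
        assert barcodes["S0_g0"] == "110"
        assert barcodes["S1_g0"] == "110"
        assert len(groups) == 2  # no full group for gene 0

    def test_score_tie_gives_no_bbh(self):
        # two identical copies in B tie for best hit of A's gene: non-greedy
        seq = "MKLVWQERTYIPASDFGHKLCNMQWERTYUPASDFGH".replace("U", "A") * 4
        a = [protein("A", "a1", seq)]
        b = [protein("B", "b1", seq, idx=0), protein("B", "b2", seq, idx=1)]
        proteomes = {"A": a, "B": b}
        hits = all_pairwise_hits(proteomes)
        barcodes, groups = bbh_orthologs(proteomes, hits)
        assert barcodes["a1"] == "10"
        assert groups == []

    def test_barcodes_match_ledger_exactly(self, small_world, small_world_barcodes):
        barcodes, groups = small_world_barcodes
        truth = small_world.ledger["family_patterns"]
        mismatches = [
            pid for pid, bits in barcodes.items()
            if bits != truth[pid.split("_", 1)[1]]
        ]
        assert mismatches == []
        n_core = sum(1 for p in truth.values() if set(p) == {"1"})
        assert len(groups) == n_core

    def test_ortholog_groups_lie_within_families(
        self, small_world, small_world_hits, small_world_barcodes
    ):
        families = build_families(small_world.proteomes, small_world_hits)
        fam_of = {pid: k for k, fam in enumerate(families) for pid in fam}
        _, groups = small_world_barcodes
        for group in groups:
            assert len({fam_of[pid] for pid in group.values()}) == 1


class TestCladeCounts:
    def test_trivial_barcode_distributions(self):
        strains = ["S0", "S1", "S2", "S3"]
        hierarchy = [["S0", "S1"], ["S2", "S3"]]
        all_ones = {f"S{i}_g{j}": "1111" for i in range(4) for j in range(5)}
        protein_strains = {pid: pid.split("_")[0] for pid in all_ones}
        counts = clade_shared_counts(all_ones, protein_strains, strains, hierarchy)
        assert counts[("S0", "S1", "S2", "S3")] == 5
        assert all(v == 0 for node, v in counts.items() if len(node) < 4)

        singles = {
            f"S{i}_g{j}": "".join("1" if k == i else "0" for k in range(4))
            for i in range(4) for j in range(2)
        }
        protein_strains = {pid: pid.split("_")[0] for pid in singles}
        counts = clade_shared_counts(singles, protein_strains, strains, hierarchy)
        assert all(counts[(s,)] == 2 for s in strains)

    def test_hand_built_hierarchy_counts(self):
        strains = ["S0", "S1", "S2", "S3"]
        hierarchy = [["S0", "S1"], ["S2", "S3"]]
        barcodes = {
            "S0_a": "1111", "S1_a": "1111", "S2_a": "1111", "S3_a": "1111",
            "S0_b": "1100", "S1_b": "1100",
            "S2_c": "0011", "S3_c": "0011",
            "S0_d": "1010",  # spans both clades: matches no node
        }
        protein_strains = {pid: pid.split("_")[0] for pid in barcodes}
        counts = clade_shared_counts(barcodes, protein_strains, strains, hierarchy)
        assert counts[("S0", "S1", "S2", "S3")] == 1
        assert counts[("S0", "S1")] == 1
        assert counts[("S2", "S3")] == 1
        assert counts[("S0",)] == 0


class TestExternalEngine:
    def test_blastp_agrees_with_builtin_families(self, tiny_world):
        import shutil

        if shutil.which("blastp") is None or shutil.which("makeblastdb") is None:
            pytest.skip("BLAST+ not on PATH")
        builtin = build_families(
            tiny_world.proteomes, all_pairwise_hits(tiny_world.proteomes)
        )
        external = build_families(tiny_world.proteomes, blastp_hits(tiny_world.proteomes))
        assert {frozenset(f) for f in builtin} == {frozenset(f) for f in external}


def test_fasta_roundtrip(tmp_path):
    records = [
        ProteinRecord("S1", "c1", 0, "S1_g0", "MKLV" * 30),
        ProteinRecord("S1", "c1", 1, "S1_g1", "WQER" * 40),
    ]
    path = tmp_path / "s1.faa"
    write_proteome_fasta(records, path)
    assert read_proteome_fasta(path) == records
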