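"""Blank subtraction, feature alignment, mode merging, intensity filtering."""

import numpy as np
import pandas as pd
import pytest

from panlink.metabolome import (
    AlignmentParams,
    align_features,
    merge_modes,
    subtract_blanks,
    top_n_by_intensity,
)
from panlink.pancore import PresenceMatrix


def rows(entries, mode="positive"):
    """entries: (sample_id, strain_id, replicate, mass, rt, intensity)"""
    return pd.DataFrame(
        [(s, st, r, mode, m, rt, i) for s, st, r, m, rt, i in entries],
        columns=["sample_id", "strain_id", "replicate", "mode", "neutral_mass",
                 "rt", "intensity"],
    )


class TestSubtractBlanks:
    def test_empty_blank_set_is_identity(self):
        table = rows([("A_r1", "A", 1, 500.0, 5.0, 10.0)])
        out = subtract_blanks(table, table.iloc[0:0])
        pd.testing.assert_frame_equal(out, table)

    def test_exact_blank_match_removed(self):
        table = rows([("A_r1", "A", 1, 500.0, 5.0, 10.0)])
        blanks = rows([("B_r1", "BLANK", 1, 500.0, 5.0, 3.0)])
        assert len(subtract_blanks(table, blanks)) == 0

    def test_counted_removal_within_tolerance(self):
        params = AlignmentParams(mass_tol_ppm=20, rt_tol=0.1)
        blanks = rows([("B_r1", "BLANK", 1, 500.0, 5.0, 1.0),
                       ("B_r1", "BLANK", 1, 700.0, 9.0, 1.0)])
        entries = []
        # 3 of 10 features fall inside both tolerances of a blank
        for k in range(10):
            if k < 2:
                entries.append((f"A_r1", "A", 1, 500.0 + 0.004 * k, 5.05, 1.0))
            elif k == 2:
                entries.append((f"A_r1", "A", 1, 700.001, 8.95, 1.0))
            elif k == 3:
                entries.append((f"A_r1", "A", 1, 500.0, 5.5, 1.0))  # RT too far
            elif k == 4:
                entries.append((f"A_r1", "A", 1, 500.2, 5.0, 1.0))  # mass too far
            else:
                entries.append((f"A_r1", "A", 1, 300.0 + k, 2.0, 1.0))
        table = rows(entries)
        # independent exhaustive check
        keep_expected = 0
        for _, row in table.iterrows():
            hit = any(
                abs(row.neutral_mass - b.neutral_mass)
                <= 20e-6 * max(row.neutral_mass, b.neutral_mass)
                and abs(row.rt - b.rt) <= 0.1
                for _, b in blanks.iterrows()
            )
            keep_expected += not hit
        out = subtract_blanks(table, blanks, params)
        assert keep_expected == 7
        assert len(out) == keep_expected

    def test_idempotent(self):
        table = rows([("A_r1", "A", 1, 500.0, 5.0, 1.0),
                      ("A_r1", "A", 1, 600.0, 6.0, 1.0)])
        blanks = rows([("B_r1", "BLANK", 1, 500.0, 5.0, 1.0)])
        once = subtract_blanks(table, blanks)
        twice = subtract_blanks(once, blanks)
        pd.testing.assert_frame_equal(once, twice)


class TestAlignFeatures:
    def test_single_sample_one_group_per_row(self):
        table = rows([("A_r1", "A", 1, 500.0, 5.0, 1.0),
                      ("A_r1", "A", 1, 600.0, 6.0, 2.0)])
        aligned = align_features(table)
        assert len(aligned) == 2

    def test_merge_within_tolerance(self):
        params = AlignmentParams(mass_tol_ppm=20, rt_tol=0.1)
        table = rows([("A_r1", "A", 1, 500.2000, 5.00, 1.0),
                      ("B_r1", "B", 1, 500.2010, 5.05, 3.0)])
        aligned = align_features(table, params)
        assert len(aligned) == 1
        # intensity-weighted mean mass
        expected = (500.2000 * 1.0 + 500.2010 * 3.0) / 4.0
        assert aligned.features["neutral_mass"].iloc[0] == pytest.approx(expected)
        assert aligned.presence.bits.sum() == 2

    def test_split_when_rt_tolerance_tightened(self):
        params = AlignmentParams(mass_tol_ppm=20, rt_tol=0.01)
        table = rows([("A_r1", "A", 1, 500.2000, 5.00, 1.0),
                      ("B_r1", "B", 1, 500.2010, 5.05, 3.0)])
        assert len(align_features(table, params)) == 2

    def test_presence_rules_over_replicates(self):
        table = rows([("A_r1", "A", 1, 500.0, 5.0, 1.0),
                      ("A_r2", "A", 2, 500.0, 5.0, 1.0),
                      ("B_r1", "B", 1, 500.0, 5.0, 1.0)])
        # B has replicates r1 and r2 overall? here B only ran r1, so both rules agree
        any_rule = align_features(table, AlignmentParams(presence_rule="any_replicate"))
        assert any_rule.presence.bits[:, 0].tolist() == [True, True]
        # give B a second, empty replicate by adding another feature seen in B_r2
        table2 = pd.concat(
            [table, rows([("B_r2", "B", 2, 800.0, 2.0, 1.0)])], ignore_index=True
        )
        strict = align_features(table2, AlignmentParams(presence_rule="all_replicates"))
        mass_order = strict.features["neutral_mass"].tolist()
        bits = strict.presence.bits
        # the 500 Da feature: A present in both replicates, B only in r1
        idx = mass_order.index(500.0)
        assert bits[0, idx] and not bits[1, idx]

    def test_no_all_zero_rows_and_recovery_without_dropout(self):
        from panlink.worldgen import WorldConfig, generate_world

        config = WorldConfig(
            n_strains=5, clade_split=((0, 1, 2), (3, 4)), clonal_pairs=(),
            n_core_families=2, n_accessory_families=2, n_singletons_per_strain=1,
            genes_per_contig=10, planted_clusters=(), features_per_strain=30,
            blank_features=4, n_halogenated_features=4, dropout_rate=0.0, seed=3,
        )
        world = generate_world(config)
        pos = world.feature_rows[world.feature_rows["mode"] == "positive"]
        aligned = align_features(pos, strain_ids=world.strain_ids)
        assert aligned.presence.bits.any(axis=0).all()
        # with no dropout, every aligned feature's presence equals the ledger
        truth = world.ledger["feature_patterns"]
        rts = world.ledger["feature_rt"]
        by_mass = sorted((m, fid) for fid, m in world.ledger["feature_mass"].items())
        import bisect

        for fid, row in aligned.features.iterrows():
            i = bisect.bisect_left(by_mass, (row.neutral_mass - 0.02, ""))
            near = [
                t for t in by_mass[i:i + 6]
                if abs(t[0] - row.neutral_mass) < 0.02 and abs(rts[t[1]] - row.rt) < 0.3
            ]
            assert len(near) == 1  # generated features are separable in mass+RT
            true_id = near[0][1]
            bits = "".join(
                "1" if b else "0"
                for b in aligned.presence.bits[:, aligned.feature_ids.index(fid)]
            )
            assert bits == truth[true_id]


class TestMergeModes:
    def build(self, masses, strains=("A", "B"), mode="positive", prefix="P"):
        entries = [
            (f"{s}_r1", s, 1, m, 5.0 + i, 1.0 + i)
            for i, m in enumerate(masses)
            for s in strains
        ]
        return align_features(
            rows(entries, mode), strain_ids=list(strains), feature_prefix=prefix
        )

    def test_disjoint_masses_concatenate(self):
        pos = self.build([500.0, 600.0])
        neg = self.build([700.0, 800.0], mode="negative", prefix="N")
        merged = merge_modes(pos, neg)
        assert len(merged) == 4

    def test_identical_tables_collapse(self):
        pos = self.build([500.0, 600.0])
        neg = self.build([500.0, 600.0], mode="negative", prefix="N")
        merged = merge_modes(pos, neg)
        assert len(merged) == 2
        assert (merged.features["mode"] == "merged").all()

    def test_count_identity(self):
        # |merged| = |P| + |N| - |matched|, the arithmetic behind a
        # 6736 + 2151 - 1697 = 7190 style bookkeeping
        pos = self.build([500.0, 600.0, 650.0, 900.0])
        neg = self.build([500.0, 600.0, 840.0], mode="negative", prefix="N")
        merged = merge_modes(pos, neg)
        matched = 2
        assert len(merged) == len(pos) + len(neg) - matched

    def test_commutative_up_to_relabeling(self):
        pos = self.build([500.0, 600.0, 650.0])
        neg = self.build([600.0, 800.0], mode="negative", prefix="N")
        ab = merge_modes(pos, neg)
        ba = merge_modes(neg, pos)
        assert sorted(ab.features["neutral_mass"]) == pytest.approx(
            sorted(ba.features["neutral_mass"])
        )
        assert np.array_equal(
            ab.presence.bits[:, np.argsort(ab.features["neutral_mass"].to_numpy())],
            ba.presence.bits[:, np.argsort(ba.features["neutral_mass"].to_numpy())],
        )


class TestTopN:
    def build_with_intensities(self, intensities):
        entries = [
            ("A_r1", "A", 1, 400.0 + 10 * i, 5.0, inten)
            for i, inten in enumerate(intensities)
        ]
        return align_features(rows(entries), strain_ids=["A"])

    def test_identity_and_single(self):
        table = self.build_with_intensities([5.0, 1.0, 3.0])
        assert top_n_by_intensity(table, 3).feature_ids == table.feature_ids
        top1 = top_n_by_intensity(table, 1)
        assert top1.features["neutral_mass"].iloc[0] == 400.0

    def test_known_ranking(self):
        table = self.build_with_intensities([5.0, 1.0, 3.0, 9.0, 2.0])
        top3 = top_n_by_intensity(table, 3)
        assert sorted(top3.features["neutral_mass"]) == [400.0, 420.0, 430.0]

    def test_overlong_request_returns_all(self):
        table = self.build_with_intensities([5.0, 1.0])
        assert len(top_n_by_intensity(table, 10)) == 2
        with pytest.raises(ValueError):
            top_n_by_intensity(table, 0)
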