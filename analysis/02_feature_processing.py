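"""Blank-subtract, align and merge the feature tables; pan/core metabolome.

Reads the world written by 01_simulate_world.py, runs the metabolite side of
the workflow, and writes the merged feature table, the strains × features
presence matrix, and the clustered-order pan/core accumulation curves.
"""

from pathlib import Path

from panlink import metabolome, pancore

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = metabolome.AlignmentParams()
    tables = {}
    for mode, tag, prefix in (("positive", "pos", "P"), ("negative", "neg", "N")):
        rows = metabolome.read_feature_table(RESULTS / "world" / f"features_{tag}.csv")
        blanks = metabolome.read_feature_table(RESULTS / "world" / f"blanks_{tag}.csv")
        clean = metabolome.subtract_blanks(rows, blanks, params)
        tables[mode] = metabolome.align_features(clean, params, feature_prefix=prefix)
        print(f"{mode}: {rows.sample_id.nunique()} samples, "
              f"{len(rows)} rows -> {len(clean)} after blank removal -> "
              f"{len(tables[mode])} aligned features")
    merged = metabolome.merge_modes(tables["positive"], tables["negative"], params)
    matched = len(tables["positive"]) + len(tables["negative"]) - len(merged)
    print(f"mode merge: {len(tables['positive'])} + {len(tables['negative'])} "
          f"- {matched} matched = {len(merged)} features")

    core, unique, per_strain = pancore.unique_and_shared_fractions(merged.presence)
    print(f"core features {core:.1%}, strain-unique features {unique:.1%}")

    order = pancore.cluster_order(merged.presence)
    curves = pancore.pan_core(merged.presence, order)
    merged.features.to_csv(RESULTS / "features_merged.csv")
    merged.presence.to_frame().astype(int).to_csv(RESULTS / "feature_presence.csv")
    curves.to_frame().to_csv(RESULTS / "pancore_metabolome.csv", index=False)
    print(f"pan-metabolome {curves.pan_curve[-1]}, core {curves.core_curve[-1]} "
          f"(clustered strain order: {' '.join(order)})")


if __name__ == "__main__":
    main()
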