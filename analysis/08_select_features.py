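"""GA/SVM selection of strain-discriminative features.

Takes the most intense merged features, log-transforms intensities, and runs
the genetic-algorithm wrapper (population 25, 10 generations, 1 mutation)
around a linear SVM (cost 100, balanced weights) with leave-one-out
validation, mirroring the feature-prioritisation step of the workflow.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from panlink import gasvm, metabolome

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    params = metabolome.AlignmentParams()
    tables = {}
    for mode, tag, prefix in (("positive", "pos", "P"), ("negative", "neg", "N")):
        rows = metabolome.read_feature_table(RESULTS / "world" / f"features_{tag}.csv")
        blanks = metabolome.read_feature_table(RESULTS / "world" / f"blanks_{tag}.csv")
        clean = metabolome.subtract_blanks(rows, blanks, params)
        tables[mode] = metabolome.align_features(clean, params, feature_prefix=prefix)
    merged = metabolome.merge_modes(tables["positive"], tables["negative"], params)

    top_n = min(500, len(merged))
    top = metabolome.top_n_by_intensity(merged, top_n)
    X = np.log1p(np.nan_to_num(top.intensities.to_numpy(float).T, nan=0.0))
    labels = [c.rsplit("_r", 1)[0] for c in top.intensities.columns]
    subset_size = min(50, top_n)
    ga_params = gasvm.GASVMParams(
        subset_size=subset_size, n_input_features=top_n, seed=seed
    )
    print(f"selecting {subset_size} of the {top_n} most intense features "
          f"({X.shape[0]} samples, {len(set(labels))} strains)")
    best, history = gasvm.ga_select(X, labels, ga_params)
    print("best-ever LOO accuracy per generation: "
          + " ".join(f"{h['best']:.3f}" for h in history))
    print(f"final subset LOO accuracy {best.fitness:.3f}")

    selected = [top.feature_ids[i] for i in best.features]
    out = top.features.loc[selected, ["neutral_mass", "rt", "mode"]]
    out.to_csv(RESULTS / "selected_features.csv")
    print(f"{len(selected)} discriminating features written to "
          f"{RESULTS / 'selected_features.csv'}")


if __name__ == "__main__":
    main()
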