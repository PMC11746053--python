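#!/usr/bin/env python
"""Assemble the grouped 0-100 aberrancy heat map.

Normalizes each biomarker mRNA to PGK1 (2^-ΔCq), adds HPV load and
lactobacilli fraction, scales every column to the 0-100 aberrancy scale
(P50 white point, downregulated mRNAs and lactobacilli inverted), and
groups rows into FN / FP discrepant blocks followed by the concordant
diagnosis blocks. A rendered PNG goes to scratch/ when matplotlib is
available.
"""

from pathlib import Path

import pandas as pd

from cqtriage import (
    LinearClassifier,
    build_heatmap,
    decision_function,
    default_panel,
    feature_matrix,
    qc_filter,
    read_cq_table,
    relative_expression,
    spearman,
)
from cqtriage.heatmap import write_heatmap
from cqtriage.panel import Role

RESULTS = Path(__file__).parents[1] / "results"
SCRATCH = Path(__file__).parents[1] / "scratch"


def main():
    panel = default_panel()
    cohort = read_cq_table(RESULTS / "cohort_wide.csv", "wide", panel=panel)
    cohort, _ = qc_filter(cohort)
    covariates = pd.read_csv(RESULTS / "covariates.csv", index_col="sample_id")
    clf = LinearClassifier.load(RESULTS / "classifiers" / "clf4.json")

    features = feature_matrix(cohort, clf.pairs)
    results = decision_function(clf, features)
    calls = pd.Series({r.sample_id: r.call for r in results})
    df = pd.Series({r.sample_id: r.df for r in results})
    diagnoses = pd.Series({s: cohort.diagnosis_of(s) for s in cohort.sample_ids})

    mean_cq = cohort.mean_cq()
    reference = panel.adequacy_target(Role.RNA_ADEQUACY).name
    values = pd.DataFrame(index=cohort.sample_ids)
    invert = {}
    for target in panel.by_role(Role.BIOMARKER):
        values[target.name] = [
            relative_expression(mean_cq.at[s, target.name], mean_cq.at[s, reference])
            for s in cohort.sample_ids
        ]
        invert[target.name] = target.regulation.value == "down"
    values["hpv_load"] = covariates.loc[cohort.sample_ids, "hpv_load"]
    invert["hpv_load"] = False
    values["lb_fraction"] = covariates.loc[cohort.sample_ids, "lb_fraction"]
    invert["lb_fraction"] = True

    matrix, blocks, scales = build_heatmap(values, diagnoses, calls, invert)
    write_heatmap(matrix, blocks, scales,
                  RESULTS / "heatmap.csv", RESULTS / "heatmap_scales.csv")

    print("block sizes:", blocks.value_counts().reindex(
        ["FN", "FP", "NILM", "LSIL", "HSIL", "CC"]).fillna(0).astype(int).to_dict())
    rs_hpv = spearman(df, covariates.loc[df.index, "hpv_load"]).spearman_rs
    rs_lb = spearman(df, covariates.loc[df.index, "lb_fraction"]).spearman_rs
    print(f"Spearman DF vs HPV load: {rs_hpv:.3f}; DF vs LB fraction: {rs_lb:.3f}")
    print(f"wrote {RESULTS / 'heatmap.csv'}")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        SCRATCH.mkdir(exist_ok=True)
        fig, ax = plt.subplots(figsize=(6, 10))
        ax.imshow(matrix.to_numpy(), aspect="auto", cmap="bwr", vmin=0, vmax=100)
        ax.set_xticks(range(len(matrix.columns)))
        ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
        ax.set_yticks([])
        fig.tight_layout()
        fig.savefig(SCRATCH / "heatmap.png", dpi=150)
        print(f"rendered {SCRATCH / 'heatmap.png'}")
    except ImportError:
        pass


if __name__ == "__main__":
    main()
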