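"""Survival analysis of the chemokine clusters.

Kaplan-Meier curves and the Peto-Peto test between the PAM-derived
clusters (the design plants a null effect, mirroring the expectation of
no association), uni-variable Cox models with spline terms for the panel
genes, and the ridge-Cox concordance comparison of clinical-only vs
clinical-plus-expression models on an independent validation cohort.
"""

import pandas as pd

from common import RESULTS, load_study
from chemonet import clustering, evaluation, survival


def main() -> None:
    design, bundles = load_study()
    b0 = bundles[0]
    tumor = b0.cohort.subset_samples(b0.cohort.tumor_samples())
    model = clustering.fit_cluster_model(tumor, design.chemokine_panel, k=2)
    meta = tumor.sample_meta

    chi2, p = survival.peto_peto_test(meta["os_time"], meta["os_event"], model.assignments)
    km_rows = []
    for name in ("high", "low"):
        ids = model.assignments.index[model.assignments == name]
        km = survival.kaplan_meier(meta.loc[ids, "os_time"], meta.loc[ids, "os_event"])
        km["cluster"] = name
        km_rows.append(km)
    pd.concat(km_rows).to_csv(RESULTS / "06_kaplan_meier.tsv", sep="\t", index=False)

    panel_frame = tumor.values.loc[list(design.chemokine_panel)].T
    panel_frame["os_time"] = meta["os_time"]
    panel_frame["os_event"] = meta["os_event"]
    cox = survival.cox_univariable_panel(
        panel_frame, "os_time", "os_event", list(design.chemokine_panel)
    )
    cox.to_csv(RESULTS / "06_cox_univariable.tsv", sep="\t")

    ridge = evaluation.ridge_concordance_gain(seed=design.seed, beta_genes=0.0)
    pd.Series(ridge).to_csv(RESULTS / "06_ridge_concordance.tsv", sep="\t", header=False)

    n_events = int(meta["os_event"].sum())
    print(f"Peto-Peto test, chemokine-high vs low ({n_events} events): "
          f"chi2 = {chi2:.3f}, p = {p:.3f} (design plants no effect).")
    print("\nUni-variable Cox per panel gene (HR per 1 log2 unit, spline "
          "non-linearity p):")
    print(cox.round(3).to_string())
    print(f"\nRidge Cox on an independent validation cohort: concordance "
          f"{ridge['c_clinical']:.3f} (clinical) vs {ridge['c_full']:.3f} "
          f"(clinical + null-effect expression); gain {ridge['gain']:+.4f} — "
          f"no add-on value from expression, as planted.")


if __name__ == "__main__":
    main()
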