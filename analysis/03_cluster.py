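"""Define chemokine-high/low clusters and project them onto the sibling cohort.

Fits PAM with cosine distance on the z-scored panel in cohort SYN00,
reports k-choice diagnostics, 10-fold cross-validated stability and
explained variance, then transfers the labels to cohort SYN01 with the
inverse-distance-weighted 15-NN classifier.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from common import RESULTS, load_study
from chemonet import clustering


def main() -> None:
    design, bundles = load_study()
    b0, b1 = bundles
    train = b0.cohort.subset_samples(b0.cohort.tumor_samples())
    test = b1.cohort.subset_samples(b1.cohort.tumor_samples())

    model = clustering.fit_cluster_model(train, design.chemokine_panel, k=2)
    scaled, _ = clustering.zscore_genes(train, design.chemokine_panel)
    diag = clustering.choose_k(scaled, range(2, 7))
    cv = clustering.crossvalidate(scaled, k=2, folds=10, seed=0)
    ev_train = clustering.explained_variance(scaled, model.assignments)

    projected = clustering.knn_project(model, test, k_neighbors=15)
    scaled_test, _ = clustering.zscore_genes(test, design.chemokine_panel)
    ev_test = clustering.explained_variance(scaled_test, projected)

    ari_train = adjusted_rand_score(b0.truth.cluster_labels, model.assignments)
    agree_test = float((projected.loc[b1.truth.cluster_labels.index]
                        == b1.truth.cluster_labels).mean())

    model.to_json(RESULTS / "03_cluster_model.json")
    pd.concat([model.assignments.rename("cluster"), projected.rename("cluster")]).to_csv(
        RESULTS / "03_assignments.tsv", sep="\t"
    )
    pd.DataFrame(
        {"wss": diag.wss, "mean_silhouette": diag.silhouette}
    ).rename_axis("k").to_csv(RESULTS / "03_k_diagnostics.tsv", sep="\t")

    print("k-choice diagnostics (mean silhouette peaks at the recommended k):")
    for k in diag.silhouette:
        print(f"  k={k}: WSS {diag.wss[k]:7.2f}  silhouette {diag.silhouette[k]:.3f}")
    print(f"Recommended k = {diag.recommended_k}")
    print(f"Training: ARI vs planted labels {ari_train:.3f}; 10-fold CV stability {cv:.3f}; "
          f"explained variance {ev_train:.3f}")
    print(f"Projection: agreement with planted labels {agree_test:.3f}; "
          f"explained variance {ev_test:.3f} (gap {abs(ev_train - ev_test):.3f})")


if __name__ == "__main__":
    main()
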