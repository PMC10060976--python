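"""Profile the chemokine-high vs chemokine-low clusters.

Genome-wide Welch differential expression with the >1.25-fold filter,
ssGSEA contrasts of the planted IFN/exhaustion, OXPHOS/TCA/FAO and
tryptophan module signatures, and Mann-Whitney infiltration contrasts —
all against the PAM-derived (not the planted) cluster labels.
"""

from common import RESULTS, load_study
from chemonet import clustering, profiling
from chemonet.core_data import GeneSetCollection


def main() -> None:
    design, bundles = load_study()
    b0 = bundles[0]
    tumor = b0.cohort.subset_samples(b0.cohort.tumor_samples())
    model = clustering.fit_cluster_model(tumor, design.chemokine_panel, k=2)

    de = profiling.differential_expression(tumor, model.assignments)
    de.to_csv(RESULTS / "04_differential_expression.tsv", sep="\t")
    sets = GeneSetCollection(
        sets={
            "IFN_EXHAUSTION": design.module_genes("ifn_exhaustion"),
            "OXPHOS_TCA_FAO": design.module_genes("oxphos_tca_fao"),
            "TRP_METABOLISM": design.module_genes("trp"),
        }
    )
    scores = profiling.ssgsea(tumor, sets)
    sig = profiling.compare_scores(scores, model.assignments)
    sig.to_csv(RESULTS / "04_signature_contrasts.tsv", sep="\t")
    infil = profiling.compare_infiltration(
        b0.infiltration.scores, model.assignments
    )
    infil.to_csv(RESULTS / "04_infiltration_contrasts.tsv", sep="\t")

    up = de[de["regulated"] & (de["direction"] == "up")]
    down = de[de["regulated"] & (de["direction"] == "down")]
    print(f"Differential expression (high vs low): {len(up)} up, {len(down)} down "
          f"of {len(de)} genes at FDR < 0.05 and fold > 1.25.")
    print("\nssGSEA module signatures (high vs low):")
    print(sig[["mean_diff", "fdr", "direction"]].round(4).to_string())
    print("\nInfiltration contrasts (Mann-Whitney):")
    print(infil.round(4).to_string())


if __name__ == "__main__":
    main()
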