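# chemonet

Chemokine-centric analysis of tumor transcriptomes, rebuilt as a tested,
reusable pipeline and exercised end-to-end on a synthetic multi-cohort
generator with known ground truth.

In clear-cell renal cell carcinoma (RCC), a small panel of chemokine
ligand/receptor axes — CXCL9/10/11–CXCR3, CXCL13–CXCR5 and XCL1–XCR1 —
marks tumors with heavy CD8⁺ T-cell infiltration. Stratifying tumors on
this 8-gene panel yields a *chemokine-high* subtype with active IFN
signaling and T-cell exhaustion, suppressed oxidative metabolism and an
activated, immunosuppressive tryptophan/kynurenine pathway, yet no
survival difference. `chemonet` implements every statistical step of that
analysis so each one can be validated against planted truth:

1. **Screening** (`chemonet.screening`) — candidate chemokines pass two
   gates: ≥ four-fold tumor enrichment over donor-matched normal tissue
   (paired *t*, FDR < 0.05, mean Δlog₂ ≥ 2) and Spearman ρ > 0.6 with CD8
   infiltration (FDR < 0.05); plus ρ > 0.4 correlation networks.
2. **Clustering** (`chemonet.clustering`) — PAM (partition around
   medoids) under the cosine distance on the z-scored panel; k chosen by
   the silhouette peak and the WSS bend; 10-fold cross-validated
   stability (adjusted Rand index); label transfer to further cohorts by
   an inverse-distance-weighted 15-nearest-neighbor classifier.
3. **Profiling** (`chemonet.profiling`) — genome-wide Welch *t* with a
   \>1.25-fold filter; single-sample gene-set enrichment (ssGSEA,
   rank-weighted running sum, α = 0.25); Mann-Whitney and χ² contrasts.
4. **Metabolic regulation** (`chemonet.metabolic`) — the pipeline's core:
   reaction-level regulation inferred from gene-level differential
   expression through gene–protein–reaction (GPR) rules. For a reaction
   with rule *R*, each Monte-Carlo draw perturbs every gene's log₂ fold
   change δ_g with its standard error, maps it to a linear activity
   2^δ_g, and evaluates *R* with AND → min (complexes are limited by the
   scarcest subunit) and OR → sum (isoenzymes add capacity); regulation
   is log₂ of that activity against an all-ones baseline. The draw
   distribution (n = 1000) gives the SD, percentile 95% CI and an
   empirical sign p-value, FDR-corrected across reactions and summarised
   per model subsystem.
5. **Survival** (`chemonet.survival`) — Kaplan-Meier, the Peto-Peto
   weighted log-rank test, uni-variable Cox with a natural-cubic-spline
   non-linearity test, and ridge-penalised Cox with Harrell's concordance
   to quantify the add-on value of expression over clinical covariates.

Because the original cohorts (TCGA KIRC, CheckMate, GEO, ICGC …) are
large or access-controlled, `chemonet.synthetic` generates multi-cohort
studies with the same statistical structure — two latent clusters split
on the panel, donor-paired tumor/normal samples, infiltration scores
coupled to panel expression, co-regulated IFN/metabolic/TRP gene modules,
null-by-default survival, and a toy metabolic model whose true reaction
regulation is analytically computable — so every stage is tested against
ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole study (fixed seed,
two cohorts of 200 tumors each) and write tidy tables to `results/`:

```sh
cd analysis
python 01_simulate.py && python 02_screen.py && python 03_cluster.py
python 04_profile.py && python 05_metabolize.py && python 06_survival.py
```

`02_screen.py` recovers exactly the planted panel from 58 candidates
(8/8 panel genes selected, 0 of 50 null genes; e.g. CXCL9: Δlog₂ = 3.10,
ρ(CD8) = 0.74). `03_cluster.py` reports the silhouette peak at k = 2
(0.656 vs 0.411 at k = 3), training ARI 1.000 against the planted labels,
10-fold CV stability 1.000, and 15-NN projection onto the sibling cohort
with 100% label agreement (explained-variance gap 0.016). A condensed
view of `05_metabolize.py`:

```
reaction_id   subsystem                  log2_reg  ci_low  ci_high  status     true_log2_reg
OXPHOS_C1     Oxidative phosphorylation    -1.389  -1.651   -1.139  inhibited           -1.0
TCA_IDH       Citric acid cycle            -1.040  -1.202   -0.872  inhibited           -1.0
FAO_ACAD      Fatty acid oxidation         -1.261  -1.483   -1.065  inhibited           -1.0
TRP_IDO       Tryptophan metabolism         1.098   0.913    1.277  activated            1.0
CTRL_NULL     Control                       0.035  -0.154    0.228  unchanged            0.0
```

All oxidative subsystems come out 100% inhibited and tryptophan
metabolism 100% activated in the chemokine-high cluster, matching the
planted module shifts, while the control reaction stays unchanged.
`06_survival.py` closes the loop on the null survival design: Peto-Peto
p = 0.767 between clusters, and ridge-Cox concordance 0.702 (clinical)
vs 0.701 (clinical + expression) — no add-on value from the panel, as
planted.

A `chemonet` console script exposes the same stages over plain-text
files (`chemonet simulate|screen|cluster|project|profile|metabolize|survive --help`).

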