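# famres

Familial resemblance and family-based heritability of dietary intake
traits, built for nutrition-epidemiology cohorts that collect repeated
food-frequency-questionnaire (FFQ) surveys on multigenerational families.

Given a pedigree (LINKAGE/PLINK-style PED text) and per-survey nutrient
intake records, `famres` answers two questions:

1. **How similar are relatives' intakes?**  For every relative-pair type
   (spouse, the four sexed parent-offspring dyads, the three sibling
   dyads, grandparent, avuncular, half-sibling, cousin) it estimates a
   familial correlation — the double-entry intraclass correlation for
   exchangeable pairs, the interclass Pearson correlation for ordered
   ones — with Fisher-z p-values and an optional family-cluster bootstrap.
2. **How heritable is each intake trait?**  It fits the Gaussian
   variance-component model y = Xβ + g + e per family, with
   cov(g) = 2Φσ²g built from the pedigree kinship matrix Φ and
   cov(e) = σ²e·I, by profile maximum likelihood over
   h² = σ²g/(σ²g + σ²e), reporting h² with a curvature-based SE.

Between the raw surveys and those analyses sits the standard FFQ
preprocessing chain: exclusion of implausible energy reports (outside
800-4200 kcal/d), per-person averaging over repeated surveys, nutrient
density (per 1000 kcal) and percent-of-energy scaling, age adjustment by
OLS residuals, and the rank-based inverse normal transform (Blom offset).

Because such cohort data are rarely shareable, the package includes a
synthetic cohort generator with known structure — gene-dropped additive
genetics plus household and couple environmental factors — so the whole
pipeline is testable by oracle equivalence and parameter recovery.  See
`docs/methods.md` for the model details and design choices.

## Worked example

The repository ships a demo configuration that simulates a 300-family
cohort, preprocesses it, and runs both analyses:

```sh
famres run-all --config examples/demo.yaml --out demo_out
```

`demo_out/fcor.tsv` holds the familial correlations.  For energy intake
(selected relations):

```text
       relation       trait     r  n_pairs    se     p  significant
         spouse energy_kcal 0.270      197 0.069 0.000         True
mother-daughter energy_kcal 0.224      191 0.071 0.002         True
     father-son energy_kcal 0.150      188 0.072 0.040         True
  sister-sister energy_kcal 0.055       69 0.122 0.656        False
 brother-sister energy_kcal 0.040      135 0.087 0.645        False
```

Spouses resemble each other most, parent-offspring pairs are
intermediate, and siblings least — the generating model's ordering.
`demo_out/h2.tsv` holds the heritability table:

```text
                trait  h2_percent  se_percent   n  converged  boundary
          energy_kcal        24.5         6.7 945       True     False
       carbohydrate_g        33.7         6.6 945       True     False
            protein_g        16.1         6.3 945       True     False
                fat_g        26.6         6.1 945       True     False
  protein_per1000kcal        19.3         6.2 945       True     False
carbohydrate_pct_kcal        26.3         6.7 945       True     False
         fat_pct_kcal        19.7         5.8 945       True     False
```

The demo traits were generated with h² = 0.20 plus household and couple
environment the two-component model cannot separate from genetics, so the
estimates scatter around and above 20% — a deliberate illustration that
family-based heritability absorbs shared environment (see
`docs/methods.md`).  `demo_out/manifest.json` records config, input and
output digests; re-running the same config reproduces identical digests.

Each stage is also available separately (`famres simulate`, `famres
preprocess`, `famres fcor`, `famres h2`) and as library functions
(`famres.read_ped`, `famres.kinship`, `famres.classify_pairs`,
`famres.preprocess`, `famres.correlation_matrix`, `famres.fit_vc`, ...).

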