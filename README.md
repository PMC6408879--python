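# aviamorph

Phylogenetic geometric morphometrics of modular skull shape.

`aviamorph` is for comparative morphologists asking how ecology shapes the
tempo and direction of phenotypic evolution across a clade — the canonical
use case being avian cranial evolution, where 3D landmark data on hundreds
of species are partitioned into anatomical modules (rostrum, palate,
cranial vault, occipital, basisphenoid, pterygoid/quadrate, naris) and
confronted with dietary and foraging-behaviour data on a time-calibrated
phylogeny. The package implements the whole chain: Procrustes alignment,
dietary-guild classification, phylogenetic distance-based MANOVA,
multivariate evolutionary-rate comparison, two-block PLS, PCA, and a
synthetic-data generator that makes every stage testable without any
external download.

## The statistics at its core

Landmark configurations are superimposed by **generalized Procrustes
analysis** (translation, rotation and scale removed; centroid size
CS = √Σᵢ‖xᵢ − x̄‖² retained as the size variable), giving the trait matrix
**Y** (N species × 3L coordinates).

Phylogenetic structure enters through the Brownian-motion covariance
**C** (Cᵢⱼ = shared root-to-MRCA path length) and its symmetric inverse
square root **P = C^(−1/2)**. With the GLS root estimate
a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹Y, the whitened residuals **U = P(Y − 1a)** are
exchangeable under Brownian motion, which licenses permutation inference:

* **Phylogenetic np-MANOVA.** Goodall-style sums of squares of the
  whitened data on a group design; F = (SS_model/df_m)/(SS_res/df_r);
  significance by the residual-randomization permutation procedure (RRPP:
  permute reduced-model residual rows, re-add reduced fits, recompute F),
  p = (b + 1)/(m + 1); effect size Z from the log-F null distribution.
* **Multivariate rate σ²_mult** = Σᵢ dᵢ²/N with dᵢ = ‖Uᵢ‖; group rates are
  subgroup means of dᵢ² from the *full-tree* transformation, compared by
  the max/min ratio against single-rate BM simulations on the same tree.
* **Phylogenetic two-block PLS.** SVD of the cross-covariance of two
  whitened, centred blocks; r-PLS is the correlation of paired axis
  scores; axis-1 significance by row permutation of the second block.
* **Dietary guilds.** Ten raw food-resource columns merge to eight
  ecological categories; a species joins the guild holding ≥ 60 %
  (inclusive) of its resources, otherwise it is an omnivore — nine guilds
  in total. Foraging descriptions become 30-dimensional scores summing to
  10 per species.

## Worked example

Generate a synthetic clade (32 tips, 21 landmarks, granivores evolving 4×
faster than invertivores) and run the full analysis:

```python
from aviamorph import SyntheticScenario, AnalysisConfig, run_full_analysis
from aviamorph.synthetic import generate_scenario_bundle

bundle = generate_scenario_bundle(
    SyntheticScenario(n_tips=32, n_landmarks=21,
                      regimes={"granivore": 4.0, "invertivore": 1.0},
                      tree_seed=7, trait_seed=8, diet_seed=9),
    "demo/in")
config = AnalysisConfig(
    landmarks=str(bundle["landmarks"]), tree=str(bundle["tree"]),
    partition=str(bundle["partition"]), resources=str(bundle["resources"]),
    foraging=str(bundle["foraging"]), seed=42, outdir="demo/out",
    iterations=999, nsim=499)
report = run_full_analysis(config)
print(report.manova[["SS_model", "R2", "F", "Z", "p"]].round(4))
```

```
                    SS_model      R2       F       Z      p
module
whole_skull           0.1538  0.0627  2.0077  2.4106  0.010
rostrum               0.0107  0.0317  0.9834  0.2373  0.419
palate                0.0238  0.0695  2.2398  1.7381  0.030
vault                 0.0310  0.0795  2.5910  1.9857  0.010
occipital             0.0144  0.0375  1.1694  0.5453  0.295
basisphenoid          0.0114  0.0343  1.0655  0.3598  0.370
pterygoid_quadrate    0.0293  0.0863  2.8321  2.0322  0.026
naris                 0.0331  0.1018  3.4000  2.6716  0.004
centroid_size        18.4234  0.0036  0.1085 -0.4263  0.741
```

Diet predicts shape significantly but weakly (whole-skull R² ≈ 0.06,
p = 0.01) while centroid size shows no group effect — the groups differ in
*rate*, not size. The rate table for the whole skull reads
σ²_mult(granivore) = 0.175 vs σ²_mult(invertivore) = 0.054, observed
ratio 3.24, p = 0.002: the simulated 4× contrast is detected (estimates
attenuate slightly because regime history mixes along lineages). PC1
carries 31 % of shape variance, and the whole-skull PLS against foraging
behaviour gives r-PLS = 0.69 (p = 0.39 — foraging tables here are drawn
independently of shape, so no covariation is expected).

The same run is available from the shell:

```sh
aviamorph simulate --tips 32 --landmarks 21 --regimes granivore:4,invertivore:1 --seed 7 --out demo/in
aviamorph run --config run.yaml
```

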