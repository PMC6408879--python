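# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `aviamorph`. Notation: N species, L landmarks, trait matrix
Y (N × 3L), tree covariance C, whitening P = C^(−1/2).

## Procrustes alignment

Configurations are centred, scaled to unit centroid size, and iteratively
rotated to the sample consensus; the consensus is the plain average of the
rotated configurations, rescaled to unit centroid size each round.
Rotations solve the orthogonal Procrustes problem by SVD with a
determinant correction (the smallest singular direction is sign-flipped if
the optimum would be improper), so reflections are never introduced and
chiral shapes keep their handedness. Scale is removed fully (unit centroid
size), and centroid sizes of the *original* configurations are retained
for the size analysis.

Numerical choices:

* The initial consensus is the order-independent average of the centred,
  scaled inputs (fallback to the first configuration if random
  orientations cancel the average to near zero), so specimen order only
  permutes output rows.
* Each new consensus is rotationally anchored to the previous one before
  the convergence check; the criterion (root summed squared change
  < 1e−10) therefore measures shape change of the mean, not the slow
  rotational drift an unanchored average exhibits. Default iteration cap
  1000: realistic samples converge in under ten iterations, but diffuse
  samples with no shared shape signal contract only geometrically
  (~0.75/iteration) and can need a few hundred.
* Module analyses subset the *joint* alignment — modules are never
  re-superimposed separately, so module blocks live in the coordinate
  system of the whole configuration. Re-alignment per module would change
  centring and is deliberately not done.

## Phylogenetic covariance and whitening

C is built by one postorder traversal (Cᵢⱼ = depth of the MRCA, diagonal =
tip depths); polytomies and zero-length internal branches are allowed. P
is the *symmetric* inverse square root from an eigendecomposition, with an
error raised if any eigenvalue falls below 1e−12: the symmetric root is
unique and easily verified (PCPᵀ = I), and every quadratic-form statistic
downstream is invariant to the choice of root, so this is a transparency
choice, not a statistical one. The GLS root a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹Y uses a
Cholesky solve of C.

## MANOVA with RRPP

The test is distance-based (sums of squared entries over all trait
columns), valid when 3L ≫ N. Response and design are premultiplied by P;
group effects use treatment coding. The implementation reduces every
permutation to diagonal quadratic forms of the reduced-residual Gram
matrix G = EEᵀ against gathered orthonormal design bases, so per-iteration
cost is independent of the trait count; the algebra is exact and is tested
against an independently coded closed-form GLS ANOVA F (agreement ~1e−12
relative; asserted at 1e−10).

Conventions: p = (b + 1)/(m + 1) with ties counted as extreme (p is never
0 and has resolution 1/(m+1)); the effect size Z is computed on ln F
(skew reduction), Z = (ln F_obs − mean ln F_perm)/sd ln F_perm with the
sample sd (ddof 1). Default 10 000 iterations in the pipeline; 499 in the
validation simulations, which is ample for calibration at α = 0.05.

## Rate comparison (σ²_mult)

σ²_mult = Σdᵢ²/N; group rates divide subgroup sums by group size N_g (not
N_g − 1 — with the GLS-root centring the statistic is a mean squared
whitened distance, and only rate *ratios* are ever interpreted, for which
the convention cancels). Distances always come from the full-tree
transformation; groups are compared on a common phylogenetic scale rather
than on pruned subtrees. The null simulates single-rate BM tip data as
L·Z (Cholesky factor times iid normals — distributionally identical to
branch-walk simulation at the tips, and vectorizable); the max/min ratio
is scale-free, so the common simulation rate is irrelevant (asserted by a
same-seed two-rate test). Groups need ≥ 2 members; the pipeline drops
singleton guilds from this analysis with a logged warning.

## Two-block PLS

Both blocks are whitened by P and column-centred; the SVD of R₁₂ =
Z₁ᵀZ₂/(N−1) gives paired axes. r-PLS is the Pearson correlation of paired
axis scores, with axis signs flipped to make it non-negative (sign of a
singular-vector pair is arbitrary). The axis-1 p-value permutes rows of
the whitened second block. Covariation fractions are s_k²/Σs².

## PCA

Ordinary (non-phylogenetic) column-centred SVD — this is the morphospace
ordination, purely descriptive, so no evolutionary correction is applied.
min(N−1, t) axes are retained; scores reproduce centred pairwise
distances exactly.

## Dietary classification and foraging scores

Raw tables carry the ten resource columns (terrestrial invertebrates,
three terrestrial-vertebrate columns, fish, carrion, fruit, seeds, nectar,
other plants); an optional separate `aquatic_invertebrates` column is
folded into the aquatic-animal category for datasets that score aquatic
prey apart from fish. Merging pools the vertebrate columns and
fish + aquatic invertebrates; the guild rule is scale-invariant and
inclusive at the 60 % threshold (configurable). With any threshold > 50 %
at most one category can qualify, and omnivore frequency is monotone in
the threshold.

Foraging statements are already-structured (behaviour, qualifier) lists —
the qualitative-to-structured step is human curation and is not
mechanized. Base weights: sole = 10, mostly = 7 (the smallest integer
satisfying "more than 6"), sometimes = 2, occasionally = 1,
unqualified = 3. A positive remainder to 10 is distributed one unit at a
time cycling from the earliest-listed entry (earlier-listed strategies are
up-weighted when the description gives no frequencies); an oversubscribed
base is rescaled proportionally. Rows always sum to exactly 10.

## Synthetic data

The generator produces the structure the analysis assumes, not avian
anatomy:

* **Trees**: pure-birth at unit rate, run one extra waiting time past the
  n-th tip, rescaled to root height exactly 1 — rates are therefore "per
  tree depth", which keeps recovery tolerances scale-free.
* **Regimes**: uniform root state, continuous-time Markov switching along
  branches (uniform jumps among the other regimes); a branch carries its
  child node's regime. Default switch rate 0.5 per unit branch length
  gives a handful of regime origins per 64-tip clade — regimes form
  clusters, as dietary guilds do, while still arising repeatedly.
  Paintings are resampled (≤ 100 draws) until every regime has ≥ 2 tips.
* **Shapes**: a deterministic Fibonacci-sphere template (unit centroid
  size) evolves per coordinate by BM at base_rate × regime multiplier
  (default base rate 0.001 per unit height: tip shapes stay near the
  template, as real cranial samples do relative to their consensus).
  Tips are emitted both as the latent truth and re-posed with random
  rotations, scales (0.5–2 × 10) and translations to exercise GPA. Noise
  is isotropic per coordinate.
* **Trait tables**: non-omnivores draw 65–92 % of resources in their
  guild's category (remainder Dirichlet over the others); omnivores draw
  Dirichlet compositions resampled until the maximum merged share is
  below 55 %, keeping them strictly inside the omnivore region. Foraging
  rows are scored from regime-typical statements.

What the generator does *not* emulate: anatomical templates and realistic
module covariance, allometry, measurement error, within-species variation,
fossil sampling, non-Brownian (OU/early-burst) dynamics, and any
correlation between foraging tables and shape. Passing tests therefore
demonstrate statistical correctness and calibration of the machinery, not
biological conclusions about real skulls.

## Validation design and problem sizes

The validation suite works at 64 tips / 50 landmarks (150 trait columns)
with 499 permutations or simulations per test and 100–500 replicates per
property — sizes at which binomial error bounds on a 5 % rejection rate
are tight enough to detect miscalibration while the whole suite stays
desk-scale. Known behaviour worth noting: the estimated rate ratio under
a true 4× contrast concentrates near ~3.3, not 4.0 — tips' lineages spend
part of their history in the other regime and share deep single-regime
branches, so subgroup rates are lineage-history-weighted mixtures. The
recovery band used ([3.2, 4.8] on the median) reflects that attenuation;
the estimate is strictly monotone in the true contrast.

## Pipeline reproducibility

The config seed expands to per-stage seeds as
`int.from_bytes(sha256(f"{seed}:{stage}")[:4]) % 2^31` with stage names
like `manova:whole_skull` — stages never share permutation streams, and
any stage can be replayed alone. Output TSVs use fixed headers and `%.10g`
floats; the run log records package/library versions, every stage seed and
SHA-256 checksums of all inputs. Reruns are byte-identical. Taxon sets
must match exactly (after whitespace trimming) across landmarks, tree and
trait tables; any orphan aborts the run with a full listing — silent
intersection would hide data loss.

## Known limitations

* One configuration per species; within-species variation is not modelled.
* Single-factor designs only (diet group); no multi-factor MANOVA,
  modularity/integration tests, or OU-type model fitting.
* Landmark interchange is wide-CSV (canonical) and TPS (read/write);
  no mesh formats, NEXUS trees, or missing-landmark estimation.
* The MANOVA SS column reports both model and total SS; which of the two
  a given published table prints can be ambiguous, so both are kept.
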