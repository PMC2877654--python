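# Methods

This note documents the statistical machinery in `tadfd`: the FD
measure and its conventions, the null model, the curve comparison, the
habitat ordination, and — because the pipeline is validated entirely
against synthetic data — what the generators do and do not emulate.

## Functional diversity on a regional dendrogram

**Gower distance.** For species *i*, *j* over *T* traits,
d(i,j) = (1/T) Σₜ δₜ with δₜ the range-normalised absolute difference
for continuous traits and the mismatch indicator for binary traits.
All columns are weighted equally by default.  Because a multi-state
ecological trait (e.g. six oral-disc shapes) is dummy-coded into
several binary columns, the flat weighting implicitly up-weights
multi-state traits; `gower_distance(..., per_group_weights=True)`
instead gives each ecological trait total weight 1.  The flat treatment
is the default because the trait table is defined as 18 equally listed
columns.  Continuous ranges are computed over the full regional pool;
a zero-range continuous trait is an error (it carries no information
and makes the normalisation undefined).  Missing values are rejected
rather than pairwise-deleted.

**Dendrogram.** Agglomerative clustering by Lance–Williams updates for
single, complete, UPGMA, WPGMA, and Ward linkage.  A merge at linkage
distance *d* creates a node at height *d*/2, so the cophenetic distance
between two leaves is the linkage distance of the merge that joined
them and the tree is ultrametric (Ward operates on squared distances;
its height is the square root of the merge criterion, halved).  Ties in
the minimal distance are broken by the lexicographically smallest pair
of cluster representatives (a cluster is represented by its smallest
member label), which makes trees bit-reproducible across platforms.
All five linkages agree with an independent implementation
(scipy.cluster.hierarchy) to machine precision on tie-free inputs; the
hand-rolled agglomerator exists to own the tie-break rule and to keep
the tree object (heights, leaf sets, branch lengths) in the form FD
needs.

**Method selection.** For each candidate linkage the criterion is
Σᵢ<ⱼ (d(i,j) − c(i,j))², with c the candidate's cophenetic matrix; the
argmin wins, ties resolved by the fixed preference order UPGMA, WPGMA,
complete, single, Ward.  An ultrametric input is reproduced exactly by
UPGMA (criterion 0).

**FD.** One dendrogram is built from the full regional pool; a
community's FD is the total branch length of the minimal subtree
spanning its members, truncated at the members' lowest common ancestor.
Equivalently, a branch counts iff the member set intersects the leaves
below it without containing them — the form used by the vectorised
implementation (one boolean matrix product per batch of communities).
Conventions: FD(singleton) = 0; FD(full pool) = total branch length.
The regional-tree convention (rather than re-clustering each community)
guarantees set monotonicity — A ⊆ B ⇒ FD(A) ≤ FD(B) — and puts
observed and random assemblages on the same scale, which the null model
requires.

## Null model and curve comparison

**Predicted FD.** For a site with richness S, the null distribution is
FD over uniform S-subsets of the full 36-species pool, drawn without
replacement; the site's predicted FD is the mean over 500 replicates
(the spread and Monte-Carlo SE are reported).  Sites of equal richness
share one batch of draws — the null depends on a site only through S.
The exact expectation is also available in closed form: branch *b* with
n_b descendant leaves is spanned with hypergeometric probability
1 − C(N−n_b, S)/C(N, S) − C(n_b, S)/C(N, S) (last term when n_b ≥ S),
and E[FD] = Σ_b len_b · P(spanned).  The closed form is validated
against exhaustive subset enumeration for pools ≤ 12 in the test suite
and is used as the oracle for the Monte-Carlo sampler.

**Redundancy.** OLS of observed FD on SR (linear) and on SR + SR²
(quadratic, raw powers).  Verdict "redundancy" when the quadratic
coefficient is negative with p < 0.05.  With 29 sites the denominator
df are 27 (linear) and 26 (quadratic).  Raw rather than orthogonal
polynomials: at these sizes the quadratic term's test is unaffected,
and raw coefficients are directly interpretable as curvature.

**Michaelis–Menten comparison.** Observed and predicted points are fit
jointly as FD = (F + δF·g)·S/((K + δK·g) + S), g = 1 for observed, by
nonlinear least squares (trust-region via `scipy.optimize.curve_fit`,
starting values F₀ = 1.1·max FD, K₀ = median SR, with a 3×3 restart
grid scaling both by {0.5, 1, 2}; non-convergence after the grid is an
explicit error).  K is the half-saturation richness (the standard
Michaelis constant).  t = δ/SE(δ) with joint-fit standard errors and
df = n − 4 (54 for 29 + 29 points); p-values are one-sided for the
alternative "observed below predicted", matching a design whose
filtering hypothesis is directional — a positive offset, however large,
is never evidence and yields p near 1.  The verdict "low FD" requires
the one-sided test on δF to reject; the K contrast is reported but a
high observed FD is never asserted from this test.

## Habitat ordination

Variables whose absolute sample skewness exceeds 1 are Box-Cox
transformed (λ on the grid [−2, 2] step 0.1 by profile log-likelihood;
zeros handled by an offset of half the smallest positive value,
recorded in the output).  The skewness rule operationalises
"transform the outlier-prone variables" reproducibly; the transformed
set is always reported.

PCA is computed on the correlation matrix (eigenvalues sum to 14, the
variable count), loadings sign-fixed so each component's
largest-magnitude loading is positive.  Loading significance uses the
bootstrapped-eigenvector approach: resample sites with replacement,
recompute the PCA, align bootstrap axes to the original greedily by
maximal absolute loading-vector inner product (sign flipped to positive
congruence), and flag a loading when its (1 − α) percentile interval
excludes zero.  Degenerate resamples (a variable constant) are redrawn
and counted.  Calibration measured on pure-noise tables (n = 29,
p = 14): the overall flag rate is ~2–3 % at α = 5 %, composed of a
liberal leading axis (~10–13 % — the bootstrap reproduces the chance
anisotropy of the sample) and conservative trailing axes (~0–2 %,
whose eigenvectors rotate freely across resamples).  This
heterogeneity is a known property of the method, not a tuning choice;
the acceptance benchmark records the overall rate.

Component retention defaults to the broken-stick rule (retain leading
components whose variance share exceeds bₖ = (1/p) Σ_{j≥k} 1/j), with a
manual override for scree-plot judgement.  SR is then regressed on the
retained component scores without interactions; components with
p ≥ 0.05 are removed backward, worst first, to a minimal adequate
model, and the elimination trace is reported.

## Synthetic data: what it emulates

The generators reproduce the study geometry: a 36-species pool scored
on 18 traits (two 6-state one-hot shape groups, one free binary trait,
five continuous traits), 29 sites with richness uniform on 2–18, and
14 habitat variables.

**Guild structure.** Species belong to functional guilds (default 6)
with skewed prevalences (0.35, 0.25, 0.15, 0.12, 0.08, 0.05;
apportioned by largest remainder — sizes 13, 9, 5, 4, 3, 2 at pool
36).  A guild fixes the modal state of each shape group (carried with
fidelity 0.9) and the centre of each continuous trait (clipped normal,
sd 5 % of the range).  This matters: real trait pools are organised
into ecomorphs, and that organisation is what makes the regional
dendrogram clustered and the FD–SR curve saturating (half-saturation
K ≈ 10–18 at these defaults).  A pool of independent uniform traits
yields a near-star tree whose FD curve is almost linear over SR 2–18
(K ≈ 50), and the asymptote comparison then sits on an F–K ridge and
loses all power — so uniform traits are not a neutral default but a
structurally different (and unrealistic) regime.  It remains available
via `TraitSpec(n_guilds=0)`.

**Assembly.** Neutral sites are uniform subsets.  Filtering uses a
single regional optimum — the pool's modal phenotype (species with
minimal mean Gower distance to the pool) — and an effective strength
that ramps linearly from 0 at the onset richness (default: midpoint of
the richness range) to the nominal strength at the top of the range;
species are drawn without replacement with weight exp(−s_eff·d to the
optimum).  One shared optimum and a richness-dependent ramp encode the
ecological picture of a single stream size–velocity gradient whose
filter acts on species-rich (large-stream) communities while poor
communities assemble randomly; 29 independent per-site filters of
uniform strength produce an FD deficit concentrated at low richness,
which changes the curve's shape rather than its asymptote and is not
the pattern this pipeline is built to detect.  Competition assembles
greedily at every site, weighting each newcomer by exp(strength · min
distance to residents).  Strength 0 reduces every rule to neutral.

**Calibration at the study scale** (29 sites, 500 null replicates,
α = 0.05, seeded): the low-FD verdict fires in ≈ 4–6 % of neutral
replicates and in ≥ 95 % of filtering replicates at the benchmark
strength 16 (power exceeds 80 % from strength ≈ 8 upward).

**Habitat.** One latent axis is built with Pearson correlation equal to
the requested coupling with SR (default 0.9), loading positively on
width and dragonfly larvae, negatively on slope and both canopy covers;
the four substrate percentages are a logistic-normal composition
summing to 100 that shifts from leaves/sand to gravel/rock along the
axis; the remaining five variables are independent noise.  Coupling 0
decouples everything from SR.

**What passing tests do not show.** The generators draw independent
sites (no spatial autocorrelation along stream networks), presences
without abundances, exactly met richness (no detection error), and
habitat noise that is well-behaved (no heavy-tailed measurement error
beyond the skewed marginals).  Calibration results therefore speak to
the statistical machinery under the stated generative assumptions, not
to robustness against field-data pathologies.

## Numerical conventions

- All generators and resampling procedures are pure functions of
  (parameters, seed); the pipeline splits one root seed into named
  per-stage substreams (traits, communities, habitat, null model,
  bootstrap) in a fixed order, and the JSON report is byte-identical
  across re-runs.
- Agglomeration ties: lexicographic representative pairs (above);
  selection ties: fixed preference order; merge heights are clamped
  monotone as a floating-point guard.
- The MM fit treats both groups with unit weights; predicted points
  (means of 500 draws) are nearly noise-free, so the pooled residual
  variance is dominated by the observed group.  The measured type-I
  rate of the verdict under neutral assembly (~5 %) shows this pooling
  is benign at the study scale.
- Problem sizes in the test suite and acceptance benchmark (pools ≤ 12
  for exhaustive enumeration, 100 oracle instances, 500 calibration
  replicates, n_boot 199/999) were chosen as the smallest sizes at
  which the binomial/Monte-Carlo error bands in the assertions are
  meaningful.

## Known limitations

- FD is presence-based; abundance-weighted diversity (e.g. Rao's Q) is
  out of scope.
- No consensus trees across clustering methods; one selected linkage
  builds the dendrogram.
- The bootstrapped-eigenvector flags have heterogeneous per-axis error
  rates (see above); treat per-loading significance as descriptive.
- The low-FD verdict tests the asymptote offset only; filtering regimes
  that depress FD mostly at low richness alter K or the curve shape and
  are not detected by this contrast.
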