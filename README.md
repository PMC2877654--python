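# tadfd

Dendrogram-based functional diversity for stream tadpole communities:
Gower trait distances, UPGMA functional dendrograms, richness-controlled
null models, and habitat ordination — as one tested, reproducible
pipeline.

## The scientific problem

Species richness (SR) counts species as interchangeable units.
Functional diversity (FD) instead measures how much *ecological
function* a community spans: species are placed in a trait space
(here, 18 tadpole morphological traits related to feeding and habitat
use — oral-disc shape, jaw-sheath shape, keratodont rows, papillae,
body-shape ratios, eye position), pairwise dissimilarities are computed
with **Gower's coefficient** (the standard choice for mixed
binary/continuous traits),

d(i, j) = (1/T) Σₜ δₜ(i, j),   δₜ = |xᵢₜ − xⱼₜ|/rangeₜ (continuous) or [xᵢₜ ≠ xⱼₜ] (binary),

the regional pool is clustered into an ultrametric dendrogram (UPGMA is
chosen automatically by minimising Σᵢ<ⱼ (dᵢⱼ − cᵢⱼ)² between input and
cophenetic distances), and the FD of a community is the **total branch
length of the minimal subtree** connecting its members (the
Petchey–Gaston measure).

Two questions follow for a set of stream communities:

1. **Functional redundancy** — does FD saturate as SR grows?  Tested by
   polynomial regression FD ~ SR + SR²; a significantly negative
   quadratic term means added species increasingly duplicate functions.
2. **Low FD / environmental filtering** — is observed FD lower than in
   random assemblages of equal richness?  Each site's *predicted FD* is
   the mean FD of 500 random draws of the same number of species from
   the full regional pool.  Observed and predicted FD–SR curves are
   fitted jointly with Michaelis–Menten saturation curves
   FD(S) = F·S/(K + S) with group offsets, and a one-sided t-test on
   the F (asymptote) offset (df = n − 4) flags "low FD" — the signature
   of habitat filtering — when the observed asymptote is significantly
   below the predicted one.

A habitat stage links SR to the environment: Box-Cox transforms for
skewed variables, PCA on the correlation matrix of the 14 stream/forest
variables, bootstrapped-eigenvector significance tests for loadings,
broken-stick component retention, and backward-eliminated regression of
SR on the retained components.

Because the field data behind this design (29 Madagascan rainforest
stream sections, 36 tadpole species) were never deposited, the package
ships a first-class synthetic-data module that generates
guild-structured trait pools, communities assembled under neutral /
filtering / competition rules, and habitat tables organised around one
stream size–velocity gradient.  Everything downstream is calibrated
against these generators.

## Worked example

```python
from tadfd import RunConfig, run_pipeline

cfg = RunConfig(simulation={"rule": "filtering", "strength": 16.0}, seed=1)
report = run_pipeline(cfg, outdir="results/demo")
st = report["stages"]
print(st["trait_space"]["selected_linkage"])
print(st["redundancy"]["redundancy"], st["mm_comparison"]["t_delta_fmax"])
print(st["verdict"]["verdict"])
```

With this seed the run prints (via the report):

```
selected linkage: upgma        # criterion 0.75 vs WPGMA 0.96, complete 3.1, single 5.8, Ward 273
PC shares: [51.1, 11.3, 9.3]   # % variance of PC1..PC3; PC1 = size-velocity gradient
SR model: ['PC1'] R2 0.72      # PC2/PC3 backward-eliminated
redundancy: R2 lin 0.36 quad 0.59, quad coef -0.0052 (p 0.0008) -> True
MM: Fmax obs 1.192 pred 2.072, t -3.42, df 54, p 0.0006
verdict: low FD
```

Read: the habitat PCA recovers one dominant gradient that predicts
richness; the FD–SR curve bends down (functional redundancy); and the
observed asymptotic FD sits significantly below the random-assembly
expectation (one-sided t on the asymptote offset), i.e. species-rich
communities are more functionally similar than chance — environmental
filtering.  Under `rule="neutral"` the same pipeline returns
`"not low"` for ~95 % of seeds.

The same stages are available from the shell:

```bash
tadfd simulate --rule filtering --strength 16 --seed 1 --outdir data/
tadfd fd --traits data/traits.tsv --communities data/communities.tsv --outdir out/
tadfd nullmodel --tree out/dendrogram.nwk --communities data/communities.tsv --outdir out/
tadfd ordinate --habitat data/habitat.tsv --communities data/communities.tsv --outdir out/
tadfd run-all --seed 1 --outdir run/
```

Artifacts are plain text: TSV tables, a Newick dendrogram with branch
lengths, and a JSON report that is byte-identical across re-runs with
the same config and seed.

## Layout

| module | contents |
| --- | --- |
| `tadfd.traitspace` | Gower distances, agglomerative dendrograms (single/complete/UPGMA/WPGMA/Ward, deterministic tie-breaks), clustering-method selection, subtree FD |
| `tadfd.simulate`   | guild-structured trait pools, neutral/filtering/competition assembly, habitat gradients, sampling-design helpers |
| `tadfd.nullmodel`  | richness-controlled null FD (Monte Carlo + exact hypergeometric expectation), redundancy regression, grouped Michaelis–Menten comparison, low-FD verdict |
| `tadfd.ordination` | Box-Cox screening, correlation-matrix PCA, bootstrapped-eigenvector loading test, broken-stick retention, SR regression with backward elimination |
| `tadfd.pipeline`   | end-to-end orchestration with per-stage seed substreams and a reproducible JSON report |
| `tadfd.cli`        | `tadfd simulate / ordinate / fd / nullmodel / compare / run-all` |

See `docs/methods.md` for the statistical methods, default parameters,
and the design decisions behind the synthetic generators.
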