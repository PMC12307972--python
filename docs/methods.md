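# Methods

`cyclewealth` analyses two-layer sociocentric village networks — an
undirected friendship layer and an undirected borrow/lend layer — and asks
how participation in short network cycles, and the wealth of the people on
those cycles, relates to individual and village wealth. Because cohort data
of this kind are restricted, the package ships a synthetic cohort generator
that reproduces the statistical structure the analysis assumes; every
statistical claim the test suite makes is made about that generator's output,
not about any real population.

## Network construction

Ties come from survey name generators. A friendship edge joins a dyad if
either member nominates the other under any of three friendship generators
(closest friend, free time, personal/private matters); a borrow/lend edge if
either nominates the other as a trusted borrowing or lending partner. Three
cleaning rules apply before any analysis: self-nominations are dropped,
nominations of persons outside the analyzable roster are dropped, and ties
within a household are removed (household members share the wealth index, so
within-household ties carry no wealth contrast). All layers are simple
undirected graphs over the full roster; people with no ties stay in the node
set and receive zero censuses. Overlap accounting reports the shared-tie
count against the borrow/lend, friendship, and union volumes; in pooled mode
counts are summed over villages and waves before dividing. The union volume
is always computed as |F| + |B| − |F∩B| from the package's own counts.

## Cycle and path censuses

A k-cycle is a closed walk of k edges over k distinct vertices; a k-path is
a simple path of exactly k edges. For k ≤ 5 the set of closed walks over
contiguous distinct edges coincides with the set of simple cycles (two
edge-disjoint sub-cycles need at least six edges), a fact the test suite
asserts with an independent walk-enumeration oracle. The census is a
depth-first search from each anchor vertex restricted to higher-labelled
vertices, emitting each cycle exactly once in canonical form (smallest
vertex first, then toward the smaller of its two neighbours) and each path
once oriented from its smaller-labelled endpoint. Per-node path incidence
counts all positions, endpoints and interior alike. Node counts and graph
totals satisfy Σₙ Cy_k(n) = k·|P_k(G)| and Σₙ path incidence =
(k+1)·(path total); both identities are asserted on every output in tests.
Enumeration is guarded at K ≤ 6 (the analysis range is 3–5); a brute-force
census over ordered vertex tuples (≤ 14 nodes) serves as the test oracle.
Cycle membership, when requested, is stored as the canonical vertex
*sequence*, not the vertex set, because distinct 4- and 5-cycles can share a
vertex set inside dense subgraphs.

## Null ensembles and cyclic density

The null model preserves node count, edge count, and the full per-node
degree vector via double-edge swaps that reject self-loops and multi-edges.
The default rewiring depth is 10·|E| accepted swaps (a common mixing
heuristic); graphs with no swappable edge pair (stars) are returned
unchanged with a warning flag rather than looping forever. With 50
replicates (the default), the package reports per-k null means and SDs, the
count Z-score (observed − mean)/SD, and the k-cyclic density

    C_k(G) = ln( max(1, |P_k(G)|) / max(1, E|P_k(G_R)|) ),

with the overall density C(G) the arithmetic mean over k = 3..5. The
max(1,·) guard is applied to the numerator as well as the denominator: an
observed count of zero would otherwise send the logarithm to −∞, so it is
clamped and flagged `observed_zero` instead. Z is reported as NaN (flagged),
never 0, when the null SD vanishes. Expected counts use the ensemble mean.

## Wealth index

Household wealth is a relative index built from 14 categorical asset items
(water source, toilet type, stove use, cooking fuel, electricity, radio,
television, mobile and non-mobile phone, separate kitchen, windows, floor,
wall and roof materials) by multiple correspondence analysis: simple
correspondence analysis of the complete disjunctive matrix, no
Benzécri/Greenacre inertia correction (raw inertia shares are reported and
printed in every report). Dimension-1 row principal coordinates are the
household scores; the sign is fixed so the highest category of a
configurable anchor item (default: electricity present) sits on the positive
pole. Scores are invariant to duplicating households and to category
relabelling (up to global sign); both are property-tested. Households are
then weighted by household size and cut into person-weighted quintiles
(class 1 = poorest fifth of persons, 5 = richest); tie blocks straddling a
breakpoint go to the lower class. For regressions, each multi-category
"type" item is binarized high/low; the default mapping marks codes strictly
above the midpoint of the observed code range as improved, and a custom
mapping can be supplied and is echoed into reports.

## Cycle composition ("cycle quality")

The k-cycle composition of node n summarises the wealth w_j of the alters on
its k-cycles. Two variants are computed. The *literal* variant divides the
alter-wealth sum by k·|P_k(n)| even though each cycle contributes k−1
alters, so constant wealth w scores (k−1)·w/k; the *alters-mean* variant
divides by (k−1)·|P_k(n)| and equals the plain average alter wealth. The two
differ only by the constant factor (k−1)/k, which z-scoring removes; the
alters-mean is the default in all downstream models because it is directly
interpretable as "average wealth of the alters". Nodes in no k-cycle are
undefined (NaN) and are excluded from composition models, never
zero-imputed. Composition is affine-equivariant in wealth and invariant to
node relabelling (property-tested).

The wealth-class assortativity matrix counts each undirected edge once under
its unordered class pair and normalises by the edge count (total
normalisation; a row-normalised view is available). Control centralities are
degree, eigenvector centrality (per connected component, tolerance 1e-10,
zero for isolates, global unit-max scaling), and normalised shortest-path
betweenness.

## Individual-level model batteries

Every battery cell is a mixed model with a village random intercept,
matching a sampling design of mutually isolated villages. Binary outcomes (the
high/low asset items) use a random-intercept logistic fitted by marginal
maximum likelihood with 25-node Gauss–Hermite quadrature — written in-package
because no installed Python library provides a frequentist binomial GLMM —
and validated against `lme4::glmer` (nAGQ = 25) on a frozen fixture, where
coefficients, SEs and the intercept SD agree to ~4 decimals. Continuous
outcomes (the 1–5 wealth index, cycle counts, quality) use statsmodels
MixedLM (REML, with optimizer fallbacks lbfgs → bfgs → cg → powell).

All continuous predictors and outcomes are z-scored before fitting, so
coefficients are per-SD ("scaled"); a divide-by-2-SD mode is available via
config. Cycle and path counts are log1p-transformed before standardisation
(their raw distributions are heavily right-tailed). The quantity families
control for same-length path incidence, layer degree, and leave-self-out
village mean wealth; longitudinal families additionally control for the
wave-1 value of the outcome; quality families control for village wealth
only. Reverse families swap the key predictor and the outcome. Non-
convergence and possible separation are flagged on the result, not raised;
a rank-deficient design (e.g. a control duplicating the key predictor) is a
caller error and raises. Variance inflation factors are computed per fit and
flagged above 10.

Benjamini–Hochberg correction is applied within each declared family (one
heatmap's worth of tests), and rendered heatmaps mask cells with q ≥ 0.05.
The q-values are property-tested against a direct step-up implementation.

The gain/loss stratification contrasts, within each wave-1 wealth-class
stratum, persons who rose versus fell a class by wave 2 (stable persons
excluded) in a mixed logistic of gain on the standardized cycle metric.
Class 5 cannot rise, so its "gain" is defined as holding class 5 versus
dropping; this boundary rule is stamped into the output. Strata with fewer
than 10 contrasts or 2 villages are reported not-estimable rather than
raising.

## Village level

Village summaries carry size, person-mean wealth, per-k cycle totals,
cyclic/path densities, and mean cycle quality over quality-defined nodes
(missing, not zero, when no node qualifies). Two regression specifications
run per k: village wealth on cyclic and path density, size, and a wave
indicator with a village random intercept (both waves pooled; "time" is the
wave dummy), and village wealth on mean cycle quality and size by OLS. A
screening block regresses cycle totals and densities on village size.

The permutation null shuffles wealth labels uniformly within each village
(default B = 1000; tests use B = 200–300), holding the network fixed — so
village size, the wealth multiset, and mean wealth are preserved exactly —
and recomputes mean cycle quality from cached cycle membership (an
incidence-matrix product; equality with full re-enumeration is spot-checked
in tests). Per-village z = (observed − null mean)/null SD; villages with no
k-cycles are excluded from pooling and recorded, and constant-wealth or
single-cycle villages are flagged degenerate. Pooling uses Stouffer's
weighted combination (weights √(defined-node count)) with a two-sided
p-value; the combining procedure is a package choice and is labelled in the
output. Note the statistic has power only when cycle *participation* is
wealth-structured: homophily alone relabels who sits next to whom without
shifting the village mean quality, so detection requires something like the
wealth–degree link described below.

## Synthetic cohort generator

The generator's defaults describe one village: 30 households, household
sizes 1 + Poisson(3.3) (≈ 130 persons, matching a ~22.5k-person, 174-village
cohort), uniform latent wealth-class probabilities, friendship mean degree
8, borrow/lend mean degree 3.5, and 76% of borrow/lend edges drawn inside
the friendship layer (a typical overlap in rural cohorts of this kind). Latent
wealth is assigned at household level and shared by members. Asset items
follow ordinal logit models with slope `item_loading` (default 1.2) on
standardized latent wealth. Edge probabilities combine a lognormal degree
propensity (σ = 0.6, heavy-tailed degree), an exponential homophily kernel
exp(−h·|w_i − w_j|) (default h = 1.0; any monotone kernel would satisfy the
qualitative tests, so the simplest is used), and a log-linear wealth–degree
link `degree_wealth_effect` (default 0.5 per SD of wealth class) reflecting
that richer individuals hold more borrow/lend ties and therefore sit in more
cycles; setting homophily and the wealth–degree link to zero yields a fully
random-mixing cohort, the null condition for calibration tests. Edge
probabilities are scaled by bisection to hit the target mean degree;
borrow/lend edges outside friendship are drawn without replacement by
Gumbel top-k under the same kernel. Within-household ties are never
generated.

Wave 2 retains each wave-1 edge with probability `persistence` (default 0.7
— field estimates of wave-to-wave tie persistence are not available, so this
is a placeholder, not an estimate) and redraws the removed count from absent dyads under the same
kernel. Household wealth moves at most one class per wave (default move
probability 0.25, also a placeholder): movers go up with probability
sigmoid(`gain_effect_quality` · q), where q is the household's mean
standardized wave-1 borrow/lend triangle quality, else down, clamped to
1..5. `gain_effect_quality` is the plantable effect for parameter-recovery
tests and is recorded in the cohort's truth mapping. Per-village seeds
derive deterministically from the master seed via
`SeedSequence(entropy=seed, spawn_key=(1, village_index))`, so any village
regenerates bit-identically.

What the generator does *not* emulate: directed lending flows or amounts,
kinship layers beyond the household exclusion, village-size heterogeneity
beyond Poisson noise, item non-response, and measurement error in the
survey. Passing tests therefore demonstrate internal correctness and
calibration of the methods under these idealised conditions, not properties
of any real cohort.

## Numerical choices and problem sizes

Optimizer tolerances are fixed (GLMM ftol 1e-8; eigenvector centrality
1e-10) and all fits are single-threaded, so identical inputs give
bit-identical outputs. Canonical dyads and node orderings are lexicographic
on string labels. The test suite and acceptance script use deliberately
modest problem sizes chosen for statistical adequacy: planted-effect
recovery uses 20 replicates of 30 villages × ~80 persons (the planted
log-odds of 1.0 per SD makes power essentially 1 at this size); FDR control
uses 50 null replicates of 12 villages; null-model calibration uses 40 seeds
× 50 rewiring replicates; permutation calibration uses 100 seeds at B = 200
(scaled down from the production default B = 1000); MCA recovery uses 1,000
households. The pipeline's analysis range is K = 3..5.

## Known limitations

The GLMM uses fixed (non-adaptive) Gauss–Hermite quadrature, adequate for
village-sized clusters and moderate intercept variance but less accurate for
very large clusters with extreme variance. The permutation pooling assumes
per-village permutation z-scores are approximately normal under the null,
which B = 200 supports only roughly (the pooled null p is slightly
conservative in calibration runs). Path censuses of dense layers (friendship
at mean degree 8, K = 5) dominate runtime; the census is exact enumeration,
so cost grows with dᴷ⁻¹. Undirected ties mean some cycles may reflect
re-direction rather than circulation; nothing here identifies causal
effects of cycle participation.
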