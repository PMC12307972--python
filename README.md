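# cyclewealth

Cycle-motif participation and wealth in two-layer sociocentric village
networks.

In rural settings where formal credit is scarce, borrowing and lending run
through trust-based peer ties, and those ties close into loops: A lends to
B, B to C, C back to A. `cyclewealth` is a toolkit for asking whether such
*network cycles* — and the wealth of the people on them — are associated
with individual and collective wealth. It is written for computational
social scientists and biostatisticians working with sociocentric cohort
data (complete village network censuses over multiple survey waves), and it
ships a synthetic cohort generator because real data of this kind are
typically access-restricted.

## What it computes

For each village's friendship and borrow/lend layers (undirected simple
graphs after household-tie and incomplete-roster cleaning):

- **k-cycle / k-path censuses** (k = 3..5): `Cy_k(n) = |P_k(n)|`, the number
  of distinct simple k-cycles containing person n, counted once per cycle in
  canonical form, with the identity Σₙ Cy_k(n) = k·|P_k(G)|; per-node path
  incidence analogously.
- **Null ensembles and cyclic density**: degree-preserving double-edge-swap
  replicates give count Z-scores and
  `C_k(G) = ln(|P_k(G)| / max{1, E|P_k(G_R)|})`, with the overall density
  `C(G)` the mean over k.
- **MCA wealth index**: multiple correspondence analysis of 14 categorical
  household asset items; dimension-1 scores, person-weighted quintile
  classes 1 (poorest) to 5 (richest).
- **Cycle composition ("cycle quality")**:
  `Cq_k(n) = (1/(k·|P_k(n)|)) Σ_{j∈P_k(n)} w_j` over the alters j of n's
  k-cycles (plus the alters-mean variant with divisor (k−1)·|P_k(n)|, the
  default in models), with wealth-class assortativity matrices and control
  centralities.
- **Association batteries**: mixed-effects regressions (village random
  intercept; Gauss–Hermite logistic GLMM for binary asset outcomes,
  MixedLM for continuous ones) of wealth variables on cycle quantity and
  quality, cross-sectional and longitudinal, forward and reverse, with
  path/degree/village-wealth controls, centrality benchmarking, gain/loss
  stratification, and Benjamini–Hochberg FDR within each family.
- **Village-level analysis**: summaries, density/quality regressions, and a
  wealth-label permutation null (labels shuffled within village, network
  fixed, B permutations; Stouffer-pooled across villages).

See `docs/methods.md` for the full model description and design choices.

## Worked example

```bash
python examples/03_null_densities.py
```

```
two-sided 5% threshold: Z = 1.96

k  observed  null_mean  null_sd      Z   cyclic_density
3        32       20.6     4.56   2.50   +0.441
4       116       75.0    11.02   3.72   +0.436
5       426      277.2    37.71   3.95   +0.430

overall cyclic density C(G) = +0.436 (mean over k).
```

One synthetic village's borrow/lend layer contains 32 triangles where
degree-preserving rewiring expects ~21, a Z of 2.50 — the village closes
significantly more three-person lending loops than its degree sequence
alone explains, and the log-ratio density is positive at every length.

The other examples each demonstrate one capability (cohort generation,
censuses, the wealth index, composition and assortativity, the regression
battery, the permutation test, the full pipeline); each prints what its
numbers mean. The same pipeline is scriptable from the shell:

```bash
cyclewealth run --out-dir run1 --n-villages 8 --seed 3
```

which writes stage tables, figure-analogue report CSVs, and a manifest with
content hashes (identical configs reproduce identical hashes).

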