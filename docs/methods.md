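# Methods

## Study design assumed throughout

A balanced two-factor layout: body-weight group (LBW/HBW; birds selected
from beyond one standard deviation of the flock mean, emulated flock
2696 ± 227 g) crossed with sampling place (jejunum chymus JC, jejunum mucosa
JM, caecum chymus CC), five birds per group, one sample per bird ×
compartment (30 samples). All screening statistics assume this balance;
`group_mean_table` and the two-way ANOVA refuse unbalanced cells rather than
silently reweighting.

## Synthetic data generator

Counts are Dirichlet-multinomial. Per compartment each genus g has a
baseline log abundance `mu[g] ~ N(0, baseline_sigma²)`; for bird b,

    l[g,b] = mu[g] + eps[g,b] + Σ_blocks loading·f[block,b] + ln2·beta[g]·z[b]

with `eps ~ N(0, noise_sigma²)`, one latent `f ~ N(0,1)` per (factor, bird)
shared by all genera of a planted block (blocks naming the same factor share
it across compartments — the lumen→mucosa driver construction), `beta` the
planted log2-fold change per SD of body weight, and `z[b]` the bird's
standardised weight — so both the group-label ANOVA and the continuous
Spearman screen receive signal from the same planted effect. Relative
abundances are the softmax of `l`; then `p ~ Dirichlet(rel·dispersion)` and
`counts ~ Multinomial(depth, p)`, depth uniform on `depth_range`.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_birds_per_group | 5 | the emulated design |
| places | JC, JM, CC | the emulated design |
| n_genera | 40 | desk-scale genus richness; keeps prevalence-filtered networks at the few-dozen-node scale the method operates on |
| depth_range | 12,000–20,000 reads | all samples survive rarefaction to 10,000 while depths still vary |
| bw mean / sd | 2696 / 227 g | the emulated flock |
| baseline_sigma | 3.5 | a few dominant taxa plus a long rare tail, so the 4-of-5 prevalence filter keeps a minority of genera (sparse networks) |
| noise_sigma | 0.15 | see calibration note below |
| dispersion | 5000 | mild Dirichlet-multinomial overdispersion |
| planted_baseline | 4.5 | planted genera sit in the reliably detected range the screens operate on |

**Calibration note.** The generator exists to give the validation suite
known truth at the study's tiny n. The planted-block loading of 2.0 is, by
construction, a loading that saturates rank correlation at n = 5: with the
defaults above, the median within-block pairwise Spearman rho is 0.9 and a
planted 7-genus block is recovered as a significant component in ~85-90% of
replicates. The noise scales were fixed once to realise that operating point
and are not re-tuned per experiment. Because abundances live on the simplex,
a shared factor partially cancels when its block dominates the community
(closure); planted blocks are therefore kept a minor fraction of the total.

What the generator does **not** emulate: sequencing-error and chimera
processes, taxonomy misassignment, phylogenetic signal in abundances (the
simulated tree is independent of the counts), overdispersion heterogeneity
across taxa, and any real lumen-mucosa biology. Passing recovery tests
therefore demonstrate the statistical machinery under its own assumptions,
not performance on real communities.

## Numerical and procedural choices

* **Rarefaction** subsamples without replacement via the multivariate
  hypergeometric distribution; one draw per sample (the curve operation
  averages over replicates when wanted). Samples under depth are dropped
  with a logged warning; only an all-samples-short table is an error.
* **Chao1** uses the bias-corrected form `S + F1(F1-1)/(2(F2+1))`, finite
  when doubletons are absent.
* **Shannon** defaults to log base 2 (the scale on which a ~360-OTU caecal
  sample scores ~6); natural log is a parameter away.
* **Faith's PD** is computed directly as the branch-length sum over edges
  whose subtree contains an observed leaf (root included). Multifurcating
  rooted trees are accepted.
* **Chi-square distance** is computed on sample profiles (each sample
  normalised to sum 1, equal sample masses): on relative-abundance input
  this equals the correspondence-analysis distance, and it makes the
  distance exactly invariant to rescaling any one sample.
* **Bray-Curtis** is a semimetric (triangle inequality not guaranteed);
  nothing downstream assumes otherwise. An all-zero sample pair yields 0
  with a warning.
* **PCoA** reports negative eigenvalues verbatim; no Lingoes/Cailliez
  correction.
* **PERMANOVA/ANOSIM** permute labels freely (no strata; the design states
  none). p = (exceed + 1)/(B + 1), never zero, deterministic under seed.
* **CCA** standardises the grand-total-normalised table to
  `(P - rcᵀ)/sqrt(rcᵀ)`, projects rows onto the row-weighted span of the
  centred constraints, and tests the constrained-inertia pseudo-F by
  permuting constraint rows. Verified against vegan's `cca` on shared input.
* **Two-way ANOVA** uses the balanced decomposition (equal to Type I/II
  here), vectorised across taxa; constant taxa get missing p-values and are
  excluded from the FDR families. Abundances are untransformed by default
  (robustness of ANOVA in balanced designs); an arcsine-square-root flag
  exists but defaults off.
* **FDR families**: one BH family per effect (SP, BW, SP×BW) across taxa —
  the convention matched by per-effect FDR columns in group-mean tables.
* **Tukey HSD** uses the studentized-range tail with the two-way error MS;
  letters are maximal cliques of the non-significance graph.
* **B/F ratio**: per-sample ratios averaged within groups. Mean-of-ratios
  and ratio-of-means differ (Jensen gap) — the former is reported, and this
  is why B/F margins cannot be recomputed from a table's B and F rows.
* **BW correlation screen**: "0.01% of the total microbial population" is
  read as mean relative abundance across the place's samples, the only scale
  on which the threshold is dimensionally meaningful; prevalence (≥ 8
  samples) is per place, where 10 samples exist. Correlation is against
  individual grams, not group labels. No multiplicity correction, by the
  screen's stated rule — a documented caveat. Exact p up to n = 8
  (enumeration conditions on the observed tie pattern), t approximation
  beyond; the exact routine accepts n ≤ 10 on request.
* **Network edge rule**: |rho| ≥ 0.9 is a descriptive threshold, not a
  per-edge test — at n = 5 the exact two-sided p of rho = 0.9 is 0.083, and
  only |rho| = 1 clears 0.05, which would empty every network. Significance
  is established at the connection-count level instead. Negative edges are
  allowed by default and carry their sign.
* **Monte Carlo null**: each genus's vector is permuted independently
  within the group — marginals (including zero structure and ties) are
  preserved exactly, all cross-genus association is destroyed. Degree p is
  the exceedance of the observed degree; component p compares a component's
  edge count against the *maximum* component edge count of each null
  replicate, so one comparison covers the network's strongest community and
  the per-network multiplicity is absorbed into the null.
* **Degree-test discreteness**: degrees are integers and the per-pair null
  tail moves in steps of 1/120 at n = 5, so the attained level sits at the
  largest achievable tail below α. Over study-like networks (~20-30 nodes)
  the measured per-genus false-positive rate at α = 0.05 is ≈ 0.04.
* **Determinism**: one master seed; every stage and every simulation
  derives a child seed by hashing a stage label, so reruns are
  byte-identical and stages are insensitive to each other's draw counts.

## Problem sizes used by the validation suite

Calibration: 1,000 null simulations per permutation test at 199
permutations; 200 null tables (~4,500 genus-level degree tests) at B = 199.
Recovery: 100 simulations at B = 1,000. These sizes put the Monte Carlo
standard error well inside the decision bands (e.g. ±0.007 on a 5% rate at
1,000 simulations).

## Known limitations

* Compositional effects are handled only implicitly (rank statistics,
  permutation nulls); no log-ratio methodology (SparCC/ALDEx2-style) is
  included or intended.
* The exact-Spearman enumeration is factorial; beyond n = 10 only the
  t approximation is offered.
* At n = 5 the co-occurrence procedure has no per-edge error control by
  design; edges are descriptive and only degree/component statistics carry
  p-values.
* Published per-sample values (alpha-diversity tables, correlation
  coefficients, network p-values of the motivating study) depend on the
  sequenced dataset and are not reproducible from printed summaries; the
  package validates against printed *margins*, closed forms, independent
  oracles, and planted synthetic truth instead.
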