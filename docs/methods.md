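# Methods

`micronet` implements a weighted co-occurrence network analysis for paired
(two-condition crossover) microbiome studies: each subject contributes one
OTU count profile under a placebo condition (`PL`) and one under a
nitrate-rich condition (`BR`), together with per-condition host traits and a
small set of baseline-only traits. The analysis asks which clusters of
co-occurring taxa ("modules") exist, which taxa respond to the intervention,
and which module-trait relationships are *stable across both conditions* —
the consensus screen that is the core of the method.

## Input filtering and transformation

Counts are filtered in two sequential passes before any analysis:

1. an OTU is removed if its count is below 10 in *every* sample of both
   conditions (an OTU reaching 10 anywhere survives — the alternative
   "below 10 in any sample" reading would remove essentially all taxa);
2. a surviving OTU is removed if its count is below 5 in at least 50% of
   samples.

Each removed OTU is attributed to exactly one rule and filtering is
idempotent. Relative abundances are per-sample fractions; network inputs are
`log10(fraction + pseudocount)` with the pseudocount defaulting to half the
smallest non-zero fraction of the table — a standard variance-stabilising
choice for compositional data entering correlation networks. The same
pseudocount is shared between conditions so the two network inputs are on a
common scale.

## Diversity and community comparison

Shannon entropy uses the natural log (configurable base); Chao1 uses
`S_obs + F1^2/(2 F2)` with the bias-corrected `S_obs + F1(F1-1)/2` fallback
when no doubletons exist. NMDS is a Kruskal stress-1 SMACOF with monotone
(isotonic) regression of configuration distances on ranked dissimilarities,
run from one classical-MDS start plus `n_starts` random starts
(deterministic given the seed; convergence at stress decrease < 1e-6).
PERMANOVA partitions squared Bray-Curtis dissimilarities into between/within
group sums; because the design is paired, permutations are restricted within
subject strata by default (each subject's two condition labels may swap, but
labels never cross subjects). The permutation p-value uses the
`(hits + 1)/(n_perm + 1)` convention, so its floor is `1/(n_perm + 1)`.

## Differential abundance

Taxa whose mean relative abundance across all samples exceeds 0.01%
(strictly) are tested with two-sided paired t-tests; p-values are
Benjamini-Hochberg adjusted (step-up, monotonicity enforced). The t-test is
computed on `log10(fraction + pseudocount)`: condition effects are
multiplicative and abundances approximately log-normal across subjects, so
differences of raw fractions are dominated by between-subject spread and
carry almost no power, while log-scale differences cancel the subject effect.
Reported means and percent changes (`100 (BR - PL)/PL`, integer-rounded for
display) remain on the raw fraction scale. Lineage rollups (phylum / genus /
species) sum fractions within the truncated taxonomy string before testing.

## Signed network, TOM, and consensus

The adjacency is the signed WGCNA map `a_ij = ((1 + cor_ij)/2)^beta`
(Pearson on the log-transformed fractions by default, Spearman by option),
so negative correlations carry no weight and modules consist of positively
co-varying OTUs. The soft power `beta` is the smallest one whose signed
scale-free fit R^2 (log-log regression of the binned degree distribution,
sign-flipped by slope) reaches the target (default 0.8) in *both*
conditions. Because raising the power always improves the fit while
collapsing the network, candidate powers are restricted to those keeping
mean connectivity above `max(5, n/50)`; if no candidate reaches the target,
the candidate with the best minimum-across-conditions R^2 is used and a
warning is issued. On the synthetic preset this fallback selects powers in
the 6-9 range, where module recovery is empirically stable.

Adjacency is smoothed into the topological overlap matrix
`TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 - a_ij)`; the consensus TOM first
power-transforms the BR TOM so its 0.95 quantile matches PL's (removing
scale differences), then takes the element-wise minimum, keeping only
overlap supported by both conditions.

## Module detection: validated-cut scan

Average-linkage hierarchical clustering is run on `1 - TOM`. Rather than a
single fixed-height cut, flat cuts over a grid of 50 merge-height quantiles
are each scored by the clusters that pass a cohesion validation:

- at least `min_module_size` members (default 20, consistent with the
  smallest module the analysis is expected to resolve);
- mean within-cluster TOM at least `cohesion_ratio` times the mean
  cluster-to-rest TOM, and above the network background (median off-diagonal
  TOM) by a margin of 0.02.

The cut maximising (number of validated clusters, OTUs assigned) wins.
`deep_split` (0-4, default 2) maps to `cohesion_ratio = 3 - 0.5 * deep_split`,
so larger values admit weaker modules. Finally, modules whose eigengenes
correlate above `1 - merge_height` (default 0.75) in *every* condition are
iteratively merged (most-correlated pair first). Everything else — clusters
failing validation and leftover OTUs — is unassigned (module 0, "grey").

This scheme was chosen after two simpler designs failed on realistic
simulations: a purely top-down recursive tree walk accepts unions of modules
whenever the dendrogram's local split does not fall on the module boundary,
and Newman-modularity cut selection has a resolution limit that favours
two-cluster partitions when one module is large. The cohesion ratio is
deliberately self-penalising against over-splitting: a fragment of a true
module fails validation because its "rest" includes its sibling fragment.
On pure-noise input no cluster validates and all OTUs stay unassigned.

Module eigengenes are the first principal component of the
column-standardised member profiles, scaled to unit variance and
sign-oriented to correlate positively with the module's mean profile; kME is
the correlation of each OTU with each eigengene. Detection is fully
deterministic (no RNG anywhere in the network stage).

## Module-trait consensus screen

Per condition, module eigengenes are correlated with every trait (Pearson,
pairwise-complete, two-sided Student p; cells with fewer than 4 complete
pairs are set missing). Baseline-only traits (measured once; the ACE-III
cognitive subscores) are attached to the placebo network only. The consensus
of the two networks keeps a cell only when the signs agree, with
`r = sign * min(|r_PL|, |r_BR|)` and `p = max(p_PL, p_BR)`; discordant cells
get `r = 0, p = 1`. Significant cells are those with `p <= alpha`
(default 0.05), reported with raw per-cell p-values; a Benjamini-Hochberg
option exists but is off by default, matching the convention of reporting
raw eigengene-trait correlations.

## Module drivers (LDA effect size)

Within each module, member OTUs are screened with a tie-corrected
Kruskal-Wallis test at `alpha`; survivors get a bootstrapped
linear-discriminant effect size: abundances are scaled to parts-per-million,
and per bootstrap (default 30 draws of a per-class 2/3 subsample) a feature's
effect is the average of its share of the class separation along the unit
discriminant axis and its raw class-mean difference. The reported score is
`log10` of the bootstrap-mean effect (clamped at effect = 1 ppm so the
magnitude stays monotone in the effect), signed positive for BR-enriched
features. Drivers are features with `|score| >= 2` (threshold configurable).
The two-class design has no subclass structure, so the multi-class
"all-against-all" machinery of the general procedure reduces to this
two-class case; a within-subject subclass stage is deliberately not
implemented. Note the ppm scale means rare taxa cannot reach threshold 2
regardless of fold change — a property inherited from the score's
definition, not a bug.

## Synthetic data generator

The generator is the package's test bed and models exactly the statistical
structure the analysis assumes. Per OTU `i`, subject `s`, condition `c`:

    log a_isc = baseline_i + lambda_i * f_{s, module(i)}
                + log_fc_i * [c = BR] + u_is + eps_isc

- `f` — per-subject module factors, standard normal, shared across
  conditions (the crossover pairing);
- `u` — subject-OTU carriage effects (sd 0.8), also shared across
  conditions — real microbiomes are strongly subject-specific;
- `eps` — condition-specific noise (sd 0.3);
- `baseline_i ~ N(0, 1)` (effect-carrying OTUs drawn from N(0.5, 0.75) so
  the planted responders are moderately abundant);
- `lambda_i ~ U(1.0, 1.5)` for module members, 0 for background OTUs.

Counts are Dirichlet-multinomial: the softmax of `log a` scaled to
concentration 3000 parameterises a Dirichlet, and a multinomial draw at
depth 100,000 closes each sample to the exact stated depth (the depth
reflects pooling several saliva collections per subject-condition; the
concentration adds mild technical overdispersion on top of the biological
log-normal spread).

Defaults mirror the study scale: 26 subjects, eight modules of sizes
(243, 48, 24, 71, 57, 71, 46, 24) plus 26 background OTUs, condition
effects of -80% to +628% placed on named nitrate-sensitive species in their
reported modules, and trait couplings at r = -0.44 (MAP, MM6),
-0.39 (reaction time, MM5), +0.48 (resting VO2, MM7) stable across
conditions, plus four per-condition-only couplings at |r| = 0.45 (the
spurious relationships the consensus screen should reject) and baseline
ACE-III couplings analysed in the placebo network.

Traits are linear in the module *eigengene* computed from the generated
counts (with the planted labels): `trait = sum r_m e_m + sqrt(1 - sum r^2) eps`,
so the population trait-eigengene correlation equals the target exactly.
Coupling to the latent factor instead would leave ~17% attenuation from the
log-transform's censoring of rare members. Everything is drawn from one
`numpy` Generator seeded once; a dataset is byte-identical given
`(params, seed)`.

What the generator does *not* emulate: phylogenetic correlation between
related taxa, sparsity beyond what the Dirichlet-multinomial induces,
taxonomic mis-assignment, and temporal drift within a supplementation
period. Passing recovery tests therefore show the pipeline is correct under
its own model assumptions — not that those assumptions hold in any given
16S data set.

## What the validation runs show (and their sizes)

- **Module recovery** — full pipeline on the default preset recovers the
  planted eight-module structure with adjusted Rand index typically
  0.90-0.97 (occasionally ~0.8 when a large module's weakest, noise-dominated
  members drop to grey — at 26 subjects their profiles genuinely carry no
  signal). Problem size: ~610 OTUs, 52 samples.
- **Consensus screen** — across 100 replicates, couplings planted in one
  condition only are rejected in ~98% of cells. Stable couplings at
  |r| = 0.39-0.48 are *individually* retained only 25-55% of the time:
  at n = 26 the two-sided alpha = 0.05 critical correlation is 0.388, i.e.
  the planted effects sit at the significance boundary, and the max-p
  consensus rule demands significance in both conditions at once. This is a
  fundamental power limit of the design, not an implementation artefact —
  a single study observing all three such couplings simultaneously should be
  read accordingly.
- **Calibration** — eigengene-trait null type-I error at alpha = 0.05 is
  0.050-0.052 over 200 null replicates (12,800 cells); the LEfSe null driver
  rate per module is ~3e-4, far below the 0.05 control line; PERMANOVA null
  p-values are uniform (KS test over 200 replicates).
- **Oracles** — TOM agrees with the definitional O(n^3) triple loop to
  1e-12; the BH adjustment agrees with the definitional min-over-tails form
  (and statsmodels) to 1e-12 on 1000 random vectors.
- **Determinism** — two full `run_all` executions with the same seed and
  config produce byte-identical output files (checksums compared from the
  run manifest).

Power-dependent properties are tested at sizes where power suffices and the
statement is about the method rather than the sample: planted-effect
sensitivity >= 0.9 at n = 80 subjects; percent-change and trait-coupling
calibration at n = 500 and n = 2000.

## Numerical choices and edge cases

- Correlation of a zero-variance profile is defined as 0 (flagged).
- Paired t on all-zero differences returns (0, 1); zero-variance non-zero
  differences return p = 0 with a degeneracy warning.
- A single-member module's eigengene is its standardised profile (warned).
- Consensus quantile scaling is skipped when either TOM's quantile is 0 or 1.
- `round_half_away` (half away from zero) is the display rounding for dose
  values; computations are never rounded internally.
- NMDS records its stress history; convergence is a stress decrease below
  1e-6. Configurations are centred at the origin (rotation/reflection remain
  arbitrary).

## Known limitations

- Module detection assumes modules are positively co-varying blocks; it will
  not find sign-mixed clusters (by design, matching the signed network).
- The LDA effect-size score depends on the ppm scale and so under-weights
  rare taxa; cross-study comparisons of scores require equal scaling.
- The consensus screen's retention power at n = 26 is low for |r| < 0.5
  (see above); the screen is best read as a high-specificity filter.
- BIOM support is v1 (JSON) read-only.
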