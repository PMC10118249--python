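# Methods

## Scope and data model

The package operates on an OTU table (samples × taxa, non-negative counts or
proportions) with per-sample group labels and an optional rooted phylogeny
whose tips cover the taxa.  Everything upstream of the table — read QC,
alignment, chimera removal, OTU calling — is out of scope.  Tables are TSV
(comma fallback by header sniffing), trees newick, networks GraphML or a
plain `taxonA<TAB>taxonB<TAB>correlation` edge list.

## Preprocessing

1. **Decontamination** removes every taxon whose label contains a
   contaminant pattern, case-insensitively (default `["Halomonas"]`, the
   classic saline-bronchoscope contaminant of low-biomass respiratory
   samples).  Removal happens on counts, before normalization.
2. **Total-sum scaling** divides each sample's counts by its total, so rows
   sum to 1 exactly.
3. **Prevalence filtering** at a 50 % bar, applied per group: a taxon is
   kept in a group iff it is non-zero in *at least* half of that group's
   samples (the boundary is read strictly: "less than 50 %" is eliminated,
   exactly 50 % survives).  Retained taxon sets may differ between groups.
   For comparative analyses a *uniform set* variant instead keeps, in all
   groups, any taxon strictly exceeding the bar in at least one group.
   Rows are **not** renormalized after taxon drops — proportions keep their
   original denominators — so a relative table's row sums may fall below 1;
   the container validates sums ≤ 1.  Correlation inference re-derives
   fractions from the filtered *counts*, so this choice does not leak into
   the estimator.

## Alpha diversity

Chao1 is S_obs + F1²/(2·F2) with singletons F1 and doubletons F2, switching
to the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) when F2 = 0; both
forms can also be forced (`bias_corrected="always"/"never"`).  It requires
integer counts.  Inverse Simpson is 1/Σp_i² over positive proportions.
Faith's PD (via scikit-bio) is the branch length of the minimal subtree
spanning the root and the present taxa.  No rarefaction is applied before
any index.  Group contrasts use the classical one-way ANOVA F; the
richness–diversity relationship is a Pearson r with the two-sided t-based
p-value on n − 2 df.

## Beta diversity and ordination

Unweighted UniFrac is unique/total branch length of the two communities'
subtrees; weighted UniFrac is Σ b_i |A_i − B_i|, normalized by default
(flag provided).  Both go through scikit-bio; because its internals cast
abundance vectors to integers, proportions are scaled by 1e9 and rounded
first (≤ 1e-9 relative mass error).  Presence for unweighted UniFrac is
proportion > 0, with no detection threshold.  Trees with trifurcating roots
are accepted as given.

PCoA Gower-centers −½·J·D²·J and eigendecomposes; coordinates are
eigenvectors scaled by √λ for λ > 0.  Negative eigenvalues (the
non-Euclidean part of the distance) get no real axes but are retained as an
*imaginary* coordinate block scaled by √(−λ).

PERMANOVA computes the pseudo-F from the distance-based sum-of-squares
decomposition (between/(g−1))/(within/(n−g)) and a permutation p-value
(1 + exceedances)/(1 + permutations), counting ties (F* ≥ F) as exceedances
— the canonical convention, which also sets the attainable minimum p for
small designs.  999 permutations by default; the seed is mandatory.

Group dispersion embeds the samples by PCoA (keeping the imaginary block),
locates each group's spatial median by Weiszfeld iterative reweighting
(tolerance 1e-8; centroid optional), and reports the per-group mean of
√max(0, d_real² − d_imag²) — the betadisper construction.

## Compositional correlation inference

The estimator works on the filtered counts table (≥ 4 taxa, ≥ 5 samples):

- log-ratio variances t_ij = Var(log x_i − log x_j) with the n−1
  denominator, computed from the covariance of the log fractions;
- basis variances from the sparsity approximation: summing t_ij over the
  non-excluded partners of taxon i gives A ω² = b with A[i,i] = #partners,
  A[i,j] = 1 — for no exclusions exactly the normal equations of the least
  squares fit t_ij ≈ ω_i² + ω_j², which is what the test-suite oracle
  solves directly; ω² is floored at 1e-12 before taking roots;
- ρ_ij = (ω_i² + ω_j² − t_ij)/(2 ω_i ω_j), clipped to [−1, 1];
- iterative exclusion: the single most-correlated pair with |ρ| above the
  exclusion threshold (default 0.1) is removed from the system and the
  solve repeated, up to D − 3 times, so strong associations do not inflate
  the variance estimates;
- Dirichlet resampling: each of 20 inner repetitions draws per-sample
  fractions from the posterior with a uniform prior (counts + 1); the
  reported ρ is the element-wise median.  Everything is driven by one seed.

Pseudo p-values permute each taxon's counts across samples independently —
an exchangeable no-association null that preserves marginals — re-estimate
ρ per replicate (default B = 100, minimum 19 to resolve α = 0.05), and
report two-sided (1 + #{|ρ*| ≥ |ρ|})/(1 + B).  No multiple-testing
correction is applied to edge p-values; edges are thresholded at raw
p < 0.05 as is conventional for these networks.

## Networks, Markov clustering, clubs

The co-occurrence network keeps edges with p < α (default 0.05) and
|ρ| ≥ `min_abs_r` (default 0: the network is faithful to the significance
filter alone).  Node attribute: mean relative abundance.

Markov clustering runs on the **positive**-edge subgraph (the flow matrix
must be non-negative; negative edges are reserved for rivalry detection):
unit self-loops, column normalization, then expansion (matrix power 2),
inflation (element-wise power 2.0), pruning of entries < 1e-5 and
renormalization until the maximum change < 1e-8 or 100 iterations
(non-convergence is flagged, the current interpretation returned).
Clusters are read off attractor systems (connected components of the
attractor–attractor flow); a node drawn by several systems joins the one
sending it the largest mass, remaining ties going to the smallest cluster
id; isolated nodes become singletons.  The procedure contains no
randomness and is invariant to node relabeling.

Because a per-group network at n ≈ 9–24 samples retains many noise-level
positive edges at p < 0.05 (the null sd of a correlation at n = 24 is
≈ 0.21, so hundreds of pairs put dozens of spurious edges in the network),
the *flow graph only* is additionally thresholded at
`mcl_min_weight = tanh(3.29/√(n−3))` — the two-sided 99.9 % null band of a
correlation coefficient at the group's sample size (≈ 0.62 at n = 24,
≈ 0.84 at n = 9).  This keeps noise edges from stitching spurious clusters
together while leaving the network itself, the tightness statistics and the
rival-edge pool untouched.  The threshold is a pipeline default; pass an
explicit `mcl_min_weight` (e.g. 0) to disable it.

Social clubs are clusters with ≥ 3 members (a permissive floor; real
cohorts' clubs typically have ≥ 5); tightness is the mean ± sd of
correlations on intra-club edges *present in the network*, i.e. significant
pairs (an all-pairs variant is a matter of passing the full ρ matrix).  For
each unordered pair of social clubs the significant negative edges between
them are collected; the pair is rival iff ≥ 3 such edges exist with mean
ρ ≤ −0.4.  Both knobs are configuration; the defaults are permissive enough
that typical reported rival means (−0.5 to −0.8) qualify.

Heatmap export orders taxa by cluster (decreasing size, ties by smallest
member label) and within a cluster by decreasing mean intra-cluster
correlation, restoring block-diagonal structure in the reordered ρ matrix.

## Synthetic cohorts

The generator is a logistic-normal → multinomial model: per sample, latent
log-abundances z ~ MVN(μ + group shift, Σ), proportions ∝ exp(z), counts
multinomial at a uniform-random depth.  Σ is built from a base log-sd
vector and a correlation matrix with equicorrelated blocks (the planted
clubs), negative cross-block entries (planted rivalries) and ones on the
diagonal; positive definiteness is checked and non-PD specifications are
rejected with the offending blocks named.  The factor diag(sd)·chol(corr)
is used so taxa with sd = 0 are legal.  A companion random rooted binary
phylogeny (sequential random joins, Exponential(1) branch lengths) supports
the phylogenetic stages.

The default specification emulates a 55-subject, 3-group cohort: groups
NS/FS/AS of 9/24/22 samples, read depths uniform in 2 500–4 100 (matching a
~3 600-read mean), 60 taxa — three abundant blocks of 6/5/5 taxa at latent
intra-correlation 0.85, one rivalry (block 0 vs 1) at −0.5, and a 0 → −6
log-mean rank-abundance decay over the remaining 44 taxa so the tail is
realistically rare and partly falls under the prevalence filter.  The AS
group carries a +1.5 log-fold shift on block 0: a dominance effect that
concentrates reads and depresses observed richness, the analogue of the
Proteobacteria takeover seen in smokers.  Sixty taxa is a deliberate
scale-down from the several hundred of a real cohort, keeping the
taxa-to-sample ratio workable for correlation inference while leaving the
club-bearing structure untouched.

What the generator does *not* emulate: sequencing error, chimeras,
contaminant taxa, the heavy right tail of real read-depth distributions
(depth is uniform by design), taxonomic label structure, and phylogenetic
signal in the correlation blocks (the tree is independent of the clubs).
Passing end-to-end tests therefore demonstrates correct recovery of planted
compositional structure under realistic sample sizes and depths — not
robustness to the full messiness of real 16S data.

## Numerical choices and degenerate inputs

- ω² floored at 1e-12; ρ clipped to [−1, 1]; singular basis systems raise
  with advice to reduce exclusions.
- Relative tables validate row sums ≤ 1 + 1e-9; zero-total samples are
  rejected by name.
- Chao1 rejects non-integer input; inverse Simpson rejects compositions not
  summing to 1 (tolerance 1e-9).
- Weiszfeld iteration snaps to a data point when the median coincides with
  one (distance < 1e-8).
- PCoA treats |λ| below 1e-10 × max|λ| as zero.
- MCL tie-breaks: largest flow mass, then smallest cluster id; cluster ids
  densely renumbered by first appearance in sorted node order — all outputs
  are byte-reproducible for a fixed config and seed.

## Problem sizes used by the checks

The calibration and recovery experiments run at: PERMANOVA type-I error —
500 null replicates of n = 20 with 199 permutations; estimator null — 50
independent log-normal taxa, n = 500, depth 5 000, B = 100; planted-club
recovery — a 5-taxon club at 0.7 among 50 taxa, n = 200, depth 5 000, 10
replicate cohorts; end-to-end — the default 55 × 60 cohort above, evaluated
on the largest group (n = 24).  These sizes are the package's validation
conditions; larger cohorts only improve the estimator's accuracy (verified
by the depth-monotonicity test).

## Known limitations

- The basis-variance system needs ≥ 4 taxa and loses identifiability if
  exclusions strip a taxon of all partners; the solver stops excluding
  rather than solving a singular system.
- Rival detection conditions on both clubs having been recovered as social
  clubs; a rivalry involving a fragmented club is not reported.
- With ~9 samples per group the flow-graph threshold is necessarily severe
  (≈ 0.84), so weakly coupled clubs may fragment — a statement about the
  information in 9 compositional samples, not about the clustering.
- PERMANOVA assumes exchangeability under the null; group-specific
  dispersion differences (which betadisper measures) can inflate it.
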