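# microclubs

Downstream analysis of lower-respiratory-tract 16S OTU count tables:
normalization and prevalence filtering, alpha/beta diversity, compositional
correlation inference, co-occurrence network construction, Markov clustering
into microbial "social clubs", and detection of "rival clubs" — the cluster
pairs joined predominantly by negative (co-avoidance) correlations.  It is
aimed at microbiome researchers who have an OTU table (samples × taxa read
counts), per-sample group labels (e.g. never / former / active smokers) and
optionally a rooted phylogeny, and who want the community-structure half of a
16S workflow as a reproducible, seeded library rather than a pile of
notebooks.  A synthetic cohort generator with planted clubs, rivalries and
group effects lets every stage be validated end to end.

## The methods at the core

**Compositional correlations (SparCC-style).** Relative abundances x_i sum
to 1, so naive Pearson correlations between taxa are biased.  The log-ratio
variance t_ij = Var log(x_i/x_j) decomposes as

    t_ij = ω_i² + ω_j² − 2 ρ_ij ω_i ω_j

where ω_i² and ρ_ij are the variances and correlations of the latent
(unconstrained) *basis* abundances.  Under sparsity (most ρ_ij ≈ 0), summing
t_ij over j yields a linear system for ω²; the most-correlated pair above a
threshold (default 0.1) is then excluded and the system re-solved,
iteratively.  Counts are converted to strictly positive fractions by
Dirichlet resampling (counts + 1), the estimate is the element-wise median
over 20 repetitions, and pseudo p-values p = (1 + #{|ρ*| ≥ |ρ|})/(1 + B)
come from B per-taxon permutations of the counts across samples.

**Social and rival clubs.** Taxon pairs with p < 0.05 form a signed
co-occurrence network (node size = mean relative abundance, edge weight =
ρ).  Markov clustering — alternating expansion (matrix power 2) and
inflation (element-wise power 2.0) of the column-stochastic flow matrix on
the positive-edge subgraph — partitions the taxa; clusters with ≥ 3 members
are social clubs, reported with tightness (mean ± sd of intra-club edge
correlations).  A pair of clubs is rival when ≥ 3 significant negative edges
connect them with mean ρ ≤ −0.4.

**Diversity.** Chao1 richness S_obs + F1²/(2F2) (bias-corrected form when
F2 = 0), inverse Simpson 1/Σp_i², Faith's PD, unweighted/weighted UniFrac,
PCoA by Gower double-centering, one-way PERMANOVA with a seeded permutation
null, and betadisper-style per-group distance-to-spatial-median (negative
PCoA eigenvalues kept as an imaginary block).

## Worked example

```python
import pathlib, tempfile
import microclubs as mc
from microclubs.pipeline import PipelineConfig, run_pipeline

tmp = pathlib.Path(tempfile.mkdtemp())
ds = mc.generate_dataset(mc.default_spec(seed=1))   # 55 samples, 60 taxa,
mc.write_table(ds.table, tmp / "counts.tsv")        # 3 planted clubs, 1 rivalry
mc.write_metadata(ds.table.group_of, tmp / "metadata.tsv")
mc.write_tree(ds.tree, tmp / "tree.nwk")

manifest = run_pipeline(PipelineConfig(
    table=str(tmp / "counts.tsv"), metadata=str(tmp / "metadata.tsv"),
    tree=str(tmp / "tree.nwk"), output_dir=str(tmp / "out"), seed=1))

info = manifest["groups"]["FS"]          # largest group, n = 24
for c in info["social_clubs"]:
    print(f"club {c['club_id']}: size {c['size']}, "
          f"tightness {c['tightness_mean']:.2f}±{c['tightness_sd']:.2f}")
for r in info["rival_pairs"]:
    print(f"rival pair ({r['club_a']}, {r['club_b']}): "
          f"mean rho {r['mean_correlation']:.2f} over {r['n_edges']} edges")
```

prints

```
club 0: size 6, tightness 0.83±0.04
club 1: size 5, tightness 0.83±0.04
club 2: size 5, tightness 0.81±0.04
rival pair (0, 1): mean rho -0.46 over 12 edges
```

The three social clubs are exactly the three planted 6/5/5-taxon blocks
(latent intra-correlation 0.85) and the rival pair is the planted block-0 vs
block-1 rivalry (latent cross-correlation −0.5): the compositional estimator
shrinks latent correlations somewhat at 24 samples and ~3 300 reads, which
is why tightness ≈ 0.83 and the rival mean ≈ −0.46.  The same run writes,
per group, the filtered table, ρ and p matrices, the network
(GraphML + edge list), the clustering, the club report and a heatmap-ordered
correlation matrix, and across groups the UniFrac distance matrix, PCoA
coordinates, PERMANOVA result and per-group dispersions (this run:
PERMANOVA F = 2.11, p = 0.042; distance-to-median AS 0.093 vs FS 0.062 /
NS 0.068).

The same pipeline runs from a shell:

```bash
microclubs simulate --out data --seed 1
microclubs run --config config.yaml
```

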