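# menstab

Molecular ecological network inference and stability analysis for microbial
abundance tables.

Soil microbiome surveys often ask whether a management regime (say, crop
rotation versus continuous monoculture) changes not just *which* microbes
are present but how densely and cooperatively they associate. The standard
answer builds a **molecular ecological network (MEN)**: correlate taxa
across samples, keep only associations above a similarity threshold chosen
by random-matrix theory, and read complexity and stability off the resulting
signed graph. `menstab` implements that workflow end to end for
taxa-by-sample count tables (zOTU/ASV tables from 16S/ITS/18S surveys or any
comparable data), together with the diversity and permutation statistics
used to compare community structure between groups, and a synthetic
community generator with planted ground truth for validating every stage.

## What it computes

- **Tables**: TSV I/O, low-abundance (< 8 reads total) and prevalence
  filters, relative abundances, rank aggregation; GraphML and edge-list
  export of networks.
- **Diversity**: richness, Chao1 = S_obs + F1²/(2F2), Shannon −Σ pᵢ ln pᵢ;
  Jaccard and Bray–Curtis distances; NMDS with Kruskal stress-1; PERMANOVA
  (pseudo-F), ANOSIM (R), MRPP (δ, A) and Mantel tests with add-one
  permutation p-values and exact exhaustive enumeration on small designs.
- **Network inference**: tie-corrected Spearman screening; RMT threshold
  selection at the GOE→Poisson transition of the nearest-neighbour spacing
  distribution of unfolded eigenvalues; signed networks (edge = |r| ≥ s,
  sign = sign(r)).
- **Topology**: avgK, density, mean clustering, transitivity, mean geodesic
  distance (GD), Freeman degree centralization (CD), power-law R²,
  modularity; Maslov–Sneppen degree-preserving null ensembles (mean ± sd
  over 100 rewired replicates); small-world check (GD ≈ ln n and clustering
  above the null).
- **Stability**: greedy-modularity module detection; Zi–Pi node roles
  (network hub / module hub / connector / peripheral at Zi > 2.5,
  Pi > 0.62); robustness = surviving fraction after random removal of 50%
  of nodes plus secondary extinction of newly isolated nodes; positive and
  negative cohesion (abundance-weighted mean positive/negative pairwise
  connectedness per sample); Mann–Whitney group contrasts with significance
  stars.
- **Simulation**: latent Gaussian copula with planted correlation modules,
  per-group association density/positivity, group fold-changes,
  Dirichlet-multinomial counts, and soil variables linked to chosen taxa —
  all recorded in a ground-truth object.

See `docs/methods.md` for the models, defaults and numerical conventions.

## Worked example

Simulate a rotation-like community (19 samples in two groups, 150 taxa,
four planted modules), build its network at a threshold of 0.70, and
measure stability:

```python
import menstab as m

cfg = m.rotation_like_config(seed=1)
table, truth = m.generate_community(cfg)
table = m.filter_low_abundance(table, 8)

corr = m.spearman_matrix(table)
net = m.build_network(corr, 0.70)
print(net.n_nodes, net.n_links, m.positive_edge_fraction(net))
# 60 122 0.9590163934426229

part = m.module_partition(net)
rob = m.robustness(net, 0.5, n_replicates=100, seed=1)
coh = m.cohesion(table)
print(f"Q={part.modularity:.3f}  robustness={rob.mean:.3f} ± {rob.sd:.3f}")
# Q=0.715  robustness=0.395 ± 0.033
print(f"cohesion+ {coh.positive.mean():.3f}  cohesion- {coh.negative.mean():.3f}")
# cohesion+ 0.214  cohesion- -0.172

groups = [table.group_of[s] for s in table.sample_ids]
dm = m.beta_distance(table, "jaccard")
res = m.permanova(dm, groups, n_perm=999, seed=1)
print(f"PERMANOVA F={res.observed:.3f} p={res.p_value:.3f}")
# PERMANOVA F=2.883 p=0.029
```

Reading: 60 of 150 taxa carry an association at |ρ| ≥ 0.70; 96% of those
edges are positive (this scenario plants mostly cooperative modules). The
network is strongly modular (Q = 0.715). After randomly deleting half the
nodes and letting newly isolated taxa drop out, on average 39.5% of the
community remains connected. Jaccard-distance PERMANOVA detects the planted
group structure at p ≈ 0.03.

The same pipeline is available from the shell:

```sh
menstab --seed 1 simulate --scenario rotation-like --out-dir sim/
menstab filter --input sim/abundance.tsv --output filtered.tsv --min-total 8
menstab network --input filtered.tsv --output net.graphml --threshold 0.70
menstab --seed 1 stability --graph net.graphml --table filtered.tsv \
        --out-prefix stab
```

Omit `--threshold` to let the RMT scan choose it (`--scan-report` writes the
per-threshold spacing statistics).

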