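# usfc — a traffic map for the brain's connectome

`usfc` models how the brain's functional connections are carried by its
structural wiring.  Given per-subject structural connectivity (SC,
FA-weighted, nonnegative) and functional connectivity (FC, Pearson
correlations, possibly negative after global signal regression) over a
region atlas, it finds, for every functional connection, the most
*efficient* structural route — the path minimizing summed step costs

```
EP(i, j) = argmin over routes  Σ_k  D(n_k, n_k+1) / SC(n_k, n_k+1),   ≤ 4 steps
```

where `D` is the Euclidean distance between region centroids (mm) and `SC`
the structural strength of each step.  Every routed connection then deposits
its FC value onto each structural edge of its route; the per-edge sum is the
**unified structural–functional connectivity (USFC)** — the traffic load of
that road segment.  The package analyzes the resulting map with:

* group-level edge statistics (one-sample t-tests, Benjamini–Hochberg FDR),
  regional load sums, IQR-fence outlier regions, network-level comparisons,
  and top-k heaviest pathways;
* step-stratified SC–FC coupling: Spearman correlations between route-mean
  SC and FC, split by FC sign, over routes consistent in more than half the
  cohort;
* weighted graph metrics (global/nodal/local efficiency, betweenness
  centrality, modularity) compared across SC, |FC| and USFC connectomes.

A synthetic-cohort generator with known ground truth (a planted high-SC
backbone corridor and SC-linked negative-FC blocks) makes every stage
testable without imaging data.  It is intended for researchers in network
neuroscience who start from connectivity matrices; the package reads plain
delimited text (atlas CSV, matrix TSV), not imaging formats.

## Worked example

```python
import usfc

# simulate a small cohort with a planted backbone corridor
cfg = usfc.SynthConfig(n_regions=30, n_networks=4, n_subjects=5, seed=3)
atlas, subjects, truth = usfc.generate_dataset(cfg)

# route every functional connection along its cheapest structural pathway
D = usfc.euclidean_distances(atlas)
tables = [usfc.route_all_pairs(s, D, max_steps=4) for s in subjects]

# accumulate functional load per structural edge and test at the group level
loads = [usfc.accumulate_usfc(t, s.fc) for t, s in zip(tables, subjects)]
group = usfc.group_usfc(loads, alpha=0.05)

print("significant edges:", int(group.sig_mask.sum() // 2))
for a, b, v in usfc.top_k_edges(group, k=3):
    i, j = atlas.index_of(a), atlas.index_of(b)
    on_bb = tuple(sorted((i, j))) in truth.backbone_edges
    print(f"  {a}-{b}: mean USFC {v:.2f}  (planted backbone: {on_bb})")

nets = usfc.network_summary(loads, atlas)
print("network ranking by USFC load:", " > ".join(nets.ranking))

consistent = usfc.modal_routes(tables, subjects, threshold=0.5)
res = usfc.coupling_by_step(consistent)
cell = res.cells[(1, "-")]
print(f"1-step negative FC coupling: n={cell.n_routes}, "
      f"rho={cell.rho:.3f}, p={cell.p_value:.2g}")
```

prints

```
significant edges: 65
  R024-R028: mean USFC 25.19  (planted backbone: True)
  R020-R028: mean USFC 23.80  (planted backbone: True)
  R020-R029: mean USFC 19.73  (planted backbone: False)
network ranking by USFC load: N1 > N4 > N2 > N3
1-step negative FC coupling: n=7, rho=-0.679, p=0.11
```

The two heaviest edges are planted corridor segments, and the
corridor-hosting network (`N1`) tops the network ranking.  The negative
1-step coupling is directionally right but, at this demonstration size
(30 regions, 5 subjects), not yet significant; at the default study
conditions (90 regions, 20 subjects) it is strongly so (rho ≈ −0.95,
p ≪ 0.05).  A heavier negative FC riding a structurally *stronger* route is
the signature relation the coupling analysis looks for.

## Command line

The same pipeline is available as a shell tool:

```
usfc simulate --n-regions 90 --n-subjects 20 --seed 1 --out sim/
usfc run --atlas sim/atlas.csv --data-dir sim/ --out run/
```

`run` executes route → build → group → coupling → metrics, writes every
intermediate artifact (route tables, per-subject USFC matrices, group maps,
outlier report, coupling tables, metric comparisons) and a `report.json`
with the fully resolved configuration.  Individual stages are available as
`route`, `build`, `group`, `coupling` and `metrics` subcommands; a YAML
config file (`--config`) can hold defaults with flags overriding it.

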