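# percolearn

Sampling-guided unsupervised learning of bond-percolation phases and
critical points in complex networks.

## The problem

Bond percolation — keep each edge of a network *G* with occupation
probability φ — undergoes a continuous transition at a critical φ_c below
which the giant connected component (GCC) disappears.  It is the standard
proxy for structural resilience and for spreading processes (epidemics,
integration of transport schedules).  In practice one rarely observes the
whole network: data are noisy sub-samples of nodes.  `percolearn` asks how
much a *small, well-chosen sample of nodes* can reveal: can unsupervised
learning separate percolating from non-percolating configurations, and
can it locate φ_c — using only the trajectories of ~20 nodes?

The package is aimed at network scientists and modellers of spreading
processes who want a reproducible reference implementation of the
layer-guided sampling pipeline, with synthetic generators for every study
condition so that nothing depends on external data.

## The method

1. **State matrix.**  Simulate percolation on a φ grid (Δφ = 0.001,
   M = 1000 configurations).  Entry x(v, φ) = 1 iff node v belongs to the
   largest component at φ; phase labels are y(φ) = 0 for φ ≥ φ_c, 1
   below.  Ground truth φ_c is the argmax of the mean second-largest
   component size S₂(φ) over 100 realizations.
2. **Onion sampling.**  The onion decomposition (refined k-core) assigns
   each node a peeling *layer*; sorting nodes core→periphery and cutting
   consecutive 20-node bins groups nodes with similar percolation
   trajectories.  Coherent bins — nodes detaching from the GCC at similar
   φ — are the high-fidelity samples.
3. **Phase clustering.**  Per bin: add Gaussian noise 𝒩(0, 0.01), embed
   the M configurations in 2-D with t-SNE, split with 2-means, align and
   score against the phase labels with the mean Kronecker agreement
   α = (1/n) Σᵢ δ(ŷᵢ, yᵢ).
4. **Confusion scheme.**  Sweep a trial label boundary t over [0, 1] in
   steps of Δ = 0.005; at each t train a feed-forward classifier (bin →
   128 ReLU units, dropout 0.1 → sigmoid; binary cross-entropy, Adam
   10⁻³) on the trial labels and record test accuracy.  The curve is
   W-shaped; its interior peak estimates φ_c.
5. **Time-varying networks.**  The same machinery with window length T as
   control parameter gives the critical integration time T_c of a
   temporal contact list, and day-level epidemic-cluster detection from
   per-region case counts (infected = cases per capita > 10⁻⁴).

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
import percolearn as pl

g = pl.make_square_lattice(32)            # N = 1024, open boundaries
od = pl.onion_decomposition(g)
print("k-core shells:", sorted(set(od.coreness.values())))
print("onion layers: ", od.n_layers)

X = pl.build_state_matrix(g, dphi=0.001, seed=7)   # 1000 x 1024
print("realization phi_c:", X.realization_phic)
y = pl.make_labels(X.phis, X.realization_phic)

ordered = pl.order_nodes_core_to_periphery(od)
bins = pl.bin_nodes(ordered, 20)
outer = bins[len(bins) // 2:]
(best, coh), *_ = pl.select_high_fidelity_bins(X, outer, mode="coherence")
print(f"most coherent peripheral bin: {best.provenance} (coherence {coh:.3f})")

for b in (best, pl.random_bins(ordered, 20, 1, seed=3)[0]):
    res = pl.cluster_bin(X, b, y.y, seed=7)
    print(f"{b.provenance:18s} alpha = {res.alpha:.3f}")
```

prints

```
k-core shells: [2]
onion layers:  31
realization phi_c: 0.499
most coherent peripheral bin: layers[820:840] (coherence 0.951)
layers[820:840]    alpha = 0.945
random             alpha = 0.875
```

The lattice's single k-core shell (coreness 2 everywhere) resolves into
31 onion layers; this realization's S₂ peak puts its transition at 0.499
(realizations scatter by a few hundredths around the ensemble value, and
labels are paired with the realization's own transition).  The most
coherent peripheral bin clusters the two phases at α ≈ 0.95, above the
random-sample baseline.  On heavy-tailed networks the gap is much larger
(random ≈ 0.64, best peripheral bin ≈ 0.99) — that contrast is the point
of layer-guided sampling.

An ensemble-level φ_c (averaged over 100 independent weight draws) is
available as `pl.estimate_phic_ground_truth(g, dphi=0.001, n_runs=100,
seed=7)`.

## Command line

Every stage is scriptable:

```bash
percolearn generate-network --kind powerlaw --size 1000 --gamma 3.1 --seed 1 --out pl.edgelist
percolearn percolate --graph pl.edgelist --dphi 0.001 --runs 100 --seed 1 \
    --out X.csv --phic-out phic.txt
percolearn onion --graph pl.edgelist --out onion.csv
percolearn scan-layers --matrix X.csv --labels y.csv --graph pl.edgelist --out scan.csv
percolearn confusion --matrix X.csv --columns bin.txt --delta 0.005 --out curve.csv
percolearn run --config study.yaml      # whole pipeline from one config
```

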