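# emgnet

Muscle functional-network analysis of multichannel surface EMG, aimed at one
practical question: **where should the few EMG sensors of a lower-limb
prosthesis sit on the residual limb so that they capture the most movement
information?**

The package is written for researchers in movement neuroscience and
prosthetics who record high-density surface EMG (here: 33 electrodes
V1…V33 at 2000 Hz over the front, back and side of the stump, during
repeated lift–hold–lower movements) and want a reproducible pipeline from
raw signals to a ranked, surface-covering sensor subset.  Because such
recordings are rarely shared, the package ships a synthetic-data module
that emulates the recording protocol with planted correlation groups and
planted causal directions, so every claim the pipeline makes can be checked
against ground truth.

## The analysis

1. **Functional network.** Channels are nodes.  Pairwise dependence is
   histogram mutual information over B = 16 equal-width bins,

   `MI(S,Q) = H(S) + H(Q) − H(S,Q)`,   `H(S) = −Σᵢ P(sᵢ) log₂ P(sᵢ)`,

   normalized by `√(H(S)·H(Q))` into the weighted adjacency `A(aᵢⱼ)` and
   thresholded at the largest TH that keeps the network connected with
   average degree `⟨k⟩ > 2 ln n` (6.99 for n = 33).
2. **Topology.** Degrees `kᵢ`, degree distribution `P(k) = nₖ/n`, local
   clustering `Cᵢ = 2Eᵢ/(kᵢ(kᵢ−1))`, average shortest-path length
   `L = Σ_{i≠j} d_{ij} / (n(n−1))`, and per-area mean degrees over the six
   electrode areas (two per stump surface).
3. **Node importance by contraction.** Network cohesion `∂(M) = 1/(nL)`;
   contracting node *i* merges it with its whole neighbourhood, and
   `IMC(i) = 1 − ∂(M)/∂(M×i)` scores how much the network tightens.  Nodes
   with `IMC > 0.5` (union over movement conditions) are the key nodes.
4. **Directed information flow.** Convergent cross-mapping between key-node
   pairs: delay-embed each series (`x(t) = ⟨x[t], x[t−τ], …⟩`), predict one
   channel from the other's manifold by simplex projection over the E+1
   nearest neighbours, and watch the Pearson skill *r* converge as the
   library grows.  A four-rule table on the converged skill difference
   `D = Mx − My` (thresholds 0.3 / 0.1 / 0.5) turns skill pairs into
   directed verdicts; per-condition verdicts are merged into one
   information-flow network.
5. **Sensor selection.** Nodes are ranked sources-first (longest incoming
   path, then out-degree − in-degree, then label) and the top *m* = 5 are
   adjusted minimally so every stump surface stays covered.

## Worked example

The canonical recovery scenario plants a strongly coupled side-surface
group (V24–V33, group strength 0.8) and one information source, V28,
driving V24 and V31:

```python
from emgnet import planted_sensor_scenario, run_pipeline, PipelineParams

report = run_pipeline(
    {"appropriate": planted_sensor_scenario(seed=0)},
    params=PipelineParams(seed=0, ccm_repeats=2),
)
print(report.threshold)                  # 0.05
print(list(report.key_nodes))            # ['V6', 'V9', 'V12', 'V13', 'V22',
                                         #  'V24', ..., 'V33']  (side group inside)
print([(e["src"], e["dst"]) for e in report.overall_directed.edges])
                                         # [('V28', 'V24'), ('V28', 'V31')]
print(report.selection.selected)         # ('V28', 'V6', 'V9', 'V12', 'V13')
```

The selected threshold (0.05) is the largest grid value keeping the network
connected with `⟨k⟩ > 6.99`; the key-node set contains the entire planted
side group (e.g. `IMC(V28) = 0.98` against 0.40 for a background channel);
cross-mapping recovers exactly the two planted arcs and nothing else; and
the driver heads the sensor ranking while the final five sensors still
cover all three stump surfaces.

The same stages are scriptable from the shell:

```bash
emgnet simulate --seed 3 --coupling V28:V24:0.1 --out rec.csv
emgnet network rec.csv --outdir net/
emgnet ccm rec.csv --nodes V28,V24,V1 --embedding 4 --outdir flow/
```

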