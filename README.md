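# mesograph

Weakly supervised scoring of mesothelioma tissue-microarray cores at
single-cell resolution.

Mesothelioma is subtyped by the relative amounts of epithelioid (round,
better prognosis) and sarcomatoid (spindle-shaped, aggressive) tumour
cells, but routine labels exist only per tissue core: epithelioid (E),
biphasic (B) or sarcomatoid (S). `mesograph` treats each core as a *bag*
of cells with an ordinal label along the sarcomatoid axis
(E = 0 < B = 1 < S = 2), builds a cell graph (nodes = detected cells,
edges between centroids ≤ 30 µm apart, 129 morphology / stain / texture
/ neighbourhood features per cell), and trains a dual-branch EdgeConv
graph network with jumping-knowledge concatenation:

    z_v^(s) = σ(α_s · f_s([h_v^(1) ‖ … ‖ h_v^(5)]) + β_s)   (and z_v^(e) likewise)
    Z       = mean_v ( z_v^(s) − z_v^(e) )  ∈ (−1, 1)

where α, β are per-core calibration scalars computed from the core's
mean feature vector. Supervision is a pairwise ranking hinge on bag
scores only, L = Σ_ij max(0, 1 − (Y_i − Y_j)(Z_i − Z_j)), with one head
ranking S > B > E and the other E > B > S. Although no cell-level label
is ever seen, the per-cell score z_v^(s) − z_v^(e) localises the
sarcomatoid component inside biphasic cores.

Because the clinical cohorts are access-controlled, the package ships a
synthetic TMA generator (hard-core point patterns of textured elliptical
cells in an H&E-like Beer–Lambert colour model, with planted per-cell
classes and regionally separated biphasic components) so the entire
pipeline — rendering, stain deconvolution, feature extraction, graph
building, training, evaluation, eigen-cell analysis — is testable end to
end. See `docs/methods.md` for the model, parameters and limitations.

## Worked example

```python
import mesograph as mg
from mesograph.evaluation import run_cross_validation
from mesograph.training import TrainConfig

cohort = mg.simulate_cohort((8, 8, 8), 2, seed=0, n_cells_range=(80, 140),
                            core_diameter=400.0)
result = run_cross_validation(
    cohort, seed=0, train_config=TrainConfig(seed=0, max_epochs=200))

print(f"pooled bag AUROC : {result.pooled_metrics['auroc']:.3f}")
print(f"instance AUROC   : {result.instance_auroc:.3f}")
for subtype in ("E", "B", "S"):
    print(f"mean Z [{subtype}]       : {result.mean_z_by_subtype[subtype]:+.3f}")
ss = result.test_scoresets[next(c.core_id for c in cohort
                                if c.subtype == 'B')]
gram = mg.mesogram(ss, n_bins=8)
print("MesoGram counts  :", gram.counts.tolist(),
      f"(core {gram.core_id}, n={gram.counts.sum()})")
```

prints (about two minutes on one CPU):

```
pooled bag AUROC : 0.969
instance AUROC   : 0.802
mean Z [E]       : -0.467
mean Z [B]       : +0.189
mean Z [S]       : +0.757
MesoGram counts  : [0, 3, 14, 23, 26, 25, 10, 2] (core core_003, n=103)
```

Held-out cores are mostly scored on the correct side of zero and the
mean bag scores respect the ordinal ordering S > B > E. The MesoGram is
the histogram of per-cell scores within one biphasic core — its spread
reflects the two cell populations. At this miniature scale (24 bags,
200 epochs) cell-level resolution is still modest; the full 90-bag
experiment below reaches instance AUROC ≈ 0.9 inside biphasic cores.

A thin CLI wraps the same library: `mesograph simulate | featurize |
build-graphs | train | predict | evaluate | eigencells` (every
subcommand takes `--seed`; run `mesograph --help`).

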