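# mirdsd

**From miRNA expression to a DNA-computing diagnosis.** `mirdsd` implements, as a
tested Python library, an analysis pipeline that turns a miRNA expression cohort
into a molecular classifier built from toehold-mediated DNA strand displacement
(DSD):

1. **Biomarker selection** — Welch-t differential expression on log2(FPKM+1),
   the DEG screen (|log2FC| > 1 and p < 0.01), and selection of the top two up-
   and down-regulated miRNAs; K-means (K = 10) representative cases per group.
2. **Co-expression network** — WGCNA-style unsigned network
   a<sub>ij</sub> = |cor(x<sub>i</sub>, x<sub>j</sub>)|<sup>β</sup> with the
   soft power β chosen by the scale-free topology fit (target R² ≥ 0.8 over
   β = 1…20), topological overlap, average-linkage module detection, module
   eigengenes, module–trait Pearson correlations and intramodular hub genes
   (kWithin, optionally trait-weighted).
3. **Circuit compilation** — a two-layer winner-take-all (WTA) circuit: each
   marker becomes an input strand at its FPKM value in nM; layer-1 gates
   release tumor-side or health-side outputs at rate |log2FC| × k with
   k = 0.003 nM⁻¹s⁻¹; the outputs compete for a limiting gate 3 set to the
   mean concentration of the health-channel inputs, releasing FAM (tumor) or
   ROX (health) fluorophores.
4. **Kinetics** — deterministic mass-action ODE trajectories (stiff-capable
   solver, rtol 1e-8 / atol 1e-10 nM, sampled every 10 s for 1000 s), an
   independent Gillespie stochastic simulator, and conserved-moiety mass
   balance checks.
5. **Classification** — endpoint FAM/ROX comparison with a detection floor
   and tie tolerance (indeterminate is a first-class call), cohort confusion
   summaries, lymph-node-count binning (≤15 / 16–28 / ≥29) and two-hub
   clinical-trait circuits.

A synthetic-cohort generator with planted differential markers, latent-factor
co-expression modules and module-driven clinical traits makes the entire
pipeline testable end to end without any data download. It is intended for
researchers prototyping expression-driven molecular classifiers and for
anyone who wants a reproducible, simulation-backed account of how a WTA DSD
readout behaves.

## Worked example

Compile and simulate one sample's diagnostic circuit
(`examples/04_circuit_simulation.py`):

```text
11 species, 6 reactions; gate3 = 17.0 nM
endpoint signals at t = 1000 s: FAM = 9.85 nM, ROX = 7.15 nM
conserved strand moieties: 5, max drift = 1.14e-13 nM
Gillespie check (50 runs, ~1e3 molecules): mean FAM = 9.95 nM vs ODE 9.85 nM
```

The health-channel inputs (20 and 14 nM) set gate 3 to their mean, 17 nM.
The tumor channel ends higher (FAM 9.85 > ROX 7.15 nM), so the winner-take-all
call is *positive*. Mass balance holds to solver precision and the stochastic
mean reproduces the deterministic endpoint.

Classify a 100-sample synthetic cohort end to end
(`examples/05_cohort_classification.py`):

```text
confusion table (rows: true class, columns: call):
            positive  negative  indeterminate
true_class
normal             0        50              0
tumor             50         0              0

per-class accuracy: {'normal': 1.0, 'tumor': 1.0}
overall accuracy (indeterminate = error): 1.000
```

With markers planted at log2FC ±2 and log-scale noise SD 0.5, the screen
recovers the planted panel and the circuit separates the groups perfectly.
The other `examples/` scripts cover cohort generation, biomarker selection,
the co-expression network and clinical-trait circuits; each prints the
quantities it computes and what they mean.

A thin CLI mirrors the library (`mirdsd run-all --config cfg.yaml --outdir out`,
plus `simulate-data`, `select-biomarkers`, `build-network`, `compile-circuit`,
`simulate`, `classify`).

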