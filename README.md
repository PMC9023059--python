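# altconf

Sampling **alternative protein conformations** with a structure-prediction
network, and analysing the resulting model ensembles.

Membrane transporters and GPCRs function by interconverting between
conformations (inward-/outward-facing, inactive/active), yet a prediction
network fed a deep multiple sequence alignment returns essentially one
state. Feeding it *stochastically subsampled, shallow* MSAs (as few as 16
sequences), with a single recycle and no relaxation, diversifies the output:
among ~50 models per MSA depth, both end states and intermediates appear.
`altconf` provides both halves of that workflow for structural biologists:

* **Protocol generation** — seeded A3M subsampling and machine-readable run
  specifications for an external ColabFold-compatible engine (inference is
  never run by this package; no GPU or weights required).
* **Ensemble analysis** — misfolded-decoy exclusion by coclustering,
  TM-score and Kabsch superposition, per-residue RMSF vs. experimental
  displacement with pLDDT filtering, and Cα-coordinate PCA with
  extreme-model selection.

## The statistics at the core

For a model scored against an experimental reference over the
sequence-mapped Cα pairs,

    TM = (1/L_ref) Σ_i 1 / (1 + (d_i/d0)²),   d0 = max(0.5, 1.24·(L_ref−15)^⅓ − 1.8),

maximized over rigid superpositions (fragment-seeded iterative inlier
refinement). Ensembles are placed in a common frame by iterative
mean-structure Kabsch alignment; per-residue flexibility is
RMSF_i = √⟨|x_i − ⟨x_i⟩|²⟩, compared by R² against the Cα displacement of
each residue between the two superposed experimental structures (residues
with pLDDT ≤ 75 excluded). The conformational landscape is the PCA of the
masked 3N Cα coordinate vectors; experimental references are projected into
the model-only basis, and the k most extreme PC1 models per side are the
candidates for each end state.

## Worked example

Everything below runs in seconds on a laptop using the built-in synthetic
two-state system (a 60-residue Cα coil whose residues 18–47 hinge by 10 Å
between end states A and B, 50 models interpolated between them with 0.5 Å
noise, plus 2 misfolded decoys):

```sh
altconf simulate-ensemble --out demo --seed 13
altconf run-analysis --ensemble demo/ens \
    --ref1 demo/stateA.pdb --ref2 demo/stateB.pdb --out demo/analysis
altconf tm-score demo/stateA.pdb demo/stateB.pdb
```

prints

```
wrote 52 models to demo/ens
bundle written to demo/analysis
{"aligned_pairs": 60, "d0": 2.611, "rmsd": 10.982, "score": 0.55764}
```

The TM-score line says the two end states share a fold (score 0.56 over 60
aligned pairs) but differ substantially — the hinge moiety sits ~11 Å RMSD
away under the score-optimal superposition. In `demo/analysis/`:

* `outliers.json` — both decoys excluded as `singleton/undersized cluster`;
  all 50 genuine models kept.
* `landscape.json` — PC1 captures 88.2 % of the ensemble variance, and the
  reference projections (−21.8 and +20.8) flank every model's PC1 value:
  the experimental states sit at the extremes of the sampled landscape.
* `correlation.json` — `displacement_rmsf_r_squared: 0.991`: the ensemble's
  per-residue flexibility tracks the displacement implied by the two
  references.
* `selection.json` — the top-1 models at the two PC1 extremes have TM ≈ 0.89
  to their nearer end state, and |Pearson r| between PC1 and TM-score is
  ≈ 0.97: picking models from the PC1 extremes picks the most accurate
  representatives of each conformation.

The protocol side is GPU-free to generate:

```sh
altconf subsample-msa --in query.a3m --out sub16.a3m --depth 16 --seed 7
altconf make-runspec --msa sub16.a3m --depth 5120
```

The emitted run specification encodes the protocol constants: 1 recycle, no
relaxation, 5 networks × 10 models (or 2 × 25 with templates, similarity
cutoff 1 %), `max_msa_clusters` 512 at depth 5120, one derived seed per
model.

## Layout

| module | contents |
|---|---|
| `altconf.msa` | A3M/FASTA I/O, seeded subsampling, Needleman–Wunsch identity |
| `altconf.structures` | PDB Cα traces, pLDDT, truncation, residue correspondence |
| `altconf.superpose` | Kabsch, TM-score, iterative-mean ensemble alignment |
| `altconf.ensemble_stats` | displacement/RMSF profiles, pLDDT filter, misfold coclustering |
| `altconf.landscape` | Cα PCA, reference projection, extreme-model selection |
| `altconf.protocol` | run specifications, depth ladder, template vetting |
| `altconf.fixtures` | synthetic two-state proteins, ensembles, alignments |
| `altconf.workflow` / `altconf.cli` | end-to-end bundle + `altconf` CLI |

See `docs/methods.md` for the full description of the models, defaults and
their rationale.
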