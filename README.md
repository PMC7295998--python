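# fpsubnet

Multimodal brain-network analysis of a target functional system that
splits into two opposed subnetworks, packaged as a tested, reusable
pipeline exercisable end-to-end on a synthetic cohort with planted
effects.

The pipeline:

1. **Synthetic cohort** (`fpsubnet.cohort`) — multi-subject, multi-run
   regional timeseries with planted subnetwork-system couplings,
   per-subject structural matrices with a planted block motif,
   probe-level gene expression with a planted within-subnetwork
   coexpression margin, and behavior scores tied to subnetwork
   amplitudes and inter-system coupling.
2. **Connectomics** (`fpsubnet.connectomics`) — Pearson functional
   connectivity matrices, system-level averaging, subnetwork-system
   coupling, subnetwork RMS activity, structural normalization and
   thresholding.
3. **Subnetwork detection** (`fpsubnet.wsbm`) — weighted stochastic
   block model (normal edge-weight model) fit by greedy maximum
   likelihood with restarts, z-Rand partition similarity, consensus
   partition, label-permutation null, and bootstrap comparison of block
   counts.
4. **Boundary control** (`fpsubnet.control`) — per-region boundary
   control over two target systems, top-percentile selection, and an
   enrichment test with both a permutation null and an exact
   hypergeometric oracle.
5. **Gene coexpression** (`fpsubnet.coexpression`) — probe-centered
   aggregation, parcel-parcel coexpression, and the bootstrap-over-genes
   / permute-membership test of within- vs between-subnetwork
   coexpression.
6. **Oscillator model** (`fpsubnet.hopf`) — networks of noisy
   Stuart-Landau (Hopf normal form) oscillators with diffusive
   structural coupling, Kuramoto synchrony, parameter sweeps, and the
   amplitude-manipulation / coupling-ablation experiments (4-, 192- and
   400-unit presets).
7. **Statistics** (`fpsubnet.stats`) — random-intercept multilevel model
   (profiled maximum likelihood, optional Huber robust weighting),
   repeated-measures correlation, paired-swap permutation test,
   Bonferroni correction.
8. **Pipeline** (`fpsubnet.pipeline`) — orchestrates everything and
   emits a JSON report with ten canonical sign checks (coupling signs,
   activity-to-coupling slopes, structural orderings, oscillator
   experiment signs).

## Run the tests

```bash
python -m pytest tests/                 # full suite incl. acceptance
python -m pytest tests/ --ignore=tests/test_acceptance.py   # fast units
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(closed forms, planted recovery, oracle equivalence, calibration); the
end-to-end criterion runs the full default study plus a 100-seed null
calibration and takes a few minutes.

## CLI

```bash
fpsubnet run --config study.yaml --out results/        # full synthetic study
fpsubnet generate --config study.yaml --out cohort/    # write cohort TSVs
fpsubnet fc cohort/timeseries/sub-000_run-0.tsv --out fc.tsv
fpsubnet fit-wsbm subgraph.tsv --k 2 --restarts 20 --seed 1 --out partition.tsv
fpsubnet boundary-control cs.tsv --parcellation parc.tsv --out-prefix bc
fpsubnet hopf --preset 4 --target SN-A --reps 5 --seed 1 --out table.tsv
```

A config is JSON or YAML with a mandatory integer `seed` and optional
per-stage sections (`cohort`, `wsbm`, `compare_k`, `boundary_control`,
`coexpression`, `hopf`, `stats`); unknown keys are rejected.  Minimal
example:

```yaml
seed: 7
wsbm:
  restarts: 20
hopf:
  reps: 5
```

All randomness derives from the master seed via documented per-stage
seed sequences, so identical config + seed reproduces the report.

## Data formats

Tab-delimited text throughout: matrices with a header row/column of
1-based region ids, timeseries as regions x timepoints, parcellations as
`region_id / system / subnetwork` tables, probe-level expression as long
`parcel / gene / probe / value` tables.  Reports are JSON.
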