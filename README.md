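# cubicdock

Symmetric docking of homomeric protein assemblies with cubic point-group
symmetry (tetrahedral, octahedral, icosahedral). A subunit structure —
typically a structure-predictor model with per-residue confidence in the
B-factor column — is placed by six rigid-body parameters (three Euler
angles about its center of mass; axial and radial translations z, x; a
rotation λ about the setup-fold axis) and expanded through the point group
into a 12-, 24- or 60-chain assembly. A differential-evolution memetic
optimizer searches this parameter space, guided by a fast backbone
point-cloud score (CloudContactScore) for clash-free packing and a
surrogate soft Lennard-Jones interface energy (Iscore) for selection.

The package covers the full pipeline on synthetic data: ensemble
preparation from predictor outputs (confidence filtering, terminal
trimming, redundancy pruning, oligomer parameter extraction), docking in
recapitulation / local / global modes (including the 180° orientation-flip
handling in global mode), the 1000 → 100 → 5 selection funnel, and
symmetry-aware evaluation (symmetric RMSD over fold-equivalent chain
assignments, per-interface DockQ with ΔSASA weighting, an assembly
TM-score, quality classification, and a run-resampling success estimator).
A fixtures module generates everything needed for end-to-end runs without
downloads: ideal helical/hairpin toy subunits, clash-free ideal cubic
assemblies, fake predictor ensembles and run tables.

## Command line

```sh
cubicdock show-defaults                      # print the full default config
cubicdock fixtures  --sym T --fold 3 --out toy/          # toy native + symdef
cubicdock dock      --mode recapitulate --sym T --fold 3 \
                    --ensemble toy_ensemble/ --symdef toy/native.symm \
                    --seed 1 --out run/
cubicdock evaluate  --model run/best_model.pdb --native toy/native.pdb \
                    --sym T --fold 3
cubicdock ensemble  --models models/ --manifest manifest.json \
                    --mode multimer --out prepared/
cubicdock select    --individuals run/individuals.csv --ensemble toy_ensemble/ \
                    --sym T --fold 3 --symdef toy/native.symm --out final/
cubicdock ccs-score --subunit toy/subunit.pdb --symdef toy/native.symm
```

Every run writes a `provenance.json` (config, config hash, seed, version).
Config files are YAML with the published protocol as defaults (population
100, 50 generations, mutation/recombination 0.1/0.7, trimming thresholds
90/70/70, redundancy pruning 0.1 Å with 0.005 Å relaxation steps, …);
unknown keys are rejected.

## Layout

| module | role |
| --- | --- |
| `structure_io` | PDB + score-manifest I/O, array-backed atomic data model |
| `symmetry` | point groups, six-parameter placement, expansion, subsystem, bounds, parameter extraction |
| `ccs` | CloudContactScore: surface point cloud, clashes, H-bond surrogate, CB–CB contacts |
| `energy` | surrogate interface energy (Iscore) and the fast assembly scorer |
| `engine` | DE memetic optimizer: sliding, Monte-Carlo local search, selection, backbone trials |
| `ensemble` | predictor-output filtering, trimming, pruning, oligomer parameter extraction |
| `evaluation` | symmetric RMSD, DockQ, pairwise DockQ, TM-score, quality classes, bootstrap |
| `selection` | harvest → k-means clustering → refine → five ranked models |
| `fixtures` | synthetic toys, ideal assemblies, fake ensembles, run tables |
| `config`, `cli` | YAML run configuration, provenance, `cubicdock` subcommands |
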