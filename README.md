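# poserescore

Rescoring toolkit for protein–ligand binding affinity prediction from
docked poses. It implements:

- **Vina energy terms** — the five pairwise interaction terms (gauss1,
  gauss2, repulsion, hydrophobic, H-bonding) summed inter- and
  intra-molecularly, the composite score with rotor penalty, and the
  kcal/mol → pKd conversion (`poserescore.vina`).
- **Elemental contact features** — the 36 occurrence counts of
  (ligand element × protein element) heavy-atom pairs within a distance
  cutoff, default 12 Å (`poserescore.contacts`).
- **Pose-selection schemes 1–6** — crystal pose, best-scored docked pose,
  lowest-RMSD pose, affinity-closest pose, all nine poses, top two poses —
  with the padding rule for short pose lists, producing feature vectors of
  length 11/47 (single pose), 21/93 (two poses) or 91/415 (nine poses)
  (`poserescore.schemes`).
- **Four scoring models** — fixed-weight Vina; multiple linear regression
  with a two-stage rotor-penalty grid search (101 then 31 candidates);
  and random forests (500 trees, mtry selected by out-of-bag RMSE, ten
  seeds) on the 11-feature or 47-feature sets (`poserescore.models`).
- **Evaluation** — RMSE, SD (residual SD of the measured-on-predicted
  regression), Pearson/Spearman correlation, heavy-atom pose RMSD without
  superposition, redocking success rates at the 2 Å threshold, and the
  pose-error vs prediction-error correlation analysis
  (`poserescore.metrics`).
- **Synthetic fixtures** — seeded generators for receptors, ligands, pose
  ensembles with controlled RMSD and affinities with known feature
  dependence, written as PDBQT/CSV trees, so everything is testable
  offline (`poserescore.synthetic`).

Structures are read and written as PDBQT (multi-MODEL docking output with
`REMARK VINA RESULT` and `TORSDOF` records); plain PDB is accepted for
receptors. Waters are removed on load; metal ions are retained.

## Command-line usage

All workflows are under one entry point:

```sh
# generate a synthetic PDBbind-like directory tree
poserescore simulate --n 30 --poses 5 --seed 1 --out data/train
poserescore simulate --n 15 --poses 5 --seed 2 --out data/test

# feature table for a scheme / feature set
poserescore featurize --data data/train --scheme 2 --features vinaelem47 --out features.csv

# train and apply a model
poserescore train --data data/train --model rf-vinaelem --scheme 2 \
    --seeds 10 --trees 500 --out rf.joblib
poserescore score --model-file rf.joblib --data data/test
poserescore evaluate --model-file rf.joblib --data data/test --out report.json

# per-pose RMSD against the crystal pose
poserescore rmsd --crystal data/test/cmpl0001/ligand_crystal.pdbqt \
    --docked data/test/cmpl0001/ligand_docked.pdbqt

# the full (model × train-scheme × test-scheme) evaluation matrix
poserescore matrix --train-dir data/train --test-dir data/test \
    --schemes 1:1,1:2,2:1,2:2 --models vina,mlr,rf-vina,rf-vinaelem \
    --out matrix.csv
```

Schemes 3 and 4 are valid for training only; requesting them at test time
is an error. Forest and MLR selection criteria default to deployable
choices (OOB / cross-validated RMSE); `--selection test` reproduces the
held-out-set selection convention used for benchmarking.

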