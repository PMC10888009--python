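# morphnet

Single-subject gray-matter **morphological connectomes** and everything
downstream of them:

1. **KLS networks** — per-subject 90×90 similarity matrices over the AAL
   non-cerebellar parcellation. Each region's gray-matter intensity samples
   are turned into a kernel-density profile on a subject-shared grid, and
   each region pair is scored with `KLS = exp(−(KL(P‖Q) + KL(Q‖P)))`
   (1 = identical distributions, → 0 = disjoint).
2. **Graph metrics** — binary graphs at sparsity thresholds 0.10–0.34
   (step 0.01); global metrics (Cp, Lp, γ, λ, σ, Eglob, Eloc; normalization
   against 100 degree-preserving Maslov–Sneppen rewired references) and
   nodal metrics (degree, nodal efficiency, betweenness), each summarized
   by the trapezoidal AUC across the sweep.
3. **Group statistics** — two-tailed permutation tests on AUC values
   (10,000 permutations by default, +1-smoothed p), Benjamini–Hochberg FDR
   within each nodal metric × contrast family, and partial correlations
   with clinical scores using age and sex as covariates.
4. **Classification** — connectome upper-triangle features (4005 full /
   105 for the 15-region submatrix), per-feature Gaussian-process
   residualization of the 3-level medication code, optional autoencoder or
   supervised-network dimensionality reduction, SVM / random forest /
   gradient-boosted-tree classifiers, stratified 5-fold CV with all
   fitting confined to training folds, balanced accuracy / sensitivity /
   specificity, and label-permutation validation.
5. **Synthetic cohorts** — a first-class generator producing subject
   tables and per-region intensity samples with planted group effects,
   covariates, medication confounds, and score coupling, tuned so default
   cohorts sit in the small-world regime (σ > 1 across the whole sweep).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the heavyweight end-to-end criteria
(small-world sweep validation, oracle equivalence, statistical calibration,
effect recovery, classification sanity); the rest are per-module unit and
property tests.

## CLI

```bash
morphnet simulate --out run/ --seed 1 --n-per-group "HC=20,MDD=20,BD=20"
morphnet build-networks --subjects run/subjects.csv --samples run/samples.csv --out run/
morphnet metrics --matrices run/matrices --out run/
morphnet validate-sweep --matrices run/matrices
morphnet stats --out run/
morphnet classify --out run/ --task bd-vs-mdd --features submatrix --reducer dnn --model xgb
morphnet run-all --config config.yaml
```

`run-all` executes the whole pipeline from a YAML config (see
`morphnet.pipeline.RunConfig` for the keys) and writes a single
deterministic `results.json` bundle; per-subject matrices and AUC tables
are cached as text files and reruns skip completed stages.

Input formats: subject table CSV (`subject_id, group, age, sex,
medication_code, hamd, hama, ymrs`), long-format samples CSV
(`subject_id, region_label, value`), matrices as labeled CSV. An optional
NIfTI entry point (`morphnet.io_formats.extract_roi_samples`) pulls
per-parcel intensity samples out of a GM volume + integer atlas pair.

## Layout

```
src/morphnet/
  io_formats.py        readers/writers, AAL-90 canonical order, NIfTI extraction
  synthetic_cohort.py  cohort generator (CohortDesign / generate_cohort)
  kls_network.py       KDE density profiles, KL divergence, KLS matrices
  graph_metrics.py     thresholding, global/nodal metrics, rewiring, AUC sweeps
  group_stats.py       permutation tests, BH-FDR, partial correlations
  classification.py    features, GP confound residualization, reducers, CV grid
  pipeline.py / cli.py orchestration, caching, and the `morphnet` CLI
```
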