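# fatetrace

Analysis toolkit for bifurcating single-cell differentiation data, where
a common progenitor population (P) splits into two fates (an adipogenic
upper branch U and a structural lower branch L). The package covers the
full desk-scale pipeline:

- **synthetic** — generators with planted ground truth: bifurcating
  negative-binomial UMI counts (branch-specific genes with planted
  divergence times and kinetic archetypes, library-size variation,
  mitochondrial genes, optional dedifferentiating cells), two-component
  signature mixtures, and dot images for the counting stage.
- **io_qc** — 10x-style MTX / dense CSV readers, QC filtering (detected
  genes in (200, 9000), UMIs ≤ 120 000, mitochondrial fraction ≤ 8 %
  with an on/off switch, genes expressed in ≥ 3 cells), log
  normalization to 10 000 counts per cell, OLS residualization against
  technical covariates.
- **trajectory** — stretched pseudotime (every root-to-leaf path mapped
  to [0, 100]), branch × pseudotime-decile stratification (30 strata for
  three branches), and a simplified PCA → k-means → MST bifurcation
  inference with marker-based branch orientation.
- **branch_genes** — likelihood-ratio test for branch-dependent genes
  (full model `expr ~ spline(t) + branch + spline(t):branch` vs reduced
  `expr ~ spline(t)` on U/L cells), BH correction, the q < 0.05 and
  |avg logFC| > 0.3 filters, and hierarchical kinetic clustering of
  branch-dependent expression curves (k = 6 by default).
- **divergence** — Nadaraya–Watson smoothing of per-branch expression
  onto a [0, 100] grid and divergence-point calling: t\* is the earliest
  grid point from which the between-branch gap keeps its sign (and, in
  strict mode, at least the minimum magnitude) through the end of the
  axis; genes that cross back are rejected as non-persistent.
- **deconv** — stratum profiles (non-log means) and two-component
  simplex-constrained least-squares estimation of brown/white content.
- **enrichment** — one-tailed cumulative hypergeometric gene-set
  enrichment with BH correction, and the directional z-score
  `(up − down) / sqrt(count)`.
- **label_transfer** — joint PCA embedding over shared genes and kNN
  label transfer with vote-fraction confidences.
- **imaging** — nuclei dot counting: greyscale conversion, multi-Otsu
  background removal, 8-connectivity components, knee-point maximum-size
  gating (capped by a hardcoded maximum), min/max size gates, count.
- **pipeline / cli** — orchestrated end-to-end runs with a YAML config,
  stage toggles and a SHA-256 reproducibility manifest.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (stratification
arithmetic, stretched-pseudotime endpoints, divergence recovery on 200
planted genes, branch-test calibration/power, deconvolution recovery,
hypergeometric p vs exhaustive enumeration, z-score formula, exact dot
counts, kNN transfer accuracy, kinetic-cluster recovery), one test per
criterion. Unit suites check each operation against independent oracles
(brute-force suffix enumeration, grid search, flood fill, exhaustive
threshold search, literal combinatorial enumeration).

## CLI

```sh
fatetrace simulate --n-cells 800 --n-genes 500 --seed 1 --out sim/
fatetrace qc --counts sim/ --out qc/            # thresholds as flags
fatetrace trajectory --counts qc/ --out traj.csv
fatetrace branchtest --counts qc/ --meta traj.csv --out branch.csv
fatetrace divergence --counts qc/ --meta traj.csv --delta 0.25 --out div.csv
fatetrace deconv --counts qc/ --meta traj.csv --signature sig.csv --out frac.csv
fatetrace enrich --query genes.txt --gmt terms.gmt --universe all.txt --out enr.csv
fatetrace transfer --ref ref/ --ref-labels labels.csv --query qry/ --out pred.csv
fatetrace countdots image.png --min-size 20 --max-size 2000 --out report.json
fatetrace run-all --config config.yaml --out run/
```

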